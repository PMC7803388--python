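"""Synthetic alignment-level fixtures with planted vector integrations.

Targeted capture of vector-containing fragments followed by paired-end
sequencing and local alignment yields, around each true integration, a
characteristic signature: junction-spanning reads split between a genome
scaffold and the vector scaffold (primary alignment plus SA-tagged
supplementary), flanking read pairs whose depth decays with distance from
the junction (capture probability falls off away from the probed vector),
PCR duplicates, off-target genome pairs, vector-internal pairs, and the
occasional low-quality spurious chimera.  This module emits that
signature directly as SAM records with known ground truth, so the caller,
capture statistics and clonality stages are testable hermetically —
without an aligner, probes or sequencing data.

Reads are emitted as alignments, not as FASTQ through a real aligner, and
sequence content is i.i.d. uniform bases: repeat-driven mapping failures
are modeled abstractly by the ``suppress_sa`` truth flag (genome-side
alignments whose vector half could not be placed), not at sequence level.
All randomness flows from one seed; a fixed seed gives byte-identical
output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alignment import AlignmentRecord, ReferenceSet, parse_alignment_line
from .errors import ConfigurationError, PlacementError

__all__ = [
    "IntegrationTruth",
    "SimConfig",
    "SimResult",
    "make_reference",
    "write_fasta",
    "simulate_sam",
    "preset",
    "study_samples",
    "make_study_reference",
    "PRESET_NAMES",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class IntegrationTruth:
    """One planted vector–genome junction (simulator ground truth).

    ``vector_end`` follows the caller's labeling: "left" means the low-
    coordinate vector terminus abuts the genome (and the genome flank
    covered by capture extends to the *left* of ``genome_pos``); "right"
    is the mirror case.  Per-junction overrides (``support``, ``mapq``,
    NM values) exist so filter behavior can be probed junction by
    junction; ``suppress_sa`` emits the genome-side alignments without
    their SA tag, emulating a vector half that maps ambiguously (e.g. to
    a duplicated vector element) and therefore yields no called site.
    """

    scaffold: str
    genome_pos: int
    vector_end: str  # "left" | "right"
    vector_pos: int
    microdeletion: int = 0  # genome bp lost at the junction; sequence-level only
    support: int | None = None  # override SimConfig.support_per_junction
    mapq: int = 60
    nm_genome: int = 0
    nm_vector: int = 0
    suppress_sa: bool = False


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    Defaults mirror the multiplexed clonality runs this simulator
    emulates: 100 bp paired-end reads from ~250 bp fragments, and a
    capture probability that decays with distance from the junction.
    """

    read_len: int = 100
    fragment_mean: int = 250
    fragment_sd: int = 30
    support_per_junction: int = 20
    capture_decay: float = 0.01  # per-base decay of flank capture probability
    background_pairs_per_junction: int = 15
    vector_only_pairs: int = 20
    genome_only_pairs: int = 10
    unmapped_pairs: int = 2
    dup_rate: float = 0.1
    n_decoys: int = 0
    decoy_mapq: int = 10
    decoy_support: int = 2
    seed: int = 0
    sample: str = "sample"

    def __post_init__(self) -> None:
        for name in ("capture_decay", "dup_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        if self.read_len < 40:
            raise ConfigurationError("read_len must be >= 40")

    def replace(self, **changes) -> "SimConfig":
        return dataclasses.replace(self, **changes)


def make_reference(
    n_scaffolds: int,
    scaffold_len: int,
    vector_len: int,
    seed: int,
    vector_name: str = "vector",
) -> tuple[dict[str, str], ReferenceSet]:
    """Random genome scaffolds plus the appended vector scaffold.

    Returns the sequences (name -> string) and the matching
    :class:`ReferenceSet`.  Deterministic under ``seed``.
    """
    if n_scaffolds < 1:
        raise ConfigurationError("n_scaffolds must be >= 1")
    if scaffold_len < 1000 or vector_len < 1000:
        raise ConfigurationError("scaffold/vector lengths must be >= 1000 bp")
    rng = np.random.default_rng(seed)
    sequences: dict[str, str] = {}
    for i in range(1, n_scaffolds + 1):
        seq = rng.choice(_BASES, size=scaffold_len)
        sequences[f"scaffold_{i}"] = seq.tobytes().decode()
    sequences[vector_name] = rng.choice(_BASES, size=vector_len).tobytes().decode()
    refs = ReferenceSet(
        scaffold_lengths={f"scaffold_{i}": scaffold_len for i in range(1, n_scaffolds + 1)},
        vector_name=vector_name,
        vector_length=vector_len,
    )
    return sequences, refs


def write_fasta(sequences: Mapping[str, str], path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, path, "fasta")


@dataclass
class SimResult:
    """Simulated SAM text plus the planted-junction truth table."""

    header: str
    lines: list[str]
    truth: pd.DataFrame
    refs: ReferenceSet

    def sam_text(self) -> str:
        return self.header + "".join(line + "\n" for line in self.lines)

    def write_sam(self, path: str) -> None:
        with open(path, "w") as handle:
            handle.write(self.sam_text())

    def write_truth(self, path: str) -> None:
        self.truth.to_csv(path, sep="\t", index=False)

    def iter_records(self) -> Iterator[AlignmentRecord]:
        header = self.refs.to_pysam_header()
        for i, line in enumerate(self.lines, start=1):
            yield parse_alignment_line(line, header, line_number=i)


def _sam_line(
    qname: str,
    flag: int,
    rname: str,
    pos: int,
    mapq: int,
    cigar: str,
    seq: str,
    nm: int | None = None,
    sa: str | None = None,
    rnext: str = "*",
    pnext: int = 0,
) -> str:
    qual = "I" * len(seq) if seq != "*" else "*"
    fields = [
        qname,
        str(flag),
        rname,
        str(pos),
        str(mapq),
        cigar,
        rnext,
        str(pnext),
        "0",
        seq,
        qual,
    ]
    if nm is not None:
        fields.append(f"NM:i:{nm}")
    if sa is not None:
        fields.append(f"SA:Z:{sa}")
    return "\t".join(fields)


# SAM FLAG values used by the emitter
_MATE1 = 0x1 | 0x2 | 0x20 | 0x40  # 99: paired, proper, mate reverse, first
_MATE2 = 0x1 | 0x2 | 0x10 | 0x80  # 147: paired, proper, reverse, second
_SUPP = 0x800
_DUP = 0x400
_UNMAPPED1 = 0x1 | 0x4 | 0x8 | 0x40  # 77
_UNMAPPED2 = 0x1 | 0x4 | 0x8 | 0x80  # 141


def _check_truth(truth: IntegrationTruth, refs: ReferenceSet, config: SimConfig) -> None:
    if truth.scaffold not in refs.scaffold_names:
        raise PlacementError(f"unknown scaffold {truth.scaffold!r}")
    scaffold_len = refs.length(truth.scaffold)
    margin = 2 * config.read_len
    if not margin < truth.genome_pos <= scaffold_len - margin:
        raise PlacementError(
            f"junction at {truth.scaffold}:{truth.genome_pos} too close to a "
            f"scaffold edge for {config.read_len} bp reads"
        )
    expected_end = "left" if 2 * truth.vector_pos <= refs.vector_length else "right"
    if expected_end != truth.vector_end:
        raise PlacementError(
            f"vector_pos {truth.vector_pos} lies in the {expected_end} half of the "
            f"vector but vector_end is {truth.vector_end!r}"
        )
    if truth.vector_end == "right" and truth.vector_pos <= config.read_len:
        raise PlacementError("right-end vector_pos leaves no room for the vector half")
    if (
        truth.vector_end == "left"
        and truth.vector_pos + config.read_len > refs.vector_length
    ):
        raise PlacementError("left-end vector_pos leaves no room for the vector half")


def _substr(sequences: Mapping[str, str] | None, name: str, start: int, length: int) -> str:
    """1-based inclusive substring, or placeholder when no sequences given."""
    if sequences is None:
        return ""
    return sequences[name][start - 1 : start - 1 + length]


class _Emitter:
    """Accumulates read pairs and applies duplicate copies at the end."""

    def __init__(self, config: SimConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        self.pairs: list[list[str]] = []
        self._n = 0

    def next_qname(self, tag: str) -> str:
        self._n += 1
        return f"{self.config.sample}:{tag}:{self._n:06d}"

    def add_pair(self, lines: list[str]) -> None:
        self.pairs.append(lines)

    def finish(self) -> list[str]:
        out: list[str] = []
        for pair in self.pairs:
            out.extend(pair)
            if self.rng.random() < self.config.dup_rate:
                for line in pair:
                    fields = line.split("\t")
                    fields[0] = fields[0] + ":dup"
                    fields[1] = str(int(fields[1]) | _DUP)
                    out.append("\t".join(fields))
        return out


def _emit_junction(
    emitter: _Emitter,
    truth: IntegrationTruth,
    refs: ReferenceSet,
    config: SimConfig,
    sequences: Mapping[str, str] | None,
    tag: str,
) -> None:
    """Emit junction-spanning pairs for one planted junction.

    Each pair: mate 1 is the split read (genome-side primary with SA tag
    plus the mirrored vector-side supplementary record), mate 2 a fully
    genomic flank read at a capture-decayed distance.
    """
    rng = emitter.rng
    read_len = config.read_len
    support = truth.support if truth.support is not None else config.support_per_junction
    scaffold_len = refs.length(truth.scaffold)
    vec = refs.vector_name

    for _ in range(support):
        g = int(rng.integers(20, read_len - 19))  # genome bases in the split read
        v = read_len - g
        qname = emitter.next_qname(tag)
        if truth.vector_end == "right":
            # read = vector suffix + genome; genome flank extends rightward
            genome_cigar = f"{v}S{g}M"
            genome_aln_pos = truth.genome_pos
            vector_cigar = f"{v}M{g}S"
            vector_aln_pos = truth.vector_pos - v
            seq = (
                _substr(sequences, vec, vector_aln_pos, v)
                + _substr(sequences, truth.scaffold, genome_aln_pos, g)
            ) or "*"
        else:
            # read = genome + vector prefix; genome flank extends leftward
            genome_cigar = f"{g}M{v}S"
            genome_aln_pos = truth.genome_pos - g
            vector_cigar = f"{g}S{v}M"
            vector_aln_pos = truth.vector_pos
            seq = (
                _substr(sequences, truth.scaffold, genome_aln_pos, g)
                + _substr(sequences, vec, vector_aln_pos, v)
            ) or "*"
        if genome_aln_pos < 1 or vector_aln_pos < 1:
            raise PlacementError(f"read placement escapes reference at {truth}")

        # mate 2: genome-only flank read, capture-decayed distance from junction
        gap = int(rng.geometric(config.capture_decay))
        if truth.vector_end == "right":
            mate2_pos = min(truth.genome_pos + g + gap, scaffold_len - read_len + 1)
        else:
            mate2_pos = max(truth.genome_pos - g - gap - read_len + 1, 1)
        mate2_seq = _substr(sequences, truth.scaffold, mate2_pos, read_len) or "*"

        lines = [
            _sam_line(
                qname,
                _MATE1,
                truth.scaffold,
                genome_aln_pos,
                truth.mapq,
                genome_cigar,
                seq,
                nm=truth.nm_genome,
                sa=(
                    None
                    if truth.suppress_sa
                    else f"{vec},{vector_aln_pos},+,{vector_cigar},{truth.mapq},{truth.nm_vector};"
                ),
                rnext="=",
                pnext=mate2_pos,
            )
        ]
        if not truth.suppress_sa:
            lines.append(
                _sam_line(
                    qname,
                    _MATE1 | _SUPP,
                    vec,
                    vector_aln_pos,
                    truth.mapq,
                    vector_cigar,
                    seq,
                    nm=truth.nm_vector,
                    sa=f"{truth.scaffold},{genome_aln_pos},+,{genome_cigar},{truth.mapq},{truth.nm_genome};",
                    rnext=truth.scaffold,
                    pnext=mate2_pos,
                )
            )
        lines.append(
            _sam_line(
                qname,
                _MATE2,
                truth.scaffold,
                mate2_pos,
                60,
                f"{read_len}M",
                mate2_seq,
                nm=0,
                rnext="=",
                pnext=genome_aln_pos,
            )
        )
        emitter.add_pair(lines)

    # flanking genome-only pairs with capture-decayed depth
    for _ in range(config.background_pairs_per_junction):
        qname = emitter.next_qname(tag + ":bg")
        d1 = int(rng.geometric(config.capture_decay))
        d2 = d1 + int(rng.normal(config.fragment_mean, config.fragment_sd))
        if truth.vector_end == "right":
            p1 = min(truth.genome_pos + d1, scaffold_len - read_len + 1)
            p2 = min(truth.genome_pos + max(d2, d1), scaffold_len - read_len + 1)
        else:
            p1 = max(truth.genome_pos - d1 - read_len + 1, 1)
            p2 = max(truth.genome_pos - max(d2, d1) - read_len + 1, 1)
        emitter.add_pair(
            [
                _sam_line(
                    qname, _MATE1, truth.scaffold, p1, 60, f"{read_len}M",
                    _substr(sequences, truth.scaffold, p1, read_len) or "*",
                    nm=0, rnext="=", pnext=p2,
                ),
                _sam_line(
                    qname, _MATE2, truth.scaffold, p2, 60, f"{read_len}M",
                    _substr(sequences, truth.scaffold, p2, read_len) or "*",
                    nm=0, rnext="=", pnext=p1,
                ),
            ]
        )


def simulate_sam(
    truths: Sequence[IntegrationTruth],
    config: SimConfig,
    refs: ReferenceSet,
    sequences: Mapping[str, str] | None = None,
) -> SimResult:
    """Emit SAM records for planted junctions plus background and decoys.

    Junction-spanning pairs are mutually consistent split alignments
    (complementary clip lengths, matching SA coordinates, MAPQ/NM from
    the truth record); background pairs populate the other mapping
    categories; ``dup_rate`` of pairs is re-emitted duplicate-flagged;
    decoy chimeras carry ``decoy_mapq``.
    """
    for truth in truths:
        _check_truth(truth, refs, config)
    rng = np.random.default_rng(config.seed)
    emitter = _Emitter(config, rng)

    for i, truth in enumerate(truths, start=1):
        _emit_junction(emitter, truth, refs, config, sequences, tag=f"jx{i}")

    # decoy chimeras: structurally identical split reads at random spots,
    # but carrying the configured (low) MAPQ and thin support
    scaffolds = sorted(refs.scaffold_names)
    for d in range(config.n_decoys):
        scaffold = scaffolds[int(rng.integers(0, len(scaffolds)))]
        margin = 2 * config.read_len + 1
        genome_pos = int(rng.integers(margin, refs.length(scaffold) - margin))
        vector_pos = int(
            rng.integers(refs.vector_length // 2 + config.read_len + 1, refs.vector_length)
        )
        decoy = IntegrationTruth(
            scaffold=scaffold,
            genome_pos=genome_pos,
            vector_end="right",
            vector_pos=vector_pos,
            support=config.decoy_support,
            mapq=config.decoy_mapq,
        )
        _emit_junction(
            emitter, decoy, refs, config.replace(background_pairs_per_junction=0),
            sequences, tag=f"decoy{d + 1}",
        )

    read_len = config.read_len
    # off-target pairs: vector-internal, distant genome, unmapped
    for _ in range(config.vector_only_pairs):
        qname = emitter.next_qname("vec")
        p1 = int(rng.integers(1, refs.vector_length - 2 * read_len))
        p2 = p1 + int(abs(rng.normal(config.fragment_mean - read_len, config.fragment_sd)))
        p2 = min(p2, refs.vector_length - read_len + 1)
        emitter.add_pair(
            [
                _sam_line(
                    qname, _MATE1, refs.vector_name, p1, 60, f"{read_len}M",
                    _substr(sequences, refs.vector_name, p1, read_len) or "*",
                    nm=0, rnext="=", pnext=p2,
                ),
                _sam_line(
                    qname, _MATE2, refs.vector_name, p2, 60, f"{read_len}M",
                    _substr(sequences, refs.vector_name, p2, read_len) or "*",
                    nm=0, rnext="=", pnext=p1,
                ),
            ]
        )
    for _ in range(config.genome_only_pairs):
        qname = emitter.next_qname("gen")
        scaffold = scaffolds[int(rng.integers(0, len(scaffolds)))]
        p1 = int(rng.integers(1, refs.length(scaffold) - 2 * read_len))
        p2 = p1 + int(abs(rng.normal(config.fragment_mean - read_len, config.fragment_sd)))
        p2 = min(p2, refs.length(scaffold) - read_len + 1)
        emitter.add_pair(
            [
                _sam_line(
                    qname, _MATE1, scaffold, p1, 60, f"{read_len}M",
                    _substr(sequences, scaffold, p1, read_len) or "*",
                    nm=0, rnext="=", pnext=p2,
                ),
                _sam_line(
                    qname, _MATE2, scaffold, p2, 60, f"{read_len}M",
                    _substr(sequences, scaffold, p2, read_len) or "*",
                    nm=0, rnext="=", pnext=p1,
                ),
            ]
        )
    for _ in range(config.unmapped_pairs):
        qname = emitter.next_qname("unm")
        seq = "N" * read_len if sequences is not None else "*"
        emitter.add_pair(
            [
                _sam_line(qname, _UNMAPPED1, "*", 0, 0, "*", seq),
                _sam_line(qname, _UNMAPPED2, "*", 0, 0, "*", seq),
            ]
        )

    header_lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name in list(refs.scaffold_lengths) + [refs.vector_name]:
        header_lines.append(f"@SQ\tSN:{name}\tLN:{refs.length(name)}")
    header_lines.append("@PG\tID:clonesite\tPN:clonesite")
    header = "".join(line + "\n" for line in header_lines)

    truth_df = pd.DataFrame(
        [
            {
                "scaffold": t.scaffold,
                "pos": t.genome_pos,
                "vector_end": t.vector_end,
                "vector_pos": t.vector_pos,
                "planted_support": (
                    t.support if t.support is not None else config.support_per_junction
                ),
                "suppressed": t.suppress_sa,
            }
            for t in truths
        ]
    )
    return SimResult(header=header, lines=emitter.finish(), truth=truth_df, refs=refs)


# ---------------------------------------------------------------------------
# Presets emulating the validation cell line and the five clonal lineages
# ---------------------------------------------------------------------------

# shared reference geometry for all presets
STUDY_N_SCAFFOLDS = 7
STUDY_SCAFFOLD_LEN = 50_000
STUDY_VECTOR_LEN = 8_000
# junction coordinates on the linearized vector: one near each terminus
VECTOR_LEFT_POS = 150
VECTOR_RIGHT_POS = 7_850

PRESET_NAMES = ("sh87", "lineage_A", "lineage_B", "lineage_C", "lineage_D", "lineage_E")


def _both_ends(scaffold: str, pos: int, separation: int) -> list[IntegrationTruth]:
    """One insertion observed from both sides: a left-end junction (genome
    flank to the left) and a right-end junction ``separation`` bp away."""
    return [
        IntegrationTruth(scaffold, pos, "left", VECTOR_LEFT_POS),
        IntegrationTruth(scaffold, pos + separation, "right", VECTOR_RIGHT_POS),
    ]


def preset(name: str) -> tuple[list[IntegrationTruth], SimConfig]:
    """Named integration structures emulating the study's cell lines.

    * ``sh87`` — deep single-sample validation line: three integration
      loci, both vector ends recovered at each (six junctions), 250 bp
      reads from ~500 bp fragments.
    * ``lineage_A`` — one locus, both ends ~30 bp apart.
    * ``lineage_B`` / ``lineage_D`` — one locus, a single end called.
    * ``lineage_C`` — one called end plus a second end < 50 bp away whose
      vector half maps ambiguously (suppressed SA) and is never called.
    * ``lineage_E`` — three loci on distinct scaffolds, both ends ~100 bp
      apart at one of them (four junctions).
    """
    multiplex = SimConfig(
        read_len=100,
        fragment_mean=250,
        support_per_junction=12,
        background_pairs_per_junction=15,
        vector_only_pairs=20,
        genome_only_pairs=10,
        unmapped_pairs=2,
        dup_rate=0.1,
        n_decoys=2,
        sample=name,
    )
    if name == "sh87":
        truths = (
            _both_ends("scaffold_1", 20_000, 40)
            + _both_ends("scaffold_2", 25_000, 40)
            + _both_ends("scaffold_3", 30_000, 40)
        )
        config = SimConfig(
            read_len=250,
            fragment_mean=500,
            fragment_sd=60,
            support_per_junction=25,
            background_pairs_per_junction=40,
            vector_only_pairs=40,
            genome_only_pairs=20,
            unmapped_pairs=4,
            dup_rate=0.1,
            n_decoys=2,
            sample="sh87",
        )
        return truths, config
    if name == "lineage_A":
        return _both_ends("scaffold_1", 20_000, 30), multiplex
    if name == "lineage_B":
        return [IntegrationTruth("scaffold_2", 30_000, "right", VECTOR_RIGHT_POS)], multiplex
    if name == "lineage_C":
        return (
            [
                IntegrationTruth("scaffold_3", 15_000, "right", VECTOR_RIGHT_POS),
                IntegrationTruth(
                    "scaffold_3", 15_045, "left", VECTOR_LEFT_POS, suppress_sa=True
                ),
            ],
            multiplex,
        )
    if name == "lineage_D":
        return [IntegrationTruth("scaffold_4", 35_000, "left", VECTOR_LEFT_POS)], multiplex
    if name == "lineage_E":
        truths = [
            IntegrationTruth("scaffold_5", 12_000, "right", VECTOR_RIGHT_POS),
            *_both_ends("scaffold_6", 22_000, 100),
            IntegrationTruth("scaffold_7", 18_000, "left", VECTOR_LEFT_POS),
        ]
        return truths, multiplex
    raise ConfigurationError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")


def make_study_reference(seed: int = 0) -> tuple[dict[str, str], ReferenceSet]:
    """Reference shared by all presets: 7 scaffolds plus the vector."""
    return make_reference(
        STUDY_N_SCAFFOLDS, STUDY_SCAFFOLD_LEN, STUDY_VECTOR_LEN, seed
    )


def study_samples(seed: int = 0) -> dict[str, tuple[list[IntegrationTruth], SimConfig]]:
    """The full multiplexed clonality study: 32 samples from 5 lineages.

    Thirteen lineage-A sublines plus a technical duplicate of A-1, three
    lineage-B sublines, single unrelated lines C-1 and D-1, and thirteen
    lineage-E sublines.  Study-observed irregularities are reproduced:
    A-2 carries an extra junction 1 kbp downstream of its locus, E-2 and
    E-10 carry one 4.7 kbp downstream of locus 6, and in E-1 the second
    end of locus 6 has support below the calling threshold, so its site
    set is a strict subset of its siblings'.
    """
    rng = np.random.default_rng(seed)
    samples: dict[str, tuple[list[IntegrationTruth], SimConfig]] = {}
    names = (
        [f"A-{i}" for i in range(1, 14)]
        + ["A-1D"]
        + [f"B-{i}" for i in range(1, 4)]
        + ["C-1", "D-1"]
        + [f"E-{i}" for i in range(1, 14)]
    )
    for idx, sample_id in enumerate(names):
        lineage = sample_id[0]
        truths, config = preset(f"lineage_{lineage}")
        truths = list(truths)
        if sample_id == "A-2":
            truths.append(
                IntegrationTruth("scaffold_1", 21_000, "right", VECTOR_RIGHT_POS)
            )
        if sample_id in ("E-2", "E-10"):
            truths.append(
                IntegrationTruth("scaffold_6", 26_700, "right", VECTOR_RIGHT_POS)
            )
        if sample_id == "E-1":
            truths = [
                dataclasses.replace(t, support=3)
                if t.scaffold == "scaffold_6" and t.vector_end == "right"
                and t.genome_pos == 22_100
                else t
                for t in truths
            ]
        support = int(rng.integers(8, 19))
        config = config.replace(
            sample=sample_id,
            support_per_junction=support,
            seed=int((seed * 1_000 + idx * 7 + 1) % 2**31),
        )
        samples[sample_id] = (truths, config)
    return samples
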