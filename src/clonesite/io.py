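"""Readers and writers for site tables, stats and clonality reports.

The site table is the exchange format between the calling stage and the
clonality stage: a TSV with one called junction per row and 1-based
genome coordinates (stated in the header comment).  BED output converts
to 0-based half-open at write time.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .caller import IntegrationSite
from .clonality import ClonalityReport, SampleSiteSet, SiteKey
from .stats import MappingStats

__all__ = [
    "SITE_TABLE_COLUMNS",
    "write_site_table",
    "read_site_table",
    "write_bed",
    "write_sites_json",
    "write_stats_json",
    "write_stats_table",
    "write_clonality_report",
]

SITE_TABLE_COLUMNS = [
    "sample",
    "scaffold",
    "genome_pos",
    "vector_pos",
    "vector_end",
    "strand",
    "support",
]

_COORDS_COMMENT = "# coordinates: 1-based inclusive (SAM convention)\n"


def sites_to_frame(sites: Iterable[IntegrationSite]) -> pd.DataFrame:
    rows = [
        {
            "sample": s.sample,
            "scaffold": s.scaffold,
            "genome_pos": s.genome_pos,
            "vector_pos": s.vector_pos,
            "vector_end": s.vector_end,
            "strand": s.strand,
            "support": s.support,
        }
        for s in sites
    ]
    frame = pd.DataFrame(rows, columns=SITE_TABLE_COLUMNS)
    return frame.sort_values(["sample", "scaffold", "genome_pos"]).reset_index(drop=True)


def write_site_table(sites: Iterable[IntegrationSite], path: str | Path) -> None:
    frame = sites_to_frame(sites)
    with open(path, "w") as handle:
        handle.write(_COORDS_COMMENT)
        frame.to_csv(handle, sep="\t", index=False)


def read_site_table(path: str | Path) -> dict[str, SampleSiteSet]:
    """Load a (possibly multi-sample) site table into per-sample site sets."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    missing = set(SITE_TABLE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"site table {path} lacks columns: {sorted(missing)}")
    out: dict[str, SampleSiteSet] = {}
    for sample, group in frame.groupby("sample", sort=True):
        sites = {
            SiteKey(row.scaffold, int(row.genome_pos), row.vector_end): int(row.support)
            for row in group.itertuples()
        }
        out[str(sample)] = SampleSiteSet(sample_id=str(sample), sites=sites)
    return out


def write_bed(sites: Iterable[IntegrationSite], path: str | Path) -> None:
    """BED5 of called junctions; 1-based inclusive -> 0-based half-open."""
    with open(path, "w") as handle:
        handle.write(
            'track name="integration_sites" '
            'description="vector-genome junctions (converted to 0-based half-open)"\n'
        )
        for s in sorted(sites, key=lambda x: (x.scaffold, x.genome_pos)):
            name = f"{s.sample}:{s.vector_end}:{s.vector_pos}"
            handle.write(
                f"{s.scaffold}\t{s.genome_pos - 1}\t{s.genome_pos}\t{name}\t{s.support}\n"
            )


def write_sites_json(sites: Iterable[IntegrationSite], path: str | Path) -> None:
    payload = sites_to_frame(sites).to_dict(orient="records")
    with open(path, "w") as handle:
        json.dump({"coordinates": "1-based inclusive", "sites": payload}, handle, indent=2)
        handle.write("\n")


def write_stats_json(stats: MappingStats, path: str | Path) -> None:
    with open(path, "w") as handle:
        json.dump(stats.as_dict(), handle, indent=2)
        handle.write("\n")


def write_stats_table(stats: Sequence[MappingStats], path: str | Path) -> None:
    """Combined per-sample stats, one row per sample."""
    frame = pd.DataFrame([s.as_dict() for s in stats])
    frame.to_csv(path, sep="\t", index=False)


def write_clonality_report(
    report: ClonalityReport, json_path: str | Path, matrix_path: str | Path
) -> None:
    """JSON report plus a human-readable TSV matrix of pairwise relations."""
    with open(json_path, "w") as handle:
        json.dump(report.as_dict(), handle, indent=2, sort_keys=True)
        handle.write("\n")
    samples = sorted({r.sample_a for r in report.pairwise} | {r.sample_b for r in report.pairwise})
    if not samples:  # single-sample run: no pairs
        samples = [g[0] for g in report.lineage_groups]
    cell = {(s, s): "identical" for s in samples}
    for r in report.pairwise:
        label = f"{r.relation}({r.jaccard:.2f})"
        cell[(r.sample_a, r.sample_b)] = label
        cell[(r.sample_b, r.sample_a)] = label
    frame = pd.DataFrame(
        [[cell.get((a, b), "") for b in samples] for a in samples],
        index=samples,
        columns=samples,
    )
    frame.to_csv(matrix_path, sep="\t", index_label="sample")
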