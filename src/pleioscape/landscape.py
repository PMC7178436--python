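"""Peak selection for the plotted surfaces.

Two views are computed from a harmonized table:

* the entire-genome view — for each (chromosome, phenotype) only the maximum
  -log10(p) record is kept;
* the single-chromosome view — each chromosome segment contributes at most
  one record per phenotype (the highest peak), and a segment is shown only
  when at least one phenotype exceeds the minimum significance threshold
  (-log10(p) > 6 by default).

Both views respect a sectional "stratum": a half-open significance interval
[lo, hi) on the -log10(p) axis that restricts the landscape to a sub-surface
band (e.g. the [100, inf) section of a deeply significant landscape).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ingest import LandscapeTable, SummaryRecord
from .segmentation import SegmentScheme

__all__ = [
    "Stratum",
    "BinPeakGrid",
    "sectional_filter",
    "genome_peaks",
    "chromosome_peaks",
    "retained_segments",
]

DEFAULT_THRESHOLD_MIN = 6.0


@dataclass(frozen=True)
class Stratum:
    """Half-open significance interval [lo, hi) on the -log10(p) scale."""

    lo: float = 0.0
    hi: float = math.inf

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"stratum requires lo < hi, got [{self.lo}, {self.hi})")
        if self.lo < 0:
            raise ValueError(f"stratum lower bound must be >= 0, got {self.lo}")

    def contains(self, neglog10p: float) -> bool:
        return self.lo <= neglog10p < self.hi


FULL_VIEW = Stratum(0.0, math.inf)


@dataclass
class BinPeakGrid:
    """Per (segment, phenotype) top record for one chromosome.

    ``cells`` maps (segment id, phenotype) to the maximal in-stratum record;
    only segments in ``retained`` — those where some phenotype exceeds
    ``threshold_min`` — carry cells. ``n_gap_dropped`` counts records that
    fell in blocks-mode gaps.
    """

    chrom: int
    scheme: SegmentScheme
    stratum: Stratum
    threshold_min: float
    phenotypes: list[str]
    cells: dict[tuple[int, str], SummaryRecord] = field(default_factory=dict)
    retained: list[int] = field(default_factory=list)
    n_gap_dropped: int = 0

    def cell(self, segment: int, phenotype: str) -> SummaryRecord | None:
        return self.cells.get((segment, phenotype))

    def is_empty(self) -> bool:
        return not self.retained


def sectional_filter(table: LandscapeTable, stratum: Stratum) -> LandscapeTable:
    """Restrict a table to records with lo <= -log10(p) < hi."""
    nl = table.frame["neglog10p"]
    mask = nl >= stratum.lo
    if math.isfinite(stratum.hi):
        mask &= nl < stratum.hi
    return table.subset(table.frame[mask])


def _argmax_per_group(df: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
    """Deterministic per-group maximum of neglog10p.

    Ties break toward the smaller position, then the lexicographically
    smaller snp_id, so repeated runs are bit-identical.
    """
    ordered = df.sort_values(
        ["neglog10p", "pos", "snp_id"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    return ordered.groupby(keys, sort=True).head(1)


def _row_to_record(row: pd.Series) -> SummaryRecord:
    return SummaryRecord(
        snp_id=str(row["snp_id"]),
        chrom=int(row["chrom"]),
        pos=int(row["pos"]),
        neglog10p=float(row["neglog10p"]),
        effect=float(row["effect"]),
        effect_type=str(row["effect_type"]),
        se=float(row["se"]),
        allele1=str(row["allele1"]),
        allele2=str(row["allele2"]),
        phenotype=str(row["phenotype"]),
    )


def genome_peaks(
    table: LandscapeTable, stratum: Stratum = FULL_VIEW
) -> dict[tuple[int, str], SummaryRecord]:
    """Entire-genome view: maximal in-stratum record per (chrom, phenotype).

    No minimum-significance floor applies at genome level; combinations with
    no in-stratum record are simply absent from the mapping.
    """
    sub = sectional_filter(table, stratum).frame
    if sub.empty:
        return {}
    top = _argmax_per_group(sub, ["chrom", "phenotype"])
    return {(int(r["chrom"]), str(r["phenotype"])): _row_to_record(r) for _, r in top.iterrows()}


def chromosome_peaks(
    table: LandscapeTable,
    chrom: int,
    scheme: SegmentScheme,
    stratum: Stratum = FULL_VIEW,
    threshold_min: float = DEFAULT_THRESHOLD_MIN,
) -> BinPeakGrid:
    """Single-chromosome view: per-segment, per-phenotype top records.

    A segment is retained iff at least one of its phenotype cells exceeds
    ``threshold_min`` (strict). In retained segments *every* phenotype's
    highest in-stratum peak is kept, even sub-threshold ones. Records in
    blocks-mode gaps are excluded and counted.
    """
    if chrom not in range(1, 23):
        raise ValueError(f"chromosome must be 1-22, got {chrom}")
    grid = BinPeakGrid(
        chrom=chrom,
        scheme=scheme,
        stratum=stratum,
        threshold_min=threshold_min,
        phenotypes=list(table.phenotypes),
    )
    sub = sectional_filter(table, stratum).frame
    sub = sub[sub["chrom"] == chrom]
    if sub.empty:
        return grid
    sub = sub.copy()
    seg = [scheme.assign(chrom, int(p)) for p in sub["pos"]]
    sub["segment"] = seg
    grid.n_gap_dropped = int(sub["segment"].isna().sum())
    sub = sub.dropna(subset=["segment"])
    if sub.empty:
        return grid
    sub["segment"] = sub["segment"].astype(int)

    top = _argmax_per_group(sub, ["segment", "phenotype"])
    seg_max = top.groupby("segment")["neglog10p"].max()
    retained = sorted(int(s) for s, m in seg_max.items() if m > threshold_min)
    grid.retained = retained
    keep = set(retained)
    for _, row in top.iterrows():
        s = int(row["segment"])
        if s in keep:
            grid.cells[(s, str(row["phenotype"]))] = _row_to_record(row)
    return grid


def retained_segments(grid: BinPeakGrid) -> list[int]:
    """Segment ids shown in the view, in genomic order."""
    return list(grid.retained)


def segment_records(
    table: LandscapeTable,
    chrom: int,
    segment: int,
    scheme: SegmentScheme,
    phenotype: str | None = None,
) -> list[SummaryRecord]:
    """All records inside one segment, optionally for a single phenotype.

    The working set for LD pop-ups, thinning and regional inspection.
    """
    start, end = scheme.interval(chrom, segment)
    df = table.frame
    sub = df[(df["chrom"] == chrom) & (df["pos"] >= start) & (df["pos"] <= end)]
    if phenotype is not None:
        sub = sub[sub["phenotype"] == phenotype]
    return [_row_to_record(row) for _, row in sub.iterrows()]
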