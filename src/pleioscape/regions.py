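"""Regional export for colocalization follow-up.

A region of interest — a chromosome segment or an explicit base-pair range —
is exported across all phenotypes as one wide TSV: one row per SNP present in
any phenotype, with per-phenotype (beta, se, neglog10p) column triplets.
Multi-trait colocalization tools consume aligned per-trait effect/se vectors,
so SNPs missing in some phenotype are kept with blanks and complete-case
filtering is left to the consumer.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .ingest import LandscapeTable
from .segmentation import SegmentScheme

__all__ = ["RegionSelection", "export_region", "read_region_export"]


@dataclass(frozen=True)
class RegionSelection:
    """Either (chrom, segment, scheme) or (chrom, start, end), 1-based closed."""

    chrom: int
    segment: int | None = None
    scheme: SegmentScheme | None = None
    start: int | None = None
    end: int | None = None

    def resolve(self) -> tuple[int, int, int]:
        """(chrom, start, end) of the selected range."""
        if self.segment is not None:
            if self.scheme is None:
                raise ValueError("segment selection requires a SegmentScheme")
            start, end = self.scheme.interval(self.chrom, self.segment)
        else:
            if self.start is None or self.end is None:
                raise ValueError("range selection requires both start and end")
            start, end = self.start, self.end
        if start > end:
            raise ValueError(f"empty range [{start}, {end}]")
        return self.chrom, start, end


def export_region(
    table: LandscapeTable, sel: RegionSelection, path: str | Path
) -> dict[str, int]:
    """Write the wide-format regional TSV; returns per-phenotype record counts.

    Raises ValueError when the selection contains no records.
    """
    chrom, start, end = sel.resolve()
    df = table.frame
    sub = df[(df["chrom"] == chrom) & (df["pos"] >= start) & (df["pos"] <= end)]
    if sub.empty:
        raise ValueError(f"no records in selection chr{chrom}:{start}-{end}")

    counts = {p: int((sub["phenotype"] == p).sum()) for p in table.phenotypes}

    base = (sub.groupby(["snp_id", "chrom", "pos"], as_index=False)
               .agg(allele1=("allele1", "first"), allele2=("allele2", "first")))
    wide = base.sort_values(["pos", "snp_id"]).reset_index(drop=True)
    for pheno in table.phenotypes:
        psub = sub[sub["phenotype"] == pheno].set_index(["snp_id", "chrom", "pos"])
        idx = pd.MultiIndex.from_frame(wide[["snp_id", "chrom", "pos"]])
        for src, dst in (("effect", "beta"), ("se", "se"), ("neglog10p", "neglog10p")):
            wide[f"{pheno}.{dst}"] = psub[src].reindex(idx).to_numpy()

    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# region: chr{chrom}:{start}-{end} (1-based closed)\n")
        fh.write("# layout: snp_id, chrom, pos, allele1, allele2, then per-phenotype "
                 "(beta, se, neglog10p) triplets named <phenotype>.<field>; "
                 "blank = SNP absent from that phenotype's summary file\n")
        fh.write(f"# phenotypes: {','.join(table.phenotypes)}\n")
        wide.to_csv(fh, sep="\t", index=False, na_rep="")
    return counts


def read_region_export(path: str | Path) -> pd.DataFrame:
    """Read a regional export back into long format (phenotype rows).

    Inverse of :func:`export_region` up to records that were entirely blank.
    """
    path = Path(path)
    wide = pd.read_csv(path, sep="\t", comment="#", dtype={"snp_id": str})
    phenos: list[str] = []
    for col in wide.columns:
        if col.endswith(".beta"):
            phenos.append(col[: -len(".beta")])
    rows = []
    for _, row in wide.iterrows():
        for p in phenos:
            nl = row.get(f"{p}.neglog10p")
            if pd.isna(nl):
                continue
            rows.append({
                "phenotype": p, "snp_id": row["snp_id"], "chrom": int(row["chrom"]),
                "pos": int(row["pos"]), "neglog10p": float(nl),
                "effect": row.get(f"{p}.beta"), "se": row.get(f"{p}.se"),
                "allele1": row["allele1"], "allele2": row["allele2"],
            })
    return pd.DataFrame(rows)
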