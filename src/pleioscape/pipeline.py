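"""End-to-end convenience: simulate/ingest/analyze in one call.

Used by the example scripts and the reproduction script; wraps the module
chain ingest -> segmentation -> landscape -> ld without adding behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .ingest import ColumnMap, LandscapeTable, harmonize, read_summary_file
from .landscape import chromosome_peaks, segment_records
from .ld import Category, TableLDBackend, categorize_locus
from .segmentation import SegmentScheme, fixed_bins
from .synthetic import SimulationResult, simulate_study

__all__ = ["SYNTHETIC_COLUMN_MAP", "ingest_study", "concordance_report"]

#: Column map matching the synthetic generator's summary-file layout.
SYNTHETIC_COLUMN_MAP = ColumnMap(snp_id="SNP", chrom="CHR", pos="BP", p="P",
                                 effect="BETA", se="SE", allele1="A1", allele2="A2")


def ingest_study(result: SimulationResult) -> LandscapeTable:
    """Phase 1 on a simulated study: read every summary file and harmonize."""
    per = {p: read_summary_file(f, SYNTHETIC_COLUMN_MAP, p).records
           for p, f in result.files.items()}
    return harmonize(per, result.truth["phenotypes"])


@dataclass
class ConcordanceReport:
    """Category tallies from replaying planted truth through the categorizer."""

    n_lead_checks: int = 0
    n_lead_matches: int = 0          # planted lead is the displayed cell
    n_lead_a: int = 0                # ... and categorized A
    n_satellite_checks: int = 0
    n_satellite_b: int = 0           # strong satellites categorized B
    n_secondary_checks: int = 0
    n_secondary_c2: int = 0          # buried leads categorized C(2)

    def mismatches(self) -> int:
        return ((self.n_lead_checks - self.n_lead_a)
                + (self.n_satellite_checks - self.n_satellite_b)
                + (self.n_secondary_checks - self.n_secondary_c2))


def concordance_report(
    result: SimulationResult,
    table: LandscapeTable | None = None,
    scheme: SegmentScheme | None = None,
) -> ConcordanceReport:
    """Replay every planted signal through the displayed grid and categorizer.

    Planted leads should come back as the displayed cell (category A), strong
    satellites (r2 and D' above 0.75) as B, and buried secondary leads as C(2).
    """
    table = table if table is not None else ingest_study(result)
    scheme = scheme or fixed_bins(result.truth["bin_width"])
    backend = TableLDBackend.from_file(result.ld_table)
    rep = ConcordanceReport()
    for locus in result.truth["loci"]:
        grid = chromosome_peaks(table, locus["chrom"], scheme)
        for pheno in locus["phenotypes"]:
            cell = grid.cell(locus["segment"], pheno)
            records = segment_records(table, locus["chrom"], locus["segment"],
                                      scheme, pheno)
            rep.n_lead_checks += 1
            if cell is not None and cell.snp_id == locus["lead"]["snp_id"]:
                rep.n_lead_matches += 1
            if cell is None:
                continue
            cat = categorize_locus(locus["lead"]["snp_id"], cell, records, backend)
            if cat.kind == "A":
                rep.n_lead_a += 1
            for sat in locus["satellites"]:
                if sat["r2"] > 0.75 and sat["dprime"] > 0.75:
                    rep.n_satellite_checks += 1
                    cat = categorize_locus(sat["snp_id"], cell, records, backend)
                    if cat.kind == "B":
                        rep.n_satellite_b += 1
            if locus["secondary"] is not None:
                rep.n_secondary_checks += 1
                cat = categorize_locus(locus["secondary"]["snp_id"], cell, records, backend)
                if (cat.kind, cat.level) == ("C", 2):
                    rep.n_secondary_c2 += 1
    return rep
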