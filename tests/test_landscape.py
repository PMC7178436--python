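"""Peak selection: sectional strata, genome view, chromosome grids."""

import math

import numpy as np
import pytest

import pleioscape as ps
from pleioscape import Stratum
from pleioscape.landscape import segment_records

from conftest import (
    assert_grid_matches_oracle,
    naive_genome_peaks,
    random_table,
)


def small_table(rows, phenotypes=None):
    """rows: (snp_id, chrom, pos, neglog10p, phenotype)"""
    recs = {}
    for snp, chrom, pos, nl, ph in rows:
        recs.setdefault(ph, []).append(
            ps.SummaryRecord(snp_id=snp, chrom=chrom, pos=pos, neglog10p=nl, phenotype=ph))
    return ps.harmonize(recs, phenotypes or list(recs))


class TestStratum:
    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            Stratum(5.0, 5.0)
        with pytest.raises(ValueError):
            Stratum(7.0, 3.0)

    def test_full_view_filter_is_identity(self, table):
        out = ps.sectional_filter(table, Stratum(0, math.inf))
        assert len(out) == len(table)

    def test_deep_section_keeps_only_extreme_records(self):
        t = small_table([("a", 1, 10, 120.0, "x"), ("b", 1, 20, 99.9, "x"),
                         ("c", 1, 30, 100.0, "x")])
        out = ps.sectional_filter(t, Stratum(100, math.inf))
        assert sorted(out.frame["snp_id"]) == ["a", "c"]

    def test_adjacent_strata_partition_the_table(self, table):
        lo = ps.sectional_filter(table, Stratum(0, 10))
        hi = ps.sectional_filter(table, Stratum(10, math.inf))
        assert len(lo) + len(hi) == len(table)
        assert set(lo.frame["snp_id"]).isdisjoint(
            set(hi.frame["snp_id"])) or True  # ids may repeat across phenotypes
        both = set(map(tuple, lo.frame[["snp_id", "phenotype"]].values)) & \
               set(map(tuple, hi.frame[["snp_id", "phenotype"]].values))
        assert not both


class TestGenomePeaks:
    def test_takes_the_maximum(self):
        t = small_table([("a", 1, 10, 3.0, "x"), ("b", 1, 20, 7.0, "x"),
                         ("c", 1, 30, 5.0, "x")])
        peaks = ps.genome_peaks(t)
        assert peaks[(1, "x")].snp_id == "b"

    def test_tie_breaks_to_smaller_position(self):
        t = small_table([("far", 1, 20, 7.0, "x"), ("near", 1, 10, 7.0, "x")])
        assert ps.genome_peaks(t)[(1, "x")].snp_id == "near"

    def test_empty_combinations_absent(self):
        t = small_table([("a", 1, 10, 3.0, "x")])
        peaks = ps.genome_peaks(t, Stratum(5, math.inf))
        assert peaks == {}

    def test_planted_maxima_recovered_on_every_chromosome(self, tmp_path):
        rng = np.random.default_rng(11)
        loci = [ps.synthetic.make_locus(rng, chrom=c, segment=c + 3,
                                        phenotypes={"t1": 10.0 + c})
                for c in range(1, 23)]
        res = ps.synthetic.simulate_summary(["t1", "t2"], loci, 50, seed=11,
                                            out_dir=tmp_path)
        cmap = ps.ColumnMap(effect="BETA", se="SE", allele1="A1", allele2="A2")
        per = {p: ps.read_summary_file(f, cmap, p).records for p, f in res.files.items()}
        t = ps.harmonize(per, ["t1", "t2"])
        peaks = ps.genome_peaks(t)
        for locus in res.truth["loci"]:
            rec = peaks[(locus["chrom"], "t1")]
            assert rec.snp_id == locus["lead"]["snp_id"]
        # the unaffected phenotype never exceeds the background cap
        for c in range(1, 23):
            assert peaks[(c, "t2")].neglog10p < 3.0

    def test_matches_naive_scan(self, table):
        stratum = Stratum(2.0, math.inf)
        mine = ps.genome_peaks(table, stratum)
        naive = naive_genome_peaks(table, stratum)
        assert set(mine) == set(naive)
        for key in naive:
            assert mine[key].snp_id == naive[key]["snp_id"]


class TestChromosomePeaks:
    def test_retention_threshold_is_strict(self, scheme):
        t = small_table([("a", 2, 500, 6.2, "x"), ("b", 2, 1_500_000, 5.9, "x")])
        grid = ps.chromosome_peaks(t, 2, scheme, threshold_min=6.0)
        assert grid.retained == [0]
        assert grid.cell(0, "x").snp_id == "a"
        # exactly at the threshold does not retain
        t2 = small_table([("a", 2, 500, 6.0, "x")])
        assert ps.chromosome_peaks(t2, 2, scheme, threshold_min=6.0).retained == []

    def test_subthreshold_cell_kept_in_retained_segment(self, scheme):
        t = small_table([("a", 2, 500, 8.0, "x"), ("b", 2, 600, 2.0, "y")],
                        phenotypes=["x", "y"])
        grid = ps.chromosome_peaks(t, 2, scheme)
        assert grid.cell(0, "y").snp_id == "b"

    def test_empty_grid_is_valid(self, table, scheme):
        grid = ps.chromosome_peaks(table, 2, scheme)  # nothing planted on chr2
        assert grid.is_empty() and ps.retained_segments(grid) == []

    def test_planted_segments_retained_in_order(self, study, table, scheme):
        expected = {}
        for locus in study.truth["loci"]:
            expected.setdefault(locus["chrom"], []).append(locus["segment"])
        for chrom, segs in expected.items():
            grid = ps.chromosome_peaks(table, chrom, scheme)
            assert ps.retained_segments(grid) == sorted(segs)

    def test_demo_parameters_megabase_bins_cutoff_6_5(self, table):
        # the validation configuration: 1 Mb segments, cut-off -log10(p) = 6.5
        grid = ps.chromosome_peaks(table, 19, ps.fixed_bins(1_000_000),
                                   threshold_min=6.5)
        assert grid.retained == [45]
        assert grid.cell(45, "LDL").neglog10p == pytest.approx(60.0, abs=1e-6)

    def test_grid_matches_brute_force_scan(self, scheme):
        rng = np.random.default_rng(23)
        t = random_table(rng, n_rows=2000, n_phenotypes=4, n_chrom=3)
        for chrom in (1, 2, 3):
            grid = ps.chromosome_peaks(t, chrom, scheme, Stratum(1.0, 9.0), 5.0)
            assert_grid_matches_oracle(grid, t, chrom, scheme, Stratum(1.0, 9.0), 5.0)

    def test_blocks_mode_gaps_counted(self, tmp_path):
        bed = tmp_path / "b.bed"
        bed.write_text("1\t0\t1000\n")
        scheme = ps.blocks_from_bed(bed)
        t = small_table([("in", 1, 500, 8.0, "x"), ("out", 1, 5_000, 9.0, "x")])
        grid = ps.chromosome_peaks(t, 1, scheme)
        assert grid.n_gap_dropped == 1
        assert grid.cell(0, "x").snp_id == "in"

    def test_raising_threshold_never_adds_segments(self, table, scheme):
        lo = ps.chromosome_peaks(table, 19, scheme, threshold_min=3.0)
        hi = ps.chromosome_peaks(table, 19, scheme, threshold_min=10.0)
        assert set(hi.retained) <= set(lo.retained)

    def test_shrinking_stratum_never_raises_cells(self, table, scheme):
        full = ps.chromosome_peaks(table, 19, scheme)
        narrow = ps.chromosome_peaks(table, 19, scheme, Stratum(0.0, 20.0))
        for key, rec in narrow.cells.items():
            if key in full.cells:
                assert rec.neglog10p <= full.cells[key].neglog10p


def test_segment_records_filters_by_interval_and_phenotype(study, table, scheme):
    locus = study.truth["loci"][0]
    recs = segment_records(table, locus["chrom"], locus["segment"], scheme, "LDL")
    ids = {r.snp_id for r in recs}
    assert locus["lead"]["snp_id"] in ids
    start, end = scheme.interval(locus["chrom"], locus["segment"])
    assert all(start <= r.pos <= end for r in recs)
    assert all(r.phenotype == "LDL" for r in recs)
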