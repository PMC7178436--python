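"""Summary-statistics-only LD analytics: neighbours, thinning, categories."""

import itertools

import pytest

import pleioscape as ps
from pleioscape.landscape import segment_records
from pleioscape.ld import LDPair, LDUnavailableError, TableLDBackend


def rec(snp, nl, pos, pheno="x", chrom=1):
    return ps.SummaryRecord(snp_id=snp, chrom=chrom, pos=pos, neglog10p=nl,
                            phenotype=pheno)


@pytest.fixture
def toy_backend():
    b = TableLDBackend()
    b.add("lead", "s1", 0.9, 0.95)
    b.add("lead", "s2", 0.8, 0.8)
    b.add("lead", "s3", 0.75, 0.75)
    b.add("lead", "s4", 0.8, 0.5)   # fails the D' threshold
    b.add("lead", "s5", 0.5, 0.9)   # fails the r2 threshold
    return b


class TestBackend:
    def test_queries_are_symmetric(self, toy_backend):
        ab = toy_backend.query("lead", ["s1"])["s1"]
        ba = toy_backend.query("s1", ["lead"])["lead"]
        assert (ab.r2, ab.dprime) == (ba.r2, ba.dprime)

    def test_repeat_queries_are_idempotent(self, toy_backend):
        first = toy_backend.query("lead", ["s1", "s2", "zzz"])
        second = toy_backend.query("lead", ["s1", "s2", "zzz"])
        assert first == second
        assert "zzz" not in first  # unknown SNPs silently absent

    def test_from_file_roundtrip(self, tmp_path):
        path = tmp_path / "pairs.ld"
        path.write_text(
            "CHR_A\tBP_A\tSNP_A\tCHR_B\tBP_B\tSNP_B\tR2\tDP\n"
            "1\t10\ta\t1\t20\tb\t0.9\t0.85\n")
        b = TableLDBackend.from_file(path)
        assert b.query("b", ["a"])["a"] == LDPair("a", 0.9, 0.85)

    def test_out_of_range_values_rejected(self):
        b = TableLDBackend()
        with pytest.raises(ValueError):
            b.add("a", "b", 1.2, 0.5)

    def test_missing_required_column_rejected(self, tmp_path):
        path = tmp_path / "pairs.ld"
        path.write_text("SNP_A\tSNP_B\n a\tb\n")
        with pytest.raises(ValueError, match="R2"):
            TableLDBackend.from_file(path)


class TestLdNeighbors:
    def test_both_thresholds_are_conjunctive(self, toy_backend):
        s = ps.ld_neighbors(toy_backend, "lead", ["s1", "s2", "s3", "s4", "s5"])
        assert sorted(s.member_ids) == ["s1", "s2", "s3"]  # >= on both

    def test_zero_thresholds_keep_every_known_candidate(self, toy_backend):
        s = ps.ld_neighbors(toy_backend, "lead", ["s1", "s4", "s5", "unknown"],
                            r2_min=0.0, dprime_min=0.0)
        assert sorted(s.member_ids) == ["s1", "s4", "s5"]

    def test_lead_never_its_own_member(self, toy_backend):
        s = ps.ld_neighbors(toy_backend, "lead", ["lead", "s1"])
        assert "lead" not in s.member_ids

    def test_threshold_domain_checked(self, toy_backend):
        with pytest.raises(ValueError):
            ps.ld_neighbors(toy_backend, "lead", ["s1"], r2_min=1.5)


class TestMutualLd:
    def make_set(self, members):
        return ps.LDSet(lead="L", members=[LDPair(m, 0.9, 0.9) for m in members],
                        r2_min=0.75, dprime_min=0.75, backend_label="table")

    def test_intersection(self):
        sets = {"p1": self.make_set(["a", "b", "c"]), "p2": self.make_set(["b", "c", "d"])}
        assert ps.mutual_ld(sets) == ["b", "c"]

    def test_disjoint_sets_share_nothing(self):
        sets = {"p1": self.make_set(["a"]), "p2": self.make_set(["b"])}
        assert ps.mutual_ld(sets) == []

    def test_three_way_single_shared(self):
        sets = {"p1": self.make_set(["x", "a"]), "p2": self.make_set(["x", "b"]),
                "p3": self.make_set(["x"])}
        assert ps.mutual_ld(sets) == ["x"]

    def test_position_ordering_when_known(self):
        sets = {"p1": self.make_set(["a", "b"]), "p2": self.make_set(["a", "b"])}
        assert ps.mutual_ld(sets, positions={"a": 500, "b": 100}) == ["b", "a"]

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(ValueError):
            ps.mutual_ld({"p1": self.make_set(["a"])})


class TestLinkedProportion:
    def make(self, members, significant):
        return ps.LDSet(lead="L", members=[LDPair(m, 0.9, 0.9) for m in members],
                        r2_min=0.75, dprime_min=0.75, backend_label="table",
                        above_threshold=frozenset(significant))

    def test_ratio(self):
        s = self.make(["a", "b", "c", "d"], [f"g{i}" for i in range(6)] + ["a", "b", "c", "d"])
        assert ps.linked_proportion(s) == pytest.approx(0.4)

    def test_zero_significant_is_undefined_not_zero(self):
        assert ps.linked_proportion(self.make(["a"], [])) is None

    def test_all_linked_gives_one(self):
        s = self.make(["a", "b"], ["a", "b"])
        assert ps.linked_proportion(s) == 1.0


class FailingBackend:
    label = "failing"

    def __init__(self, fail_after=0):
        self.calls = 0
        self.fail_after = fail_after

    def query(self, lead, candidates, chrom=None):
        self.calls += 1
        if self.calls > self.fail_after:
            raise LDUnavailableError("service down")
        return {}


class TestThinSnps:
    def segment(self):
        # two independent signals: lead1 with satellites, lead2 with its own
        b = TableLDBackend()
        b.add("lead1", "a1", 0.9, 0.9)
        b.add("lead1", "a2", 0.85, 0.95)
        b.add("lead2", "b1", 0.9, 0.9)
        b.add("lead1", "lead2", 0.05, 0.05)
        records = [rec("lead1", 30.0, 100), rec("a1", 25.0, 110), rec("a2", 20.0, 120),
                   rec("lead2", 15.0, 200), rec("b1", 12.0, 210)]
        return records, b

    def test_depth_one_is_the_segment_max(self):
        records, b = self.segment()
        out = ps.thin_snps(records, b, depth=1)
        assert [r.snp_id for r in out.leads] == ["lead1"]

    def test_two_independent_signals_at_depth_two(self):
        records, b = self.segment()
        out = ps.thin_snps(records, b, depth=2)
        assert [r.snp_id for r in out.leads] == ["lead1", "lead2"]

    def test_exhaustion_before_requested_depth(self):
        records, b = self.segment()
        out = ps.thin_snps(records, b, depth=5)
        assert [r.snp_id for r in out.leads] == ["lead1", "lead2"]
        assert out.exhausted

    def test_leads_are_pairwise_non_linked(self, study, table, backend, scheme):
        locus = next(l for l in study.truth["loci"] if l["secondary"])
        for pheno in locus["phenotypes"]:
            records = segment_records(table, locus["chrom"], locus["segment"],
                                      scheme, pheno)
            out = ps.thin_snps(records, backend, depth=4)
            for a, b in itertools.combinations(out.leads, 2):
                pair = backend.query(a.snp_id, [b.snp_id]).get(b.snp_id)
                assert pair is None or pair.r2 < 0.75 or pair.dprime < 0.75

    def test_depth_one_equals_chromosome_peak_cell(self, study, table, backend, scheme):
        for locus in study.truth["loci"]:
            grid = ps.chromosome_peaks(table, locus["chrom"], scheme)
            for pheno in locus["phenotypes"]:
                records = segment_records(table, locus["chrom"], locus["segment"],
                                          scheme, pheno)
                out = ps.thin_snps(records, backend, depth=1)
                assert out.leads[0] == grid.cell(locus["segment"], pheno)

    def test_backend_failure_yields_partial_result(self):
        records, _ = self.segment()
        out = ps.thin_snps(records, FailingBackend(), depth=3)
        assert [r.snp_id for r in out.leads] == ["lead1"]
        assert out.error is not None

    def test_empty_or_bad_depth_rejected(self):
        records, b = self.segment()
        with pytest.raises(ValueError):
            ps.thin_snps([], b, depth=1)
        with pytest.raises(ValueError):
            ps.thin_snps(records, b, depth=0)


class TestCategorizeLocus:
    def setup_segment(self):
        records, b = TestThinSnps().segment()
        cell = records[0]  # lead1 is the displayed peak
        return records, b, cell

    def test_identical_lead_is_category_a(self):
        records, b, cell = self.setup_segment()
        assert ps.categorize_locus("lead1", cell, records, b).kind == "A"

    def test_linked_snp_is_category_b(self):
        records, b, cell = self.setup_segment()
        cat = ps.categorize_locus("a1", cell, records, b)
        assert cat.kind == "B" and str(cat) == "B"

    def test_boundary_ld_is_not_b(self):
        # category B uses strict > thresholds; exactly 0.75 is not enough
        b = TableLDBackend()
        b.add("lead", "edge", 0.75, 0.75)
        records = [rec("lead", 20.0, 100), rec("edge", 10.0, 110)]
        cat = ps.categorize_locus("edge", records[0], records, b)
        assert cat.kind != "B"

    def test_buried_independent_signal_is_c2(self):
        records, b, cell = self.setup_segment()
        cat = ps.categorize_locus("lead2", cell, records, b)
        assert (cat.kind, cat.level) == ("C", 2)
        assert str(cat) == "C(2)"
        # a satellite of the buried signal surfaces at the same depth
        cat2 = ps.categorize_locus("b1", cell, records, b)
        assert (cat2.kind, cat2.level) == ("C", 2)

    def test_unknown_snp_is_unmatched_with_reason(self):
        records, b, cell = self.setup_segment()
        cat = ps.categorize_locus("rs_nowhere", cell, records, b)
        assert cat.kind == "unmatched" and cat.reason

    def test_categories_partition_the_reported_snps(self, study, table, backend, scheme):
        locus = next(l for l in study.truth["loci"] if l["secondary"])
        grid = ps.chromosome_peaks(table, locus["chrom"], scheme)
        pheno = next(iter(locus["phenotypes"]))
        records = segment_records(table, locus["chrom"], locus["segment"], scheme, pheno)
        cell = grid.cell(locus["segment"], pheno)
        reported = ([locus["lead"]["snp_id"]]
                    + [s["snp_id"] for s in locus["satellites"]]
                    + [locus["secondary"]["snp_id"], "rs_unseen"])
        kinds = [ps.categorize_locus(r, cell, records, backend).kind for r in reported]
        assert all(k in {"A", "B", "C", "unmatched"} for k in kinds)
        assert kinds.count("A") == 1
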