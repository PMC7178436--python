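"""Shared fixtures: synthetic study, harmonized table, brute-force oracles."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import pleioscape as ps
from pleioscape.ingest import CANONICAL_COLUMNS

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


STUDY_SEED = 1


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """The standard 4-phenotype synthetic study (demo scenario, seed 1)."""
    out = tmp_path_factory.mktemp("study")
    return ps.synthetic.simulate_study(seed=STUDY_SEED, out_dir=out,
                                       background_snps_per_chrom=200)


@pytest.fixture(scope="session")
def column_map():
    return ps.ColumnMap(snp_id="SNP", chrom="CHR", pos="BP", p="P",
                        effect="BETA", se="SE", allele1="A1", allele2="A2")


@pytest.fixture(scope="session")
def table(study, column_map):
    per = {p: ps.read_summary_file(f, column_map, p).records
           for p, f in study.files.items()}
    return ps.harmonize(per, study.truth["phenotypes"])


@pytest.fixture(scope="session")
def scheme():
    return ps.fixed_bins(1_000_000)


@pytest.fixture(scope="session")
def backend(study):
    return ps.TableLDBackend.from_file(study.ld_table)


def random_table(rng: np.random.Generator, n_rows: int = 400, n_phenotypes: int = 3,
                 n_chrom: int = 4, max_pos: int = 5_000_000,
                 nl_max: float = 12.0) -> ps.LandscapeTable:
    """A fully random landscape table (no planted structure) for oracle tests."""
    phenos = [f"ph{i}" for i in range(n_phenotypes)]
    df = pd.DataFrame({
        "phenotype": rng.choice(phenos, size=n_rows),
        "snp_id": [f"rs{i}" for i in range(n_rows)],
        "chrom": rng.integers(1, n_chrom + 1, size=n_rows),
        "pos": rng.integers(1, max_pos + 1, size=n_rows),
        "neglog10p": rng.uniform(0.0, nl_max, size=n_rows),
        "effect": rng.normal(0.0, 0.2, size=n_rows),
        "effect_type": "beta",
        "se": rng.uniform(0.01, 0.05, size=n_rows),
        "allele1": rng.choice(list("ACGT"), size=n_rows),
        "allele2": rng.choice(list("ACGT"), size=n_rows),
    })
    df = df.sort_values(["chrom", "pos", "phenotype"]).reset_index(drop=True)
    return ps.LandscapeTable(frame=df[CANONICAL_COLUMNS], phenotypes=phenos)


def naive_chromosome_grid(table: ps.LandscapeTable, chrom: int, scheme, stratum,
                          threshold_min: float):
    """Brute-force oracle for chromosome_peaks: plain Python scan, no pandas."""
    best: dict[tuple[int, str], dict] = {}
    for row in table.frame.to_dict("records"):
        if row["chrom"] != chrom:
            continue
        nl = row["neglog10p"]
        if not (stratum.lo <= nl < stratum.hi):
            continue
        seg = scheme.assign(chrom, row["pos"])
        if seg is None:
            continue
        key = (seg, row["phenotype"])
        prev = best.get(key)
        # tie rule: larger -log10(p), then smaller position, then smaller snp_id
        rank = (-nl, row["pos"], row["snp_id"])
        if prev is None or rank < (-prev["neglog10p"], prev["pos"], prev["snp_id"]):
            best[key] = row
    seg_max: dict[int, float] = {}
    for (seg, _), row in best.items():
        seg_max[seg] = max(seg_max.get(seg, -math.inf), row["neglog10p"])
    retained = sorted(s for s, m in seg_max.items() if m > threshold_min)
    cells = {k: v for k, v in best.items() if k[0] in set(retained)}
    return retained, cells


def naive_genome_peaks(table: ps.LandscapeTable, stratum):
    best: dict[tuple[int, str], dict] = {}
    for row in table.frame.to_dict("records"):
        nl = row["neglog10p"]
        if not (stratum.lo <= nl < stratum.hi):
            continue
        key = (row["chrom"], row["phenotype"])
        prev = best.get(key)
        rank = (-nl, row["pos"], row["snp_id"])
        if prev is None or rank < (-prev["neglog10p"], prev["pos"], prev["snp_id"]):
            best[key] = row
    return best


def assert_grid_matches_oracle(grid, table, chrom, scheme, stratum, threshold_min):
    retained, cells = naive_chromosome_grid(table, chrom, scheme, stratum, threshold_min)
    assert grid.retained == retained
    assert set(grid.cells) == set(cells)
    for key, row in cells.items():
        rec = grid.cells[key]
        assert rec.snp_id == row["snp_id"], key
        assert rec.pos == row["pos"]
        assert rec.neglog10p == row["neglog10p"]
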