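"""Synthetic multi-phenotype GWAS study generator with planted ground truth.

Emulates the inputs of a multi-trait summary-statistics study so every module
is testable hermetically: per-phenotype summary files (TSV with scientific
p-value strings), a gene-interval BED, a PLINK-style pairwise LD table, and a
truth record listing every planted signal.

The planted structure mirrors what the landscape is built to expose:

* single-trait loci — one phenotype carries a significant lead;
* pleiotropic loci — several phenotypes share a lead in the same segment;
* satellite SNPs around each lead with declared r2/D' above or below the
  0.75 display thresholds (so LD pop-ups and category-B calls are checkable);
* optional buried secondary leads in the same segment, unlinked to the
  primary (r2 ~ 0.05), recoverable only by recursive thinning at depth 2.

Background SNPs are drawn with -log10(p) uniform on [0, 3), far below the
significance threshold of 6, and never inside a planted segment — the
planted truth is therefore unambiguous. Significance is generated directly
on the -log10 scale and *printed* as a scientific-notation p-value string,
so re-ingesting the files exercises the underflow-safe p-value parser.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PlantedSatellite",
    "SecondaryLead",
    "PlantedLocus",
    "SimulationResult",
    "make_locus",
    "simulate_summary",
    "simulate_ld_table",
    "write_genes_bed",
    "simulate_study",
    "demo_loci",
    "DEMO_PHENOTYPES",
]

ALLELES = ("A", "C", "G", "T")
DEMO_PHENOTYPES = ["HDL", "LDL", "TG", "TC"]

DEFAULT_BACKGROUND_MAX = 3.0
DEFAULT_BIN_WIDTH = 1_000_000
DEFAULT_CHROM_LENGTH = 50_000_000


@dataclass(frozen=True)
class PlantedSatellite:
    snp_id: str
    pos: int
    r2: float
    dprime: float
    neglog10p: dict[str, float]  # per affected phenotype


@dataclass(frozen=True)
class SecondaryLead:
    snp_id: str
    pos: int
    neglog10p: dict[str, float]
    satellites: tuple[PlantedSatellite, ...] = ()


@dataclass(frozen=True)
class PlantedLocus:
    chrom: int
    segment: int
    lead_id: str
    lead_pos: int
    phenotypes: dict[str, float]  # phenotype -> lead -log10(p)
    effects: dict[str, float] = field(default_factory=dict)
    satellites: tuple[PlantedSatellite, ...] = ()
    secondary: SecondaryLead | None = None


@dataclass
class SimulationResult:
    out_dir: Path
    files: dict[str, Path]
    genes_bed: Path | None
    ld_table: Path | None
    truth: dict


def _p_string(neglog10p: float) -> str:
    """Format -log10(p) as a scientific p-value string, e.g. 319.8 -> '1.6e-320'.

    Works far beyond double range because only the mantissa is a float.
    """
    e = math.floor(neglog10p)
    frac = neglog10p - e
    if frac == 0.0:
        return f"1.0000000000e-{e:02d}"
    m = 10.0 ** (1.0 - frac)
    if m >= 10.0:  # floating-point edge when frac ~ 0
        m /= 10.0
        e -= 1
    return f"{m:.10f}e-{e + 1:02d}"


def make_locus(
    rng: np.random.Generator,
    chrom: int,
    segment: int,
    phenotypes: dict[str, float],
    n_strong_satellites: int = 4,
    n_weak_satellites: int = 2,
    strong_r2: float = 0.9,
    strong_dprime: float = 0.9,
    weak_r2: float = 0.3,
    weak_dprime: float = 0.3,
    secondary_neglog10p: float | None = None,
    bin_width: int = DEFAULT_BIN_WIDTH,
) -> PlantedLocus:
    """Plant one locus in a segment, with satellites and an optional buried lead.

    ``phenotypes`` maps affected phenotype -> lead -log10(p) (must exceed the
    satellite band, i.e. > 16 when a secondary lead is requested). Strong
    satellites sit above the 0.75 LD thresholds, weak ones below; the
    secondary lead (and its own satellites) is unlinked to the primary.
    """
    seg_lo, seg_hi = segment * bin_width + 1, (segment + 1) * bin_width
    span = seg_hi - seg_lo
    # draw distinct positions; the lead takes the middle one so it is interior
    pool = sorted(int(p) for p in (seg_lo + rng.choice(span, size=64, replace=False)))
    mid = len(pool) // 2
    lead_pos = pool[mid]
    cursor = iter(pool[:mid] + pool[mid + 1:])

    tag = f"{chrom}s{segment}"
    lead_id = f"rs{tag}L"
    max_lead = max(phenotypes.values())

    sats: list[PlantedSatellite] = []
    for i in range(n_strong_satellites):
        nl = {p: max(6.5, lead_nl - float(rng.uniform(1.0, 5.0))) for p, lead_nl in phenotypes.items()}
        sats.append(PlantedSatellite(
            snp_id=f"rs{tag}S{i}", pos=next(cursor),
            r2=strong_r2, dprime=strong_dprime, neglog10p=nl,
        ))
    for i in range(n_weak_satellites):
        nl = {p: float(rng.uniform(6.5, 9.5)) for p in phenotypes}
        sats.append(PlantedSatellite(
            snp_id=f"rs{tag}W{i}", pos=next(cursor),
            r2=weak_r2, dprime=weak_dprime, neglog10p=nl,
        ))

    secondary = None
    if secondary_neglog10p is not None:
        if secondary_neglog10p <= 9.5 or secondary_neglog10p >= min(phenotypes.values()):
            raise ValueError(
                "secondary lead significance must exceed the weak-satellite band (9.5) "
                "and stay below every primary lead value"
            )
        sec_sats = tuple(
            PlantedSatellite(
                snp_id=f"rs{tag}T{i}", pos=next(cursor),
                r2=strong_r2, dprime=strong_dprime,
                neglog10p={p: max(6.5, secondary_neglog10p - float(rng.uniform(1.0, 3.0)))
                           for p in phenotypes},
            )
            for i in range(2)
        )
        secondary = SecondaryLead(
            snp_id=f"rs{tag}X", pos=next(cursor),
            neglog10p={p: secondary_neglog10p for p in phenotypes},
            satellites=sec_sats,
        )

    effects = {p: float(rng.normal(0.0, 0.3)) or 0.1 for p in phenotypes}
    return PlantedLocus(
        chrom=chrom, segment=segment, lead_id=lead_id, lead_pos=lead_pos,
        phenotypes=dict(phenotypes), effects=effects,
        satellites=tuple(sats), secondary=secondary,
    )


def _locus_rows(locus: PlantedLocus, phenotype: str, rng: np.random.Generator) -> list[dict]:
    """Planted rows of one locus for one phenotype (empty if unaffected)."""
    if phenotype not in locus.phenotypes:
        return []
    a1, a2 = "A", "G"
    rows = [{
        "SNP": locus.lead_id, "CHR": locus.chrom, "BP": locus.lead_pos,
        "neglog10p": locus.phenotypes[phenotype],
        "BETA": locus.effects.get(phenotype, 0.1),
        "SE": round(float(rng.uniform(0.005, 0.05)), 6), "A1": a1, "A2": a2,
    }]
    everything = list(locus.satellites)
    if locus.secondary is not None:
        everything.append(PlantedSatellite(
            snp_id=locus.secondary.snp_id, pos=locus.secondary.pos,
            r2=0.05, dprime=0.05, neglog10p=locus.secondary.neglog10p))
        everything.extend(locus.secondary.satellites)
    for sat in everything:
        rows.append({
            "SNP": sat.snp_id, "CHR": locus.chrom, "BP": sat.pos,
            "neglog10p": sat.neglog10p[phenotype],
            "BETA": round(float(rng.normal(0.0, 0.2)), 6),
            "SE": round(float(rng.uniform(0.005, 0.05)), 6), "A1": a1, "A2": a2,
        })
    return rows


def simulate_summary(
    phenotypes: list[str],
    loci: list[PlantedLocus],
    background_snps_per_chrom: int = 500,
    seed: int = 0,
    out_dir: str | Path = ".",
    n_chromosomes: int = 22,
    chrom_length: int = DEFAULT_CHROM_LENGTH,
    background_max: float = DEFAULT_BACKGROUND_MAX,
    bin_width: int = DEFAULT_BIN_WIDTH,
) -> SimulationResult:
    """Write per-phenotype summary TSVs and return the planted-truth record.

    Background SNPs share positions across phenotypes (as real study SNP
    panels do) with independent sub-significant p-values, and are excluded
    from every planted segment. Identical seeds yield byte-identical files.
    """
    if len(set(phenotypes)) != len(phenotypes):
        raise ValueError("phenotype labels must be unique")
    for locus in loci:
        unknown = set(locus.phenotypes) - set(phenotypes)
        if unknown:
            raise ValueError(f"locus on chr{locus.chrom} names unknown phenotypes {unknown}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    forbidden: dict[int, set[int]] = {}
    planted_pos: dict[int, set[int]] = {}
    for locus in loci:
        forbidden.setdefault(locus.chrom, set()).add(locus.segment)
        ppos = planted_pos.setdefault(locus.chrom, set())
        ppos.add(locus.lead_pos)
        for sat in locus.satellites:
            ppos.add(sat.pos)
        if locus.secondary is not None:
            ppos.add(locus.secondary.pos)
            ppos.update(s.pos for s in locus.secondary.satellites)

    # shared background panel
    background: dict[int, list[tuple[str, int]]] = {}
    for chrom in range(1, n_chromosomes + 1):
        bad_segs = forbidden.get(chrom, set())
        taken = set(planted_pos.get(chrom, set()))
        positions: list[int] = []
        attempts = 0
        while len(positions) < background_snps_per_chrom:
            attempts += 1
            if attempts > 50 * background_snps_per_chrom:
                raise RuntimeError(f"cannot place background SNPs on chr{chrom}")
            pos = int(rng.integers(1, chrom_length + 1))
            if (pos - 1) // bin_width in bad_segs or pos in taken:
                continue
            taken.add(pos)
            positions.append(pos)
        positions.sort()
        background[chrom] = [(f"rs{chrom}b{i}", pos) for i, pos in enumerate(positions)]

    files: dict[str, Path] = {}
    n_rows: dict[str, int] = {}
    for pheno in phenotypes:
        rows: list[dict] = []
        for chrom in range(1, n_chromosomes + 1):
            for snp_id, pos in background[chrom]:
                rows.append({
                    "SNP": snp_id, "CHR": chrom, "BP": pos,
                    "neglog10p": float(rng.uniform(0.0, background_max)),
                    "BETA": round(float(rng.normal(0.0, 0.02)), 6),
                    "SE": round(float(rng.uniform(0.005, 0.05)), 6),
                    "A1": str(rng.choice(ALLELES)), "A2": str(rng.choice(ALLELES)),
                })
        for locus in loci:
            rows.extend(_locus_rows(locus, pheno, rng))
        rows.sort(key=lambda r: (r["CHR"], r["BP"], r["SNP"]))
        path = out_dir / f"{pheno}.tsv"
        with open(path, "w") as fh:
            fh.write("SNP\tCHR\tBP\tP\tBETA\tSE\tA1\tA2\n")
            for r in rows:
                fh.write(f"{r['SNP']}\t{r['CHR']}\t{r['BP']}\t{_p_string(r['neglog10p'])}\t"
                         f"{r['BETA']}\t{r['SE']}\t{r['A1']}\t{r['A2']}\n")
        files[pheno] = path
        n_rows[pheno] = len(rows)

    truth = {
        "phenotypes": list(phenotypes),
        "seed": int(seed),
        "bin_width": bin_width,
        "background_max": background_max,
        "n_rows": n_rows,
        "total_rows": int(sum(n_rows.values())),
        "loci": [_locus_truth(l) for l in loci],
    }
    return SimulationResult(out_dir=out_dir, files=files, genes_bed=None, ld_table=None, truth=truth)


def _locus_truth(locus: PlantedLocus) -> dict:
    d = {
        "chrom": locus.chrom, "segment": locus.segment,
        "lead": {"snp_id": locus.lead_id, "pos": locus.lead_pos},
        "phenotypes": dict(locus.phenotypes), "effects": dict(locus.effects),
        "satellites": [
            {"snp_id": s.snp_id, "pos": s.pos, "r2": s.r2, "dprime": s.dprime,
             "neglog10p": dict(s.neglog10p)}
            for s in locus.satellites
        ],
        "secondary": None,
    }
    if locus.secondary is not None:
        d["secondary"] = {
            "snp_id": locus.secondary.snp_id, "pos": locus.secondary.pos,
            "neglog10p": dict(locus.secondary.neglog10p),
            "satellites": [
                {"snp_id": s.snp_id, "pos": s.pos, "r2": s.r2, "dprime": s.dprime}
                for s in locus.secondary.satellites
            ],
        }
    return d


def simulate_ld_table(loci: list[PlantedLocus], seed: int, path: str | Path) -> Path:
    """Write a symmetric PLINK-style pairwise LD table for the planted loci.

    Lead<->satellite pairs carry the declared r2/D'; the secondary lead is
    written at r2 = 0.05 to the primary (independent), with its own
    satellites linked to it alone. Both orientations of every pair are
    written, so the table is symmetric by construction.
    """
    path = Path(path)
    lines: list[str] = []

    def emit(chrom: int, a: str, pa: int, b: str, pb: int, r2: float, dp: float) -> None:
        lines.append(f"{chrom}\t{pa}\t{a}\t{chrom}\t{pb}\t{b}\t{r2:.4f}\t{dp:.4f}")
        lines.append(f"{chrom}\t{pb}\t{b}\t{chrom}\t{pa}\t{a}\t{r2:.4f}\t{dp:.4f}")

    for locus in loci:
        for sat in locus.satellites:
            emit(locus.chrom, locus.lead_id, locus.lead_pos, sat.snp_id, sat.pos, sat.r2, sat.dprime)
        if locus.secondary is not None:
            sec = locus.secondary
            emit(locus.chrom, locus.lead_id, locus.lead_pos, sec.snp_id, sec.pos, 0.05, 0.05)
            for sat in sec.satellites:
                emit(locus.chrom, sec.snp_id, sec.pos, sat.snp_id, sat.pos, sat.r2, sat.dprime)
    with open(path, "w") as fh:
        fh.write("CHR_A\tBP_A\tSNP_A\tCHR_B\tBP_B\tSNP_B\tR2\tDP\n")
        fh.write("\n".join(lines) + ("\n" if lines else ""))
    return path


def write_genes_bed(loci: list[PlantedLocus], path: str | Path, half_width: int = 2_000) -> Path:
    """Write one synthetic gene interval per planted locus (4-column BED)."""
    path = Path(path)
    entries = []
    for locus in loci:
        start0 = max(0, locus.lead_pos - half_width - 1)  # BED 0-based
        end0 = locus.lead_pos + half_width
        entries.append((locus.chrom, start0, end0, f"GENE{locus.chrom}S{locus.segment}"))
    entries.sort()
    with open(path, "w") as fh:
        for chrom, s, e, sym in entries:
            fh.write(f"{chrom}\t{s}\t{e}\t{sym}\n")
    return path


def demo_loci(rng: np.random.Generator, phenotypes: list[str] | None = None) -> list[PlantedLocus]:
    """The standard demonstration scenario: a 4-trait lipid-like panel.

    One strongly pleiotropic locus on chr19 segment 45 (three shared traits,
    a buried secondary signal, strong and weak satellites — an APOE-region
    analog), plus two single-trait loci on chr1 and chr5.
    """
    phenotypes = phenotypes or DEMO_PHENOTYPES
    p = phenotypes
    return [
        make_locus(rng, chrom=19, segment=45,
                   phenotypes={p[0]: 25.0, p[1]: 60.0, p[3]: 50.0},
                   n_strong_satellites=5, n_weak_satellites=2,
                   secondary_neglog10p=15.0),
        make_locus(rng, chrom=1, segment=12, phenotypes={p[0]: 12.0},
                   n_strong_satellites=3, n_weak_satellites=1),
        make_locus(rng, chrom=5, segment=50, phenotypes={p[2]: 18.0},
                   n_strong_satellites=3, n_weak_satellites=1),
    ]


def simulate_study(
    seed: int,
    out_dir: str | Path,
    phenotypes: list[str] | None = None,
    loci: list[PlantedLocus] | None = None,
    background_snps_per_chrom: int = 500,
    **kwargs,
) -> SimulationResult:
    """One-call study: summary files + genes BED + LD table + truth JSON."""
    phenotypes = phenotypes or list(DEMO_PHENOTYPES)
    rng = np.random.default_rng(seed + 1)
    if loci is None:
        loci = demo_loci(rng, phenotypes)
    result = simulate_summary(
        phenotypes, loci, background_snps_per_chrom=background_snps_per_chrom,
        seed=seed, out_dir=out_dir, **kwargs,
    )
    result.genes_bed = write_genes_bed(loci, Path(out_dir) / "genes.bed")
    result.ld_table = simulate_ld_table(loci, seed, Path(out_dir) / "ld_table.tsv")
    with open(Path(out_dir) / "truth.json", "w") as fh:
        json.dump(result.truth, fh, indent=1, sort_keys=True)
    return result
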