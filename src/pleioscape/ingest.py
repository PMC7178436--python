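"""Reading and harmonizing per-phenotype GWAS summary-statistics files.

One GWAS summary file is read per phenotype. Files are delimited text with a
header row; a :class:`ColumnMap` names the source columns for the canonical
fields (SNP id, chromosome, position, p-value, and optionally effect size,
standard error and alleles). All files are merged into a single long-format
:class:`LandscapeTable`, the input to every downstream view. This merge is the
expensive first phase of the workflow and is executed once per study.

P-values are handled on the -log10 scale throughout. Because genome-wide
association p-values routinely underflow double precision (e.g. ``1.6e-320``),
they are parsed from their *string* representation with arbitrary-precision
decimal arithmetic before any float conversion; see :func:`parse_pvalue`.
"""

from __future__ import annotations

import decimal
import io
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SummaryRecord",
    "ColumnMap",
    "LandscapeTable",
    "IngestCounters",
    "ReadResult",
    "ConfigurationError",
    "PValueError",
    "parse_pvalue",
    "read_summary_file",
    "harmonize",
    "write_table",
    "read_table",
]

#: Fixed column order of the canonical harmonized TSV.
CANONICAL_COLUMNS = [
    "phenotype",
    "snp_id",
    "chrom",
    "pos",
    "neglog10p",
    "effect",
    "effect_type",
    "se",
    "allele1",
    "allele2",
]

AUTOSOMES = frozenset(range(1, 23))

#: Sentinel shown in hover payloads for missing se/alleles.
MISSING = "NA"


class ConfigurationError(ValueError):
    """A column mapping or configuration problem (named column absent, ...)."""


class PValueError(ValueError):
    """A p-value string outside (0, 1] or unparseable."""


@dataclass(frozen=True)
class SummaryRecord:
    """One SNP x phenotype association row.

    ``neglog10p`` is always finite and non-negative; ``effect`` is a beta or an
    odds ratio as declared by ``effect_type``; ``se`` and alleles may be
    missing (NaN / :data:`MISSING`).
    """

    snp_id: str
    chrom: int
    pos: int
    neglog10p: float
    effect: float = math.nan
    effect_type: str = "beta"
    se: float = math.nan
    allele1: str = MISSING
    allele2: str = MISSING
    phenotype: str = ""


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from canonical field names to source-file column names.

    Required canonical fields: ``snp_id``, ``chrom``, ``pos``, ``p``.
    Optional: ``effect``, ``se``, ``allele1``, ``allele2`` — unmapped optional
    fields yield missing values, never errors.

    ``p_scale`` is ``"raw"`` when the p column holds probabilities in (0, 1]
    and ``"neglog10"`` when it already holds -log10(p). ``effect_type`` flags
    the effect column as a beta coefficient or an odds ratio (stored as given,
    no log transform).
    """

    snp_id: str = "SNP"
    chrom: str = "CHR"
    pos: str = "BP"
    p: str = "P"
    effect: str | None = None
    se: str | None = None
    allele1: str | None = None
    allele2: str | None = None
    p_scale: str = "raw"
    effect_type: str = "beta"

    def __post_init__(self) -> None:
        if self.p_scale not in ("raw", "neglog10"):
            raise ConfigurationError(f"p_scale must be 'raw' or 'neglog10', got {self.p_scale!r}")
        if self.effect_type not in ("beta", "OR"):
            raise ConfigurationError(f"effect_type must be 'beta' or 'OR', got {self.effect_type!r}")


@dataclass
class IngestCounters:
    """Bookkeeping for rows dropped during a single-file read."""

    n_rows: int = 0
    n_kept: int = 0
    n_non_autosomal: int = 0
    n_unparseable: int = 0
    n_duplicate_collapsed: int = 0

    def conserved(self) -> bool:
        return self.n_kept == self.n_rows - (
            self.n_non_autosomal + self.n_unparseable + self.n_duplicate_collapsed
        )


@dataclass
class ReadResult:
    records: list[SummaryRecord]
    counters: IngestCounters


@dataclass
class LandscapeTable:
    """Harmonized long-format table over all phenotypes.

    ``frame`` holds one row per :class:`SummaryRecord` in the canonical column
    order, sorted by (chrom, pos, phenotype). ``phenotypes`` is the z-axis
    order and always equals the user-supplied order. A SNP absent from one
    phenotype's file simply has no row for that phenotype.
    """

    frame: pd.DataFrame
    phenotypes: list[str]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frame)

    def records(self) -> list[SummaryRecord]:
        return [SummaryRecord(**row) for row in self.frame.to_dict("records")]

    def subset(self, frame: pd.DataFrame) -> "LandscapeTable":
        return LandscapeTable(frame.reset_index(drop=True), list(self.phenotypes), dict(self.metadata))


_CHROM_RE = re.compile(r"^(?:chr)?(\d+)(?:\.0+)?$", re.IGNORECASE)


def normalize_chrom(label: object) -> int | None:
    """Normalize a chromosome label to an autosome number, or None.

    "chr19", "19", "19.0" all map to 19; sex chromosomes and non-numeric
    contigs map to None (the caller drops and counts them).
    """
    m = _CHROM_RE.match(str(label).strip())
    if not m:
        return None
    c = int(m.group(1))
    return c if c in AUTOSOMES else None


def parse_pvalue(text: str, p_scale: str = "raw") -> float:
    """Parse a p-value string to -log10(p) without double-precision underflow.

    The string is handled with arbitrary-precision decimal arithmetic, so a
    value such as ``"1.6e-320"`` — below the smallest normal double — yields
    its exact -log10 (319.79588...) instead of infinity. With
    ``p_scale="neglog10"`` the text is taken as an already-transformed
    non-negative number.

    Raises :class:`PValueError` for 0, negative, or > 1 raw values.
    """
    s = str(text).strip()
    if p_scale == "neglog10":
        try:
            v = float(s)
        except ValueError as exc:
            raise PValueError(f"unparseable -log10(p) value {text!r}") from exc
        if not math.isfinite(v) or v < 0:
            raise PValueError(f"-log10(p) must be finite and >= 0, got {text!r}")
        return v
    try:
        d = decimal.Decimal(s)
    except decimal.InvalidOperation as exc:
        raise PValueError(f"unparseable p-value {text!r}") from exc
    if not d.is_finite() or d <= 0 or d > 1:
        raise PValueError(f"p-value must lie in (0, 1], got {text!r}")
    with decimal.localcontext() as ctx:
        ctx.prec = 50
        return float(-d.log10())


def _sniff_sep(path: str | Path) -> str | None:
    """Return an explicit delimiter, or None for whitespace splitting."""
    opener = pd.io.common.get_handle(str(path), "r", compression="infer")
    with opener as handle:
        first = handle.handle.readline()
    if "\t" in first:
        return "\t"
    if "," in first:
        return ","
    return None


def read_summary_file(
    path: str | Path,
    column_map: ColumnMap,
    phenotype: str,
    sep: str | None = "auto",
) -> ReadResult:
    """Read one per-phenotype summary file into tagged records.

    Chromosome labels are normalized; rows on non-autosomal contigs or with
    unparseable chrom/pos/p are dropped and counted. Duplicate
    (snp_id, chrom, pos) rows keep the most significant record. ``sep="auto"``
    sniffs tab/comma, falling back to arbitrary whitespace; gzip input is
    transparent.
    """
    path = Path(path)
    if sep == "auto":
        sep = _sniff_sep(path)
    read_kwargs: dict = {"dtype": str, "comment": "#"}
    if sep is None:
        read_kwargs["sep"] = r"\s+"
    else:
        read_kwargs["sep"] = sep
    try:
        df = pd.read_csv(path, **read_kwargs)
    except pd.errors.EmptyDataError as exc:
        raise ConfigurationError(f"{path}: file is empty") from exc
    if df.empty:
        raise ConfigurationError(f"{path}: file has a header but no data rows")

    required = {"snp_id": column_map.snp_id, "chrom": column_map.chrom,
                "pos": column_map.pos, "p": column_map.p}
    for canonical, source in required.items():
        if source not in df.columns:
            raise ConfigurationError(
                f"{path}: mapped column {source!r} (for {canonical!r}) not found; "
                f"columns present: {list(df.columns)}"
            )
    for canonical in ("effect", "se", "allele1", "allele2"):
        source = getattr(column_map, canonical)
        if source is not None and source not in df.columns:
            raise ConfigurationError(
                f"{path}: mapped column {source!r} (for {canonical!r}) not found"
            )

    counters = IngestCounters(n_rows=len(df))
    records: list[SummaryRecord] = []
    for row in df.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        chrom = normalize_chrom(row[column_map.chrom])
        if chrom is None:
            counters.n_non_autosomal += 1
            continue
        try:
            pos = int(float(row[column_map.pos]))
            neglog10p = parse_pvalue(row[column_map.p], column_map.p_scale)
        except (ValueError, TypeError):
            counters.n_unparseable += 1
            continue
        effect = math.nan
        if column_map.effect is not None:
            try:
                effect = float(row[column_map.effect])
            except (ValueError, TypeError):
                effect = math.nan
        se = math.nan
        if column_map.se is not None:
            try:
                se = float(row[column_map.se])
                if se <= 0:
                    se = math.nan
            except (ValueError, TypeError):
                se = math.nan
        a1 = str(row[column_map.allele1]) if column_map.allele1 is not None else MISSING
        a2 = str(row[column_map.allele2]) if column_map.allele2 is not None else MISSING
        records.append(
            SummaryRecord(
                snp_id=str(row[column_map.snp_id]),
                chrom=chrom,
                pos=pos,
                neglog10p=neglog10p,
                effect=effect,
                effect_type=column_map.effect_type,
                se=se,
                allele1=a1 if a1 == a1 and a1 != "nan" else MISSING,
                allele2=a2 if a2 == a2 and a2 != "nan" else MISSING,
                phenotype=phenotype,
            )
        )

    # Collapse duplicate (snp_id, chrom, pos), keeping the larger -log10(p).
    best: dict[tuple[str, int, int], SummaryRecord] = {}
    for rec in records:
        key = (rec.snp_id, rec.chrom, rec.pos)
        prev = best.get(key)
        if prev is None or rec.neglog10p > prev.neglog10p:
            best[key] = rec
    counters.n_duplicate_collapsed = len(records) - len(best)
    records = list(best.values())
    counters.n_kept = len(records)
    return ReadResult(records=records, counters=counters)


def records_to_frame(records: Iterable[SummaryRecord]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in records])
    if df.empty:
        df = pd.DataFrame(columns=CANONICAL_COLUMNS)
    return df[CANONICAL_COLUMNS]


def harmonize(
    per_phenotype_records: Sequence[Sequence[SummaryRecord]] | Mapping[str, Sequence[SummaryRecord]],
    phenotype_order: Sequence[str] | None = None,
    metadata: Mapping | None = None,
) -> LandscapeTable:
    """Concatenate per-phenotype record lists into one landscape table.

    The table is sorted by (chrom, pos, phenotype); the phenotype axis keeps
    the user-supplied order. Duplicate phenotype labels are an error.
    """
    if isinstance(per_phenotype_records, Mapping):
        if phenotype_order is None:
            phenotype_order = list(per_phenotype_records.keys())
        lists = [per_phenotype_records[p] for p in phenotype_order]
    else:
        lists = [list(l) for l in per_phenotype_records]
        if phenotype_order is None:
            phenotype_order = []
            for l in lists:
                if not l:
                    raise ValueError("cannot infer phenotype label from an empty record list")
                phenotype_order.append(l[0].phenotype)
    phenotype_order = list(phenotype_order)
    if len(set(phenotype_order)) != len(phenotype_order):
        raise ValueError(f"duplicate phenotype labels in {phenotype_order}")
    if not any(len(l) for l in lists):
        raise ValueError("no records supplied")

    frames = [records_to_frame(l) for l in lists if len(l)]
    df = pd.concat(frames, ignore_index=True)
    df = df.sort_values(["chrom", "pos", "phenotype"], kind="mergesort").reset_index(drop=True)
    dup = df.duplicated(subset=["phenotype", "chrom", "pos", "snp_id"])
    if dup.any():
        df = df[~dup].reset_index(drop=True)
    meta = {"n_records_per_phenotype": {p: int(len(l)) for p, l in zip(phenotype_order, lists)},
            "coordinate_system": "1-based"}
    if metadata:
        meta.update(metadata)
    return LandscapeTable(frame=df, phenotypes=phenotype_order, metadata=meta)


def write_table(table: LandscapeTable, path: str | Path) -> None:
    """Write the canonical harmonized TSV (fixed column order)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# phenotype_order: " + ",".join(table.phenotypes) + "\n")
        table.frame.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> LandscapeTable:
    """Re-read a canonical harmonized TSV written by :func:`write_table`."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        phenotypes: list[str] | None = None
        if first.startswith("# phenotype_order:"):
            phenotypes = first.split(":", 1)[1].strip().split(",")
        else:
            fh.seek(0)
        df = pd.read_csv(fh, sep="\t", dtype={"snp_id": str, "allele1": str, "allele2": str})
    df["chrom"] = df["chrom"].astype(int)
    df["pos"] = df["pos"].astype(int)
    df["allele1"] = df["allele1"].fillna(MISSING)
    df["allele2"] = df["allele2"].fillna(MISSING)
    if phenotypes is None:
        phenotypes = list(pd.unique(df["phenotype"]))
    return LandscapeTable(frame=df[CANONICAL_COLUMNS], phenotypes=phenotypes,
                          metadata={"coordinate_system": "1-based"})
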