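"""Summary-statistics-only linkage-disequilibrium analytics.

No genotypes are required anywhere in this module: LD between a lead SNP and
its in-segment neighbours comes from a pluggable backend — either an offline
pairwise table (PLINK ``.ld``-style) or an Ensembl-compatible REST service.
On top of the backend sit the landscape's LD features:

* ``ld_neighbors``   — the SNPs linked to a displayed lead at r2/D' >= 0.75
  (the pop-up list);
* ``mutual_ld``      — linked SNPs shared between phenotypes;
* ``linked_proportion`` — of the genome-wide-significant SNPs in a segment,
  the fraction linked to the lead;
* ``thin_snps``      — recursive clumping without genotypes: repeatedly take
  the most significant remaining SNP and discard everything linked to it,
  surfacing independent signals buried under the top peak;
* ``categorize_locus`` — the concordance categorizer for externally reported
  lead SNPs: A (identical to the displayed lead), B (in LD with it,
  strict r2 > 0.75 and D' > 0.75), C(k) (surfaced by thinning at depth k),
  or unmatched.
"""

from __future__ import annotations

import json
import math
import urllib.error
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence

from .ingest import SummaryRecord

__all__ = [
    "LDBackend",
    "LDUnavailableError",
    "LDPair",
    "LDSet",
    "TableLDBackend",
    "EnsemblRestBackend",
    "ld_neighbors",
    "mutual_ld",
    "linked_proportion",
    "ThinResult",
    "thin_snps",
    "Category",
    "categorize_locus",
]

DEFAULT_R2 = 0.75
DEFAULT_DPRIME = 0.75
DEFAULT_DEPTH_MAX = 3


class LDUnavailableError(RuntimeError):
    """The LD backend cannot be reached (transport failure, not unknown SNPs)."""


@dataclass(frozen=True)
class LDPair:
    snp_id: str
    r2: float
    dprime: float | None  # None when the source table carries no D' column


class LDBackend(Protocol):
    """Query contract: pairwise LD of one lead against candidate SNPs.

    ``query`` returns one :class:`LDPair` per candidate known to the backend;
    unknown SNPs are simply absent. Values are symmetric: querying (a, {b})
    and (b, {a}) return identical r2/D'. A backend that cannot be reached
    raises :class:`LDUnavailableError`.
    """

    label: str

    def query(self, lead: str, candidates: Sequence[str], chrom: int | None = None) -> dict[str, LDPair]:
        ...


class TableLDBackend:
    """Offline backend over a PLINK-style pairwise LD table.

    Expected whitespace-delimited columns (header required):
    ``CHR_A BP_A SNP_A CHR_B BP_B SNP_B R2 [DP]``. The table is symmetrized
    on load, so a pair listed in either orientation answers both.
    """

    label = "table"

    def __init__(self, pairs: Mapping[tuple[str, str], tuple[float, float | None]] | None = None):
        self._pairs: dict[tuple[str, str], tuple[float, float | None]] = {}
        if pairs:
            for (a, b), (r2, dp) in pairs.items():
                self.add(a, b, r2, dp)

    def add(self, a: str, b: str, r2: float, dprime: float | None = None) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r2 must be in [0, 1], got {r2} for ({a}, {b})")
        if dprime is not None and not (0.0 <= dprime <= 1.0):
            raise ValueError(f"D' must be in [0, 1], got {dprime} for ({a}, {b})")
        key = (a, b) if a <= b else (b, a)
        self._pairs[key] = (float(r2), None if dprime is None else float(dprime))

    @classmethod
    def from_file(cls, path: str | Path) -> "TableLDBackend":
        path = Path(path)
        backend = cls()
        with open(path) as fh:
            header = fh.readline().split()
            cols = {name: i for i, name in enumerate(header)}
            for need in ("SNP_A", "SNP_B", "R2"):
                if need not in cols:
                    raise ValueError(f"{path}: LD table missing column {need!r}; header: {header}")
            has_dp = "DP" in cols
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                dp = float(parts[cols["DP"]]) if has_dp else None
                backend.add(parts[cols["SNP_A"]], parts[cols["SNP_B"]], float(parts[cols["R2"]]), dp)
        return backend

    def query(self, lead: str, candidates: Sequence[str], chrom: int | None = None) -> dict[str, LDPair]:
        out: dict[str, LDPair] = {}
        for cand in candidates:
            key = (lead, cand) if lead <= cand else (cand, lead)
            hit = self._pairs.get(key)
            if hit is not None:
                out[cand] = LDPair(snp_id=cand, r2=hit[0], dprime=hit[1])
        return out


class EnsemblRestBackend:
    """Ensembl-compatible REST LD backend (live queries; not used in tests).

    Queries ``GET <base>/ld/human/pairwise/<a>/<b>?population_name=<pop>``
    and caches pairs in memory for the process lifetime.
    """

    label = "ensembl-rest"

    def __init__(self, base_url: str = "https://rest.ensembl.org",
                 population: str = "1000GENOMES:phase_3:EUR", timeout: float = 10.0):
        self.base_url = base_url.rstrip("/")
        self.population = population
        self.timeout = timeout
        self._cache: dict[tuple[str, str], LDPair | None] = {}

    def _fetch_pair(self, a: str, b: str) -> LDPair | None:
        key = (a, b) if a <= b else (b, a)
        if key in self._cache:
            return self._cache[key]
        url = (f"{self.base_url}/ld/human/pairwise/{key[0]}/{key[1]}"
               f"?population_name={self.population};content-type=application/json")
        try:
            with urllib.request.urlopen(url, timeout=self.timeout) as resp:
                payload = json.load(resp)
        except urllib.error.HTTPError as exc:
            if exc.code == 400:  # unknown variant
                self._cache[key] = None
                return None
            raise LDUnavailableError(f"LD service error {exc.code} for {url}") from exc
        except (urllib.error.URLError, TimeoutError) as exc:
            raise LDUnavailableError(f"LD service unreachable: {exc}") from exc
        pair: LDPair | None = None
        if payload:
            entry = payload[0]
            pair = LDPair(snp_id=b, r2=float(entry["r2"]), dprime=float(entry.get("d_prime", math.nan)))
        self._cache[key] = pair
        return pair

    def query(self, lead: str, candidates: Sequence[str], chrom: int | None = None) -> dict[str, LDPair]:
        out: dict[str, LDPair] = {}
        for cand in candidates:
            pair = self._fetch_pair(lead, cand)
            if pair is not None:
                out[cand] = LDPair(snp_id=cand, r2=pair.r2, dprime=pair.dprime)
        return out


@dataclass
class LDSet:
    """SNPs linked to a lead at the display thresholds (r2 and D' >= 0.75).

    ``members`` hold every candidate meeting *both* thresholds; the lead is
    never its own member. ``above_threshold`` is the set of candidates that
    were genome-wide significant, used by :func:`linked_proportion`.
    """

    lead: str
    members: list[LDPair]
    r2_min: float
    dprime_min: float
    backend_label: str
    above_threshold: frozenset[str] = frozenset()

    @property
    def member_ids(self) -> list[str]:
        return [m.snp_id for m in self.members]

    @property
    def n_candidates_above_threshold(self) -> int:
        return len(self.above_threshold)


def _meets(pair: LDPair, r2_min: float, dprime_min: float) -> bool:
    if pair.r2 < r2_min:
        return False
    if pair.dprime is None:  # no D' in source: only the r2 threshold can apply
        return True
    return pair.dprime >= dprime_min


def _meets_strict(pair: LDPair, r2_min: float, dprime_min: float) -> bool:
    if pair.r2 <= r2_min:
        return False
    if pair.dprime is None:
        return True
    return pair.dprime > dprime_min


def ld_neighbors(
    backend: LDBackend,
    lead: str,
    candidates: Iterable[str],
    r2_min: float = DEFAULT_R2,
    dprime_min: float = DEFAULT_DPRIME,
    significant_ids: Iterable[str] | None = None,
) -> LDSet:
    """SNPs in LD with ``lead`` at both thresholds (>=, the display rule).

    Candidates unknown to the backend are silently absent. ``significant_ids``
    optionally records which candidates passed the genome-wide significance
    threshold, enabling :func:`linked_proportion`.
    """
    for t, name in ((r2_min, "r2_min"), (dprime_min, "dprime_min")):
        if not (0.0 <= t <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {t}")
    cands = [c for c in dict.fromkeys(candidates) if c != lead]
    pairs = backend.query(lead, cands, None)
    members = [pairs[c] for c in cands if c in pairs and _meets(pairs[c], r2_min, dprime_min)]
    sig = frozenset(significant_ids) if significant_ids is not None else frozenset()
    return LDSet(lead=lead, members=members, r2_min=r2_min, dprime_min=dprime_min,
                 backend_label=backend.label, above_threshold=sig)


def mutual_ld(sets: Mapping[str, LDSet], positions: Mapping[str, int] | None = None) -> list[str]:
    """SNP ids linked to the lead in *every* supplied phenotype's LD set.

    Sorted by genomic position when positions are known, else lexicographic.
    """
    if len(sets) < 2:
        raise ValueError(f"mutual LD needs >= 2 phenotypes, got {len(sets)}")
    ids = [set(s.member_ids) for s in sets.values()]
    shared = set.intersection(*ids)
    if positions:
        return sorted(shared, key=lambda s: (positions.get(s, math.inf), s))
    return sorted(shared)


def linked_proportion(ldset: LDSet) -> float | None:
    """Fraction of above-threshold segment SNPs linked to the lead.

    Returns None (undefined) when no candidate reached the significance
    threshold — deliberately distinct from a true 0.
    """
    n = ldset.n_candidates_above_threshold
    if n == 0:
        return None
    linked = len(set(ldset.member_ids) & ldset.above_threshold)
    return linked / n


@dataclass
class ThinResult:
    """Leads surfaced by recursive clumping, in discovery order."""

    leads: list[SummaryRecord]
    exhausted: bool  # ran out of records before reaching the requested depth
    error: str | None = None


def _rank_key(rec: SummaryRecord) -> tuple:
    return (-rec.neglog10p, rec.pos, rec.snp_id)


def thin_snps(
    records: Sequence[SummaryRecord],
    backend: LDBackend,
    depth: int,
    r2_min: float = DEFAULT_R2,
    dprime_min: float = DEFAULT_DPRIME,
) -> ThinResult:
    """Recursive clumping of one phenotype's in-segment records.

    Iteration k takes the most significant remaining record as lead k, then
    removes it and every record the backend links to it at both thresholds
    (significant or not). Depth 1 therefore always returns the segment
    maximum, and successive leads are pairwise non-linked. Stops early when
    the segment is exhausted; a backend failure mid-recursion returns the
    partial result with an error message.
    """
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    if not records:
        raise ValueError("thin_snps requires a non-empty record list")
    remaining = sorted(records, key=_rank_key)
    leads: list[SummaryRecord] = []
    while remaining and len(leads) < depth:
        lead = remaining.pop(0)
        leads.append(lead)
        if not remaining:
            break
        try:
            pairs = backend.query(lead.snp_id, [r.snp_id for r in remaining], lead.chrom)
        except LDUnavailableError as exc:
            return ThinResult(leads=leads, exhausted=False, error=str(exc))
        remaining = [
            r for r in remaining
            if r.snp_id not in pairs or not _meets(pairs[r.snp_id], r2_min, dprime_min)
        ]
    return ThinResult(leads=leads, exhausted=not remaining)


@dataclass(frozen=True)
class Category:
    """Concordance category of an externally reported lead SNP.

    ``kind`` is "A", "B", "C" or "unmatched"; ``level`` is the 1-based
    thinning depth for C; ``reason`` explains an unmatched outcome.
    """

    kind: str
    level: int | None = None
    reason: str | None = None

    def __str__(self) -> str:
        if self.kind == "C":
            return f"C({self.level})"
        return self.kind


def categorize_locus(
    reported_snp: str,
    segment_cell: SummaryRecord,
    records: Sequence[SummaryRecord],
    backend: LDBackend,
    depth_max: int = DEFAULT_DEPTH_MAX,
    r2_min: float = DEFAULT_R2,
    dprime_min: float = DEFAULT_DPRIME,
) -> Category:
    """Classify a reported SNP against the segment's displayed lead.

    A — the reported SNP *is* the displayed lead. B — it is in LD with the
    lead at strict thresholds (r2 > 0.75 and D' > 0.75). C(k) — neither, but
    recursive thinning surfaces it (or a SNP in strict LD with it) as the
    depth-k lead, k <= depth_max. Otherwise unmatched.
    """
    if reported_snp == segment_cell.snp_id:
        return Category("A")
    known_ids = {r.snp_id for r in records}
    pairs = backend.query(segment_cell.snp_id, [reported_snp], segment_cell.chrom)
    known_to_backend = reported_snp in pairs
    if known_to_backend and _meets_strict(pairs[reported_snp], r2_min, dprime_min):
        return Category("B")
    if reported_snp not in known_ids and not known_to_backend:
        return Category("unmatched", reason="reported SNP absent from records and unknown to LD backend")
    thin = thin_snps(records, backend, depth=depth_max, r2_min=r2_min, dprime_min=dprime_min)
    for k, lead in enumerate(thin.leads, start=1):
        if lead.snp_id == reported_snp:
            return Category("C", level=k)
        lead_pairs = backend.query(lead.snp_id, [reported_snp], lead.chrom)
        if reported_snp in lead_pairs and _meets_strict(lead_pairs[reported_snp], r2_min, dprime_min):
            return Category("C", level=k)
    return Category("unmatched", reason=f"not surfaced by thinning within depth {depth_max}")
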