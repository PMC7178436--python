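"""SNP-to-gene mapping by interval overlap and the gene-view heatmap.

Genes come from a user-supplied 4-column BED (chrom, start, end, symbol).
A SNP maps to every gene whose interval, widened by a window (100 kb by
default, matching the mapping convention of large lipid-consortium loci),
contains its position. The gene-view matrix is a binary phenotype-sharing
heatmap: within a group of chromosome segments, a (gene, phenotype) cell is
lit when that phenotype has at least one above-threshold SNP mapped to the
gene — uniform brightness, so secondary signals are not visually masked by
the dominant peak the way they can be on the graded -log10(p) scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

from .ingest import LandscapeTable, normalize_chrom
from .segmentation import SegmentScheme

__all__ = [
    "GeneIntervalMap",
    "GeneViewMatrix",
    "load_gene_intervals",
    "map_snp_to_genes",
    "gene_view_matrix",
]

DEFAULT_GENE_WINDOW_BP = 100_000


@dataclass
class GeneIntervalMap:
    """Per-chromosome gene intervals, 1-based closed, with a point-query index.

    Intervals may overlap (real genes do); queries return all hits.
    """

    trees: dict[int, IntervalTree] = field(default_factory=dict)
    n_skipped_non_autosomal: int = 0
    n_intervals: int = 0

    def add(self, chrom: int, start: int, end: int, symbol: str) -> None:
        tree = self.trees.setdefault(chrom, IntervalTree())
        # IntervalTree is half-open; store [start, end] as [start, end + 1).
        tree.addi(start, end + 1, symbol)
        self.n_intervals += 1


def load_gene_intervals(path: str | Path) -> GeneIntervalMap:
    """Load a 4-column BED (chrom, start, end, symbol) of gene intervals.

    BED 0-based half-open coordinates become 1-based closed; exact duplicate
    lines collapse to one interval; non-autosomal entries are skipped and
    counted. A missing symbol column is an error.
    """
    path = Path(path)
    gmap = GeneIntervalMap()
    seen: set[tuple[int, int, int, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: gene BED needs 4 columns (chrom start end symbol)")
            chrom = normalize_chrom(parts[0])
            if chrom is None:
                gmap.n_skipped_non_autosomal += 1
                continue
            start0, end0 = int(parts[1]), int(parts[2])
            key = (chrom, start0 + 1, end0, parts[3])
            if key in seen:
                continue
            seen.add(key)
            gmap.add(chrom, start0 + 1, end0, parts[3])
    return gmap


def map_snp_to_genes(
    gmap: GeneIntervalMap, chrom: int, pos: int, window_bp: int = DEFAULT_GENE_WINDOW_BP
) -> list[str]:
    """All gene symbols whose window-expanded interval contains ``pos``.

    Symbols are ordered by ascending distance from the SNP to the
    *unexpanded* interval (0 for SNPs inside the gene), ties alphabetical.
    """
    tree = gmap.trees.get(chrom)
    if tree is None:
        return []
    hits = tree.overlap(pos - window_bp, pos + window_bp + 1)
    scored: list[tuple[int, str]] = []
    for iv in hits:
        start, end = iv.begin, iv.end - 1
        if pos < start:
            dist = start - pos
        elif pos > end:
            dist = pos - end
        else:
            dist = 0
        scored.append((dist, iv.data))
    seen: set[str] = set()
    out: list[str] = []
    for _, sym in sorted(scored):
        if sym not in seen:
            seen.add(sym)
            out.append(sym)
    return out


@dataclass
class GeneViewMatrix:
    """Binary gene x phenotype sharing matrix for a segment group.

    ``matrix[i, j] == 1`` iff phenotype j has >= 1 SNP above the significance
    threshold mapped to gene i; rows are sorted by genomic position of the
    gene's first above-threshold SNP.
    """

    genes: list[str]
    phenotypes: list[str]
    matrix: np.ndarray  # shape (len(genes), len(phenotypes)), dtype int8
    gene_positions: dict[str, int] = field(default_factory=dict)

    def is_empty(self) -> bool:
        return self.matrix.size == 0


def gene_view_matrix(
    table: LandscapeTable,
    chrom: int,
    segment_group: Iterable[int],
    gmap: GeneIntervalMap,
    scheme: SegmentScheme,
    threshold: float,
    window_bp: int = DEFAULT_GENE_WINDOW_BP,
) -> GeneViewMatrix:
    """Build the gene-view heatmap for a group of segments on one chromosome.

    Every record with -log10(p) > ``threshold`` inside the segment group is
    mapped to genes; each mapped gene lights the record's phenotype column.
    """
    segments = set(int(s) for s in segment_group)
    if not segments:
        raise ValueError("segment_group must be non-empty")
    phenotypes = list(table.phenotypes)
    df = table.frame
    df = df[(df["chrom"] == chrom) & (df["neglog10p"] > threshold)]
    lit: dict[str, set[str]] = {}
    first_pos: dict[str, int] = {}
    for _, row in df.iterrows():
        pos = int(row["pos"])
        if scheme.assign(chrom, pos) not in segments:
            continue
        for sym in map_snp_to_genes(gmap, chrom, pos, window_bp):
            lit.setdefault(sym, set()).add(str(row["phenotype"]))
            first_pos[sym] = min(first_pos.get(sym, pos), pos)
    genes = sorted(lit, key=lambda g: (first_pos[g], g))
    matrix = np.zeros((len(genes), len(phenotypes)), dtype=np.int8)
    for i, g in enumerate(genes):
        for j, p in enumerate(phenotypes):
            if p in lit[g]:
                matrix[i, j] = 1
    return GeneViewMatrix(genes=genes, phenotypes=phenotypes, matrix=matrix, gene_positions=first_pos)
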