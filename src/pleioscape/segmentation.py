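"""Chromosome segmentation: fixed-width bins or LD-block intervals.

A chromosome is partitioned into base-pair interval segments either as
equal-width bins (default 1 Mb) or from a BED file of population LD blocks.
Internal coordinates are 1-based closed; BED input (0-based half-open) is
converted here and nowhere else. In fixed mode segment ``k`` covers positions
``[k*width + 1, (k+1)*width]``, so with 1 Mb bins "region 45" of a chromosome
is 45,000,001-46,000,000.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path

from .ingest import normalize_chrom

__all__ = ["SegmentScheme", "SegmentationError", "fixed_bins", "blocks_from_bed", "assign_segment"]

DEFAULT_BIN_BP = 1_000_000


class SegmentationError(ValueError):
    pass


@dataclass(frozen=True)
class SegmentScheme:
    """Partition of chromosomes into interval segments.

    ``mode="fixed"``: every chromosome shares the same bin width.
    ``mode="blocks"``: per-chromosome sorted non-overlapping 1-based closed
    intervals; gaps between blocks are allowed, and positions falling in a
    gap have no segment.
    """

    mode: str
    width: int | None = None
    blocks: dict[int, list[tuple[int, int]]] = field(default_factory=dict)

    def assign(self, chrom: int, pos: int) -> int | None:
        return assign_segment(self, chrom, pos)

    def interval(self, chrom: int, segment: int) -> tuple[int, int]:
        """1-based closed [start, end] of a segment."""
        if self.mode == "fixed":
            assert self.width is not None
            return segment * self.width + 1, (segment + 1) * self.width
        return self.blocks[chrom][segment]

    def label(self, chrom: int, segment: int) -> str:
        return f"chr{chrom}:{segment}"


def fixed_bins(width_bp: int = DEFAULT_BIN_BP) -> SegmentScheme:
    """Fixed-width scheme; the default bin is 1 M base pairs."""
    width_bp = int(width_bp)
    if width_bp <= 0:
        raise SegmentationError(f"bin width must be positive, got {width_bp}")
    return SegmentScheme(mode="fixed", width=width_bp)


def blocks_from_bed(path: str | Path) -> SegmentScheme:
    """Build a blocks-mode scheme from a 3+ column BED file of LD blocks.

    BED coordinates (0-based half-open) become internal 1-based closed
    intervals. Overlapping blocks on one chromosome are an error naming the
    offenders; non-autosomal lines are skipped.
    """
    path = Path(path)
    raw: dict[int, list[tuple[int, int]]] = {}
    n_usable = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise SegmentationError(f"{path}:{lineno}: expected >= 3 BED columns, got {len(parts)}")
            chrom = normalize_chrom(parts[0])
            try:
                start0, end0 = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise SegmentationError(f"{path}:{lineno}: non-integer coordinates {parts[1:3]}") from exc
            if end0 <= start0:
                raise SegmentationError(f"{path}:{lineno}: empty or inverted interval [{start0}, {end0})")
            if chrom is None:
                continue
            raw.setdefault(chrom, []).append((start0 + 1, end0))
            n_usable += 1
    if n_usable == 0:
        raise SegmentationError(f"{path}: no usable blocks")
    blocks: dict[int, list[tuple[int, int]]] = {}
    for chrom, ivals in raw.items():
        ivals = sorted(set(ivals))
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 <= e1:
                raise SegmentationError(
                    f"overlapping LD blocks on chr{chrom}: [{s1}, {e1}] and [{s2}, {e2}]"
                )
        blocks[chrom] = ivals
    return SegmentScheme(mode="blocks", blocks=blocks)


def assign_segment(scheme: SegmentScheme, chrom: int, pos: int) -> int | None:
    """Segment id containing ``pos``, or None for a blocks-mode gap.

    Fixed mode is the total step function ``(pos - 1) // width``.
    """
    if pos < 1:
        raise ValueError(f"positions are 1-based, got {pos}")
    if scheme.mode == "fixed":
        assert scheme.width is not None
        return (pos - 1) // scheme.width
    ivals = scheme.blocks.get(chrom, [])
    i = bisect.bisect_right(ivals, (pos, float("inf"))) - 1
    if i >= 0 and ivals[i][0] <= pos <= ivals[i][1]:
        return i
    return None
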