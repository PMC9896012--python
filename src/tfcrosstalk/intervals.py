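"""Genomic intervals and overlap primitives.

All coordinates are 0-based half-open (BED convention). Chromosome names
are taken verbatim from inputs; no prefix normalisation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

VALID_STRANDS = ("+", "-", ".")


@dataclass
class GenomicInterval:
    """A half-open genomic span [start, end) with optional BED6 extras."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two spans share >= 1 bp on the same chromosome."""
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


def overlaps_any(
    queries: Sequence[GenomicInterval], targets: Sequence[GenomicInterval]
) -> np.ndarray:
    """Boolean mask over *queries*: does each overlap >= 1 bp of any target?

    Sorted-sweep per chromosome; equivalent to the all-pairs check but
    O((n+m) log m).
    """
    mask = np.zeros(len(queries), dtype=bool)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for t in targets:
        by_chrom.setdefault(t.chrom, []).append((t.start, t.end))
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        ms, me = [], []
        for s, e in spans:
            if ms and s <= me[-1]:
                me[-1] = max(me[-1], e)
            else:
                ms.append(s)
                me.append(e)
        merged[chrom] = (np.asarray(ms), np.asarray(me))
    for i, q in enumerate(queries):
        if q.chrom not in merged:
            continue
        starts, ends = merged[q.chrom]
        # candidate merged block: last block starting before q.end
        j = int(np.searchsorted(starts, q.end, side="left")) - 1
        if j >= 0 and ends[j] > q.start:
            mask[i] = True
    return mask


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge intervals that overlap by >= 1 bp into maximal blocks."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start < cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out
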