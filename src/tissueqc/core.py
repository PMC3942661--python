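"""Shared data containers for the QC pipeline.

Coordinate conventions: 0-based half-open everywhere in memory; SAM
(1-based) and GTF (1-based closed) offsets are applied only at I/O
boundaries.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

BASES = "ACGTN"


@dataclass
class ReadPair:
    """One sequenced fragment: two mates with Phred scores (0-60)."""

    id: str
    bases1: str
    quals1: np.ndarray
    bases2: str
    quals2: np.ndarray

    def __post_init__(self) -> None:
        self.quals1 = np.asarray(self.quals1, dtype=np.int64)
        self.quals2 = np.asarray(self.quals2, dtype=np.int64)
        if len(self.bases1) != len(self.quals1) or len(self.bases2) != len(self.quals2):
            raise ValueError(f"read {self.id}: bases and quality lengths differ")

    @property
    def mates(self):
        return (self.bases1, self.quals1), (self.bases2, self.quals2)


@dataclass
class AlignmentRecord:
    """Placement of one mate on a reference.

    ``start`` is 0-based; ``length`` is the aligned span on the
    reference (single gapless block). ``qual_sum`` carries the summed
    base qualities used for duplicate tie-breaking.
    """

    read_id: str
    mate: int  # 1 or 2
    reference: str
    start: int
    strand: str  # '+' or '-'
    length: int
    mapq: int
    mate_reference: str = ""
    mate_start: int = 0
    qual_sum: int = 0

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("alignment start must be >= 0")
        if not 0 <= self.mapq <= 255:
            raise ValueError("mapping quality must be in [0, 255]")
        if self.mate not in (1, 2):
            raise ValueError("mate index must be 1 or 2")

    @property
    def end(self) -> int:
        return self.start + self.length


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/touching half-open intervals."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass
class GeneModel:
    """Gene with exon intervals; union-exon length is the FPKM length."""

    gene_id: str
    reference: str
    strand: str
    exons: list[tuple[int, int]]  # 0-based half-open, sorted on construction

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"gene {self.gene_id}: empty exon ({s}, {e})")

    @property
    def union_exons(self) -> list[tuple[int, int]]:
        return merge_intervals(self.exons)

    @property
    def union_length(self) -> int:
        return sum(e - s for s, e in self.union_exons)

    @property
    def span(self) -> tuple[int, int]:
        ex = self.union_exons
        return ex[0][0], ex[-1][1]

    # -- spliced ("transcript") coordinate helpers -------------------------
    def _offsets(self) -> list[tuple[int, int, int]]:
        """(genomic_start, genomic_end, transcript_offset) per union exon."""
        out, off = [], 0
        for s, e in self.union_exons:
            out.append((s, e, off))
            off += e - s
        return out

    def transcript_to_genome(self, tpos: int) -> int:
        for s, e, off in self._offsets():
            if off <= tpos < off + (e - s):
                return s + (tpos - off)
        raise ValueError(f"transcript position {tpos} outside gene {self.gene_id}")

    def genome_to_transcript_intervals(
        self, start: int, end: int
    ) -> list[tuple[int, int]]:
        """Project a genomic interval onto spliced coordinates (may be empty)."""
        out = []
        for s, e, off in self._offsets():
            lo, hi = max(start, s), min(end, e)
            if hi > lo:
                out.append((off + lo - s, off + hi - s))
        return merge_intervals(out)


@dataclass
class CountMatrix:
    """Integer fragment counts (genes x libraries) plus library metadata.

    ``meta`` is indexed by library name with at least columns
    ``group`` and ``cdna_input``.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.meta.empty and list(self.meta.index) != list(self.counts.columns):
            raise ValueError("metadata index must match count matrix columns")

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    def subset(self, libraries: Sequence[str]) -> "CountMatrix":
        libraries = list(libraries)
        meta = self.meta.loc[libraries] if not self.meta.empty else self.meta
        return CountMatrix(self.counts[libraries].copy(), meta.copy())
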