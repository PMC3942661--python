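"""Read-level quality filters, 5' trimming and nucleotide-bias profiling.

A pair is dropped when *either* mate fails *any* rule; the rules are
checked in a fixed order (unknown nucleotides, homopolymers, mean Phred)
and the first failing rule is reported. Trimming removes the leading k
cycles of both mates and is applied before filtering, so reads whose
mean quality is dragged down by degraded 5' cycles can be rescued.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import groupby
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import BASES, ReadPair

DROP_REASONS = ("unknown_nt", "homopolymer", "low_quality")


@dataclass
class FilterThresholds:
    """Defaults follow the standard protocol: no N allowed, homopolymer
    runs >= 50 nt, mean Phred < 30, optional 5' trim of 10 cycles."""

    max_n: int = 0
    homopolymer_min: int = 50
    mean_phred_min: float = 30.0
    trim5: int = 0

    def __post_init__(self) -> None:
        if self.homopolymer_min < 1:
            raise ValueError("homopolymer_min must be >= 1")
        if self.trim5 < 0:
            raise ValueError("trim5 must be >= 0")
        if self.max_n < 0:
            raise ValueError("max_n must be >= 0")


@dataclass
class FilterVerdict:
    keep: bool
    reason: str | None = None  # first failing rule when dropped


def _max_run(bases: str) -> int:
    """Longest run of one identical base; N neither forms nor extends runs."""
    best = 0
    for base, grp in groupby(bases):
        if base != "N":
            best = max(best, sum(1 for _ in grp))
    return best


def filter_read_pair(pair: ReadPair, thresholds: FilterThresholds) -> FilterVerdict:
    mates = pair.mates
    if thresholds.max_n is not None:
        for bases, _ in mates:
            if bases.count("N") > thresholds.max_n:
                return FilterVerdict(False, "unknown_nt")
    for bases, _ in mates:
        if _max_run(bases) >= thresholds.homopolymer_min:
            return FilterVerdict(False, "homopolymer")
    for bases, quals in mates:
        # empty mate carries no quality evidence: dropped as low quality
        if len(quals) == 0 or float(np.mean(quals)) < thresholds.mean_phred_min:
            return FilterVerdict(False, "low_quality")
    return FilterVerdict(True)


def trim_five_prime(pair: ReadPair, k: int) -> ReadPair:
    """Remove the first k bases and quality scores from each mate."""
    if k < 0:
        raise ValueError("trim length must be >= 0")
    if k == 0:
        return pair
    if k >= min(len(pair.bases1), len(pair.bases2)):
        raise ValueError(
            f"trim length {k} >= mate length "
            f"{min(len(pair.bases1), len(pair.bases2))}"
        )
    return ReadPair(
        pair.id, pair.bases1[k:], pair.quals1[k:], pair.bases2[k:], pair.quals2[k:]
    )


@dataclass
class FilterSummary:
    """Stream-level tally of a filtering pass."""

    total: int = 0
    kept: int = 0
    dropped_by_reason: dict = field(
        default_factory=lambda: {r: 0 for r in DROP_REASONS}
    )

    @property
    def dropped(self) -> int:
        return self.total - self.kept


def filter_reads(
    pairs: Iterable[ReadPair], thresholds: FilterThresholds
) -> tuple[list[ReadPair], FilterSummary]:
    """Trim (if configured) then filter a stream of pairs."""
    summary = FilterSummary()
    kept: list[ReadPair] = []
    for pair in pairs:
        if thresholds.trim5:
            pair = trim_five_prime(pair, thresholds.trim5)
        summary.total += 1
        verdict = filter_read_pair(pair, thresholds)
        if verdict.keep:
            summary.kept += 1
            kept.append(pair)
        else:
            summary.dropped_by_reason[verdict.reason] += 1
    return kept, summary


@dataclass
class NucleotideProfile:
    """Per-position A/C/G/T/N counts over the first P sequencing cycles."""

    counts: np.ndarray  # shape (P, 5), columns ordered ACGTN
    total: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts.sum(axis=1) != self.total).any():
            raise ValueError("per-position counts must sum to the read total")

    @property
    def positions(self) -> int:
        return self.counts.shape[0]

    def fractions(self) -> np.ndarray:
        return self.counts / self.total

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(BASES))
        df.index = pd.RangeIndex(1, self.positions + 1, name="position")
        return df


def nucleotide_profile(reads: Iterable[str | ReadPair], positions: int) -> NucleotideProfile:
    """Exact per-position base tallies over the first ``positions`` cycles.

    Accepts base strings or read pairs (both mates are profiled).
    """
    seqs: list[str] = []
    for r in reads:
        if isinstance(r, ReadPair):
            seqs.extend((r.bases1, r.bases2))
        else:
            seqs.append(r)
    if not seqs:
        raise ValueError("no reads to profile")
    if min(len(s) for s in seqs) < positions:
        raise ValueError("profile positions exceed minimum read length")
    counts = np.zeros((positions, 5), dtype=np.int64)
    lookup = {b: i for i, b in enumerate(BASES)}
    for s in seqs:
        for p in range(positions):
            counts[p, lookup[s[p]]] += 1
    return NucleotideProfile(counts, len(seqs))


def bias_score(profile: NucleotideProfile, m: int) -> float:
    """Largest total-variation distance between any of the first m
    positions' base distributions and the pooled distribution of
    positions m+1..P. 0 means no 5' composition bias; 1 is maximal."""
    if profile.positions < m + 10:
        raise ValueError("profile must cover at least m + 10 positions")
    freqs = profile.fractions()
    pooled = profile.counts[m:].sum(axis=0).astype(float)
    if pooled.sum() <= 0:
        raise ValueError("degenerate pooled distribution")
    pooled /= pooled.sum()
    tv = 0.5 * np.abs(freqs[:m] - pooled).sum(axis=1)
    return float(tv.max())


def filter_truth_scores(
    labels: pd.DataFrame, verdicts: Sequence[tuple[str, bool]]
) -> dict[str, float]:
    """Precision/recall of the drop decision against simulator truth.

    Truth positives are the constructed QC-failing categories
    (``corrupt_*``); ``verdicts`` holds (read_id, kept).
    """
    truth_drop = {
        r.read_id: r.category.startswith("corrupt_") for r in labels.itertuples()
    }
    tp = fp = fn = 0
    for read_id, kept in verdicts:
        dropped = not kept
        if dropped and truth_drop[read_id]:
            tp += 1
        elif dropped:
            fp += 1
        elif truth_drop[read_id]:
            fn += 1
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    return {"precision": precision, "recall": recall}
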