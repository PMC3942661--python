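"""Audit of shRNA-transgene interference with target-gene quantification.

In an unstranded library, reads from a double-stranded shRNA hairpin
homologous to the 3' half of its target are indistinguishable from
endogenous transcript reads. The audit (i) profiles fragment coverage
along the target's spliced gene model, (ii) compares the fraction of
target fragments falling in the shRNA-homologous region between
knockdown and control groups, and (iii) re-quantifies the target using
only fragments confined to the non-targeted 5' region, whose sole
possible origin is the endogenous gene.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import AlignmentRecord, GeneModel
from .de import nb_test
from .quant import pair_alignments


@dataclass
class RegionPartition:
    """Split of a gene's spliced coordinates into the shRNA-homologous
    (targeted) interval and the non-targeted 5' remainder."""

    gene_id: str
    targeted: tuple[int, int]  # half-open, spliced coordinates
    non_targeted: tuple[int, int]

    def __post_init__(self) -> None:
        for name, (s, e) in (
            ("targeted", self.targeted),
            ("non_targeted", self.non_targeted),
        ):
            if s < 0 or e < s:
                raise ValueError(f"{name} interval invalid: {(s, e)}")
        lo = max(self.targeted[0], self.non_targeted[0])
        hi = min(self.targeted[1], self.non_targeted[1])
        if hi > lo:
            raise ValueError("targeted and non-targeted intervals overlap")

    def validate_against(self, gene: GeneModel) -> None:
        L = gene.union_length
        for s, e in (self.targeted, self.non_targeted):
            if e > L:
                raise ValueError(f"interval {(s, e)} exceeds gene length {L}")


def _fragment_intervals(
    alignments: Iterable[AlignmentRecord], gene: GeneModel
) -> list[tuple[int, int]]:
    """Spliced-coordinate extent of each fragment overlapping the gene."""
    pairs, _ = pair_alignments(alignments)
    out = []
    for m1, m2 in pairs:
        pieces = []
        for rec in (m1, m2):
            if rec.reference != gene.reference:
                continue
            pieces.extend(gene.genome_to_transcript_intervals(rec.start, rec.end))
        if pieces:
            out.append((min(s for s, _ in pieces), max(e for _, e in pieces)))
    return out


def coverage_profile(
    alignments: Iterable[AlignmentRecord], gene: GeneModel, n_bins: int
) -> np.ndarray:
    """Fragment counts along the gene's spliced span, in equal bins.

    A fragment increments every bin its spliced extent overlaps.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    L = gene.union_length
    edges = np.linspace(0, L, n_bins + 1)
    bins = np.zeros(n_bins, dtype=np.int64)
    for s, e in _fragment_intervals(alignments, gene):
        first = int(np.searchsorted(edges, s, side="right") - 1)
        last = int(np.searchsorted(edges, max(e - 1, s), side="right") - 1)
        bins[max(first, 0) : min(last, n_bins - 1) + 1] += 1
    return bins


@dataclass
class InterferenceResult:
    ratio: float  # R = mean targeted-fraction (knockdown) / (control)
    fractions: pd.Series  # per-library targeted-region fragment fraction
    flagged: bool
    excluded: list  # libraries without target fragments
    threshold: float


def interference_statistic(
    alignments_by_library: Mapping[str, Iterable[AlignmentRecord]],
    groups: Mapping[str, str],
    gene: GeneModel,
    partition: RegionPartition,
    control_group: str = "WT",
    threshold: float = 1.5,
) -> InterferenceResult:
    """Targeted-region fragment-fraction ratio between groups.

    Per library, f is the fraction of the gene's fragments whose spliced
    midpoint lies inside the targeted region; R is the mean f of the
    knockdown group over the mean f of the control group. R far above 1
    means the targeted region accumulates extra reads in knockdown
    libraries, i.e. suspected shRNA interference.
    """
    partition.validate_against(gene)
    t_lo, t_hi = partition.targeted
    fractions = {}
    excluded = []
    for lib, alignments in alignments_by_library.items():
        frags = _fragment_intervals(alignments, gene)
        if not frags:
            warnings.warn(f"library {lib}: no fragments on {gene.gene_id}; excluded")
            excluded.append(lib)
            continue
        mids = [(s + e) / 2.0 for s, e in frags]
        fractions[lib] = float(np.mean([t_lo <= m < t_hi for m in mids]))
    f = pd.Series(fractions, dtype=float)
    in_control = [lib for lib in f.index if groups[lib] == control_group]
    in_kd = [lib for lib in f.index if groups[lib] != control_group]
    if not in_control or not in_kd:
        raise ValueError("need >= 1 usable library per group")
    mean_control = f[in_control].mean()
    if mean_control == 0:
        ratio = float("inf") if f[in_kd].mean() > 0 else 1.0
    else:
        ratio = float(f[in_kd].mean() / mean_control)
    return InterferenceResult(ratio, f, ratio > threshold, excluded, threshold)


def region_restricted_counts(
    alignments_by_library: Mapping[str, Iterable[AlignmentRecord]],
    gene: GeneModel,
    partition: RegionPartition,
) -> pd.Series:
    """Fragments overlapping only the non-targeted 5' interval, per library.

    Fragments touching the targeted region are excluded in every
    library, so the restriction is symmetric between groups.
    """
    partition.validate_against(gene)
    n_lo, n_hi = partition.non_targeted
    if n_hi <= n_lo:
        raise ValueError("non-targeted region is empty")
    t_lo, t_hi = partition.targeted
    counts = {}
    for lib, alignments in alignments_by_library.items():
        n = 0
        for s, e in _fragment_intervals(alignments, gene):
            touches_targeted = s < t_hi and t_lo < e
            touches_non = s < n_hi and n_lo < e
            if touches_non and not touches_targeted:
                n += 1
        counts[lib] = n
    return pd.Series(counts, dtype=np.int64)


def region_restricted_de(
    alignments_by_library: Mapping[str, Iterable[AlignmentRecord]],
    gene: GeneModel,
    partition: RegionPartition,
    groups: Mapping[str, str],
    factors: pd.Series,
    dispersion: float,
) -> pd.DataFrame:
    """NB test of the target gene on 5'-restricted counts.

    Uses the global size factors (the restriction changes one gene, not
    library depth) and a supplied dispersion.
    """
    restricted = region_restricted_counts(alignments_by_library, gene, partition)
    counts = restricted.to_frame().T
    counts.index = [gene.gene_id]
    counts = counts[list(factors.index)]
    return nb_test(
        counts,
        pd.Series({lib: groups[lib] for lib in counts.columns}),
        factors=factors,
        pooled_dispersion=dispersion,
    )
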