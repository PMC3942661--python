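"""PCR-duplicate removal, duplicate/input diagnostics, union-mode
fragment counting and FPKM normalization.

Duplicate pairs share a fragment signature (reference, leftmost start,
rightmost end, orientation); one representative is kept per signature
(highest summed base quality, first occurrence on ties), matching
paired-end ``rmdup`` semantics. Counting assigns one count per fragment
in union mode: the feature set is the union of genes whose exons
overlap either mate, with sets of size >= 2 ambiguous, empty sets
no_feature, and sub-threshold mapping quality counted separately.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .core import AlignmentRecord, GeneModel

CATEGORIES = ("counted", "ambiguous", "no_feature", "low_quality")


@dataclass(frozen=True)
class PairSignature:
    """Coordinates identifying one original cDNA fragment."""

    reference: str
    left_start: int
    right_end: int
    orientation: tuple[str, str]  # strands ordered by position

    def __post_init__(self) -> None:
        if self.left_start > self.right_end:
            raise ValueError("leftmost start must be <= rightmost end")


def pair_alignments(
    alignments: Iterable[AlignmentRecord],
) -> tuple[list[tuple[AlignmentRecord, AlignmentRecord]], list[AlignmentRecord]]:
    """Group records into (mate1, mate2) pairs; odd ones out are orphans."""
    seen: dict[str, AlignmentRecord] = {}
    pairs = []
    orphans = []
    for rec in alignments:
        if rec.read_id in seen:
            first = seen.pop(rec.read_id)
            if first.mate == rec.mate:
                orphans.extend((first, rec))
                continue
            pairs.append((first, rec) if first.mate == 1 else (rec, first))
        else:
            seen[rec.read_id] = rec
    orphans.extend(seen.values())
    return pairs, orphans


def fragment_signature(
    mate1: AlignmentRecord, mate2: AlignmentRecord
) -> PairSignature:
    if mate1.reference != mate2.reference:
        raise ValueError(f"pair {mate1.read_id} spans two references")
    left, right = sorted((mate1, mate2), key=lambda r: (r.start, r.end))
    return PairSignature(
        mate1.reference, left.start, max(left.end, right.end),
        (left.strand, right.strand),
    )


@dataclass
class DedupResult:
    alignments: list[AlignmentRecord]  # retained records, original order
    duplicate_rate: float
    n_pairs: int
    n_removed: int
    n_orphans: int


def remove_duplicates(alignments: Iterable[AlignmentRecord]) -> DedupResult:
    """Keep one pair per fragment signature.

    Orphan mates (no partner record) are excluded and tallied; pairs on
    two references cannot form a fragment and are treated the same way.
    """
    pairs, orphans = pair_alignments(alignments)
    best: dict[PairSignature, tuple[int, int]] = {}  # sig -> (qual, pair index)
    n_orphans = len(orphans)
    clean_pairs = []
    for idx, (m1, m2) in enumerate(pairs):
        try:
            sig = fragment_signature(m1, m2)
        except ValueError:
            n_orphans += 1
            continue
        clean_pairs.append((sig, m1, m2))
        qual = m1.qual_sum + m2.qual_sum
        if sig not in best or qual > best[sig][0]:
            best[sig] = (qual, len(clean_pairs) - 1)
    keep_idx = {i for _, i in best.values()}
    kept: list[AlignmentRecord] = []
    for i, (_, m1, m2) in enumerate(clean_pairs):
        if i in keep_idx:
            kept.extend((m1, m2))
    total = len(clean_pairs)
    removed = total - len(keep_idx)
    rate = removed / total if total else 0.0
    return DedupResult(kept, rate, total, removed, n_orphans)


@dataclass
class DuplicateDiagnostic:
    """Correlation between duplication and nominal cDNA input."""

    table: pd.DataFrame
    r_rate: float  # Pearson r of duplicate rate vs input
    r_count: float  # Pearson r of duplicate count vs input
    flagged: bool  # strong negative rate/input correlation
    note: str = ""


def duplicate_input_diagnostic(
    duplicate_rates: Sequence[float],
    cdna_inputs: Sequence[float],
    duplicate_counts: Sequence[float] | None = None,
    libraries: Sequence[str] | None = None,
    r_threshold: float = 0.8,
) -> DuplicateDiagnostic:
    rates = np.asarray(duplicate_rates, dtype=float)
    inputs = np.asarray(cdna_inputs, dtype=float)
    if len(rates) != len(inputs) or len(rates) < 3:
        raise ValueError("need matched rates and inputs for >= 3 libraries")
    counts = (
        np.asarray(duplicate_counts, dtype=float)
        if duplicate_counts is not None
        else rates
    )
    table = pd.DataFrame(
        {
            "library": list(libraries) if libraries is not None else list(range(len(rates))),
            "duplicate_rate": rates,
            "duplicate_count": counts,
            "cdna_input": inputs,
        }
    )
    if np.ptp(inputs) == 0 or np.ptp(rates) == 0:
        return DuplicateDiagnostic(
            table, float("nan"), float("nan"), False,
            note="correlation undefined: constant input or rate vector",
        )
    r_rate = float(stats.pearsonr(rates, inputs).statistic)
    r_count = float(stats.pearsonr(counts, inputs).statistic)
    flagged = abs(r_rate) > r_threshold and r_rate < 0
    return DuplicateDiagnostic(table, r_rate, r_count, flagged)


# -------------------------------------------------------------- counting
@dataclass
class CountResult:
    counts: pd.Series  # fragments per gene
    categories: dict  # counted/ambiguous/no_feature/low_quality tallies

    @property
    def total(self) -> int:
        return int(sum(self.categories.values()))


def build_exon_index(genes: Iterable[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        tree = trees.setdefault(g.reference, IntervalTree())
        for s, e in g.union_exons:
            tree.addi(s, e, g.gene_id)
    return trees


def count_union(
    alignments: Iterable[AlignmentRecord],
    genes: Sequence[GeneModel],
    min_mapq: int = 10,
) -> CountResult:
    """Union-mode fragment counting with a mapping-quality floor.

    Strand is ignored (unstranded protocol). Fragments with either mate
    below ``min_mapq`` are tallied as low_quality before any overlap
    test, mirroring ``htseq-count -a``.
    """
    genes = list(genes)
    trees = build_exon_index(genes)
    known_refs = {g.reference for g in genes}
    counts = pd.Series(0, index=[g.gene_id for g in genes], dtype=np.int64)
    cats = {c: 0 for c in CATEGORIES}
    pairs, orphans = pair_alignments(alignments)
    if orphans:
        raise ValueError(
            f"count_union expects deduplicated proper pairs; {len(orphans)} orphan records"
        )
    for m1, m2 in pairs:
        for rec in (m1, m2):
            if rec.reference not in known_refs:
                raise ValueError(f"alignment on unknown reference {rec.reference!r}")
        if min(m1.mapq, m2.mapq) < min_mapq:
            cats["low_quality"] += 1
            continue
        features: set[str] = set()
        for rec in (m1, m2):
            tree = trees.get(rec.reference)
            if tree is not None:
                features |= {iv.data for iv in tree.overlap(rec.start, rec.end)}
        if len(features) == 1:
            counts[features.pop()] += 1
            cats["counted"] += 1
        elif features:
            cats["ambiguous"] += 1
        else:
            cats["no_feature"] += 1
    return CountResult(counts, cats)


def fpkm(
    counts: pd.Series, genes: Sequence[GeneModel], counted_total: int | None = None
) -> pd.Series:
    """Fragments per kilobase of union-exon model per million counted
    fragments. The denominator defaults to the column's counted total."""
    lengths = pd.Series({g.gene_id: g.union_length for g in genes})
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(counts.index[lengths.isna()])
        raise ValueError(f"genes without models: {missing[:5]}")
    if (lengths <= 0).any():
        raise ValueError("zero-length gene model")
    if counted_total is None:
        counted_total = int(counts.sum())
    if counted_total <= 0:
        raise ValueError("counted_total must be > 0")
    return counts / (lengths / 1e3) / (counted_total / 1e6)


def count_matrix_fpkm(
    counts: pd.DataFrame, genes: Sequence[GeneModel]
) -> pd.DataFrame:
    """Per-library FPKM, each column on its own counted total."""
    return pd.DataFrame(
        {lib: fpkm(counts[lib], genes) for lib in counts.columns}
    )


def brute_force_count_union(
    alignments: Iterable[AlignmentRecord],
    genes: Sequence[GeneModel],
    min_mapq: int = 10,
) -> CountResult:
    """All-pairs interval-overlap oracle for count_union (test use)."""
    genes = list(genes)
    counts = pd.Series(0, index=[g.gene_id for g in genes], dtype=np.int64)
    cats = {c: 0 for c in CATEGORIES}
    pairs, orphans = pair_alignments(alignments)
    if orphans:
        raise ValueError("oracle expects proper pairs")
    for m1, m2 in pairs:
        if min(m1.mapq, m2.mapq) < min_mapq:
            cats["low_quality"] += 1
            continue
        features = set()
        for g in genes:
            for s, e in g.union_exons:
                for rec in (m1, m2):
                    if rec.reference == g.reference and rec.start < e and s < rec.end:
                        features.add(g.gene_id)
        if len(features) == 1:
            counts[features.pop()] += 1
            cats["counted"] += 1
        elif features:
            cats["ambiguous"] += 1
        else:
            cats["no_feature"] += 1
    return CountResult(counts, cats)
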