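"""Tissue-expression-class composition of DE gene lists and the
associated significance tests.

Differentially expressed genes are intersected with curated
tissue-class sets (neuronal / glial / ubiquitous); class percentages
are compared between experimental designs with the pooled
two-proportion z-test, and gene-list overlaps are scored with the
upper-tail hypergeometric test.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

CLASS_NAMES = ("neuronal", "glial", "ubiquitous")


@dataclass
class TissueClassSets:
    """Named tissue-expression gene sets, pairwise disjoint.

    Genes annotated to more than one class are ambiguous and are
    removed from all classes by :meth:`from_overlapping`.
    """

    neuronal: frozenset
    glial: frozenset
    ubiquitous: frozenset
    n_dropped_overlapping: int = 0

    def __post_init__(self) -> None:
        self.neuronal = frozenset(self.neuronal)
        self.glial = frozenset(self.glial)
        self.ubiquitous = frozenset(self.ubiquitous)
        sets = [self.neuronal, self.glial, self.ubiquitous]
        for a, b in combinations(range(3), 2):
            if sets[a] & sets[b]:
                raise ValueError(
                    "class sets overlap; build with from_overlapping()"
                )

    @classmethod
    def from_overlapping(
        cls,
        neuronal: Iterable,
        glial: Iterable,
        ubiquitous: Iterable,
    ) -> "TissueClassSets":
        raw = [set(neuronal), set(glial), set(ubiquitous)]
        multi = set()
        for a, b in combinations(range(3), 2):
            multi |= raw[a] & raw[b]
        clean = [s - multi for s in raw]
        return cls(*map(frozenset, clean), n_dropped_overlapping=len(multi))

    def as_dict(self) -> dict[str, frozenset]:
        return {
            "neuronal": self.neuronal,
            "glial": self.glial,
            "ubiquitous": self.ubiquitous,
        }


def round_percentage(count: int, total: int) -> float:
    """Percentage rounded half-up to one decimal."""
    pct = Decimal(count) * 100 / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def classify_de(
    de_genes: Sequence, classes: TissueClassSets
) -> pd.DataFrame:
    """Class membership counts and percentages for one DE gene list."""
    de_list = list(de_genes)
    if not de_list:
        raise ValueError("empty DE gene list")
    if len(set(de_list)) != len(de_list):
        raise ValueError("duplicate gene ids in DE list")
    de = set(de_list)
    rows = []
    for name, members in classes.as_dict().items():
        k = len(de & members)
        rows.append(
            {
                "class": name,
                "class_size": len(members),
                "de_in_class": k,
                "de_total": len(de),
                "percent": round_percentage(k, len(de)),
            }
        )
    return pd.DataFrame(rows).set_index("class")


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z-test, two-sided.

    z = (x1/n1 - x2/n2) / sqrt(p*(1-p)*(1/n1 + 1/n2)) with the pooled
    p = (x1+x2)/(n1+n2); p-value is 2*Phi(-|z|). Degenerate pooled
    proportions (0 or 1) return p = 1 by convention.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n < 1 or not 0 <= x <= n:
            raise ValueError("need 0 <= x <= n and n >= 1 in both groups")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        warnings.warn("degenerate pooled proportion; p-value set to 1")
        return 0.0, 1.0
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (x1 / n1 - x2 / n2) / se
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def hypergeometric_overlap(
    list_a_size: int, list_b_size: int, overlap: int, universe_size: int
) -> float:
    """Upper-tail overlap significance P(X >= overlap) for X drawn
    hypergeometrically (universe N, successes = list B, draws = list A).
    Computed in log space for numerical range."""
    if not 0 <= overlap <= min(list_a_size, list_b_size):
        raise ValueError("overlap must be <= both list sizes")
    if max(list_a_size, list_b_size) > universe_size:
        raise ValueError("list sizes must be <= universe size")
    if overlap == 0:
        return 1.0
    logp = stats.hypergeom.logsf(
        overlap - 1, universe_size, list_b_size, list_a_size
    )
    return float(np.exp(logp))


def enrichment_table(
    de_lists: Mapping[str, Sequence],
    classes: TissueClassSets,
    sig_level: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Class composition per comparison plus pairwise z-test p-values."""
    per_comp = {}
    for name, genes in de_lists.items():
        per_comp[name] = classify_de(genes, classes)
    table = pd.concat(per_comp, names=["comparison", "class"])
    z_rows = []
    for (a, ta), (b, tb) in combinations(per_comp.items(), 2):
        for cls in CLASS_NAMES:
            z, p = two_proportion_z(
                int(ta.loc[cls, "de_in_class"]),
                int(ta.loc[cls, "de_total"]),
                int(tb.loc[cls, "de_in_class"]),
                int(tb.loc[cls, "de_total"]),
            )
            z_rows.append(
                {
                    "comparison_1": a,
                    "comparison_2": b,
                    "class": cls,
                    "z": z,
                    "pvalue": p,
                    "significant": p < sig_level,
                }
            )
    return table, pd.DataFrame(z_rows)
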