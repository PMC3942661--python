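"""Size-factor normalization, NB dispersion estimation, two-group
differential expression and concordance diagnostics.

The count model is negative binomial with variance ``mu + alpha*mu**2``.
Library depth is removed with median-of-ratios size factors; per-gene
dispersions are method-of-moments estimates pooled within groups,
shrunk conservatively toward a robust mean-dispersion trend (the
working dispersion is the max of the gene estimate and the trend).
Differential expression is a Wald test on the difference of normalized
group means with NB variance, adjusted by Benjamini-Hochberg.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library scaling factors.

    For genes with nonzero counts in every library, each library's
    factor is the median ratio of its counts to the per-gene geometric
    mean across libraries.
    """
    if counts.shape[1] < 2:
        raise ValueError("need >= 2 libraries to normalize")
    everywhere = (counts > 0).all(axis=1)
    if not everywhere.any():
        raise ValueError("no gene with nonzero counts in all libraries")
    logc = np.log(counts.loc[everywhere].astype(float))
    loggeo = logc.mean(axis=1)
    factors = np.exp(logc.sub(loggeo, axis=0).median(axis=0))
    return factors


@dataclass
class DispersionEstimates:
    alpha_hat: pd.Series  # per-gene method-of-moments estimate
    trend: pd.Series  # fitted mean-dispersion trend, evaluated per gene
    working: pd.Series  # max(alpha_hat, trend); NaN for untestable genes
    base_mean: pd.Series


def estimate_dispersion(
    normalized: pd.DataFrame, groups: pd.Series
) -> DispersionEstimates:
    """Per-gene NB dispersion from normalized counts.

    ``alpha_hat = max(0, (s2 - mu) / mu**2)`` with the variance pooled
    within groups; a robust linear fit of log alpha_hat on log mu gives
    the trend, and the working value is the elementwise max. All-zero
    genes get NaN and are excluded from testing downstream.
    """
    groups = pd.Series(groups, index=normalized.columns)
    sizes = groups.value_counts()
    if (sizes < 2).all():
        raise ValueError("need >= 2 replicates in some group")
    mu = normalized.mean(axis=1)
    ss = pd.Series(0.0, index=normalized.index)
    df = 0
    for g, n_k in sizes.items():
        if n_k < 2:
            continue
        sub = normalized.loc[:, groups[groups == g].index]
        ss += ((sub.sub(sub.mean(axis=1), axis=0)) ** 2).sum(axis=1)
        df += n_k - 1
    s2 = ss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_hat = ((s2 - mu) / mu**2).clip(lower=0.0)
    alpha_hat[mu <= 0] = np.nan

    fit_mask = (alpha_hat > 0) & (mu > 0)
    if fit_mask.sum() >= 5:
        x = sm.add_constant(np.log(mu[fit_mask]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rlm = sm.RLM(np.log(alpha_hat[fit_mask]), x, M=sm.robust.norms.HuberT()).fit()
        b0, b1 = rlm.params
        trend_vals = np.exp(b0 + b1 * np.log(mu.where(mu > 0)))
    else:
        fallback = float(alpha_hat[fit_mask].median()) if fit_mask.any() else 1e-8
        trend_vals = pd.Series(fallback, index=mu.index)
    trend = pd.Series(trend_vals, index=mu.index).clip(lower=1e-8, upper=20.0)
    trend[mu <= 0] = np.nan
    working = pd.concat([alpha_hat, trend], axis=1).max(axis=1)
    working[mu <= 0] = np.nan
    return DispersionEstimates(alpha_hat, trend, working, mu)


def nb_test(
    counts: pd.DataFrame,
    groups: pd.Series,
    factors: pd.Series | None = None,
    dispersions: pd.Series | None = None,
    sig_level: float = 0.05,
    pooled_dispersion: float | None = None,
) -> pd.DataFrame:
    """Two-sided Wald test of equal NB means between two groups.

    The statistic is the difference of normalized group means over its
    NB standard error, referred to the standard normal. The working
    dispersion's conservative max-of-estimate-and-trend rule offsets
    the small-sample anti-conservatism of a plug-in normal Wald test;
    the combination is calibrated by simulation. Returns a per-gene
    frame with means, fold change (group2/group1), dispersion, p-value
    and BH-adjusted p-value.
    """
    groups = pd.Series(groups, index=counts.columns)
    levels = list(dict.fromkeys(groups))
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    n1 = int((groups == levels[0]).sum())
    n2 = int((groups == levels[1]).sum())
    if min(n1, n2) < 2 and pooled_dispersion is None:
        raise ValueError(
            "single replicate in a group: supply pooled_dispersion to override"
        )
    if factors is None:
        factors = size_factors(counts)
    q = counts.div(factors, axis=1)
    if dispersions is None:
        if pooled_dispersion is not None:
            dispersions = pd.Series(pooled_dispersion, index=counts.index)
        else:
            dispersions = estimate_dispersion(q, groups).working
    alpha = dispersions.reindex(counts.index)

    cols = {g: groups[groups == g].index for g in levels}
    m1 = q[cols[levels[0]]].mean(axis=1)
    m2 = q[cols[levels[1]]].mean(axis=1)
    inv1 = (1.0 / factors[cols[levels[0]]]).sum()
    inv2 = (1.0 / factors[cols[levels[1]]]).sum()
    v1 = (m1 * inv1 + n1 * alpha * m1**2) / n1**2
    v2 = (m2 * inv2 + n2 * alpha * m2**2) / n2**2
    se = np.sqrt(v1 + v2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (m2 - m1) / se
    z = z.where(se > 0, 0.0)
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    pvalue = pd.Series(pvalue, index=counts.index).clip(upper=1.0)

    testable = alpha.notna() & ((m1 > 0) | (m2 > 0))
    pvalue[~testable] = np.nan
    padj = pd.Series(np.nan, index=counts.index)
    if testable.any():
        padj[testable] = multipletests(pvalue[testable], method="fdr_bh")[1]

    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(m1 > 0, m2 / m1, np.where(m2 > 0, np.inf, 1.0))
        log2fc = np.log2(fold)
    return pd.DataFrame(
        {
            "base_mean": (m1 * n1 + m2 * n2) / (n1 + n2),
            f"mean_{levels[0]}": m1,
            f"mean_{levels[1]}": m2,
            "fold_change": fold,
            "log2_fold_change": log2fc,
            "dispersion": alpha,
            "stat": z,
            "pvalue": pvalue,
            "padj": padj,
            "significant": padj < sig_level,
        }
    )


def transform_counts(
    counts: pd.DataFrame, factors: pd.Series | None = None
) -> pd.DataFrame:
    """Variance-damping transform log2(count / size_factor + 1)."""
    if factors is None:
        factors = size_factors(counts)
    return np.log2(counts.div(factors, axis=1) + 1.0)


@dataclass
class Concordance:
    correlations: pd.DataFrame
    linkage_matrix: np.ndarray  # average linkage on correlation distance
    libraries: list
    pca: pd.DataFrame  # libraries x (PC1, PC2)
    explained_variance: np.ndarray
    notes: list


def concordance(transformed: pd.DataFrame) -> Concordance:
    """Pairwise Pearson correlation, average-linkage tree on 1 - r, and
    PCA of gene-centered values for the library panel."""
    if transformed.shape[1] < 3:
        raise ValueError("need >= 3 libraries")
    corr = transformed.corr(method="pearson")
    notes = []
    if corr.isna().any().any():
        bad = [lib for lib in corr.columns if corr[lib].isna().any()]
        notes.append(f"correlation undefined for constant libraries: {bad}")
    dist = 1.0 - corr.fillna(0.0).values
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    lk = linkage(squareform(dist, checks=False), method="average")
    centered = transformed.sub(transformed.mean(axis=1), axis=0)
    n_comp = min(2, transformed.shape[1] - 1)
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(centered.T.values)
    if n_comp < 2:
        coords = np.hstack([coords, np.zeros((coords.shape[0], 1))])
    pca_df = pd.DataFrame(
        coords[:, :2], index=transformed.columns, columns=["PC1", "PC2"]
    )
    return Concordance(
        corr, lk, list(transformed.columns), pca_df,
        pca.explained_variance_ratio_, notes,
    )


def group_silhouette(coords: pd.DataFrame, groups: pd.Series) -> float:
    """Mean silhouette of the group labeling in PCA space."""
    labels = pd.Series(groups, index=coords.index)
    if labels.nunique() < 2:
        raise ValueError("need >= 2 groups for a silhouette")
    return float(silhouette_score(coords.values, labels.values))
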