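"""Size factors, dispersion estimation, NB testing and concordance."""
import numpy as np
import pandas as pd
import pytest

from tissueqc.de import (
    concordance,
    estimate_dispersion,
    group_silhouette,
    nb_test,
    size_factors,
    transform_counts,
)
from tissueqc.sim import (
    SimulationConfig,
    build_profiles,
    mixture_abundance,
    simulate_counts,
)


def nb_frame(mu, n_per_group, alpha, seed, mu2=None):
    """Two-group NB count frame with per-gene means mu (and mu2)."""
    rng = np.random.default_rng(seed)
    mu = np.asarray(mu, dtype=float)
    mu2 = mu if mu2 is None else np.asarray(mu2, dtype=float)
    size = 1 / alpha if alpha > 0 else None

    def draw(m, n):
        if size is None:
            return rng.poisson(m[:, None], (len(m), n))
        return rng.negative_binomial(size, size / (size + m[:, None]), (len(m), n))

    data = np.hstack([draw(mu, n_per_group), draw(mu2, n_per_group)])
    cols = [f"A{i}" for i in range(n_per_group)] + [
        f"B{i}" for i in range(n_per_group)
    ]
    frame = pd.DataFrame(data, columns=cols)
    return frame, pd.Series(["A"] * n_per_group + ["B"] * n_per_group, index=cols)


class TestSizeFactors:
    def test_identical_libraries_get_unit_factors(self):
        counts = pd.DataFrame({"L1": [5, 10, 20], "L2": [5, 10, 20]})
        np.testing.assert_allclose(size_factors(counts), [1.0, 1.0])

    def test_doubled_library_hand_computation(self):
        # B = 2A on a 5-gene toy: ratios to the geometric mean are
        # 1/sqrt(2) and sqrt(2), so factors are (0.7071, 1.4142)
        a = pd.Series([10, 20, 30, 40, 50])
        counts = pd.DataFrame({"A": a, "B": 2 * a})
        f = size_factors(counts)
        np.testing.assert_allclose(f, [1 / np.sqrt(2), np.sqrt(2)])
        assert f["B"] / f["A"] == pytest.approx(2.0)

    def test_invariant_to_gene_order(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.poisson(100, (40, 4)), columns=list("wxyz"))
        shuffled = counts.sample(frac=1, random_state=0)
        pd.testing.assert_series_equal(size_factors(counts), size_factors(shuffled))

    def test_requires_gene_nonzero_everywhere(self):
        counts = pd.DataFrame({"A": [0, 5], "B": [3, 0]})
        with pytest.raises(ValueError):
            size_factors(counts)

    def test_normalized_median_ratio_is_one(self):
        rng = np.random.default_rng(9)
        counts = pd.DataFrame(
            rng.poisson(rng.uniform(50, 500, 100)[:, None] * [1, 2, 0.5, 1.3]),
            columns=list("abcd"),
        )
        f = size_factors(counts)
        norm = counts.div(f, axis=1)
        # median ratio of each normalized library to the pseudo-reference
        # (per-gene geometric mean of the raw counts) is exactly 1
        mask = (counts > 0).all(axis=1)
        loggeo = np.log(counts[mask]).mean(axis=1)
        ratios = np.log(norm[mask]).sub(loggeo, axis=0).median(axis=0)
        np.testing.assert_allclose(ratios, 0.0, atol=1e-12)


class TestDispersion:
    def test_constant_counts_give_zero_alpha_hat(self):
        counts = pd.DataFrame({"A1": [7, 7], "A2": [7, 7], "B1": [9, 9], "B2": [9, 9]})
        groups = pd.Series(["A", "A", "B", "B"], index=counts.columns)
        est = estimate_dispersion(counts.astype(float), groups)
        np.testing.assert_allclose(est.alpha_hat, 0.0)

    def test_poisson_median_working_dispersion_shrinks_with_replicates(self):
        mu = np.random.default_rng(1).uniform(200, 5000, 400)
        small, g_small = nb_frame(mu, 3, 0.0, 11)
        big, g_big = nb_frame(mu, 25, 0.0, 12)
        d_small = estimate_dispersion(small.astype(float), g_small).working.median()
        d_big = estimate_dispersion(big.astype(float), g_big).working.median()
        assert d_big < d_small
        assert d_big < 0.01

    def test_recovers_constant_dispersion_within_30_percent(self):
        mu = np.exp(np.random.default_rng(2).uniform(np.log(100), np.log(10_000), 2000))
        counts, groups = nb_frame(mu, 3, 0.1, 21)
        est = estimate_dispersion(counts.astype(float), groups)
        assert 0.07 < est.trend.median() < 0.13

    def test_all_zero_gene_excluded(self):
        counts = pd.DataFrame(
            {"A1": [0, 5], "A2": [0, 8], "B1": [0, 6], "B2": [0, 9]},
            index=["dead", "ok"],
        ).astype(float)
        groups = pd.Series(["A", "A", "B", "B"], index=counts.columns)
        est = estimate_dispersion(counts, groups)
        assert np.isnan(est.working["dead"])
        assert np.isfinite(est.working["ok"])


class TestNbTest:
    def test_null_type_one_error_calibrated(self):
        mu = np.random.default_rng(4).uniform(100, 10_000, 2000)
        counts, groups = nb_frame(mu, 3, 0.1, 31)
        res = nb_test(counts, groups)
        frac = (res["pvalue"].dropna() < 0.05).mean()
        assert abs(frac - 0.05) < 0.02

    def test_power_for_fourfold_change(self):
        # mu=500 vs 2000, alpha=0.05, n=3+3: power > 0.9
        rng = np.random.default_rng(5)
        hits = 0
        n_sim = 100
        for i in range(n_sim):
            mu = rng.uniform(100, 5000, 150)
            mu[0] = 500.0
            mu2 = mu.copy()
            mu2[0] = 2000.0
            counts, groups = nb_frame(mu, 3, 0.05, 100 + i, mu2=mu2)
            res = nb_test(counts, groups)
            hits += res["pvalue"].iloc[0] < 0.05
        assert hits / n_sim > 0.9

    def test_identical_groups_are_null(self):
        counts = pd.DataFrame(
            {"A1": [10, 50], "A2": [20, 40], "B1": [10, 50], "B2": [20, 40]}
        )
        groups = pd.Series(["A", "A", "B", "B"], index=counts.columns)
        res = nb_test(counts, groups)
        np.testing.assert_allclose(res["fold_change"], 1.0)
        np.testing.assert_allclose(res["pvalue"], 1.0)

    def test_bh_adjustment_is_monotone(self):
        mu = np.random.default_rng(6).uniform(50, 5000, 500)
        counts, groups = nb_frame(mu, 3, 0.1, 41)
        res = nb_test(counts, groups).dropna(subset=["pvalue"])
        assert (res["padj"] >= res["pvalue"] - 1e-12).all()
        ordered = res.sort_values("pvalue")
        assert ordered["padj"].is_monotonic_increasing

    def test_single_replicate_refused_without_override(self):
        counts = pd.DataFrame({"A1": [10], "B1": [20]})
        groups = pd.Series(["A", "B"], index=counts.columns)
        with pytest.raises(ValueError):
            nb_test(counts, groups)
        res = nb_test(counts, groups, pooled_dispersion=0.1)
        assert np.isfinite(res["pvalue"]).all()

    def test_de_count_non_increasing_in_contamination(self):
        # the signal-dilution claim at the level where it is testable
        cfg = SimulationConfig(seed=51)
        profiles = build_profiles(cfg)
        n_sig = []
        for c in (0.0, 0.45, 0.9):
            a_wt = mixture_abundance(profiles, 0.5, c, 1.0)
            a_kd = mixture_abundance(profiles, 0.5, c, 0.2)
            cols = {}
            for i in range(6):
                cols[f"WT_{i}"] = simulate_counts(
                    a_wt, 50_000, 0.1, np.random.default_rng([61, int(100 * c), i])
                )
                cols[f"KD_{i}"] = simulate_counts(
                    a_kd, 50_000, 0.1, np.random.default_rng([62, int(100 * c), i])
                )
            counts = pd.DataFrame(cols, index=profiles.gene_ids)
            groups = pd.Series(
                [col.split("_")[0] for col in counts.columns], index=counts.columns
            )
            res = nb_test(counts, groups)
            n_sig.append(int(res["significant"].fillna(False).sum()))
        assert n_sig[0] >= n_sig[1] >= n_sig[2]
        assert n_sig[0] > n_sig[2]


class TestTransformAndConcordance:
    def test_transform_zero_and_monotone(self):
        counts = pd.DataFrame({"A": [0, 1, 10], "B": [0, 2, 30]})
        f = pd.Series({"A": 1.0, "B": 1.0})
        t = transform_counts(counts, f)
        assert t.loc[0, "A"] == 0.0
        assert t["A"].is_monotonic_increasing

    def test_doubling_counts_and_factor_is_invariant(self):
        counts = pd.DataFrame({"A": [3, 9, 27], "B": [4, 16, 64]})
        t1 = transform_counts(counts, pd.Series({"A": 1.0, "B": 2.0}))
        t2 = transform_counts(counts.assign(A=counts["A"] * 2), pd.Series({"A": 2.0, "B": 2.0}))
        pd.testing.assert_series_equal(t1["A"], t2["A"])

    def test_duplicated_library_has_unit_correlation_and_zero_distance(self):
        rng = np.random.default_rng(8)
        base = rng.poisson(100, 200)
        counts = pd.DataFrame(
            {"L1": base, "L1copy": base, "L2": rng.poisson(100, 200)}
        ).astype(float)
        conc = concordance(np.log2(counts + 1))
        assert conc.correlations.loc["L1", "L1copy"] == pytest.approx(1.0)
        # the first merge in the tree joins the twins at distance 0
        assert conc.linkage_matrix[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_groups_separate_in_pca_when_clean(self):
        # 3 WT + 3 KD libraries at c=0: positive silhouette on labels
        cfg = SimulationConfig(seed=71)
        profiles = build_profiles(cfg)
        a_wt = mixture_abundance(profiles, 0.5, 0.0, 1.0)
        a_kd = mixture_abundance(profiles, 0.5, 0.0, 0.2)
        cols = {}
        for i in range(3):
            cols[f"WT_{i}"] = simulate_counts(a_wt, 40_000, 0.1, np.random.default_rng([81, i]))
            cols[f"KD_{i}"] = simulate_counts(a_kd, 40_000, 0.1, np.random.default_rng([82, i]))
        counts = pd.DataFrame(cols, index=profiles.gene_ids)
        conc = concordance(transform_counts(counts))
        groups = pd.Series([c.split("_")[0] for c in counts.columns], index=counts.columns)
        assert group_silhouette(conc.pca, groups) > 0

    def test_contaminated_library_is_tree_outgroup(self):
        from scipy.cluster.hierarchy import fcluster

        cfg = SimulationConfig(seed=91)
        profiles = build_profiles(cfg)
        cols = {}
        for i in range(5):
            cols[f"clean_{i}"] = simulate_counts(
                mixture_abundance(profiles, 0.5, 0.0, 1.0), 40_000, 0.1,
                np.random.default_rng([91, i]),
            )
        cols["dirty"] = simulate_counts(
            mixture_abundance(profiles, 0.5, 0.5, 1.0), 40_000, 0.1,
            np.random.default_rng([92]),
        )
        counts = pd.DataFrame(cols, index=profiles.gene_ids)
        conc = concordance(transform_counts(counts))
        two = fcluster(conc.linkage_matrix, 2, criterion="maxclust")
        labels = dict(zip(conc.libraries, two))
        assert sum(v == labels["dirty"] for v in labels.values()) == 1

    def test_needs_three_libraries(self):
        with pytest.raises(ValueError):
            concordance(pd.DataFrame({"A": [1.0, 2.0], "B": [1.0, 2.0]}))
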