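"""Generator-level checks: determinism, annotation geometry, the
mixing model's arithmetic, NB count moments and artifact injection."""
import filecmp

import numpy as np
import pandas as pd
import pytest

from tissueqc.io import read_gtf, write_gtf
from tissueqc.quant import count_union
from tissueqc.sim import (
    SimulationConfig,
    build_annotation,
    build_profiles,
    mixture_abundance,
    simulate_counts,
    simulate_experiment,
    simulate_library_reads,
)


class TestAnnotation:
    def test_gtf_deterministic_for_fixed_seed(self, tmp_path):
        cfg = SimulationConfig(n_genes=10, seed=1)
        for run in ("a", "b"):
            _, genes = build_annotation(cfg)
            write_gtf(genes, tmp_path / f"{run}.gtf")
        assert filecmp.cmp(tmp_path / "a.gtf", tmp_path / "b.gtf", shallow=False)

    def test_genes_do_not_overlap_on_a_reference(self):
        _, genes = build_annotation(SimulationConfig(n_genes=40, seed=3))
        by_ref = {}
        for g in genes:
            by_ref.setdefault(g.reference, []).append(g.span)
        for spans in by_ref.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_record_counts_and_transgene_reference(self, tmp_path):
        cfg = SimulationConfig(n_genes=100, seed=2)
        refs, genes = build_annotation(cfg)
        write_gtf(genes, tmp_path / "ann.gtf")
        parsed = read_gtf(tmp_path / "ann.gtf")
        assert len(parsed) == 101  # 100 genes + the transgene
        transgene = next(g for g in parsed if g.gene_id == "transgene")
        assert transgene.reference == "transgene_ref"
        assert sum(1 for g in parsed if g.reference == "transgene_ref") == 1
        assert len({g.reference for g in genes}) >= 3

    def test_rejects_invalid_sizes(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_genes=0)
        with pytest.raises(ValueError):
            SimulationConfig(library_size=-5)


@pytest.fixture(scope="module")
def profiles():
    return build_profiles(SimulationConfig(seed=5))


class TestMixture:
    def test_knockdown_dilution_arithmetic(self, profiles):
        # ubiquitous target, phi=0.5, r=0.2, c=0: bulk level is
        # 0.5*0.2 + 0.5*1 = 0.6 of its WT value
        wt = mixture_abundance(profiles, 0.5, 0.0, 1.0)
        kd = mixture_abundance(profiles, 0.5, 0.0, 0.2)
        tgt = profiles.index()[profiles.roles["knockdown_target"]]
        assert kd[tgt] / wt[tgt] == pytest.approx(0.6)

    def test_contaminant_mixing(self, profiles):
        # marker absent from target tissue: a = c * contaminant level
        con = profiles.index()[profiles.roles["contaminant_marker"]]
        base = profiles.contaminant[con]
        a = mixture_abundance(profiles, 0.5, 0.3, 1.0)
        expected = 0.7 * (0.5 * profiles.neuron[con] + 0.5 * profiles.glia[con])
        assert a[con] == pytest.approx(expected + 0.3 * base)

    def test_r_equal_one_is_identity(self, profiles):
        a = mixture_abundance(profiles, 0.5, 0.0, 1.0)
        expected = 0.5 * profiles.neuron + 0.5 * profiles.glia
        np.testing.assert_allclose(a, expected)

    def test_somatic_mode_knocks_down_everywhere(self, profiles):
        tgt = profiles.index()[profiles.roles["knockdown_target"]]
        kd = mixture_abundance(profiles, 0.5, 0.0, 0.2, "somatic")
        wt = mixture_abundance(profiles, 0.5, 0.0, 1.0)
        assert kd[tgt] / wt[tgt] == pytest.approx(0.2)

    def test_invalid_fractions_rejected(self, profiles):
        with pytest.raises(ValueError):
            mixture_abundance(profiles, 0.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            mixture_abundance(profiles, 0.5, 1.0, 1.0)


class TestCounts:
    def test_poisson_limit_mean(self):
        # alpha=0: sample mean of a mu=1000 gene within 5 s.e. over 200 draws
        a = np.array([1000.0, 1000.0])
        draws = [
            simulate_counts(a, 2000, 0.0, np.random.default_rng([9, i]))[0]
            for i in range(200)
        ]
        se = np.sqrt(1000.0 / 200)
        assert abs(np.mean(draws) - 1000.0) < 5 * se

    def test_seed_reproducibility(self):
        a = np.linspace(1, 10, 30)
        c1 = simulate_counts(a, 5000, 0.1, 123)
        c2 = simulate_counts(a, 5000, 0.1, 123)
        np.testing.assert_array_equal(c1, c2)

    def test_nb_variance_mean_relationship(self):
        # var/mean for mu=500, alpha=0.1 is 1 + alpha*mu = 51, within 20%
        a = np.array([500.0, 500.0])
        rng = np.random.default_rng(77)
        draws = np.array([simulate_counts(a, 1000, 0.1, rng)[0] for _ in range(2000)])
        ratio = draws.var(ddof=1) / draws.mean()
        assert 51 * 0.8 < ratio < 51 * 1.2

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            simulate_counts(np.ones(5), 100, -0.1, 1)


class TestReads:
    def test_duplicate_injection_rate(self, small_config):
        refs, genes = build_annotation(small_config)
        profiles = build_profiles(small_config)
        a = mixture_abundance(profiles, 0.5, 0.0, 1.0)
        rng = np.random.default_rng(4)
        counts = simulate_counts(a, 10_000, 0.05, rng)
        lib = simulate_library_reads(
            counts, profiles.gene_ids, genes, refs, small_config,
            "L1", "WT", 4.0, rng, duplicate_fraction=0.5,
        )
        rate = (lib.labels.category == "duplicate").mean()
        assert abs(rate - 0.5) < 0.02

    def test_duplicate_rate_monotone_in_input(self, small_config):
        d = [small_config.duplicate_fraction(x) for x in (1, 2, 4, 6, 10)]
        assert all(a > b for a, b in zip(d, d[1:]))

    def test_no_bias_leaves_composition_flat(self, small_config):
        import dataclasses

        from tissueqc.readqc import bias_score, nucleotide_profile

        cfg = dataclasses.replace(small_config, bias_amplitude=0.0, library_size=6000)
        refs, genes = build_annotation(cfg)
        profiles = build_profiles(cfg)
        counts = simulate_counts(
            mixture_abundance(profiles, 0.5, 0.0, 1.0), 6000, 0.0,
            np.random.default_rng(8),
        )
        lib = simulate_library_reads(
            counts, profiles.gene_ids, genes, refs, cfg, "L1", "WT", 4.0,
            np.random.default_rng(8), duplicate_fraction=0.0,
        )
        profile = nucleotide_profile(lib.pairs, 40)
        assert bias_score(profile, 10) < 0.02

    def test_truth_alignments_reproduce_counts_exactly(self, small_experiment):
        # the oracle identity: union counting of clean unique truth
        # records equals the simulated count column
        sim = small_experiment
        for lib in sim.libraries:
            unique_ids = set(lib.labels.query("category == 'unique'").read_id)
            recs = [a for a in lib.alignments if a.read_id in unique_ids]
            res = count_union(recs, sim.genes, min_mapq=10)
            expected = sim.counts.counts[lib.name]
            pd.testing.assert_series_equal(
                res.counts, expected, check_names=False
            )
            assert res.categories["counted"] == expected.sum()


class TestExperiment:
    def test_full_emission_is_byte_reproducible(self, tmp_path):
        import hashlib

        cfg = SimulationConfig(
            n_genes=12,
            library_size=300,
            contamination=(0.0, 0.0),
            groups=("WT", "KD"),
            cdna_input=(4.0, 4.0),
            seed=21,
        )
        digests = []
        for run in ("a", "b"):
            out = tmp_path / run
            simulate_experiment(cfg).write(str(out))
            h = hashlib.sha256()
            for f in sorted(out.iterdir()):
                h.update(f.name.encode())
                h.update(f.read_bytes())
            digests.append(h.hexdigest())
        assert digests[0] == digests[1]

    def test_bulk_fold_change_converges_to_mixture_prediction(self):
        # phi*r + (1-phi) = 0.6 at phi=0.5, r=0.2, c=0
        from tissueqc.de import size_factors

        cfg = SimulationConfig(seed=31)
        profiles = build_profiles(cfg)
        tgt = profiles.roles["knockdown_target"]
        a_wt = mixture_abundance(profiles, 0.5, 0.0, 1.0)
        a_kd = mixture_abundance(profiles, 0.5, 0.0, 0.2)
        cols = {}
        for i in range(50):
            cols[f"WT_{i}"] = simulate_counts(
                a_wt, 20_000, 0.1, np.random.default_rng([41, i])
            )
            cols[f"KD_{i}"] = simulate_counts(
                a_kd, 20_000, 0.1, np.random.default_rng([43, i])
            )
        counts = pd.DataFrame(cols, index=profiles.gene_ids)
        norm = counts.div(size_factors(counts), axis=1)
        wt = norm.loc[tgt, [c for c in norm if c.startswith("WT")]].mean()
        kd = norm.loc[tgt, [c for c in norm if c.startswith("KD")]].mean()
        assert kd / wt == pytest.approx(0.6, abs=0.1)
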