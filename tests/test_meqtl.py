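"""cis-meQTL engine: pairs, Bayes factors, EM, calling, interactions."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from popepimeth.meqtl import (
    ConfigModel,
    all_configurations,
    call_meqtls,
    classify_interaction,
    configuration_log_bayes_factors,
    enumerate_cis_pairs,
    filter_snps_maf,
    fit_hierarchical_weights,
    genotype_pc1,
    meqtl_variance_explained,
    subgroup_summary_stats,
)
from popepimeth.methio import MethylMatrix


class TestCisPairs:
    def test_window_boundary_inclusive(self):
        probes = pd.DataFrame({"chrom": ["chr1"], "pos": [1_000_000]}, index=["p"])
        snps = pd.DataFrame(
            {"chrom": ["chr1", "chr1", "chr2"], "pos": [1_100_000, 1_100_001, 1_000_000]},
            index=["in", "out", "wrongchrom"],
        )
        pairs = enumerate_cis_pairs(probes, snps, window_bp=200_000)
        assert list(pairs["snp"]) == ["in"]
        assert pairs["distance"].iloc[0] == 100_000

    def test_probe_without_snps_has_no_pairs(self):
        probes = pd.DataFrame({"chrom": ["chr1"], "pos": [100]}, index=["p"])
        snps = pd.DataFrame({"chrom": ["chr1"], "pos": [10_000_000]}, index=["far"])
        assert len(enumerate_cis_pairs(probes, snps)) == 0


class TestMafFilter:
    def test_retained_if_common_in_any_population(self):
        ids = pd.Index(["keep", "drop", "edge"])
        def dosage_for(freqs):
            # deterministic dosage matrix with the exact target frequency
            out = np.zeros((50, 3), dtype=np.int8)
            for j, f in enumerate(freqs):
                k = int(round(f * 100))
                flat = np.zeros(100, dtype=np.int8)
                flat[:k] = 1
                out[:, j] = flat[0::2] + flat[1::2]
            return out
        dosages = {
            "A": dosage_for([0.05, 0.05, 0.10]),
            "B": dosage_for([0.20, 0.08, 0.05]),
            "C": dosage_for([0.03, 0.09, 0.05]),
        }
        kept = filter_snps_maf(dosages, ids, 0.10)
        assert list(kept) == ["keep", "edge"]  # 0.10 is inclusive


class TestBayesFactors:
    @staticmethod
    def _stats(beta, se, pops):
        beta, se = np.atleast_2d(beta), np.atleast_2d(se)
        return {
            "beta": beta, "se": se, "usable": np.ones_like(beta, bool),
            "pop_labels": pops, "n": None, "pairs": None,
        }

    def test_abf_formula_values(self):
        # z = 0 and W = V: ABF = sqrt(V/(V+W)) = sqrt(1/2)
        V = 0.04
        stats_ = self._stats([[0.0]], [[np.sqrt(V)]], ["A"])
        lbf, configs = configuration_log_bayes_factors(stats_, grid=(V,))
        assert np.exp(lbf[0, 0]) == pytest.approx(np.sqrt(0.5), abs=1e-12)

    def test_vanishing_prior_variance_gives_bf_one(self):
        stats_ = self._stats([[1.0]], [[0.1]], ["A"])
        lbf, _ = configuration_log_bayes_factors(stats_, grid=(1e-12,))
        assert np.exp(lbf[0, 0]) == pytest.approx(1.0, abs=1e-6)

    def test_two_population_product_matches_quadrature(self):
        # per-population ABF is an exact marginal-likelihood ratio under an
        # independent N(0, W) effect prior; verify against quadrature
        W = 0.09
        beta = np.array([[0.25, -0.1]])
        se = np.array([[0.08, 0.12]])
        stats_ = self._stats(beta, se, ["A", "B"])
        lbf, configs = configuration_log_bayes_factors(stats_, grid=(W,))
        ci = configs.index(("A", "B"))

        def abf_quad(bhat, s):
            num = integrate.quad(
                lambda b: stats.norm.pdf(bhat, b, s) * stats.norm.pdf(b, 0, np.sqrt(W)),
                -3, 3,
            )[0]
            return num / stats.norm.pdf(bhat, 0, s)

        expected = abf_quad(0.25, 0.08) * abf_quad(-0.1, 0.12)
        assert np.exp(lbf[0, ci]) == pytest.approx(expected, rel=1e-6)
        # and the product structure itself
        a_only = configs.index(("A",))
        b_only = configs.index(("B",))
        assert lbf[0, ci] == pytest.approx(lbf[0, a_only] + lbf[0, b_only], abs=1e-10)

    def test_invalid_grid_rejected(self):
        stats_ = self._stats([[0.0]], [[0.1]], ["A"])
        with pytest.raises(ValueError):
            configuration_log_bayes_factors(stats_, grid=(-1.0,))
        with pytest.raises(ValueError):
            configuration_log_bayes_factors(stats_, grid=())


class TestHierarchicalEM:
    def test_planted_configuration_dominates(self, rng):
        configs = all_configurations(["A", "B"])
        n = 1000
        lbf = np.zeros((n, len(configs)))
        planted = rng.random(n) < 0.5
        ci = configs.index(("A", "B"))
        lbf[planted, ci] = np.log(1e6)
        # mildly sub-unit null BFs keep pi0 identifiable
        lbf[~planted] = np.log(0.5)
        model = fit_hierarchical_weights(lbf, configs)
        assert model.weights[ci] > 0.95
        assert model.converged

    def test_loglik_monotone_nondecreasing(self, rng):
        configs = all_configurations(["A", "B", "C"])
        lbf = rng.normal(0, 2, size=(500, len(configs)))
        model = fit_hierarchical_weights(lbf, configs)
        path = np.array(model.loglik_path)
        assert np.all(np.diff(path) >= -1e-8)

    def test_flat_bayes_factors_flagged_degenerate(self):
        configs = all_configurations(["A"])
        with pytest.warns(UserWarning, match="unidentifiable"):
            model = fit_hierarchical_weights(np.zeros((200, 1)), configs)
        assert model.degenerate
        assert model.pi0 == 0.5  # initialization returned

    def test_posteriors_sum_to_one(self, rng):
        configs = all_configurations(["A", "B"])
        lbf = rng.normal(0, 3, size=(300, len(configs)))
        model = fit_hierarchical_weights(lbf, configs)
        p_null, p_c = model.posterior(lbf)
        np.testing.assert_allclose(p_null + p_c.sum(axis=1), 1.0, atol=1e-8)


class TestCalling:
    def _model(self, configs, weights, pi0=0.5):
        return ConfigModel(configs, np.asarray(weights, float), pi0)

    def test_single_dominant_snp(self):
        configs = all_configurations(["A"])
        model = self._model(configs, [1.0], pi0=0.2)
        pairs = pd.DataFrame({"probe": ["p", "p"], "snp": ["s1", "s2"]})
        lbf = np.log(np.array([[1e6], [1.0]]))
        calls = call_meqtls(pairs, lbf, model, fdr=0.5, best_posterior=0.85)
        assert calls.iloc[0]["best_snps"] == "s1"

    def test_best_snp_set_reaches_085(self):
        # posteriors 0.5 / 0.4 / 0.1 -> smallest covering set is the first two
        configs = all_configurations(["A"])
        model = self._model(configs, [1.0], pi0=0.2)
        pairs = pd.DataFrame({"probe": ["p"] * 3, "snp": ["s1", "s2", "s3"]})
        lbf = np.log(np.array([[5.0], [4.0], [1.0]]))
        calls = call_meqtls(pairs, lbf, model, fdr=1.0, best_posterior=0.85)
        assert calls.iloc[0]["best_snps"] == "s1,s2"
        assert calls.iloc[0]["best_posterior_sum"] == pytest.approx(0.9)

    def test_three_distinct_configurations_discard_site(self):
        configs = all_configurations(["A", "B", "C"])
        weights = np.full(len(configs), 1.0 / len(configs))
        model = self._model(configs, weights, pi0=0.2)
        pairs = pd.DataFrame({"probe": ["p"] * 3, "snp": ["s1", "s2", "s3"]})
        lbf = np.full((3, len(configs)), -30.0)
        # equal pair scores but three different best configurations
        for i, cfg in enumerate([("A",), ("B",), ("C",)]):
            lbf[i, configs.index(cfg)] = np.log(10.0)
        calls = call_meqtls(pairs, lbf, model, fdr=1.0, best_posterior=0.85)
        assert calls.iloc[0]["dropped_config_conflict"]
        assert not calls.iloc[0]["called"]
        assert calls.iloc[0]["n_distinct_configs"] == 3

    def test_two_configurations_resolved_by_top_snp(self):
        configs = all_configurations(["A", "B"])
        weights = np.full(len(configs), 1 / 3)
        model = self._model(configs, weights, pi0=0.2)
        pairs = pd.DataFrame({"probe": ["p"] * 2, "snp": ["s1", "s2"]})
        lbf = np.full((2, len(configs)), -30.0)
        lbf[0, configs.index(("A",))] = np.log(20.0)   # stronger SNP: config A
        lbf[1, configs.index(("A", "B"))] = np.log(10.0)
        calls = call_meqtls(pairs, lbf, model, fdr=1.0, best_posterior=0.95)
        assert calls.iloc[0]["configuration"] == "A"
        assert not calls.iloc[0]["dropped_config_conflict"]

    def test_bayesian_fdr_prefix_rule(self):
        configs = all_configurations(["A"])
        model = self._model(configs, [1.0], pi0=0.5)
        pairs = pd.DataFrame({"probe": [f"p{i}" for i in range(4)],
                              "snp": [f"s{i}" for i in range(4)]})
        lbf = np.log(np.array([[1e8], [1e8], [1.0], [1e-8]]))
        calls = call_meqtls(pairs, lbf, model, fdr=0.01)
        called = calls[calls["called"]]
        assert set(called["probe"]) == {"p0", "p1"}


class TestSubgroupStats:
    def _toy(self, rng, n=50, slope=1.0, noise=0.01):
        samples = [f"A{i}" for i in range(n)]
        cov = pd.DataFrame({"population": "A"}, index=samples)
        g = rng.integers(0, 3, size=(n, 1)).astype(np.int8)
        m = slope * g[:, 0] + rng.normal(0, noise, n)
        methyl = MethylMatrix(m[None, :], ["p"], samples, "M")
        probes = pd.DataFrame({"chrom": ["chr1"], "pos": [100]}, index=["p"])
        pairs = pd.DataFrame({"probe": ["p"], "snp": ["s"]})
        return pairs, methyl, {"A": g}, pd.Index(["s"]), cov

    def test_slope_recovery(self, rng):
        pairs, methyl, dosages, snps, cov = self._toy(rng)
        out = subgroup_summary_stats(pairs, methyl, dosages, snps, cov, ["A"])
        assert out["beta"][0, 0] == pytest.approx(1.0, abs=0.01)
        assert out["usable"][0, 0]

    def test_monomorphic_population_flagged_unusable(self, rng):
        pairs, methyl, dosages, snps, cov = self._toy(rng)
        dosages["A"][:] = 2
        out = subgroup_summary_stats(pairs, methyl, dosages, snps, cov, ["A"])
        assert not out["usable"][0, 0]

    def test_permuted_genotypes_give_standard_normal_z(self, rng):
        n, n_pairs = 100, 1000
        samples = [f"A{i}" for i in range(n)]
        cov = pd.DataFrame({"population": "A"}, index=samples)
        g = rng.integers(0, 3, size=(n, n_pairs)).astype(np.int8)
        m = rng.normal(0, 1, size=(n_pairs, n))
        methyl = MethylMatrix(m, [f"p{i}" for i in range(n_pairs)], samples, "M")
        pairs = pd.DataFrame({"probe": [f"p{i}" for i in range(n_pairs)],
                              "snp": [f"s{i}" for i in range(n_pairs)]})
        out = subgroup_summary_stats(pairs, methyl, {"A": g},
                                     pd.Index([f"s{i}" for i in range(n_pairs)]),
                                     cov, ["A"])
        z = out["beta"][:, 0] / out["se"][:, 0]
        assert abs(z.mean()) < 0.1
        assert abs(z.std() - 1.0) < 0.1


class TestInteractionAndR2:
    def _two_pop(self, rng, slope_a, slope_b, n=100, noise=0.05):
        samples = [f"A{i}" for i in range(n)] + [f"B{i}" for i in range(n)]
        cov = pd.DataFrame({"population": ["A"] * n + ["B"] * n}, index=samples)
        ga = rng.integers(0, 3, n).astype(float)
        gb = rng.integers(0, 3, n).astype(float)
        m = np.concatenate([slope_a * ga, slope_b * gb]) + rng.normal(0, noise, 2 * n)
        methyl = MethylMatrix(m[None, :], ["p"], samples, "M")
        dosages_all = np.concatenate([ga, gb])[:, None]
        calls = pd.DataFrame({"probe": ["p"], "best_snp": ["s"], "called": [True]})
        return calls, methyl, dosages_all, pd.Index(["s"]), cov

    def test_population_specific_slope_is_gxe(self, rng):
        calls, methyl, dall, snps, cov = self._two_pop(rng, 1.0, 0.0)
        out = classify_interaction(calls, methyl, dall, snps, cov)
        assert out.iloc[0]["interaction_class"] == "GxGxE"
        total = out.iloc[0][["var_pop", "var_geno", "var_interaction"]].sum()
        assert total <= 1.0

    def test_shared_slope_is_frequency_driven(self, rng):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            calls, methyl, dall, snps, cov = self._two_pop(r, 1.0, 1.0)
            out = classify_interaction(calls, methyl, dall, snps, cov)
            hits += out.iloc[0]["interaction_class"] == "frequency-driven"
        assert hits >= 9

    def test_variance_explained(self, rng):
        n = 200
        samples = [f"A{i}" for i in range(n)]
        cov = pd.DataFrame({"population": "A"}, index=samples)
        g = rng.integers(0, 3, n).astype(float)
        m_perfect = 2.0 * g
        methyl = MethylMatrix(m_perfect[None, :], ["p"], samples, "M")
        calls = pd.DataFrame({"probe": ["p"], "best_snp": ["s"], "called": [True]})
        out = meqtl_variance_explained(calls, methyl, {"A": g[:, None]},
                                       pd.Index(["s"]), cov, ["A"])
        assert out.iloc[0]["r2_A"] == pytest.approx(1.0, abs=1e-12)

    def test_planted_r2_recovered(self, rng):
        n = 200
        samples = [f"A{i}" for i in range(n)]
        cov = pd.DataFrame({"population": "A"}, index=samples)
        g = rng.binomial(2, 0.5, n).astype(float)
        # effect sized for theoretical R^2 = 0.10 at noise sd 1
        eff = np.sqrt(0.1 / 0.9 / (2 * 0.5 * 0.5))
        m = eff * g + rng.normal(0, 1, n)
        methyl = MethylMatrix(m[None, :], ["p"], samples, "M")
        calls = pd.DataFrame({"probe": ["p"], "best_snp": ["s"], "called": [True]})
        out = meqtl_variance_explained(calls, methyl, {"A": g[:, None]},
                                       pd.Index(["s"]), cov, ["A"])
        assert out.iloc[0]["r2_A"] == pytest.approx(0.10, abs=0.05)

    def test_permuted_dosage_r2_near_null_expectation(self, rng):
        n, reps = 100, 300
        r2s = []
        for i in range(reps):
            g = rng.binomial(2, 0.5, n).astype(float)
            m = rng.normal(0, 1, n)
            r2s.append(np.corrcoef(m, g)[0, 1] ** 2)
        assert np.mean(r2s) == pytest.approx(1 / (n - 1), rel=0.3)


def test_genotype_pc1_separates_populations(small_cohort):
    c = small_cohort
    pc1 = genotype_pc1(c.all_dosages.astype(float))
    pops = c.metadata["population"].to_numpy()
    means = {p: pc1[pops == p].mean() for p in c.design.pop_labels}
    spread = max(means.values()) - min(means.values())
    assert spread > pc1.std()  # ancestry axis separates group means
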