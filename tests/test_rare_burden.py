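"""Rare-variant burden designs: weights, scores, calibration, and the test."""

import numpy as np
import numpy.testing as npt
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import expit, logit

import hapmosaic as hm
from hapmosaic.rare_burden import _logistic_score_test, dominant_ancestry


class TestAveragedMaf:
    def test_arithmetic_mean_of_folded(self):
        freqs = hm.PopulationFrequencies(
            pops=["a", "b"], f={"1": np.array([[0.1], [0.3]])},
            n_hap_per_pop={"a": 10, "b": 10})
        npt.assert_allclose(hm.averaged_maf(freqs, "1"), [0.2])

    def test_major_alt_is_folded_before_averaging(self):
        freqs = hm.PopulationFrequencies(
            pops=["a", "b"], f={"1": np.array([[0.9], [0.1]])},
            n_hap_per_pop={"a": 10, "b": 10})
        npt.assert_allclose(hm.averaged_maf(freqs, "1"), [0.1])

    def test_identical_populations_is_identity(self):
        f = np.array([[0.05, 0.2], [0.05, 0.2]])
        freqs = hm.PopulationFrequencies(pops=["a", "b"], f={"1": f},
                                         n_hap_per_pop={"a": 10, "b": 10})
        npt.assert_allclose(hm.averaged_maf(freqs, "1"), [0.05, 0.2])


class TestSelectRareLoci:
    def test_strict_threshold(self):
        idx, w = hm.select_rare_loci([0.001, 0.01, 0.2], 0.01)
        npt.assert_array_equal(idx, [0])
        npt.assert_array_equal(w, [1.0])

    def test_all_polymorphic_selected_at_half(self):
        idx, _ = hm.select_rare_loci([0.01, 0.2, 0.49], 0.5)
        npt.assert_array_equal(idx, [0, 1, 2])

    def test_monomorphic_excluded(self):
        idx, _ = hm.select_rare_loci([0.0, 0.004], 0.01)
        npt.assert_array_equal(idx, [1])

    def test_empty_set_is_error(self):
        with pytest.raises(ValueError, match="threshold"):
            hm.select_rare_loci([0.2, 0.3], 0.01)


class TestWeights:
    @pytest.mark.parametrize("f,w", [(0.5, 2.0), (0.2, 2.5)])
    def test_madsen_browning_values(self, f, w):
        assert hm.madsen_browning_weights([f])[0] == pytest.approx(w)

    def test_madsen_browning_monotone_decreasing(self):
        w = hm.madsen_browning_weights([0.01, 0.05, 0.5])
        assert w[0] > w[1] > w[2]

    def test_madsen_browning_boundary_error(self):
        with pytest.raises(ValueError):
            hm.madsen_browning_weights([0.0, 0.1])

    def test_scale_weights_examples(self):
        npt.assert_allclose(hm.scale_weights([1.0, 1.0, 1.0], 0.2), [0.2] * 3)
        npt.assert_allclose(hm.scale_weights([1.0, 3.0], 0.2), [0.1, 0.3])

    @given(st.lists(st.floats(min_value=1e-3, max_value=1e3), min_size=1,
                    max_size=30),
           st.floats(min_value=-2, max_value=2))
    @settings(deadline=None, derandomize=True)
    def test_mean_adjusted_weight_is_beta_star(self, w, beta_star):
        beta = hm.scale_weights(w, beta_star)
        assert beta.mean() == pytest.approx(beta_star, abs=1e-12)

    def test_all_zero_weights_is_error(self):
        with pytest.raises(ValueError):
            hm.scale_weights([0.0, 0.0], 0.5)


class TestBurdenScores:
    def test_dot_product_and_linearity(self):
        G = np.array([[0, 0], [1, 2], [2, 1]])
        beta = np.array([0.1, 0.2])
        c = hm.burden_scores(G, beta)
        npt.assert_allclose(c, [0.0, 0.5, 0.4])
        npt.assert_allclose(hm.burden_scores(G, 2 * beta), 2 * c)


class TestSolveAlphaRare:
    def test_cc_zero_burden(self):
        alpha = hm.solve_alpha_rare_cc(np.zeros(50), np.zeros(50, dtype=int),
                                       {"a": 0.5}, ["a"])
        assert alpha[0] == pytest.approx(0.0, abs=1e-10)

    def test_cc_constant_burden_closed_form(self):
        c0 = 0.8
        alpha = hm.solve_alpha_rare_cc(np.full(40, c0), np.zeros(40, dtype=int),
                                       {"a": 0.1}, ["a"])
        assert alpha[0] == pytest.approx(float(logit(0.1)) - c0, abs=1e-9)

    def test_cc_random_burden_plugback_and_grid(self, rng):
        c = rng.exponential(0.5, size=300)
        alpha = hm.solve_alpha_rare_cc(c, np.zeros(300, dtype=int),
                                       {"a": 0.1}, ["a"])[0]
        resid = abs(expit(alpha + c).mean() - 0.1)
        assert resid < 1e-10
        grid = np.linspace(alpha - 0.2, alpha + 0.2, 100_001)
        vals = expit(grid[None, :] + c[:, None]).mean(axis=0)
        assert alpha == pytest.approx(grid[np.argmin(np.abs(vals - 0.1))],
                                      abs=1e-5)

    def test_quant_closed_form_and_plugback(self):
        c = np.array([0.2, 0.6])  # mean 0.4
        alpha = hm.solve_alpha_rare_quant(c, np.zeros(2, dtype=int),
                                          {"a": 1.0}, ["a"])
        assert alpha[0] == pytest.approx(0.6)
        assert (alpha[0] + c).mean() == pytest.approx(1.0)


class TestSimulateRare:
    def _config(self, design, beta_star=0.3, n=400, admix=None, **kw):
        base = dict(chroms=["1"], f_thresh=0.01, scheme="madsen_browning",
                    beta_star=beta_star, n_individuals=n,
                    admixture=admix or hm.AdmixtureSpec(
                        proportions=np.array([1.0, 0.0])))
        if design == "cc":
            base["prevalence"] = kw.get("prevalence", {"pop1": 0.2, "pop2": 0.2})
        else:
            base["means"] = kw.get("means", {"pop1": 0.0, "pop2": 1.0})
            base["sigma"] = kw.get("sigma", 1.0)
        return hm.RareConfig(**base)

    def test_null_beta_gives_nominal_prevalence(self, rare_panel):
        panel, _, _, profiles = rare_panel
        n, p = 8000, 0.2
        cfg = self._config("cc", beta_star=0.0, n=n,
                           prevalence={"pop1": p, "pop2": p})
        cohort = hm.simulate_cc_rare(panel, profiles, cfg,
                                     np.random.default_rng(31))
        frac = cohort.phenotypes.mean()
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_positive_beta_cases_carry_more_burden(self, rare_panel):
        panel, _, _, profiles = rare_panel
        cfg = self._config("cc", beta_star=1.5, n=4000)
        cohort = hm.simulate_cc_rare(panel, profiles, cfg,
                                     np.random.default_rng(32))
        c = cohort.metadata["burden"]
        D = cohort.phenotypes
        assert c[D == 1].mean() > c[D == 0].mean()

    def test_cc_intercept_plugback_on_realized_cohort(self, rare_panel):
        panel, _, _, profiles = rare_panel
        cfg = self._config("cc", beta_star=0.8, n=600,
                           admix=hm.AdmixtureSpec(dirichlet=np.array([2.0, 2.0])))
        cohort = hm.simulate_cc_rare(panel, profiles, cfg,
                                     np.random.default_rng(33))
        c = cohort.metadata["burden"]
        alpha = cohort.metadata["alpha"]
        dom = dominant_ancestry(cohort.admixture)
        for k, pop in enumerate(cohort.pops):
            ck = c[dom == k]
            assert ck.size > 0
            assert abs(expit(alpha[k] + ck).mean() - 0.2) < 1e-10

    def test_quant_rare_identities(self, rare_panel):
        panel, _, _, profiles = rare_panel
        cfg = self._config("quant", beta_star=0.5, n=500, sigma=0.0)
        cohort = hm.simulate_quant_rare(panel, profiles, cfg,
                                        np.random.default_rng(34))
        c = cohort.metadata["burden"]
        alpha = cohort.metadata["alpha"]
        # sigma = 0: z = alpha_1 + c exactly (pure pop1 cohort)
        npt.assert_allclose(cohort.phenotypes, alpha[0] + c, atol=1e-12)
        assert cohort.phenotypes.mean() == pytest.approx(0.0, abs=1e-10)

    def test_quant_rare_slope_on_burden_is_one(self, rare_panel):
        panel, _, _, profiles = rare_panel
        cfg = self._config("quant", beta_star=1.0, n=3000, sigma=0.5)
        cohort = hm.simulate_quant_rare(panel, profiles, cfg,
                                        np.random.default_rng(35))
        res = stats.linregress(cohort.metadata["burden"], cohort.phenotypes)
        assert abs(res.slope - 1.0) < 3 * res.stderr


class TestBurdenTest:
    def test_constant_burden_is_error(self, rare_panel):
        panel, _, _, profiles = rare_panel
        cfg = hm.RareConfig(chroms=["1"], f_thresh=0.01, scheme="fixed",
                            beta_star=0.0, n_individuals=50,
                            admixture=hm.AdmixtureSpec(
                                proportions=np.array([1.0, 0.0])),
                            prevalence={"pop1": 0.5, "pop2": 0.5})
        cohort = hm.simulate_cc_rare(panel, profiles, cfg,
                                     np.random.default_rng(36))
        weights = cohort.metadata["weights"]
        zero = hm.BurdenWeights(loci=weights.loci[:1],
                                f_bar=weights.f_bar[:1], w=np.ones(1),
                                beta=np.zeros(1),
                                alt_is_minor=np.array([True]),
                                scheme="fixed", beta_star=0.0)
        # restrict to a locus where nobody in this small cohort is a carrier
        G = hm.burden_genotypes(cohort, weights)
        mono = np.flatnonzero(G.sum(axis=0) == 0)
        if mono.size == 0:
            pytest.skip("no monomorphic rare locus in this draw")
        zero.loci = [weights.loci[int(mono[0])]]
        with pytest.raises(ValueError, match="constant"):
            hm.burden_test(cohort, zero)

    def test_score_test_calibrated_under_null(self, rng):
        # independent c and D: p-values uniform, rejection near nominal
        pvals = []
        for _ in range(500):
            c = rng.poisson(1.0, size=150).astype(float)
            if np.ptp(c) == 0:
                continue
            D = rng.binomial(1, 0.3, size=150).astype(float)
            if D.min() == D.max():
                continue
            pvals.append(_logistic_score_test(c, D).pvalue)
        pvals = np.asarray(pvals)
        rej = (pvals < 0.05).mean()
        assert 0.02 < rej < 0.09
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_power_increases_with_effect_size(self, rare_panel):
        panel, _, _, profiles = rare_panel
        rng = np.random.default_rng(40)
        rejections = {}
        for beta_star in (0.2, 2.0):
            cfg = hm.RareConfig(
                chroms=["1"], f_thresh=0.01, scheme="madsen_browning",
                beta_star=beta_star, n_individuals=250,
                admixture=hm.AdmixtureSpec(proportions=np.array([1.0, 0.0])),
                prevalence={"pop1": 0.3, "pop2": 0.3})
            hits = 0
            for _ in range(60):
                cohort = hm.simulate_cc_rare(panel, profiles, cfg, rng)
                res = hm.burden_test(cohort, cohort.metadata["weights"])
                hits += res.pvalue < 0.05
            rejections[beta_star] = hits / 60
        assert rejections[2.0] > rejections[0.2]

    def test_permuted_phenotypes_give_uniform_pvalues(self, rare_panel):
        # Madsen-Browning weights give a continuous score; the equal-weight
        # scheme would make the permutation distribution too discrete for KS
        panel, _, _, profiles = rare_panel
        cfg = hm.RareConfig(
            chroms=["1"], f_thresh=0.01, scheme="madsen_browning", beta_star=1.0,
            n_individuals=300,
            admixture=hm.AdmixtureSpec(proportions=np.array([1.0, 0.0])),
            prevalence={"pop1": 0.3, "pop2": 0.3})
        rng = np.random.default_rng(41)
        cohort = hm.simulate_cc_rare(panel, profiles, cfg, rng)
        weights = cohort.metadata["weights"]
        c = hm.burden_scores(hm.burden_genotypes(cohort, weights), weights.w)
        D = cohort.phenotypes.astype(float)
        pvals = []
        for _ in range(400):
            Dp = rng.permutation(D)
            pvals.append(_logistic_score_test(c, Dp).pvalue)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
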