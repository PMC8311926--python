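import numpy as np
import pytest
from scipy import stats
from scipy.stats import multivariate_normal

import socialgwas as sg
from socialgwas.varcomp import LLRTest, _llr
from conftest import random_valid_params


class TestLikelihoodEvaluation:
    def test_matches_dense_mvn_oracle(self, tiny_dataset, rng):
        genotypes, cages, A = tiny_dataset
        n = cages.n
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = rng.standard_normal(n)
        for _ in range(8):
            params = random_valid_params(rng)
            b = rng.standard_normal(2)
            C = sg.build_covariance(params, A, cages)
            ll = sg.loglik_at(y, X, params, A, cages, b=b)
            oracle = multivariate_normal(
                mean=X @ b, cov=C, allow_singular=True
            ).logpdf(y)
            assert ll == pytest.approx(oracle, abs=1e-8)

    def test_profiled_b_dominates_fixed_b(self, tiny_dataset, rng):
        _, cages, A = tiny_dataset
        n = cages.n
        X = np.ones((n, 1))
        y = rng.standard_normal(n) + 0.4
        params = random_valid_params(rng)
        ll_prof = sg.loglik_at(y, X, params, A, cages)
        for _ in range(5):
            assert ll_prof >= sg.loglik_at(
                y, X, params, A, cages, b=rng.standard_normal(1)
            ) - 1e-12

    def test_fit_loglik_consistent_with_reml_evaluator(self, small_panel):
        genotypes, cages, A, comps = small_panel
        rng = np.random.default_rng(3)
        spec = sg.SimulationSpec(n_individuals=150, n_variants=200)
        y, _ = sg.simulate_phenotype(spec, genotypes, cages, A=A, comps=comps, rng=rng)
        X = np.ones((150, 1))
        fit = sg.fit_varcomp(y, X, A, cages, comps=comps, n_restarts=0)
        ll = sg.loglik_at(y, X, fit.params, A, cages, reml=True)
        assert ll == pytest.approx(fit.loglik, abs=1e-6)


class TestFitRecovery:
    def test_pure_noise_yields_small_genetic_fractions(self):
        # under iid noise the boundary-constrained genetic estimates keep
        # both aggregate fractions near zero on average; n large enough
        # that the half-normal boundary bias sits well under 5%
        rng = np.random.default_rng(11)
        n = 600
        genotypes = sg.simulate_genotypes(n, 300, (0.05, 0.5), rng)
        cages = sg.CageStructure.random(n, 3, rng)
        A = sg.compute_grm(genotypes)
        comps = sg.component_matrices(A, cages)
        X = np.ones((n, 1))
        props = []
        for _ in range(10):
            y = rng.standard_normal(n)
            fit = sg.fit_varcomp(y, X, A, cages, comps=comps, n_restarts=0)
            props.append((fit.prop_DGE, fit.prop_IGE))
        mean_dge, mean_ige = np.mean(props, axis=0)
        assert mean_dge < 0.05
        assert mean_ige < 0.05

    def test_boundary_estimates_are_valid(self, small_panel):
        genotypes, cages, A, comps = small_panel
        rng = np.random.default_rng(2)
        y = rng.standard_normal(150)
        fit = sg.fit_varcomp(y, np.ones((150, 1)), A, cages, comps=comps)
        assert fit.params.sigma2_AD >= 0
        assert fit.params.sigma2_AS >= 0
        assert 0 <= fit.prop_DGE <= 1
        assert 0 <= fit.prop_IGE <= 1

    def test_missing_values_rejected(self, small_panel):
        _, cages, A, comps = small_panel
        y = np.full(150, np.nan)
        with pytest.raises(ValueError, match="missing"):
            sg.fit_varcomp(y, np.ones((150, 1)), A, cages, comps=comps)


class TestLLRTests:
    def _fit_like(self, loglik):
        return sg.VarCompFit(
            params=None, beta=None, loglik=loglik, prop_DGE=0, prop_IGE=0,
            rho=0.2, n_used=10, C=None,
        )

    def test_identical_logliks_give_p_one(self):
        t = sg.test_aggregate_ige(self._fit_like(-5.0), self._fit_like(-5.0))
        assert t.p_value == pytest.approx(1.0)
        assert t.conservative

    def test_chi2_two_df_quantile(self):
        t = sg.test_aggregate_ige(
            self._fit_like(-10.0), self._fit_like(-10.0 - 5.99 / 2)
        )
        assert t.p_value == pytest.approx(0.05, abs=0.001)

    def test_optimization_failure_detected(self):
        with pytest.raises(RuntimeError, match="optimization"):
            sg.test_aggregate_ige(self._fit_like(-10.0), self._fit_like(-9.0))

    def test_rho_undefined_raises(self):
        fit = self._fit_like(-3.0)
        fit.rho = float("nan")
        with pytest.raises(ValueError, match="undefined"):
            sg.test_rho(fit, self._fit_like(-3.0), 0.0)

    def test_aggregate_ige_test_is_conservative_under_null(self, small_panel):
        # data with no IGE at all: 2-df test should reject at most at the
        # nominal rate (boundary null makes it conservative)
        genotypes, cages, A, comps = small_panel
        rng = np.random.default_rng(17)
        spec = sg.SimulationSpec(
            n_individuals=150, n_variants=200, ige=0.0, rho_a=0.0,
            dge=0.25, dee=0.30, iee=0.15, cage=0.25,
        )
        X = np.ones((150, 1))
        rejections = 0
        n_reps = 30
        for _ in range(n_reps):
            y, _ = sg.simulate_phenotype(
                spec, genotypes, cages, A=A, comps=comps, rng=rng
            )
            fit = sg.fit_varcomp(y, X, A, cages, comps=comps, n_restarts=0)
            fit0 = sg.fit_varcomp(
                y, X, A, cages, genetic="noige", comps=comps, n_restarts=0
            )
            if sg.test_aggregate_ige(fit, fit0).p_value < 0.05:
                rejections += 1
        # binomial upper bound for rate 0.05 at 30 replicates
        assert rejections <= 5

    def test_rho_one_data_not_rejected(self, small_panel):
        # a_S proportional to a_D (rho = 1): the |rho| = 1 constrained fit
        # should track the full fit
        genotypes, cages, A, comps = small_panel
        rng = np.random.default_rng(23)
        spec = sg.SimulationSpec(
            n_individuals=150, n_variants=200, dge=0.25, ige=0.25, rho_a=1.0,
            dee=0.25, iee=0.0, rho_e=0.0, cage=0.20,
        )
        X = np.ones((150, 1))
        non_rejections = 0
        n_reps = 8
        for _ in range(n_reps):
            y, _ = sg.simulate_phenotype(
                spec, genotypes, cages, A=A, comps=comps, rng=rng
            )
            fit = sg.fit_varcomp(y, X, A, cages, comps=comps, n_restarts=0)
            if np.isnan(fit.rho):
                non_rejections += 1  # boundary fit, no evidence against
                continue
            fit1 = sg.fit_varcomp(
                y, X, A, cages, genetic="rho1", comps=comps, n_restarts=0
            )
            if sg.test_rho(fit, fit1, 1.0).p_value >= 0.05:
                non_rejections += 1
        assert non_rejections >= 6

    def test_analyze_phenotype_bundles_everything(self, small_panel):
        genotypes, cages, A, comps = small_panel
        rng = np.random.default_rng(31)
        spec = sg.SimulationSpec(n_individuals=150, n_variants=200)
        y, _ = sg.simulate_phenotype(spec, genotypes, cages, A=A, comps=comps, rng=rng)
        res = sg.analyze_phenotype(
            y, np.ones((150, 1)), A, cages, comps=comps, n_restarts=0,
            test_rho_flag=True,
        )
        assert 0 <= res.p_ige <= 1
        assert res.p_rho_vs_0 is not None
        assert res.p_rho_vs_1 is not None
        assert res.fit.loglik >= res.fit_noige.loglik - 1e-6
        assert res.fit.loglik >= res.fit_rho0.loglik - 1e-6


class TestQvalues:
    def test_all_ones(self):
        assert np.allclose(sg.qvalues(np.ones(50)), 1.0)

    def test_single_p_bounded_by_p(self):
        p = np.array([0.03])
        q = sg.qvalues(p)
        assert q[0] <= p[0] + 1e-12

    def test_matches_direct_formula_oracle(self):
        p = np.concatenate([np.full(10, 0.001), np.full(90, 0.5)])
        q = sg.qvalues(p)
        # independent oracle: q_i = min over thresholds t >= p_i of
        # pi0 * m * t / #{p <= t}, computed by explicit search
        from socialgwas.qvalue import estimate_pi0

        pi0 = estimate_pi0(p)
        m = len(p)
        oracle = np.empty(m)
        for i, pi in enumerate(p):
            cands = [
                pi0 * m * t / (p <= t).sum() for t in np.unique(p) if t >= pi
            ]
            oracle[i] = min(min(cands), 1.0)
        assert np.allclose(q, oracle, atol=1e-12)
        assert q[0] < 0.05

    def test_monotone_in_p(self, rng):
        p = rng.uniform(size=200)
        q = sg.qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            sg.qvalues(np.array([0.5, 1.5]))
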