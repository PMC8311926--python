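import numpy as np
import pytest
from scipy import optimize, stats

import socialgwas as sg


@pytest.fixture(scope="module")
def scan_dataset():
    """n=120 (40 cages), 300 variants, phenotype with no local effects."""
    rng = np.random.default_rng(42)
    n = 120
    genotypes = sg.simulate_genotypes(n, 300, (0.1, 0.5), rng)
    cages = sg.CageStructure.random(n, 3, rng)
    A = sg.compute_grm(genotypes)
    comps = sg.component_matrices(A, cages)
    spec = sg.SimulationSpec(n_individuals=n, n_variants=300)
    y, _ = sg.simulate_phenotype(spec, genotypes, cages, A=A, comps=comps, rng=rng)
    X = np.ones((n, 1))
    fit = sg.fit_varcomp(y, X, A, cages, comps=comps, n_restarts=0)
    return genotypes, cages, A, y, X, fit


class TestSocialGenotype:
    def test_cage_of_three_sums_mates(self):
        cages = sg.CageStructure(np.array(["c", "c", "c"]))
        g = np.array([0.0, 1.0, 2.0])
        assert np.allclose(sg.social_genotype(g, cages), [3.0, 2.0, 1.0])

    def test_monomorphic_gives_constant(self, rng):
        cages = sg.CageStructure.random(12, 3, rng)
        zg = sg.social_genotype(np.full(12, 2.0), cages)
        assert np.allclose(zg, 4.0)  # 2 * (cage_size - 1)

    def test_matches_per_individual_loop(self, rng):
        cages = sg.CageStructure.random(12, 3, rng)
        g = rng.binomial(2, 0.4, 12).astype(float)
        zg = sg.social_genotype(g, cages)
        for i in range(12):
            mates = [
                j
                for j in range(12)
                if j != i and cages.cage_labels[j] == cages.cage_labels[i]
            ]
            assert zg[i] == pytest.approx(g[mates].sum())

    def test_average_coding_halves_sum(self, rng):
        cages = sg.CageStructure.random(12, 3, rng)
        g = rng.binomial(2, 0.4, 12).astype(float)
        assert np.array_equal(
            sg.social_genotype(g, cages, "average"),
            sg.social_genotype(g, cages, "sum") / 2.0,
        )


class TestLlrFixedCov:
    def _toy(self, rng, n=20):
        B = rng.standard_normal((n, n))
        C = B @ B.T / n + np.eye(n)
        X0 = np.column_stack([np.ones(n), rng.standard_normal(n)])
        g = rng.binomial(2, 0.3, n).astype(float)
        y = rng.standard_normal(n) + 0.3 * g
        return y, X0, g, C

    def test_orthogonal_column_gives_llr_zero(self, rng):
        n = 30
        C = np.eye(n)
        X0 = np.ones((n, 1))
        y = rng.standard_normal(n)
        y -= y.mean()
        # construct a column orthogonal to the y residual (C = I)
        g = rng.standard_normal(n)
        g -= g.mean()
        g -= (g @ y) / (y @ y) * y
        beta, nlp = sg.llr_fixed_cov(y, X0, np.column_stack([X0, g]), C)
        assert nlp == pytest.approx(0.0, abs=1e-8)
        assert beta == pytest.approx(0.0, abs=1e-10)

    def test_matches_numeric_likelihood_maximization(self, rng):
        # oracle: maximize the exact Gaussian likelihood (scale on C
        # profiled numerically) for null and alternative designs
        y, X0, g, C = self._toy(rng)
        X1 = np.column_stack([X0, g])
        Ci = np.linalg.inv(C)
        sign, logdetC = np.linalg.slogdet(C)
        n = len(y)

        def max_ll(X):
            k = X.shape[1]

            def nll(par):
                b, log_s = par[:k], par[k]
                r = y - X @ b
                s = np.exp(log_s)
                return 0.5 * (
                    n * np.log(2 * np.pi) + n * log_s + logdetC
                    + (r @ Ci @ r) / s
                )

            best = None
            for x0 in (np.zeros(k + 1), 0.1 * np.ones(k + 1)):
                res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                        options={"maxiter": 20000,
                                                 "xatol": 1e-10,
                                                 "fatol": 1e-12})
                if best is None or res.fun < best:
                    best = res.fun
            return -best

        llr_oracle = 2.0 * (max_ll(X1) - max_ll(X0))
        _, nlp = sg.llr_fixed_cov(y, X0, X1, C)
        nlp_oracle = -stats.chi2.logsf(llr_oracle, 1) / np.log(10)
        assert nlp == pytest.approx(nlp_oracle, abs=1e-3)

    def test_duplicate_column_errors(self, rng):
        y, X0, g, C = self._toy(rng)
        X1 = np.column_stack([X0, X0[:, 1]])
        with pytest.raises(ValueError, match="collinear"):
            sg.llr_fixed_cov(y, X0, X1, C)

    def test_symmetric_in_tested_and_conditioning_roles(self, rng):
        # the engine treats the added column generically: testing G given
        # ZG uses the same machinery as testing ZG given G
        y, X0, g, C = self._toy(rng)
        h = rng.binomial(2, 0.4, len(y)).astype(float)
        _, nlp_g = sg.llr_fixed_cov(
            y, np.column_stack([X0, h]), np.column_stack([X0, h, g]), C
        )
        _, nlp_g2 = sg.llr_fixed_cov(
            y, np.column_stack([X0, h]), np.column_stack([h, X0, g]), C
        )
        assert nlp_g == pytest.approx(nlp_g2, abs=1e-9)


class TestScan:
    def test_null_p_values_uniform(self, scan_dataset):
        genotypes, cages, A, y, X, fit = scan_dataset
        table = sg.scan(y, X, A, cages, genotypes, mode="ige", fit=fit)
        p = 10.0 ** (-table.df["neg_log10_p"].to_numpy())
        ks = stats.kstest(p, "uniform")
        assert ks.pvalue > 0.01

    def test_sum_vs_average_coding(self, scan_dataset):
        # average coding doubles beta_S and leaves p-values bit-identical
        genotypes, cages, A, y, X, fit = scan_dataset
        t_sum = sg.scan(y, X, A, cages, genotypes, mode="ige", fit=fit)
        t_avg = sg.scan(
            y, X, A, cages, genotypes, mode="ige", fit=fit,
            social_coding="average",
        )
        assert np.array_equal(
            t_sum.df["neg_log10_p"].to_numpy(),
            t_avg.df["neg_log10_p"].to_numpy(),
        )
        assert np.array_equal(
            2.0 * t_sum.df["beta_S"].to_numpy(), t_avg.df["beta_S"].to_numpy()
        )

    def test_affine_recoding_invariance(self, scan_dataset):
        genotypes, cages, A, y, X, fit = scan_dataset
        recoded = sg.GenotypeSet(
            np.clip(0.7 * genotypes.dosages + 0.3, 0, 2),
            genotypes.variant_map,
            genotypes.individual_ids,
        )
        t1 = sg.scan(y, X, A, cages, genotypes, mode="ige", fit=fit, maf_min=0)
        t2 = sg.scan(y, X, A, cages, recoded, mode="ige", fit=fit, maf_min=0)
        assert np.allclose(
            t1.df["neg_log10_p"], t2.df["neg_log10_p"], atol=1e-7
        )

    def test_agrees_with_llr_fixed_cov(self, scan_dataset):
        genotypes, cages, A, y, X, fit = scan_dataset
        table = sg.scan(y, X, A, cages, genotypes, mode="ige", fit=fit)
        for j in (0, 7, 101):
            g = genotypes.dosages[:, j]
            zg = sg.social_genotype(g, cages)
            _, nlp = sg.llr_fixed_cov(
                y, np.column_stack([X, g]), np.column_stack([X, g, zg]), fit.C
            )
            assert table.df["neg_log10_p"].iloc[j] == pytest.approx(
                nlp, abs=1e-8
            )

    def test_dge_mode_agrees_with_engine(self, scan_dataset):
        genotypes, cages, A, y, X, fit = scan_dataset
        table = sg.scan(y, X, A, cages, genotypes, mode="dge", fit=fit)
        j = 13
        g = genotypes.dosages[:, j]
        zg = sg.social_genotype(g, cages)
        _, nlp = sg.llr_fixed_cov(
            y, np.column_stack([X, zg]), np.column_stack([X, zg, g]), fit.C
        )
        assert table.df["neg_log10_p"].iloc[j] == pytest.approx(nlp, abs=1e-8)

    def test_zero_variance_variant_flagged(self, scan_dataset):
        genotypes, cages, A, y, X, fit = scan_dataset
        dosages = genotypes.dosages.copy()
        dosages[:, 5] = 1.0  # constant but MAF 0.5, passes the MAF filter
        gt = sg.GenotypeSet(dosages, genotypes.variant_map, genotypes.individual_ids)
        table = sg.scan(y, X, A, cages, gt, mode="ige", fit=fit)
        row = table.df.iloc[5]
        assert row["flag"] == "zero_variance"
        assert row["neg_log10_p"] == 0.0

    def test_detects_planted_social_effect(self, scan_dataset):
        genotypes, cages, A, y, X, fit = scan_dataset
        j = 42
        zg = sg.social_genotype(genotypes.dosages[:, j], cages)
        y2 = y + 0.8 * zg
        table = sg.scan(y2, X, A, cages, genotypes, mode="ige", fit=fit)
        assert table.df["neg_log10_p"].idxmax() == j

    def test_roundtrip_tsv(self, scan_dataset, tmp_path):
        genotypes, cages, A, y, X, fit = scan_dataset
        table = sg.scan(y, X, A, cages, genotypes, mode="ige", fit=fit,
                        phenotype="toy")
        path = tmp_path / "scan.tsv"
        table.to_tsv(path)
        back = sg.AssociationTable.from_tsv(path)
        assert back.phenotype == "toy"
        assert back.mode == "ige"
        assert np.allclose(
            back.df["neg_log10_p"], table.df["neg_log10_p"], atol=1e-12
        )
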