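"""Maximum-likelihood fitting of the social variance-component model.

The phenotype vector is modelled as y ~ N(X b, C(theta)) with C the
weighted sum of component matrices described in :mod:`socialgwas.covariance`.
Fixed effects b are profiled out in closed form (GLS); the variance
parameters are optimized by quasi-Newton iteration with analytic
gradients. Positive-definiteness of the 2x2 genetic and environmental
blocks is enforced by Cholesky parameterization, so no box constraints are
needed; boundary estimates (a variance driven to 0) are valid outputs.

Aggregate contributions of direct and indirect genetic effects are
reported as sampleVar(s2_AD A) / sampleVar(C) and
sampleVar(s2_AS Z A Z') / sampleVar(C), and the DGE-IGE correlation as
rho = s_ADS / (s_AD s_AS). Likelihood-ratio tests compare nested refits:
the aggregate IGE test removes both s2_AS and s_ADS (2 df, conservative
because the null pins a variance to its boundary), the rho tests constrain
the genetic block to rho = 0 or |rho| = 1 (1 df).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.linalg import LinAlgError, cho_factor, cho_solve

from .cages import CageStructure
from .covariance import (
    SocialCovarianceParams,
    build_covariance,
    chol_psd,
    component_matrices,
    sample_var,
)

__all__ = [
    "VarCompFit",
    "LLRTest",
    "fit_varcomp",
    "loglik_at",
    "subset_comps",
    "test_aggregate_ige",
    "test_rho",
    "analyze_phenotype",
    "PhenotypeAnalysis",
]


def subset_comps(comps: dict, idx) -> dict:
    """Restrict precomputed component matrices to focal rows/columns.

    Selecting S C S' for a selector S of focal individuals is exactly the
    covariance of their phenotypes, so models over a phenotyped subset
    reuse the full-cohort components; unphenotyped cage mates still enter
    through the social terms baked into Z A Z' etc.
    """
    idx = np.asarray(idx)
    return {k: M[np.ix_(idx, idx)] for k, M in comps.items()}

_LOG2PI = np.log(2.0 * np.pi)
_BIG = 1e12


# ---------------------------------------------------------------------------
# parameter blocks


class _GeneticBlock:
    """Maps free parameters to (s2_AD, s_ADS, s2_AS) with PSD guaranteed."""

    def __init__(self, kind: str):
        self.kind = kind
        self.n_par = {"full": 3, "noige": 1, "rho0": 2, "rho1": 2}[kind]

    def theta(self, x):
        if self.kind == "full":
            g11, g21, g22 = x
            return np.array([g11**2, g11 * g21, g21**2 + g22**2])
        if self.kind == "noige":
            return np.array([x[0] ** 2, 0.0, 0.0])
        if self.kind == "rho0":
            return np.array([x[0] ** 2, 0.0, x[1] ** 2])
        # rho1: rank-1 genetic block v v', sign of v1*v2 selects rho = +/-1
        v1, v2 = x
        return np.array([v1**2, v1 * v2, v2**2])

    def jac(self, x):
        J = np.zeros((3, self.n_par))
        if self.kind == "full":
            g11, g21, g22 = x
            J[0, 0] = 2 * g11
            J[1, 0] = g21
            J[1, 1] = g11
            J[2, 1] = 2 * g21
            J[2, 2] = 2 * g22
        elif self.kind == "noige":
            J[0, 0] = 2 * x[0]
        elif self.kind == "rho0":
            J[0, 0] = 2 * x[0]
            J[2, 1] = 2 * x[1]
        else:
            v1, v2 = x
            J[0, 0] = 2 * v1
            J[1, 0] = v2
            J[1, 1] = v1
            J[2, 1] = 2 * v2
        return J

    def init(self, v0, rng=None):
        s = np.sqrt(0.2 * v0)
        base = {
            "full": np.array([s, 0.0, s]),
            "noige": np.array([s]),
            "rho0": np.array([s, s]),
            "rho1": np.array([s, s]),
        }[self.kind]
        if rng is not None:
            base = base * rng.lognormal(0.0, 0.5, size=base.shape)
            base += rng.normal(0.0, 0.1 * np.sqrt(v0), size=base.shape)
        return base


class _EnvBlock:
    """Environmental block: full (e_D/e_S/cage) or collapsed (s2_E, rho_E).

    The collapsed block a I + b W W' (a = s2_E (1 - rho_E),
    b = s2_E rho_E) has eigenvalues a + s b on cage means and a on
    within-cage contrasts, so it is parameterized by the square roots of
    those two eigenvalues: PSD for free is guaranteed without sigmoid
    bounds, and the rho_E = -1/(s-1) boundary is smoothly reachable.
    """

    def __init__(self, kind: str, cage_size: int | None):
        self.kind = kind
        if kind == "collapsed":
            if cage_size is None:
                raise ValueError(
                    "collapsed environmental model requires equal cage sizes"
                )
            self.n_par = 2
            self.s = cage_size
        else:
            self.n_par = 4

    # full: x = (h11, h21, h22, w) -> (s2_ED, s_EDS, s2_ES, s2_C)
    # collapsed: x = (u1, u2), eigenvalues lam1 = u1^2 (cage mean),
    #            lam2 = u2^2 (contrasts) -> coefficients
    #            (lam2 on I, (lam1 - lam2)/s on W W')

    def theta(self, x):
        if self.kind == "full":
            h11, h21, h22, w = x
            return np.array([h11**2, h11 * h21, h21**2 + h22**2, w**2])
        u1, u2 = x
        return np.array([u2**2, (u1**2 - u2**2) / self.s])

    def jac(self, x):
        if self.kind == "full":
            h11, h21, h22, w = x
            J = np.zeros((4, 4))
            J[0, 0] = 2 * h11
            J[1, 0] = h21
            J[1, 1] = h11
            J[2, 1] = 2 * h21
            J[2, 2] = 2 * h22
            J[3, 3] = 2 * w
            return J
        u1, u2 = x
        return np.array([[0.0, 2 * u2], [2 * u1 / self.s, -2 * u2 / self.s]])

    def init(self, v0, rng=None):
        if self.kind == "full":
            base = np.array(
                [np.sqrt(0.3 * v0), 0.0, np.sqrt(0.05 * v0), np.sqrt(0.15 * v0)]
            )
        else:
            # s2_E = 0.6 v0, rho_E = 0.2
            lam1 = 0.6 * v0 * (1.0 + (self.s - 1) * 0.2)
            lam2 = 0.6 * v0 * 0.8
            base = np.array([np.sqrt(lam1), np.sqrt(lam2)])
        if rng is not None:
            base = base * rng.lognormal(0.0, 0.5, size=base.shape)
            base += 0.1 * np.sqrt(v0) * rng.normal(0.0, 1.0, size=base.shape)
        return base

    def params_fields(self, th):
        if self.kind == "full":
            return dict(
                sigma2_ED=th[0], sigma_EDS=th[1], sigma2_ES=th[2], sigma2_C=th[3]
            )
        s2 = th[0] + th[1]
        return dict(
            sigma2_E=s2, rho_E=th[1] / s2 if s2 > 0 else 0.0, collapsed=True
        )


_FULL_ORDER = ("A", "AZZA", "ZAZ", "I", "ZZT_sym", "ZZt", "WWt")
_COLLAPSED_ORDER = ("A", "AZZA", "ZAZ", "I", "WWt")


# ---------------------------------------------------------------------------
# likelihood


def _gls(cf, X, y):
    """GLS fixed effects given a Cholesky factorization of C.

    Returns (beta, r, alpha) with r = y - X beta and alpha = C^{-1} r.
    """
    CiX = cho_solve(cf, X)
    Ciy = cho_solve(cf, y)
    XtCiX = X.T @ CiX
    beta = np.linalg.solve(XtCiX, X.T @ Ciy)
    r = y - X @ beta
    alpha = Ciy - CiX @ beta
    return beta, r, alpha


def _contrast_basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis K of the orthocomplement of span(X)."""
    n, k = X.shape
    Q, _ = np.linalg.qr(X, mode="complete")
    return Q[:, k:]


class _Objective:
    """Negative restricted (or profiled) log-likelihood with gradient.

    method="reml" (default) maximizes the restricted likelihood, computed
    in the contrast basis K (an orthonormal basis of span(X)-perp):

        -1/2 [ (n-k) log 2pi + log|K'CK| + y'K (K'CK)^-1 K'y ]

    This formulation matters twice over. First, the standardized-dosage
    GRM satisfies A 1 = 0, so with an intercept in X the b-profiled ML
    likelihood diverges as the environmental cage-mean eigenvalue
    approaches zero (C turns singular exactly along the constant vector);
    REML excludes that direction and is bounded. Second, evaluating REML
    as log|C| + log|X'C^-1 X| cancels catastrophically near that boundary,
    whereas K'CK stays positive definite and well-conditioned.
    method="ml" gives the plain b-profiled likelihood.
    """

    def __init__(self, y, X, Ms, gen: _GeneticBlock, env: _EnvBlock,
                 method: str = "reml"):
        self.y = y
        self.X = X
        self.gen = gen
        self.env = env
        self.n = len(y)
        self.k = X.shape[1]
        if method not in ("reml", "ml"):
            raise ValueError("method must be 'reml' or 'ml'")
        self.method = method
        self.Ms = Ms  # component matrices in the original basis
        if method == "reml":
            K = _contrast_basis(X)
            self._Ms_work = [K.T @ (M @ K) for M in Ms]
            self._y_work = K.T @ y
            self._dim = self.n - self.k
        else:
            self._Ms_work = Ms
            self._y_work = y
            self._dim = self.n

    def split(self, x):
        return x[: self.gen.n_par], x[self.gen.n_par :]

    def theta(self, x):
        xg, xe = self.split(x)
        return np.concatenate([self.gen.theta(xg), self.env.theta(xe)])

    def build_C(self, th, Ms=None):
        Ms = self.Ms if Ms is None else Ms
        C = th[0] * Ms[0]
        for t, M in zip(th[1:], Ms[1:]):
            if t != 0.0:
                C = C + t * M
        return C

    def __call__(self, x):
        th = self.theta(x)
        C = self.build_C(th, self._Ms_work)
        try:
            cf = cho_factor(C, lower=True)
        except LinAlgError:
            return _BIG, np.zeros_like(x)
        logdet = 2.0 * np.log(np.diag(cf[0])).sum()
        if self.method == "reml":
            alpha = cho_solve(cf, self._y_work)
            quad = self._y_work @ alpha
        else:
            try:
                _, r, alpha = _gls(cf, self.X, self.y)
            except np.linalg.LinAlgError:
                return _BIG, np.zeros_like(x)
            quad = r @ alpha
        ll = -0.5 * (self._dim * _LOG2PI + logdet + quad)
        Cinv = cho_solve(cf, np.eye(self._dim))
        gth = np.empty(len(th))
        for j, M in enumerate(self._Ms_work):
            Ma = M @ alpha
            gth[j] = -0.5 * ((Cinv * M).sum() - alpha @ Ma)
        xg, xe = self.split(x)
        J = np.zeros((len(th), len(x)))
        J[:3, : self.gen.n_par] = self.gen.jac(xg)
        J[3:, self.gen.n_par :] = self.env.jac(xe)
        grad = J.T @ gth
        return -ll, -grad

    def loglik_only(self, x):
        return -self(x)[0]


def _full_start_from_collapsed(
    params: SocialCovarianceParams, cage_size: int
) -> np.ndarray:
    """Free-parameter vector of the full model matching a collapsed fit.

    The collapsed diagonal/within-cage pair (delta, omega) corresponds to
    full-form components via delta = s2_ED + (s-1) s2_ES + s2_C and
    omega = 2 s_EDS + (s-2) s2_ES + s2_C; a PSD-feasible preimage always
    exists for omega/delta in [-1/(s-1), 1].
    """
    s = cage_size
    delta = max(params.sigma2_E, 1e-12)
    omega = params.rho_E * params.sigma2_E
    if omega >= 0:
        env = (delta - omega, 0.0, 0.0, omega)  # (s2_ED, s_EDS, s2_ES, s2_C)
    else:
        # exact preimage with s2_C = 0: solve the two linear equations for
        # a grid of s2_ES and keep the most PSD-feasible point; the
        # feasibility margin is exactly 0 at omega = -delta/(s-1)
        best = None
        for frac in np.linspace(0.02, 0.98, 97):
            s2_ES = frac * delta / (s - 1)
            s2_ED = delta - (s - 1) * s2_ES
            s_EDS = (omega - (s - 2) * s2_ES) / 2.0
            margin = s2_ED * s2_ES - s_EDS**2
            if best is None or margin > best[0]:
                best = (margin, s2_ED, s_EDS, s2_ES)
        margin, s2_ED, s_EDS, s2_ES = best
        if margin < 0:  # clip onto the PSD boundary
            s_EDS = -np.sqrt(max(s2_ED * s2_ES, 0.0))
        env = (s2_ED, s_EDS, s2_ES, 0.0)
    h11 = np.sqrt(max(env[0], 1e-12))
    h21 = env[1] / h11
    h22 = np.sqrt(max(env[2] - h21**2, 0.0))
    w = np.sqrt(max(env[3], 0.0))
    g11 = np.sqrt(max(params.sigma2_AD, 1e-12))
    g21 = params.sigma_ADS / g11
    g22 = np.sqrt(max(params.sigma2_AS - g21**2, 0.0))
    return np.array([g11, g21, g22, h11, h21, h22, w])


@dataclass
class VarCompFit:
    """Fitted social variance-component model for one phenotype."""

    params: SocialCovarianceParams
    beta: np.ndarray
    loglik: float
    prop_DGE: float
    prop_IGE: float
    rho: float
    n_used: int
    C: np.ndarray = field(repr=False)
    converged: bool = True
    genetic: str = "full"
    method: str = "reml"
    n_restarts_used: int = 0
    restart_logliks: list = field(default_factory=list, repr=False)


def _sample_var_props(theta3, Ms, C):
    svC = sample_var(C)
    prop_dge = theta3[0] * sample_var(Ms[0]) / svC
    prop_ige = theta3[2] * sample_var(Ms[2]) / svC
    return prop_dge, prop_ige


def fit_varcomp(
    y,
    X,
    A,
    cages: CageStructure,
    collapse_env: bool | None = None,
    genetic: str = "full",
    method: str = "reml",
    n_restarts: int = 1,
    seed: int = 0,
    comps: dict | None = None,
    maxiter: int = 800,
    gtol: float = 1e-7,
) -> VarCompFit:
    """Fit the social model by maximum likelihood.

    Parameters
    ----------
    y, X : phenotype vector and covariate design (no missing values; X
        should include an intercept column).
    A : GRM.
    cages : cage structure (all cages complete).
    collapse_env : use the 2-parameter environmental form; default: yes
        when all cages share one size (where the full form is
        non-identifiable), no otherwise.
    genetic : "full", "noige" (s2_AS = s_ADS = 0), "rho0" (s_ADS = 0) or
        "rho1" (|rho| = 1, better-likelihood sign).
    method : "reml" (default; see _Objective for why) or "ml".
    n_restarts : extra seeded random restarts on top of the deterministic
        moment-based start; the best optimum is kept.
    comps : precomputed component_matrices() output, reusable across
        phenotypes/replicates that share A and cages.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    n = len(y)
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValueError("y and X must not contain missing values")
    size = cages.uniform_size
    if collapse_env is None:
        collapse_env = size is not None
    if collapse_env and size is None:
        raise ValueError("collapsed environmental model requires equal cage sizes")

    order = _COLLAPSED_ORDER if collapse_env else _FULL_ORDER
    if comps is None or any(k not in comps for k in order):
        comps = (comps or {}) | component_matrices(
            A, cages, collapsed=collapse_env
        )
    Ms = [comps[k] for k in order]

    gen = _GeneticBlock(genetic)
    env = _EnvBlock("collapsed" if collapse_env else "full", size)
    obj = _Objective(y, X, Ms, gen, env, method=method)

    # moment-based deterministic start from the OLS residual variance
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    v0 = float(np.var(y - X @ beta0))
    if v0 <= 0:
        v0 = 1.0
    starts = [np.concatenate([gen.init(v0), env.init(v0)])]
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        starts.append(np.concatenate([gen.init(v0, rng), env.init(v0, rng)]))
    if not collapse_env and size is not None and genetic == "full":
        # the full environmental form has a flat ridge when cages are
        # equal-sized; seed it with the (cheap, well-behaved) collapsed
        # optimum mapped back into the full parameterization
        try:
            warm = fit_varcomp(
                y, X, A, cages, collapse_env=True, genetic="full",
                method=method, n_restarts=0, seed=seed, comps=comps,
                maxiter=maxiter,
            )
            starts.append(_full_start_from_collapsed(warm.params, size))
        except (RuntimeError, ValueError):
            pass

    best = None
    logliks = []
    for x0 in starts:
        res = optimize.minimize(
            obj,
            x0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-13, "gtol": gtol},
        )
        logliks.append(-res.fun)
        if best is None or res.fun < best.fun:
            best = res
    if best.fun >= _BIG / 2:
        raise RuntimeError(
            f"variance-component optimization failed; restart logliks: {logliks}"
        )

    th = obj.theta(best.x)
    C = obj.build_C(th)
    # C may be singular on the boundary, but only along directions inside
    # span(X) (the constant vector); the GLS estimator is invariant to
    # adding X D X' to the covariance, which restores positive
    # definiteness without moving beta
    scale = max(float(np.abs(np.diag(C)).mean()), 1e-12)
    C_b = C + (scale / max(float((X * X).sum(axis=0).mean()), 1e-12)) * (
        X @ X.T
    )
    L = chol_psd(C_b)
    beta, _, _ = _gls((L, True), X, y)
    prop_dge, prop_ige = _sample_var_props(th[:3], Ms, C)
    params = SocialCovarianceParams(
        sigma2_AD=th[0],
        sigma_ADS=th[1],
        sigma2_AS=th[2],
        **env.params_fields(th[3:]),
    )
    rho = params.rho if min(th[0], th[2]) > 1e-10 else float("nan")
    return VarCompFit(
        params=params,
        beta=beta,
        loglik=float(-best.fun),
        prop_DGE=float(prop_dge),
        prop_IGE=float(prop_ige),
        rho=float(rho),
        n_used=n,
        C=C,
        converged=bool(best.success),
        genetic=genetic,
        method=method,
        n_restarts_used=n_restarts,
        restart_logliks=logliks,
    )


def loglik_at(
    y,
    X,
    params: SocialCovarianceParams,
    A,
    cages: CageStructure,
    b=None,
    reml: bool = False,
) -> float:
    """Gaussian log-likelihood of the social model at fixed parameters.

    With ``b`` given this is the plain N(X b, C(params)) log-density of y;
    with ``b=None`` the fixed effects are profiled (GLS). ``reml=True``
    evaluates the restricted likelihood instead (always profiling b),
    matching the criterion maximized by :func:`fit_varcomp`.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    C = build_covariance(params, A, cages, check_psd=False)
    if reml:
        # same contrast-basis convention as the fitting objective
        K = _contrast_basis(X)
        Cw = K.T @ (C @ K)
        yw = K.T @ y
        cfw = cho_factor(Cw, lower=True)
        logdet_w = 2.0 * np.log(np.diag(cfw[0])).sum()
        quad = yw @ cho_solve(cfw, yw)
        return float(
            -0.5 * ((len(y) - X.shape[1]) * _LOG2PI + logdet_w + quad)
        )
    cf = cho_factor(C, lower=True)
    logdet = 2.0 * np.log(np.diag(cf[0])).sum()
    if b is None:
        b, r, alpha = _gls(cf, X, y)
    else:
        r = y - X @ np.asarray(b, dtype=float)
        alpha = cho_solve(cf, r)
    return float(-0.5 * (len(y) * _LOG2PI + logdet + r @ alpha))


# ---------------------------------------------------------------------------
# likelihood-ratio tests


@dataclass
class LLRTest:
    statistic: float
    df: int
    p_value: float
    conservative: bool = False


def _llr(fit_alt: VarCompFit, fit_null: VarCompFit, df: int, conservative: bool):
    stat = 2.0 * (fit_alt.loglik - fit_null.loglik)
    # a just-negative statistic means the nested fit converged marginally
    # tighter on a shared optimum -> statistically a zero; larger deficits
    # signal a real optimization failure
    if stat < -1e-3:
        raise RuntimeError(
            "alternative log-likelihood below null "
            f"({fit_alt.loglik:.6f} < {fit_null.loglik:.6f}): optimization failure"
        )
    stat = max(stat, 0.0)
    return LLRTest(stat, df, float(stats.chi2.sf(stat, df)), conservative)


def test_aggregate_ige(fit_full: VarCompFit, fit_noige: VarCompFit) -> LLRTest:
    """2-df LLR test of the aggregate IGE contribution (s2_AS and s_ADS
    both removed under the null). Conservative: the null lies on the
    boundary of the parameter space."""
    return _llr(fit_full, fit_noige, df=2, conservative=True)


def test_rho(
    fit_full: VarCompFit, fit_constrained: VarCompFit, null_value: float
) -> LLRTest:
    """1-df LLR test of rho against 0 or +/-1.

    ``fit_constrained`` must be the refit with genetic="rho0" (null 0) or
    "rho1" (null |rho| = 1; the better-likelihood sign is profiled). The
    |rho| = 1 test is conservative. Raises if rho is undefined (a genetic
    variance at zero) in the unconstrained fit.
    """
    if np.isnan(fit_full.rho):
        raise ValueError(
            "rho is undefined (a genetic variance is zero); no test performed"
        )
    conservative = abs(null_value) == 1
    return _llr(fit_full, fit_constrained, df=1, conservative=conservative)


@dataclass
class PhenotypeAnalysis:
    fit: VarCompFit
    fit_noige: VarCompFit
    p_ige: float
    fit_rho0: VarCompFit | None = None
    fit_rho1: VarCompFit | None = None
    p_rho_vs_0: float | None = None
    p_rho_vs_1: float | None = None


def analyze_phenotype(
    y,
    X,
    A,
    cages: CageStructure,
    marginal_threshold: float = 0.05,
    test_rho_flag: bool | None = None,
    **fit_kw,
) -> PhenotypeAnalysis:
    """Full per-phenotype aggregate analysis.

    Fits the social model, the no-IGE null (2-df aggregate IGE test) and,
    when both aggregate contributions pass ``marginal_threshold`` (or
    ``test_rho_flag`` forces it), the rho = 0 and |rho| = 1 constrained
    models for the correlation tests.
    """
    comps = fit_kw.pop("comps", None)
    if comps is None:
        collapse = fit_kw.get("collapse_env")
        collapse = cages.uniform_size is not None if collapse is None else collapse
        comps = component_matrices(A, cages, collapsed=collapse)
    fit = fit_varcomp(y, X, A, cages, comps=comps, **fit_kw)
    fit0 = fit_varcomp(y, X, A, cages, genetic="noige", comps=comps, **fit_kw)
    p_ige = test_aggregate_ige(fit, fit0).p_value
    out = PhenotypeAnalysis(fit=fit, fit_noige=fit0, p_ige=p_ige)
    do_rho = (
        test_rho_flag
        if test_rho_flag is not None
        else (
            fit.prop_DGE > marginal_threshold
            and fit.prop_IGE > marginal_threshold
            and not np.isnan(fit.rho)
        )
    )
    if do_rho:
        out.fit_rho0 = fit_varcomp(
            y, X, A, cages, genetic="rho0", comps=comps, **fit_kw
        )
        out.fit_rho1 = fit_varcomp(
            y, X, A, cages, genetic="rho1", comps=comps, **fit_kw
        )
        out.p_rho_vs_0 = test_rho(fit, out.fit_rho0, 0.0).p_value
        out.p_rho_vs_1 = test_rho(fit, out.fit_rho1, 1.0).p_value
    return out
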