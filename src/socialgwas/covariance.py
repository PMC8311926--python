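"""Phenotypic covariance of the social mixed model.

The model for the phenotype of focal individual f is

    y_f = X_f b + a_D,f + e_D,f + Z_f a_S + Z_f e_S + W_f c

with direct genetic effects a_D ~ N(0, s2_AD * A), indirect (social)
genetic effects a_S ~ N(0, s2_AS * A) correlated with a_D through
cov(a_D, a_S) = s_ADS * A, direct/indirect environmental effects
(e_D, e_S) iid across individuals with a 2x2 covariance, and a cage effect
c ~ N(0, s2_C * I). The implied phenotypic covariance is

    C = s2_AD A + s_ADS (A Z' + Z A') + s2_AS Z A Z'
      + s2_ED I + s_EDS (Z + Z') + s2_ES Z Z' + s2_C W W'.

When every cage has the same size the three non-genetic components
(e_D, e_S, c) are not separately identifiable and the environmental part
collapses to two parameters: variance s2_E on the diagonal and covariance
rho_E * s2_E between cage mates (zero across cages). The mapping from the
full form is s2_E = s2_ED + (s-1) s2_ES + s2_C and
rho_E s2_E = 2 s_EDS + (s-2) s2_ES + s2_C for cage size s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cages import CageStructure

__all__ = [
    "SocialCovarianceParams",
    "sample_var",
    "component_matrices",
    "build_covariance",
    "chol_psd",
]


def chol_psd(C: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor, tolerating a PSD (boundary-singular) matrix.

    Variance-component fits may legitimately end on the boundary where C
    has a zero eigenvalue (e.g. a zero cage-mean environmental variance);
    a minimal escalating diagonal jitter then regularizes the factor.
    """
    scale = max(float(np.abs(np.diag(C)).mean()), 1e-30)
    for jitter in (0.0, 1e-12, 1e-10, 1e-8, 1e-6):
        try:
            return np.linalg.cholesky(
                C + jitter * scale * np.eye(C.shape[0]) if jitter else C
            )
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError(
        "covariance is not PSD even after diagonal jitter"
    )

FULL_COMPONENTS = ("A", "AZZA", "ZAZ", "I", "ZZT_sym", "ZZt", "WWt")
COLLAPSED_COMPONENTS = ("A", "AZZA", "ZAZ", "I", "WWt")


@dataclass
class SocialCovarianceParams:
    """Variance/covariance parameters of the social model.

    Either the full environmental form (sigma2_ED, sigma_EDS, sigma2_ES,
    sigma2_C) or the collapsed form (sigma2_E, rho_E) is populated,
    according to ``collapsed``.
    """

    sigma2_AD: float
    sigma_ADS: float
    sigma2_AS: float
    sigma2_ED: float | None = None
    sigma_EDS: float | None = None
    sigma2_ES: float | None = None
    sigma2_C: float | None = None
    sigma2_E: float | None = None
    rho_E: float | None = None
    collapsed: bool = False

    def validate(self):
        if self.sigma2_AD < -1e-12 or self.sigma2_AS < -1e-12:
            raise ValueError("genetic variances must be non-negative")
        bound = np.sqrt(max(self.sigma2_AD, 0.0) * max(self.sigma2_AS, 0.0))
        if abs(self.sigma_ADS) > bound + 1e-9 * (1.0 + bound):
            raise ValueError("|sigma_ADS| exceeds sqrt(sigma2_AD * sigma2_AS)")
        if self.collapsed:
            if self.sigma2_E is None or self.rho_E is None:
                raise ValueError("collapsed form requires sigma2_E and rho_E")
            if self.sigma2_E < -1e-12:
                raise ValueError("sigma2_E must be non-negative")
            if not -1.0 - 1e-9 <= self.rho_E <= 1.0 + 1e-9:
                raise ValueError("rho_E must lie in [-1, 1]")
        else:
            for name in ("sigma2_ED", "sigma2_ES", "sigma2_C"):
                v = getattr(self, name)
                if v is None:
                    raise ValueError(f"full form requires {name}")
                if v < -1e-12:
                    raise ValueError(f"{name} must be non-negative")
            if self.sigma_EDS is None:
                raise ValueError("full form requires sigma_EDS")

    @property
    def rho(self) -> float:
        """DGE-IGE correlation; nan when either genetic variance vanishes."""
        denom = self.sigma2_AD * self.sigma2_AS
        if denom < 1e-20:
            return float("nan")
        return self.sigma_ADS / np.sqrt(denom)

    def collapse(self, cage_size: int) -> "SocialCovarianceParams":
        """Map the full environmental form to the collapsed (s2_E, rho_E) form."""
        if self.collapsed:
            return self
        s = cage_size
        s2_E = self.sigma2_ED + (s - 1) * self.sigma2_ES + self.sigma2_C
        cov = 2.0 * self.sigma_EDS + (s - 2) * self.sigma2_ES + self.sigma2_C
        return SocialCovarianceParams(
            sigma2_AD=self.sigma2_AD,
            sigma_ADS=self.sigma_ADS,
            sigma2_AS=self.sigma2_AS,
            sigma2_E=s2_E,
            rho_E=cov / s2_E if s2_E > 0 else 0.0,
            collapsed=True,
        )

    def coefficients(self) -> dict:
        """Map component name -> multiplier, matching component_matrices()."""
        g = {"A": self.sigma2_AD, "AZZA": self.sigma_ADS, "ZAZ": self.sigma2_AS}
        if self.collapsed:
            within = self.rho_E * self.sigma2_E
            return g | {"I": self.sigma2_E - within, "WWt": within}
        return g | {
            "I": self.sigma2_ED,
            "ZZT_sym": self.sigma_EDS,
            "ZZt": self.sigma2_ES,
            "WWt": self.sigma2_C,
        }


def sample_var(M: np.ndarray) -> float:
    """Sample variance of a covariance matrix: Tr(P M P) / (n - 1), P = I - 11'/n.

    Equals (Tr(M) - grand_sum(M)/n) / (n - 1); the average variance of the
    mean-centered variables whose covariance is M.
    """
    M = np.asarray(M, dtype=float)
    n = M.shape[0]
    if n < 2:
        return 0.0
    return (np.trace(M) - M.sum() / n) / (n - 1)


def component_matrices(
    A: np.ndarray, cages: CageStructure, collapsed: bool = False
) -> dict:
    """Precompute the component matrices whose weighted sum is C.

    Returns a name -> (n, n) matrix dict. Keys match
    SocialCovarianceParams.coefficients().
    """
    Z, W = cages.Z, cages.W
    n = A.shape[0]
    AZ = A @ Z.T
    comps = {
        "A": A,
        "AZZA": AZ + AZ.T,
        "ZAZ": Z @ A @ Z.T,
        "I": np.eye(n),
        "WWt": W @ W.T,
    }
    if not collapsed:
        comps["ZZT_sym"] = Z + Z.T
        comps["ZZt"] = Z @ Z.T
    return comps


def build_covariance(
    params: SocialCovarianceParams,
    A: np.ndarray,
    cages: CageStructure,
    comps: dict | None = None,
    check_psd: bool = True,
    tol: float = 1e-8,
) -> np.ndarray:
    """Assemble the phenotypic covariance C for given parameters.

    Raises ValueError (carrying the most negative eigenvalue) if C is not
    positive semi-definite beyond ``tol``.
    """
    params.validate()
    if params.collapsed and cages.uniform_size is None:
        raise ValueError("collapsed environmental form requires equal cage sizes")
    if comps is None:
        comps = component_matrices(A, cages, collapsed=params.collapsed)
    coef = params.coefficients()
    n = A.shape[0]
    C = np.zeros((n, n))
    for name, theta in coef.items():
        if theta != 0.0:
            C += theta * comps[name]
    C = 0.5 * (C + C.T)
    if check_psd:
        wmin = float(np.linalg.eigvalsh(C)[0])
        scale = max(1.0, float(np.abs(np.diag(C)).max()))
        if wmin < -tol * scale:
            raise ValueError(
                f"covariance is not PSD: most negative eigenvalue {wmin:.3e}"
            )
    return C
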