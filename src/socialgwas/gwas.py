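"""igeGWAS and dgeGWAS: per-variant fixed-effect tests at fixed covariance.

For each variant the direct genotype G (focal individual's dosage) and the
social genotype Z G (sum of cage mates' dosages) enter as fixed effects on
top of the social mixed model. The covariance C is estimated once per
phenotype, in the model with no local effect, and held fixed across
variants; the per-variant models are then generalized least squares after
Cholesky whitening, with a global scale on C profiled so the
likelihood-ratio statistic is n log(RSS_null / RSS_alt).

igeGWAS tests b_S with G b_D included in BOTH null and alternative
("conditioning"); dgeGWAS tests b_D conditioning on Z G b_S. Conditioning
removes the spurious signal that otherwise arises because every individual
acts as both focal individual and social partner, which correlates G with
Z G within cages (Z G = cage total - G for complete cages).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular

from .cages import CageStructure
from .covariance import chol_psd
from .genotypes import GenotypeSet
from .varcomp import VarCompFit, fit_varcomp

__all__ = ["AssociationTable", "social_genotype", "scan", "llr_fixed_cov"]

_LN10 = np.log(10.0)


@dataclass
class AssociationTable:
    """One scan's per-variant results.

    ``df`` columns: chrom, pos, ref, alt, maf, beta_D, beta_S,
    neg_log10_p, n, flag. permutation_id 0 marks the observed scan.
    """

    df: pd.DataFrame
    phenotype: str = ""
    mode: str = "ige"
    permutation_id: int = 0
    condition: bool = True
    social_coding: str = "sum"

    def to_tsv(self, path):
        with open(path, "w") as fh:
            fh.write(
                f"# phenotype={self.phenotype} mode={self.mode} "
                f"permutation_id={self.permutation_id} "
                f"condition={self.condition} social_coding={self.social_coding}\n"
            )
            self.df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "AssociationTable":
        meta = {}
        with open(path) as fh:
            header = fh.readline()
            if header.startswith("#"):
                meta = dict(kv.split("=", 1) for kv in header[1:].split())
                df = pd.read_csv(fh, sep="\t")
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t")
        return cls(
            df,
            phenotype=meta.get("phenotype", ""),
            mode=meta.get("mode", "ige"),
            permutation_id=int(meta.get("permutation_id", 0)),
            condition=meta.get("condition", "True") == "True",
            social_coding=meta.get("social_coding", "sum"),
        )


def social_genotype(
    G: np.ndarray, cages: CageStructure, coding: str = "sum"
) -> np.ndarray:
    """Social genotype(s): per focal individual, the sum of its cage
    mates' dosages (coding="sum", the reference definition) or their
    average (coding="average", which rescales effect estimates by the
    number of cage mates but leaves test p-values unchanged).

    G may be a vector (one variant) or an (n, p) matrix.
    """
    ZG = cages.Z @ G
    if coding == "average":
        n_mates = cages.Z.sum(axis=1)
        ZG = ZG / (n_mates[:, None] if ZG.ndim == 2 else n_mates)
    elif coding != "sum":
        raise ValueError(f"unknown social coding {coding!r}")
    return ZG


def _resid_against(Q: np.ndarray, M: np.ndarray) -> np.ndarray:
    return M - Q @ (Q.T @ M)


def scan(
    y,
    X,
    A,
    cages: CageStructure,
    genotypes: GenotypeSet,
    mode: str = "ige",
    condition: bool = True,
    fit: VarCompFit | None = None,
    C: np.ndarray | None = None,
    maf_min: float = 0.01,
    social_coding: str = "sum",
    permutation: np.ndarray | None = None,
    focal_idx: np.ndarray | None = None,
    phenotype: str = "",
    permutation_id: int = 0,
    **fit_kw,
) -> AssociationTable:
    """Genome scan for local IGE (mode="ige") or local DGE (mode="dge").

    The covariance is taken from ``fit`` (a no-locus VarCompFit) or ``C``;
    if neither is given the variance-component model is fitted here.
    ``permutation`` applies one row permutation to the whole tested
    genotype matrix (social matrix for ige, direct for dge) while the
    conditioning matrix, y, X and C stay unpermuted — the permutation
    scheme behind the per-phenotype FDR. ``focal_idx`` restricts the
    focal (phenotyped) rows to a subset of the genotyped individuals;
    social genotypes are computed over everyone first, so unphenotyped
    individuals still contribute as partners. Variants with MAF below
    ``maf_min`` are dropped; a tested vector with zero variance yields a
    flagged row with p = 1.
    """
    if mode not in ("ige", "dge"):
        raise ValueError("mode must be 'ige' or 'dge'")
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    n = len(y)

    if C is None:
        if fit is None:
            fit = fit_varcomp(y, X, A, cages, **fit_kw)
        C = fit.C

    keep = np.flatnonzero(genotypes.maf >= maf_min)
    gt = genotypes.subset_variants(keep)
    Gmat = gt.dosages
    ZGmat = social_genotype(Gmat, cages, coding=social_coding)
    if focal_idx is not None:
        focal_idx = np.asarray(focal_idx)
        Gmat = Gmat[focal_idx]
        ZGmat = ZGmat[focal_idx]
        if len(y) != len(focal_idx):
            raise ValueError("y length must match focal_idx")

    tested = ZGmat if mode == "ige" else Gmat
    cond = Gmat if mode == "ige" else ZGmat
    if permutation is not None:
        tested = tested[np.asarray(permutation), :]

    L = chol_psd(C)
    yw = solve_triangular(L, y, lower=True)
    Xw = solve_triangular(L, X, lower=True)
    Tw = solve_triangular(L, tested, lower=True)
    Q, _ = np.linalg.qr(Xw)
    u = yw - Q @ (Q.T @ yw)
    B = _resid_against(Q, Tw)
    uu = float(u @ u)

    ub = u @ B
    bb = (B * B).sum(axis=0)
    raw_var = tested.var(axis=0)
    zero_var = raw_var < 1e-12

    p_var = Gmat.shape[1]
    beta_tested = np.full(p_var, np.nan)
    beta_cond = np.full(p_var, np.nan)
    llr = np.zeros(p_var)
    flag = np.array(["ok"] * p_var, dtype=object)

    if condition:
        Cw = solve_triangular(L, cond, lower=True)
        Amat = _resid_against(Q, Cw)
        ua = u @ Amat
        aa = (Amat * Amat).sum(axis=0)
        ab = (Amat * B).sum(axis=0)
        det = aa * bb - ab * ab
        collinear = det <= 1e-12 * np.maximum(aa * bb, 1e-300)
        bad = zero_var | collinear
        ok = ~bad
        aa_ok = np.where(aa > 0, aa, 1.0)
        rss0 = uu - np.where(aa > 0, ua * ua / aa_ok, 0.0)
        det_ok = np.where(bad, 1.0, det)
        quad = (bb * ua * ua - 2.0 * ab * ua * ub + aa * ub * ub) / det_ok
        rss1 = uu - quad
        beta_tested[ok] = ((aa * ub - ab * ua) / det_ok)[ok]
        beta_cond[ok] = ((bb * ua - ab * ub) / det_ok)[ok]
        llr[ok] = n * np.log(rss0[ok] / rss1[ok])
        flag[zero_var] = "zero_variance"
        flag[collinear & ~zero_var] = "collinear"
    else:
        ok = ~zero_var
        bb_ok = np.where(ok, bb, 1.0)
        rss1 = uu - ub * ub / bb_ok
        beta_tested[ok] = (ub / bb_ok)[ok]
        llr[ok] = n * np.log(uu / rss1[ok])
        flag[zero_var] = "zero_variance"

    llr = np.maximum(llr, 0.0)
    neg_log10_p = -stats.chi2.logsf(llr, 1) / _LN10
    neg_log10_p[flag != "ok"] = 0.0

    if mode == "ige":
        beta_S, beta_D = beta_tested, (beta_cond if condition else np.full(p_var, np.nan))
    else:
        beta_D, beta_S = beta_tested, (beta_cond if condition else np.full(p_var, np.nan))

    df = pd.DataFrame(
        {
            "chrom": gt.variant_map["chrom"].to_numpy(),
            "pos": gt.variant_map["pos"].to_numpy(),
            "ref": gt.variant_map.get("ref", pd.Series(["N"] * p_var)).to_numpy(),
            "alt": gt.variant_map.get("alt", pd.Series(["N"] * p_var)).to_numpy(),
            "maf": gt.maf,
            "beta_D": beta_D,
            "beta_S": beta_S,
            "neg_log10_p": neg_log10_p,
            "n": n,
            "flag": flag,
        }
    )
    return AssociationTable(
        df,
        phenotype=phenotype,
        mode=mode,
        permutation_id=permutation_id,
        condition=condition,
        social_coding=social_coding,
    )


def llr_fixed_cov(y, X_null, X_alt, C):
    """GLS likelihood-ratio test of one added column at fixed covariance.

    X_null's columns must be a subset of X_alt's, which adds exactly one
    column. The Gaussian likelihood is maximized over fixed effects and a
    global scale on C (profiled), giving LLR = n log(RSS_null / RSS_alt)
    and a chi-square(1) p-value. Returns (beta_added, neg_log10_p).
    """
    y = np.asarray(y, dtype=float)
    X_null = np.atleast_2d(np.asarray(X_null, dtype=float))
    X_alt = np.atleast_2d(np.asarray(X_alt, dtype=float))
    if X_null.shape[0] != len(y):
        X_null = X_null.T
    if X_alt.shape[0] != len(y):
        X_alt = X_alt.T
    if X_alt.shape[1] != X_null.shape[1] + 1:
        raise ValueError("X_alt must add exactly one column to X_null")
    n = len(y)

    L = np.linalg.cholesky(np.asarray(C, dtype=float))
    yw = solve_triangular(L, y, lower=True)
    Xnw = solve_triangular(L, X_null, lower=True)
    Xaw = solve_triangular(L, X_alt, lower=True)

    for name, M in (("null", Xnw), ("alt", Xaw)):
        rank = np.linalg.matrix_rank(M)
        if rank < M.shape[1]:
            # identify a collinear column by leave-one-out rank
            for j in range(M.shape[1]):
                sub = np.delete(M, j, axis=1)
                if np.linalg.matrix_rank(sub) == rank:
                    raise ValueError(
                        f"rank-deficient {name} design: column {j} is collinear"
                    )
            raise ValueError(f"rank-deficient {name} design")

    beta0, rss0 = _ols_rss(Xnw, yw)
    beta1, rss1 = _ols_rss(Xaw, yw)
    llr = max(n * np.log(rss0 / rss1), 0.0)
    nlp = float(-stats.chi2.logsf(llr, 1) / _LN10)
    return float(beta1[-1]), nlp


def _ols_rss(X, y):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return beta, float(r @ r)
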