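"""Permutation-based per-phenotype FDR and locus clumping.

Significance in the genome scans is assessed against K "permuted GWAS":
permutation r applies one row permutation to the whole tested-genotype
matrix (the social matrix for igeGWAS, the direct matrix for dgeGWAS),
leaving the phenotype, covariates, GRM, covariance and the conditioning
genotype matrix untouched. This preserves the LD between tested variants
while breaking their relationship to the phenotype. For an observed lead
p-value x,

    FDR(x) = #permuted loci with P <= x / (K * #observed loci with P <= x)

made monotone by a running minimum over decreasing x. Loci are formed by
greedy clumping: the best remaining variant leads a locus, claims a
window, and removes everything inside it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gwas import AssociationTable, scan

__all__ = ["LocusCall", "PermutationScanSet", "clump", "permute_scan", "estimate_fdr"]


@dataclass
class LocusCall:
    chrom: str
    pos: int
    neg_log10_p: float
    window_start: int
    window_end: int
    fdr: float | None = None
    significant: bool = False


@dataclass
class PermutationScanSet:
    observed: AssociationTable
    permuted: list
    seed: int
    K: int


def clump(table: AssociationTable | pd.DataFrame, window_bp: int = 1_500_000):
    """Greedy grouping of variants into loci.

    Repeatedly take the remaining variant with the largest neg_log10_p
    (ties broken by chrom then pos, ascending) as a lead, assign it the
    window lead +/- window_bp/2, drop every variant inside, and iterate.
    """
    df = table.df if isinstance(table, AssociationTable) else table
    if len(df) == 0:
        return []
    chrom = df["chrom"].astype(str).to_numpy()
    pos = df["pos"].to_numpy()
    nlp = df["neg_log10_p"].to_numpy(dtype=float)
    order = np.lexsort((pos, chrom, -nlp))
    half = window_bp / 2.0
    removed = np.zeros(len(df), dtype=bool)
    loci = []
    for i in order:
        if removed[i]:
            continue
        inside = (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= half)
        removed |= inside
        loci.append(
            LocusCall(
                chrom=chrom[i],
                pos=int(pos[i]),
                neg_log10_p=float(nlp[i]),
                window_start=int(np.ceil(pos[i] - half)),
                window_end=int(np.floor(pos[i] + half)),
            )
        )
    return loci


def permute_scan(
    y,
    X,
    A,
    cages,
    genotypes,
    mode: str = "ige",
    K: int = 100,
    seed: int = 0,
    **scan_kw,
) -> PermutationScanSet:
    """Observed scan plus K seeded permuted scans sharing one covariance.

    The covariance is estimated once (or taken from ``fit``/``C`` in
    scan_kw) and reused by every permuted scan, exactly as in the observed
    analysis.
    """
    if "C" not in scan_kw and "fit" not in scan_kw:
        from .varcomp import fit_varcomp

        fit_only_kw = {
            k: scan_kw.pop(k)
            for k in ("collapse_env", "n_restarts", "comps")
            if k in scan_kw
        }
        scan_kw["fit"] = fit_varcomp(y, X, A, cages, **fit_only_kw)
    observed = scan(y, X, A, cages, genotypes, mode=mode, **scan_kw)
    rng = np.random.default_rng(seed)
    n = len(np.asarray(y))
    permuted = []
    for r in range(1, K + 1):
        perm = rng.permutation(n)
        permuted.append(
            scan(
                y,
                X,
                A,
                cages,
                genotypes,
                mode=mode,
                permutation=perm,
                permutation_id=r,
                **scan_kw,
            )
        )
    return PermutationScanSet(observed, permuted, seed, K)


def estimate_fdr(
    scans: PermutationScanSet,
    clump_window_bp: int = 1_500_000,
    fdr_threshold: float = 0.10,
    count_unit: str = "locus",
):
    """Per-phenotype FDR at each observed locus lead.

    count_unit "locus" counts clumped loci below each threshold on both
    sides of the ratio; "variant" counts raw variants instead.
    Returns the observed LocusCall list (sorted by decreasing
    neg_log10_p) with ``fdr`` filled in and ``significant`` set where
    fdr < fdr_threshold.
    """
    if count_unit not in ("locus", "variant"):
        raise ValueError("count_unit must be 'locus' or 'variant'")
    obs_loci = clump(scans.observed, clump_window_bp)
    if not obs_loci:
        return []
    obs_loci.sort(key=lambda L: -L.neg_log10_p)
    obs_nlp = np.array([L.neg_log10_p for L in obs_loci])

    if count_unit == "locus":
        perm_nlp = np.concatenate(
            [
                np.array([L.neg_log10_p for L in clump(t, clump_window_bp)])
                if len(t.df)
                else np.empty(0)
                for t in scans.permuted
            ]
        )
        obs_count_nlp = obs_nlp
    else:
        perm_nlp = np.concatenate(
            [t.df["neg_log10_p"].to_numpy(dtype=float) for t in scans.permuted]
        )
        obs_count_nlp = scans.observed.df["neg_log10_p"].to_numpy(dtype=float)

    perm_nlp = np.sort(perm_nlp)
    obs_count_sorted = np.sort(obs_count_nlp)
    K = scans.K
    fdr_raw = np.empty(len(obs_loci))
    for i, x in enumerate(obs_nlp):
        n_perm = len(perm_nlp) - np.searchsorted(perm_nlp, x, side="left")
        n_obs = len(obs_count_sorted) - np.searchsorted(
            obs_count_sorted, x, side="left"
        )
        fdr_raw[i] = n_perm / (K * max(n_obs, 1))
    # running minimum from the weakest lead upward: FDR(x) is then
    # monotone non-increasing in neg_log10_p
    fdr_mono = np.minimum.accumulate(fdr_raw[::-1])[::-1]
    for L, q in zip(obs_loci, fdr_mono):
        L.fdr = float(min(q, 1.0))
        L.significant = bool(L.fdr < fdr_threshold)
    return obs_loci


def loci_to_frame(loci) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": L.chrom,
                "pos": L.pos,
                "neg_log10_p": L.neg_log10_p,
                "window_start": L.window_start,
                "window_end": L.window_end,
                "fdr": L.fdr,
                "significant": L.significant,
            }
            for L in loci
        ]
    )
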