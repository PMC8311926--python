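"""Genetic relatedness matrix (GRM) and sibling-outlier screening.

The GRM is the covariance kernel of the polygenic direct and indirect
genetic effects: A = (1/p) Xs Xs' where Xs is the dosage matrix with each
variant standardized to mean 0, variance 1. The 1/p scaling puts the
diagonal mean near 1 so variance components are comparable across panels.

Putative siblings confound DGE/IGE with litter and parental effects; pairs
with anomalously high relatedness flag both members' cages for exclusion.
"""

from __future__ import annotations

import numpy as np

from .cages import CageStructure
from .genotypes import GenotypeSet

__all__ = ["compute_grm", "standardize_dosages", "flag_related_cages"]


def standardize_dosages(dosages: np.ndarray) -> np.ndarray:
    """Column-standardize a dosage matrix (mean 0, variance 1 per variant).

    Raises on zero-variance (monomorphic) variants: filter upstream.
    """
    X = np.asarray(dosages, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    bad = np.flatnonzero(sd < 1e-12)
    if bad.size:
        raise ValueError(
            f"{bad.size} monomorphic variant(s) (first at column {bad[0]}); "
            "apply a MAF filter before computing the GRM"
        )
    return (X - mu) / sd


def compute_grm(genotypes: GenotypeSet | np.ndarray) -> np.ndarray:
    """GRM from (assumed LD-pruned) dosages: standardized cross-product / p."""
    dosages = (
        genotypes.dosages if isinstance(genotypes, GenotypeSet) else genotypes
    )
    if dosages.shape[1] < 2:
        raise ValueError("need at least 2 polymorphic variants")
    Xs = standardize_dosages(dosages)
    A = Xs @ Xs.T / Xs.shape[1]
    return 0.5 * (A + A.T)


def grm_factor(genotypes: GenotypeSet | np.ndarray) -> np.ndarray:
    """Matrix L with L L' = GRM (useful for exact sampling from N(0, A))."""
    dosages = (
        genotypes.dosages if isinstance(genotypes, GenotypeSet) else genotypes
    )
    Xs = standardize_dosages(dosages)
    return Xs / np.sqrt(Xs.shape[1])


def flag_related_cages(
    A: np.ndarray, cages: CageStructure, threshold: float = 0.3
) -> set:
    """Cages containing a member of any pair with A_ij above ``threshold``.

    Returns the set of cage labels to exclude (union over flagged pairs;
    both individuals' cages are flagged). The default 0.3 on the 1/p-scaled
    GRM is a conservative proxy for visual outlier screening.
    """
    A = np.asarray(A)
    n = A.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    hits = A[iu, ju] > threshold
    flagged = set()
    for i, j in zip(iu[hits], ju[hits]):
        flagged.add(cages.cage_labels[i])
        flagged.add(cages.cage_labels[j])
    return flagged
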