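"""Post-GWAS: local dense re-scan, candidate genes, variance explained.

A significant locus is re-scanned with the full (unpruned) variant set in
a 1.5-Mb window centered on the lead variant — in the source population
that window corresponds to the 95% confidence interval of an association.
Candidate causal genes are the genes overlapping the association
"plateau" (or lying within a configurable proximity of it) whose symbol
does not start with one of the prefixes Gm/Rik/Mir/Fam/Tmem, focusing the
candidate list on characterized genes. The variance explained by a
significant association is computed from a refit of the social model with
fixed effects for the direct and social genotypes of all lead variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cages import CageStructure
from .covariance import sample_var
from .fdr import LocusCall
from .genotypes import GenotypeSet
from .gwas import AssociationTable, scan, social_genotype
from .varcomp import fit_varcomp

__all__ = [
    "EXCLUDED_PREFIXES",
    "FineMapReport",
    "local_rescan",
    "find_plateau",
    "call_candidate_genes",
    "variance_explained",
]

EXCLUDED_PREFIXES = ("Gm", "Rik", "Mir", "Fam", "Tmem")
WINDOW_BP = 1_500_000
PLATEAU_DROP = 1.5  # -log10 p drop from the lead that delimits the plateau


@dataclass
class FineMapReport:
    locus: LocusCall
    dense_scan: AssociationTable
    plateau: tuple  # (start, end), 1-based inclusive
    candidate_genes: list = field(default_factory=list)


def local_rescan(
    locus: LocusCall,
    dense_genotypes: GenotypeSet,
    y,
    X,
    A,
    cages: CageStructure,
    window_bp: int = WINDOW_BP,
    **scan_kw,
) -> AssociationTable:
    """Re-run the scan on all dense-set variants in the locus window.

    Same engine, covariance and conditioning as the genome-wide scan;
    only the variant set changes (unpruned instead of LD-pruned).
    """
    half = window_bp // 2
    window = dense_genotypes.in_window(
        locus.chrom, locus.pos - half, locus.pos + half
    )
    if window.p == 0:
        return AssociationTable(
            pd.DataFrame(
                columns=[
                    "chrom", "pos", "ref", "alt", "maf",
                    "beta_D", "beta_S", "neg_log10_p", "n", "flag",
                ]
            ),
            mode=scan_kw.get("mode", "ige"),
        )
    return scan(y, X, A, cages, window, **scan_kw)


def find_plateau(
    dense_scan: AssociationTable, drop: float = PLATEAU_DROP
) -> tuple:
    """Plateau of a locus: the contiguous run of variants around the lead
    whose neg_log10_p stays within ``drop`` of the lead's, extended
    greedily in both directions. Returns (start_pos, end_pos)."""
    df = dense_scan.df.sort_values("pos").reset_index(drop=True)
    if len(df) == 0:
        raise ValueError("empty dense scan: no plateau")
    nlp = df["neg_log10_p"].to_numpy(dtype=float)
    pos = df["pos"].to_numpy()
    lead = int(np.argmax(nlp))
    cutoff = nlp[lead] - drop
    lo = lead
    while lo > 0 and nlp[lo - 1] >= cutoff:
        lo -= 1
    hi = lead
    while hi < len(df) - 1 and nlp[hi + 1] >= cutoff:
        hi += 1
    return int(pos[lo]), int(pos[hi])


def call_candidate_genes(
    plateau: tuple,
    chrom,
    annotation: pd.DataFrame,
    proximity_bp: int = 100_000,
    excluded_prefixes=EXCLUDED_PREFIXES,
) -> list:
    """Genes overlapping [plateau.start - proximity, plateau.end + proximity]
    on the locus chromosome, with excluded-prefix symbols removed.

    ``annotation`` columns: chrom, start, end, symbol (1-based inclusive).
    """
    start = plateau[0] - proximity_bp
    end = plateau[1] + proximity_bp
    ann = annotation[annotation["chrom"].astype(str) == str(chrom)]
    overlap = ann[(ann["end"] >= start) & (ann["start"] <= end)]
    return [
        s
        for s in overlap["symbol"]
        if not any(str(s).startswith(pfx) for pfx in excluded_prefixes)
    ]


def fine_map(
    locus: LocusCall,
    dense_genotypes: GenotypeSet,
    annotation: pd.DataFrame,
    y,
    X,
    A,
    cages: CageStructure,
    window_bp: int = WINDOW_BP,
    proximity_bp: int = 100_000,
    plateau_drop: float = PLATEAU_DROP,
    **scan_kw,
) -> FineMapReport:
    dense = local_rescan(
        locus, dense_genotypes, y, X, A, cages, window_bp=window_bp, **scan_kw
    )
    plateau = find_plateau(dense, drop=plateau_drop)
    genes = call_candidate_genes(plateau, locus.chrom, annotation, proximity_bp)
    return FineMapReport(locus, dense, plateau, genes)


def variance_explained(
    y,
    X,
    A,
    cages: CageStructure,
    lead_variants: GenotypeSet,
    effect_mode: str = "ige",
    social_coding: str = "sum",
    focal_idx: np.ndarray | None = None,
    **fit_kw,
):
    """Proportion of phenotypic variance explained by each lead variant.

    The social model is refitted with fixed effects for BOTH the direct
    and social genotypes of every lead variant. For lead j the reported
    proportion is (ige mode)

        var(ZG_j b_S,j) / [ sum_c var(X_c b_c) + sum_j var(G_j b_D,j)
                            + sum_j var(ZG_j b_S,j) + sampleVar(C) ]

    with var(.) the sample variance of the fitted effect vector; dge mode
    uses var(G_j b_D,j) in the numerator. Raises on collinear lead
    genotype columns.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    G = lead_variants.dosages
    ZG = social_genotype(G, cages, coding=social_coding)
    if focal_idx is not None:
        focal_idx = np.asarray(focal_idx)
        G = G[focal_idx]
        ZG = ZG[focal_idx]
    n_lead = G.shape[1]

    full = np.column_stack([X, G, ZG])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        corr = np.corrcoef(np.column_stack([G, ZG]).T)
        iu, ju = np.triu_indices(2 * n_lead, k=1)
        worst = np.argmax(np.abs(corr[iu, ju]))
        raise ValueError(
            "collinear lead-variant fixed effects "
            f"(columns {iu[worst]} and {ju[worst]} of [G | ZG])"
        )

    fit = fit_varcomp(y, full, A, cages, **fit_kw)
    k = X.shape[1]
    b_cov = fit.beta[:k]
    b_D = fit.beta[k : k + n_lead]
    b_S = fit.beta[k + n_lead :]

    var_cov = sum(float(np.var(X[:, c] * b_cov[c], ddof=1)) for c in range(k))
    var_D = np.array(
        [float(np.var(G[:, j] * b_D[j], ddof=1)) for j in range(n_lead)]
    )
    var_S = np.array(
        [float(np.var(ZG[:, j] * b_S[j], ddof=1)) for j in range(n_lead)]
    )
    denom = var_cov + var_D.sum() + var_S.sum() + sample_var(fit.C)
    numer = var_S if effect_mode == "ige" else var_D
    return numer / denom
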