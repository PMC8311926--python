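"""Genotype container for dosage matrices.

Dosages are reference-allele counts in [0, 2] (possibly fractional, e.g.
imputed from low-coverage sequencing). Variants are assumed LD-pruned for
genome-wide work; the dense (unpruned) set is only used for local
fine-mapping re-scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeSet", "compute_maf"]


def compute_maf(dosages: np.ndarray) -> np.ndarray:
    """Minor-allele frequency per variant from a (n, p) dosage matrix.

    Computed as mean dosage / 2, folded to <= 0.5.
    """
    f = np.asarray(dosages, dtype=float).mean(axis=0) / 2.0
    return np.minimum(f, 1.0 - f)


@dataclass
class GenotypeSet:
    """Dosage matrix plus variant map.

    Attributes
    ----------
    dosages : (n, p) float array
        Reference-allele dosages, individuals in rows.
    variant_map : DataFrame with columns chrom, pos, ref, alt (one row per
        variant, aligned with dosage columns; pos is 1-based).
    individual_ids : (n,) array of str
    """

    dosages: np.ndarray
    variant_map: pd.DataFrame
    individual_ids: np.ndarray = field(default=None)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x variants)")
        n, p = self.dosages.shape
        if len(self.variant_map) != p:
            raise ValueError(
                f"variant_map has {len(self.variant_map)} rows for {p} variants"
            )
        if self.individual_ids is None:
            self.individual_ids = np.array([f"id{i:05d}" for i in range(n)])
        else:
            self.individual_ids = np.asarray(self.individual_ids, dtype=object)
            if len(self.individual_ids) != n:
                raise ValueError("individual_ids length mismatch")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def p(self) -> int:
        return self.dosages.shape[1]

    @property
    def maf(self) -> np.ndarray:
        return compute_maf(self.dosages)

    def filter_maf(self, maf_min: float) -> "GenotypeSet":
        """Drop variants with folded MAF below ``maf_min``."""
        keep = self.maf >= maf_min
        return self.subset_variants(np.flatnonzero(keep))

    def subset_variants(self, idx) -> "GenotypeSet":
        idx = np.asarray(idx)
        return GenotypeSet(
            self.dosages[:, idx],
            self.variant_map.iloc[idx].reset_index(drop=True),
            self.individual_ids,
        )

    def subset_individuals(self, idx) -> "GenotypeSet":
        idx = np.asarray(idx)
        return GenotypeSet(
            self.dosages[idx, :],
            self.variant_map.copy(),
            self.individual_ids[idx],
        )

    def in_window(self, chrom, start: int, end: int) -> "GenotypeSet":
        """Variants with position in [start, end] (1-based inclusive) on chrom."""
        vm = self.variant_map
        mask = (vm["chrom"].astype(str) == str(chrom)) & (
            vm["pos"].between(start, end)
        )
        return self.subset_variants(np.flatnonzero(mask.to_numpy()))
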