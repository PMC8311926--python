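"""Cage (social group) structure.

The social design is encoded by two indicator matrices:

* ``Z`` (n x n): Z[i, j] = 1 iff j is a cage mate of i, with Z[i, i] = 0.
  ``Z @ g`` turns a dosage vector into the "social genotype" (sum of cage
  mates' dosages).
* ``W`` (n x c): W[i, k] = 1 iff i lives in cage k. ``W @ W.T`` is the
  same-cage indicator used for the shared-cage random effect.

For complete cages Z = W W' - I.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CageStructure"]


@dataclass
class CageStructure:
    cage_labels: np.ndarray  # (n,) cage label per individual
    individual_ids: np.ndarray = field(default=None)

    def __post_init__(self):
        self.cage_labels = np.asarray(self.cage_labels)
        n = len(self.cage_labels)
        if self.individual_ids is None:
            self.individual_ids = np.array([f"id{i:05d}" for i in range(n)])
        else:
            self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        codes, uniques = pd.factorize(self.cage_labels)
        self._codes = codes
        self.cage_ids = np.asarray(uniques)
        c = len(uniques)
        W = np.zeros((n, c))
        W[np.arange(n), codes] = 1.0
        self.W = W
        self.Z = W @ W.T - np.eye(n)

    @property
    def n(self) -> int:
        return len(self.cage_labels)

    @property
    def n_cages(self) -> int:
        return len(self.cage_ids)

    @property
    def sizes(self) -> np.ndarray:
        return self.W.sum(axis=0).astype(int)

    @property
    def uniform_size(self) -> int | None:
        """Common cage size, or None if cages differ in size."""
        s = self.sizes
        return int(s[0]) if len(s) and (s == s[0]).all() else None

    def members(self, cage_id) -> np.ndarray:
        return self.individual_ids[self.cage_labels == cage_id]

    @classmethod
    def random(cls, n: int, cage_size: int, rng) -> "CageStructure":
        """Random partition of n individuals into cages of ``cage_size``."""
        if n % cage_size:
            raise ValueError(f"n={n} not divisible by cage_size={cage_size}")
        perm = rng.permutation(n)
        labels = np.empty(n, dtype=object)
        for k in range(n // cage_size):
            for i in perm[k * cage_size : (k + 1) * cage_size]:
                labels[i] = f"cage{k:05d}"
        return cls(labels)

    def subset(self, idx) -> "CageStructure":
        idx = np.asarray(idx)
        return CageStructure(self.cage_labels[idx], self.individual_ids[idx])
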