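"""Storey q-values for per-phenotype FDR on aggregate IGE tests."""

from __future__ import annotations

import numpy as np

__all__ = ["estimate_pi0", "qvalues"]


def estimate_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey's smoother estimate of the null proportion pi0.

    pi0(l) = #{p > l} / (m (1 - l)) is fit with a cubic in l and evaluated
    at the largest l. Falls back to pi0 = 1 for short p-value vectors,
    where the smoother is unstable.
    """
    p = np.asarray(p, dtype=float)
    m = len(p)
    if m < 100:
        return 1.0
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_l = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lambdas])
    coef = np.polyfit(lambdas, pi0_l, deg=3)
    pi0 = float(np.polyval(coef, lambdas.max()))
    return min(max(pi0, 1.0 / m), 1.0)


def qvalues(p, pi0: float | None = None) -> np.ndarray:
    """Monotone q-values: q_i = min_{t >= p_i} pi0 * m * t / #{p <= t}."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    if pi0 is None:
        pi0 = estimate_pi0(p)
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    # running minimum from the largest p down enforces monotonicity
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
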