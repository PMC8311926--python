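"""Phenotype normalization and cage-stability filtering.

Phenotypes are Box-Cox transformed before model fitting; a phenotype is
rejected when the maximum-likelihood transformation parameter lies outside
[-2, 2] (it cannot be normalized satisfactorily). Only individuals that
kept exactly the same cage mates at every recorded timepoint, in a cage of
the configured size, enter the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["BoxCoxResult", "boxcox_normalize", "filter_stable_cages"]

LAMBDA_GRID = np.round(np.arange(-2.5, 2.5 + 1e-9, 0.01), 10)
LAMBDA_ACCEPT = (-2.0, 2.0)


@dataclass
class BoxCoxResult:
    normalized: np.ndarray
    lmbda: float
    accepted: bool
    shift: float


def _boxcox_loglik(y: np.ndarray, lmbda: float, X: np.ndarray | None) -> float:
    # Profile log-likelihood of the Box-Cox model, optionally with a linear
    # predictor X (covariates are regressed out before the variance is profiled).
    yt = stats.boxcox(y, lmbda=lmbda)
    if X is not None:
        beta, *_ = np.linalg.lstsq(X, yt, rcond=None)
        resid = yt - X @ beta
    else:
        resid = yt - yt.mean()
    n = len(y)
    rss = float(resid @ resid)
    if rss <= 0:
        return -np.inf
    return -0.5 * n * np.log(rss / n) + (lmbda - 1.0) * np.log(y).sum()


def boxcox_normalize(
    values,
    covariates: pd.DataFrame | np.ndarray | None = None,
    grid: np.ndarray = LAMBDA_GRID,
    shift: str | float = "auto",
) -> BoxCoxResult:
    """Box-Cox transform by profile likelihood on a lambda grid, then z-score.

    Parameters
    ----------
    values : 1-D array of phenotype values (no missing values).
    covariates : optional design whose linear effect is profiled out of the
        Box-Cox likelihood (an intercept is always included).
    shift : "auto" applies value - min + 1 when min <= 0 (recorded in the
        result); a float applies that shift unconditionally; 0 disables
        shifting and non-positive values raise.

    Returns
    -------
    BoxCoxResult with the transformed values standardized to mean 0 and
    variance 1, the ML lambda, and ``accepted`` = (lambda in [-2, 2]).
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 1:
        raise ValueError("values must be a 1-D vector")
    if np.isnan(y).any():
        raise ValueError("missing values must be removed before normalization")
    if len(y) < 30:
        raise ValueError(f"need >= 30 non-missing values, got {len(y)}")

    if shift == "auto":
        applied_shift = float(1.0 - y.min()) if y.min() <= 0 else 0.0
    else:
        applied_shift = float(shift)
    y = y + applied_shift
    if y.min() <= 0:
        raise ValueError(
            f"non-positive values after shift (minimum {y.min():.6g}); "
            "Box-Cox requires strictly positive data"
        )

    X = None
    if covariates is not None:
        Xc = np.asarray(covariates, dtype=float)
        if Xc.ndim == 1:
            Xc = Xc[:, None]
        X = np.column_stack([np.ones(len(y)), Xc])

    lls = np.array([_boxcox_loglik(y, float(l), X) for l in grid])
    lmbda = float(grid[int(np.argmax(lls))])
    accepted = LAMBDA_ACCEPT[0] <= lmbda <= LAMBDA_ACCEPT[1]
    yt = stats.boxcox(y, lmbda=lmbda)
    normalized = (yt - yt.mean()) / yt.std()
    return BoxCoxResult(normalized, lmbda, accepted, applied_shift)


def filter_stable_cages(assignments: pd.DataFrame, cage_size: int = 3) -> set:
    """Individuals whose full cage membership never changed.

    ``assignments`` needs columns individual_id and cage_id, optionally
    timepoint (a single implicit timepoint otherwise). A cage is retained
    iff its member set is identical at every timepoint and has exactly
    ``cage_size`` members; the returned set is the union of members of
    retained cages (so it is closed under cages). Moving one mouse out of a
    cage therefore drops the whole cage: the remaining mice no longer form
    a complete group.
    """
    df = assignments.copy()
    if "timepoint" not in df.columns:
        df["timepoint"] = 0
    timepoints = sorted(df["timepoint"].unique())

    # member set per (timepoint, cage)
    membership = {
        t: {
            cage: frozenset(sub["individual_id"])
            for cage, sub in df[df["timepoint"] == t].groupby("cage_id")
        }
        for t in timepoints
    }

    # an individual's cage at each timepoint it appears
    retained: set = set()
    first = timepoints[0]
    for cage, members in membership[first].items():
        if len(members) != cage_size:
            continue
        stable = all(membership[t].get(cage) == members for t in timepoints[1:])
        # every member must be recorded in this cage at every timepoint at
        # which they appear anywhere (guards against duplicated listings)
        if stable:
            ok = True
            for t in timepoints:
                sub = df[df["timepoint"] == t]
                listed = set(sub.loc[sub["individual_id"].isin(members), "cage_id"])
                if listed and listed != {cage}:
                    ok = False
                    break
            if ok:
                retained |= set(members)
    return retained
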