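"""Applicability-domain performance metrics.

A reaction is a *Y-outlier* when its absolute prediction error exceeds
3x RMSE, a *Y-inlier* otherwise; AD decisions split the same reactions into
X-inliers (inside the domain) and X-outliers.  Crossing the two labellings
gives the TO/TI/FO/FI quadrants from which the metrics derive:

- coverage: fraction of reactions decided X-inliers;
- OIR: RMSE outside the domain minus RMSE inside (0 when a side is empty);
- dR2_AD: R^2 restricted to X-inliers minus R^2 on all reactions;
- OD: balanced accuracy of Y-outlier detection, (TO/(TO+FI) + TI/(TI+FO))/2;
- AUC_AD: probability that a random X-inlier has a smaller absolute error
  than a random X-outlier (ties count one half) - a ranking diagnostic,
  unsuitable as a tuning objective.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "Quadrants",
    "MetricsReport",
    "coverage",
    "oir",
    "delta_r2_ad",
    "od",
    "auc_ad",
    "quadrant_counts",
    "y_outlier_flags",
    "rmse",
    "r_squared",
    "compute_report",
]


@dataclass(frozen=True)
class Quadrants:
    TO: int  # Y-outliers decided X-outliers
    TI: int  # Y-inliers decided X-inliers
    FO: int  # Y-inliers decided X-outliers
    FI: int  # Y-outliers decided X-inliers


def rmse(errors: np.ndarray) -> float:
    errors = np.asarray(errors, dtype=float)
    return float(np.sqrt(np.mean(errors**2))) if errors.size else float("nan")


def r_squared(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        return float("nan")
    return 1.0 - float(np.sum((y_true - y_pred) ** 2)) / ss_tot


def y_outlier_flags(abs_errors: np.ndarray, reference_rmse: float) -> np.ndarray:
    """True for Y-outliers: absolute error strictly greater than 3x RMSE."""
    return np.asarray(abs_errors, dtype=float) > 3.0 * reference_rmse


def coverage(decisions: np.ndarray) -> float:
    decisions = np.asarray(decisions, dtype=bool)
    if decisions.size == 0:
        raise ValueError("no decisions")
    return float(decisions.mean())


def oir(errors: np.ndarray, decisions: np.ndarray) -> float:
    """RMSE outside AD minus RMSE inside AD; 0 when either side is empty."""
    errors = np.asarray(errors, dtype=float)
    decisions = np.asarray(decisions, dtype=bool)
    if decisions.all() or not decisions.any():
        return 0.0
    return rmse(errors[~decisions]) - rmse(errors[decisions])


def delta_r2_ad(y_true: np.ndarray, y_pred: np.ndarray, decisions: np.ndarray) -> float:
    """R^2 on X-inliers minus R^2 on all reactions.

    An empty X-inlier set uses R^2_in = 0 (the all-outlier decider then
    scores -R^2_all); a degenerate inlier set (fewer than two reactions or
    constant truth) returns NaN and is excluded from ranking.
    """
    decisions = np.asarray(decisions, dtype=bool)
    r2_all = r_squared(y_true, y_pred)
    if not decisions.any():
        return 0.0 - r2_all
    y_in = np.asarray(y_true, dtype=float)[decisions]
    p_in = np.asarray(y_pred, dtype=float)[decisions]
    if y_in.size < 2 or np.all(y_in == y_in[0]):
        return float("nan")
    return r_squared(y_in, p_in) - r2_all


def quadrant_counts(y_outliers: np.ndarray, decisions: np.ndarray) -> Quadrants:
    y_outliers = np.asarray(y_outliers, dtype=bool)
    decisions = np.asarray(decisions, dtype=bool)
    if y_outliers.shape != decisions.shape:
        raise ValueError("flag and decision arrays differ in length")
    return Quadrants(
        TO=int(np.sum(y_outliers & ~decisions)),
        TI=int(np.sum(~y_outliers & decisions)),
        FO=int(np.sum(~y_outliers & ~decisions)),
        FI=int(np.sum(y_outliers & decisions)),
    )


def od(quadrants: Quadrants) -> float:
    """Balanced accuracy of Y-outlier detection; 0.5 when a Y-class is absent."""
    n_out = quadrants.TO + quadrants.FI
    n_in = quadrants.TI + quadrants.FO
    if n_out == 0 or n_in == 0:
        return 0.5
    return 0.5 * (quadrants.TO / n_out + quadrants.TI / n_in)


def auc_ad(abs_errors: np.ndarray, decisions: np.ndarray) -> float:
    """Rank-sum AUC: P(error of random X-inlier < error of random X-outlier).

    Ties count one half.  NaN when one decision class is absent.
    """
    abs_errors = np.asarray(abs_errors, dtype=float)
    decisions = np.asarray(decisions, dtype=bool)
    n_in = int(decisions.sum())
    n_out = int((~decisions).sum())
    if n_in == 0 or n_out == 0:
        return float("nan")
    ranks = rankdata(abs_errors)  # average ranks handle ties
    rank_sum_out = float(ranks[~decisions].sum())
    # pairs where the outlier error exceeds the inlier error (ties = 1/2)
    u = rank_sum_out - n_out * (n_out + 1) / 2.0
    return u / (n_in * n_out)


@dataclass
class MetricsReport:
    coverage: float
    oir: float
    delta_r2_ad: float
    od: float
    auc_ad: float
    rmse_in: float
    rmse_out: float
    r2_in: float
    r2_all: float
    quadrants: Quadrants

    def to_dict(self) -> dict:
        out = asdict(self)
        q = out.pop("quadrants")
        out.update({k: q[k] for k in ("TO", "TI", "FO", "FI")})
        return out


def compute_report(y_true: np.ndarray, y_pred: np.ndarray, decisions: np.ndarray,
                   reference_rmse: float | None = None) -> MetricsReport:
    """All metrics for one method's merged predictions and decisions.

    ``reference_rmse`` sets the 3x RMSE Y-outlier rule; by default the RMSE
    of the supplied predictions is used.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    decisions = np.asarray(decisions, dtype=bool)
    errors = np.abs(y_true - y_pred)
    ref = rmse(errors) if reference_rmse is None else reference_rmse
    flags = y_outlier_flags(errors, ref)
    quads = quadrant_counts(flags, decisions)
    rmse_in = rmse(errors[decisions]) if decisions.any() else float("nan")
    rmse_out = rmse(errors[~decisions]) if (~decisions).any() else float("nan")
    r2_all = r_squared(y_true, y_pred)
    if decisions.sum() >= 2 and not np.all(y_true[decisions] == y_true[decisions][0]):
        r2_in = r_squared(y_true[decisions], y_pred[decisions])
    else:
        r2_in = float("nan")
    return MetricsReport(
        coverage=coverage(decisions),
        oir=oir(errors, decisions),
        delta_r2_ad=delta_r2_ad(y_true, y_pred, decisions),
        od=od(quads),
        auc_ad=auc_ad(errors, decisions),
        rmse_in=rmse_in,
        rmse_out=rmse_out,
        r2_in=r2_in,
        r2_all=r2_all,
        quadrants=quads,
    )
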