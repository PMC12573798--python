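"""Per-condition records and the helicity-thermodiffusion correlation.

Each solution condition (pH, buffer) carries an alpha-helical content from CD
deconvolution and a temperature-sensitivity statistic delta_S_T from the
Soret-curve analysis.  The correlation between the two is quantified by a
weighted linear fit with leave-one-out influence diagnostics; conditions are
also ranked by sensitivity (the pH 6 > pH 4 > pH 2 ordering).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "ConditionRecord",
    "CorrelationReport",
    "HelixSensitivityRegression",
    "weighted_linear_fit",
    "correlate_conditions",
    "rank_by_sensitivity",
]

# leave-one-out slope change (relative) above which a record is flagged as
# disproportionately influential
_OUTLIER_SLOPE_CHANGE = 0.5


@dataclass(frozen=True)
class ConditionRecord:
    """One solution condition with helicity and thermodiffusion sensitivity."""

    label: str
    ph: float
    buffer_label: str = ""
    buffer_conc_mm: float = 0.0
    helix_pct: float = 0.0
    helix_sd: float = 0.0
    delta_st: Optional[float] = None   # 1/K
    delta_st_sd: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.helix_pct <= 100.0:
            raise ValueError(f"helix_pct must be in [0, 100], got {self.helix_pct}")
        if self.helix_sd < 0:
            raise ValueError("helix_sd must be >= 0")
        if self.delta_st_sd is not None and self.delta_st_sd < 0:
            raise ValueError("delta_st_sd must be >= 0")


@dataclass(frozen=True)
class CorrelationReport:
    """Summary of the linear delta_S_T versus helicity relationship.

    No p-value is attached: with a handful of conditions the report is
    descriptive, not inferential.
    """

    slope: float          # 1/K per % helix
    intercept: float      # 1/K
    slope_sd: float
    intercept_sd: float
    pearson_r: float
    n: int
    leave_one_out_slopes: Dict[str, float] = field(default_factory=dict)
    flagged_outliers: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.pearson_r <= 1.0 + 1e-12:
            raise ValueError("pearson_r must lie in [-1, 1]")
        if self.n < 3:
            raise ValueError("need at least 3 conditions")


def weighted_linear_fit(
    x, y, sy=None
) -> Tuple[float, float, np.ndarray]:
    """Closed-form weighted least-squares line ``y = slope*x + intercept``.

    Weights are 1/sy^2 (unit weights when ``sy`` is None); returns
    (slope, intercept, covariance) with the covariance from the normal
    equations.  x-uncertainties are not modelled.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError(f"need >= 3 points, got {x.size}")
    if np.all(x == x[0]):
        raise ValueError("all x values identical: design is degenerate")
    if sy is None:
        w = np.ones_like(x)
    else:
        sy = np.asarray(sy, dtype=float).ravel()
        if sy.shape != x.shape:
            raise ValueError("sy must match x in length")
        if not np.all(sy > 0):
            raise ValueError("sy must be > 0")
        w = 1.0 / sy**2
    s = w.sum()
    sx = (w * x).sum()
    sy_ = (w * y).sum()
    sxx = (w * x * x).sum()
    sxy = (w * x * y).sum()
    delta = s * sxx - sx**2
    slope = (s * sxy - sx * sy_) / delta
    intercept = (sxx * sy_ - sx * sxy) / delta
    cov = np.array([[s, -sx], [-sx, sxx]]) / delta  # order: (slope, intercept)
    if sy is None:
        # scale by residual variance when no measurement errors are supplied
        resid = y - slope * x - intercept
        dof = max(x.size - 2, 1)
        cov = cov * float((resid**2).sum() / dof)
    return float(slope), float(intercept), cov


class HelixSensitivityRegression(BaseEstimator):
    """Weighted linear regression of delta_S_T on alpha-helical content.

    Attributes after :meth:`fit`: ``slope_``, ``intercept_``,
    ``covariance_`` (2x2, order slope/intercept), ``pearson_r_``.
    """

    def __init__(self, weighted: bool = True):
        self.weighted = weighted

    def fit(self, x, y, sy=None) -> "HelixSensitivityRegression":
        sy = sy if self.weighted else None
        self.slope_, self.intercept_, self.covariance_ = weighted_linear_fit(x, y, sy)
        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if np.all(y == y[0]):
            self.pearson_r_ = 0.0  # flat response carries no correlation
        else:
            self.pearson_r_ = float(np.corrcoef(x, y)[0, 1])
        self.n_ = int(x.size)
        return self

    def predict(self, x) -> np.ndarray:
        return self.slope_ * np.asarray(x, dtype=float).ravel() + self.intercept_


def correlate_conditions(records: Sequence[ConditionRecord]) -> CorrelationReport:
    """Quantify the delta_S_T versus helicity trend over condition records.

    Runs the weighted linear fit, computes Pearson's r, and recomputes the
    slope leaving each condition out in turn; a record whose removal changes
    the slope by more than 50% is flagged as an outlier (e.g. the strongly
    acid-unfolded state can deviate from the trend).
    """
    recs = list(records)
    if len(recs) < 3:
        raise ValueError(f"need >= 3 condition records, got {len(recs)}")
    if any(r.delta_st is None for r in recs):
        raise ValueError("all records must carry a delta_st value")
    recs = sorted(recs, key=lambda r: r.label)  # order-independent output
    x = np.array([r.helix_pct for r in recs])
    y = np.array([r.delta_st for r in recs])
    sy = None
    if all(r.delta_st_sd is not None and r.delta_st_sd > 0 for r in recs):
        sy = np.array([r.delta_st_sd for r in recs])
    est = HelixSensitivityRegression().fit(x, y, sy)
    loo: Dict[str, float] = {}
    flagged: List[str] = []
    if len(recs) >= 4:
        for i, rec in enumerate(recs):
            keep = np.arange(len(recs)) != i
            try:
                s_i, _, _ = weighted_linear_fit(
                    x[keep], y[keep], None if sy is None else sy[keep]
                )
            except ValueError:
                continue
            loo[rec.label] = s_i
            if est.slope_ != 0 and abs(s_i - est.slope_) > _OUTLIER_SLOPE_CHANGE * abs(
                est.slope_
            ):
                flagged.append(rec.label)
    return CorrelationReport(
        slope=est.slope_,
        intercept=est.intercept_,
        slope_sd=float(math.sqrt(max(est.covariance_[0, 0], 0.0))),
        intercept_sd=float(math.sqrt(max(est.covariance_[1, 1], 0.0))),
        pearson_r=est.pearson_r_,
        n=len(recs),
        leave_one_out_slopes=loo,
        flagged_outliers=tuple(sorted(flagged)),
    )


def rank_by_sensitivity(records: Sequence[ConditionRecord]) -> List[str]:
    """Condition labels ordered by descending delta_S_T (ties: label order)."""
    recs = list(records)
    if any(r.delta_st is None for r in recs):
        raise ValueError("all records must carry a delta_st value")
    return [r.label for r in sorted(recs, key=lambda r: (-r.delta_st, r.label))]
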