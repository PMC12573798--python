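"""Empirical temperature law of the Soret coefficient and its sensitivity.

For aqueous solutes S_T(T) is well described by

    S_T(T) = S_T_inf + A * exp(-T / T0)

with the high-temperature asymptote ``S_T_inf``, amplitude ``A`` and bending
scale ``T0``.  When ``-A / S_T_inf > 0`` the curve crosses zero at the
sign-change temperature ``T* = T0 ln(-A / S_T_inf)`` (thermophilic below,
thermophobic above).  The temperature sensitivity statistic is

    delta_S_T = S_T(T_high) - S_T(T_low),   default endpoints 15 and 40 C,

used downstream as a hydrophilicity proxy.  Temperatures here are degrees
Celsius throughout (so T0 and T* are in C); the model form is equivalent
under a shift of temperature unit up to reparametrization of (A, T0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator

__all__ = [
    "SoretPoint",
    "SoretCurveParams",
    "SoretCurveFit",
    "DeltaST",
    "SoretCurveModel",
    "soret_model",
    "fit_soret_curve",
    "sign_change_temperature",
    "delta_st",
]


@dataclass(frozen=True)
class SoretPoint:
    """One measured Soret coefficient at a temperature (C)."""

    temperature_c: float
    s_t: float
    sigma: Optional[float] = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.temperature_c) and math.isfinite(self.s_t)):
            raise ValueError("temperature and S_T must be finite")
        if self.sigma is not None and not (math.isfinite(self.sigma) and self.sigma >= 0):
            raise ValueError("sigma must be finite and >= 0")


@dataclass(frozen=True)
class SoretCurveParams:
    """Parameters of the empirical S_T(T) law (temperatures in C)."""

    s_inf: float   # asymptotic Soret coefficient, 1/K
    a: float       # amplitude, 1/K
    t0: float      # bending scale, C

    def __post_init__(self) -> None:
        for v in (self.s_inf, self.a, self.t0):
            if not math.isfinite(v):
                raise ValueError("curve parameters must be finite")
        if self.t0 <= 0:
            raise ValueError("t0 must be > 0")

    @property
    def t_star(self) -> Optional[float]:
        """Sign-change temperature, present only when -A/S_inf > 0."""
        return sign_change_temperature(self)


@dataclass(frozen=True)
class SoretCurveFit:
    """Fitted curve parameters with covariance (order: s_inf, a, t0)."""

    params: SoretCurveParams
    covariance: np.ndarray
    converged: bool
    residual_rms: float


@dataclass(frozen=True)
class DeltaST:
    """Temperature-sensitivity statistic S_T(T_high) - S_T(T_low)."""

    value: float
    sigma: Optional[float]
    mode: str
    t_low: float
    t_high: float


def _model(t: np.ndarray, s_inf: float, a: float, t0: float) -> np.ndarray:
    return s_inf + a * np.exp(-np.asarray(t, dtype=float) / t0)


def soret_model(temperature_c, params: SoretCurveParams):
    """Evaluate ``S_T(T) = S_inf + A exp(-T/T0)`` at temperature(s) in C."""
    out = _model(temperature_c, params.s_inf, params.a, params.t0)
    return float(out) if np.ndim(temperature_c) == 0 else out


def sign_change_temperature(params: SoretCurveParams) -> Optional[float]:
    """``T* = T0 ln(-A/S_inf)`` (C), or None when S_T never changes sign."""
    if params.s_inf == 0 or params.a == 0:
        return None
    ratio = -params.a / params.s_inf
    if ratio <= 0:
        return None
    return params.t0 * math.log(ratio)


class SoretCurveModel(BaseEstimator):
    """Weighted nonlinear least-squares fit of the empirical S_T(T) law.

    Attributes after :meth:`fit`: ``params_`` (:class:`SoretCurveParams`),
    ``covariance_`` (3x3, order s_inf/a/t0), ``converged_``,
    ``residual_rms_``, ``t_star_`` (None when there is no sign change).
    """

    def __init__(self, t0_bounds: Tuple[float, float] = (1e-3, 1e4), maxfev: int = 10000):
        self.t0_bounds = t0_bounds
        self.maxfev = maxfev

    def fit(self, temperature_c, s_t, sigma=None) -> "SoretCurveModel":
        t = np.asarray(temperature_c, dtype=float).ravel()
        y = np.asarray(s_t, dtype=float).ravel()
        if t.size != y.size:
            raise ValueError("temperature and S_T arrays must have equal length")
        if t.size < 4:
            raise ValueError(f"need >= 4 points to fit the curve, got {t.size}")
        span = float(t.max() - t.min())
        if span <= 0:
            raise ValueError("temperatures must span a nonzero range")
        order = np.argsort(t)
        t, y = t[order], y[order]
        w = None
        if sigma is not None:
            w = np.asarray(sigma, dtype=float).ravel()[order]
            if not np.all(w > 0):
                w = None
        # initialization: asymptote from the hottest point, bending scale from
        # half the span, amplitude from the coldest-point residual
        s_inf0 = float(y[-1])
        t0_0 = max(span / 2.0, self.t0_bounds[0])
        a0 = float((y[0] - s_inf0) / math.exp(-t[0] / t0_0))
        lower = [-np.inf, -np.inf, self.t0_bounds[0]]
        upper = [np.inf, np.inf, self.t0_bounds[1]]
        try:
            popt, pcov = curve_fit(
                _model,
                t,
                y,
                p0=[s_inf0, a0, t0_0],
                sigma=w,
                absolute_sigma=w is not None,
                bounds=(lower, upper),
                maxfev=self.maxfev,
            )
            self.converged_ = True
        except RuntimeError:
            popt = np.array([s_inf0, a0, t0_0])
            pcov = np.full((3, 3), np.nan)
            self.converged_ = False
        self.params_ = SoretCurveParams(s_inf=popt[0], a=popt[1], t0=popt[2])
        self.covariance_ = np.asarray(pcov, dtype=float)
        resid = y - _model(t, *popt)
        self.residual_rms_ = float(np.sqrt(np.mean(resid**2)))
        self.t_star_ = sign_change_temperature(self.params_)
        return self

    def predict(self, temperature_c) -> np.ndarray:
        p = self.params_
        return _model(np.asarray(temperature_c, dtype=float).ravel(), p.s_inf, p.a, p.t0)

    def delta_st(self, t_low: float = 15.0, t_high: float = 40.0) -> DeltaST:
        """Delta S_T between the endpoints, with delta-method uncertainty."""
        p = self.params_
        eh = math.exp(-t_high / p.t0)
        el = math.exp(-t_low / p.t0)
        value = p.a * (eh - el)
        grad = np.array(
            [
                0.0,
                eh - el,
                p.a * (eh * t_high - el * t_low) / p.t0**2,
            ]
        )
        cov = self.covariance_
        sigma = None
        if np.all(np.isfinite(cov)):
            var = float(grad @ cov @ grad)
            sigma = math.sqrt(var) if var >= 0 else None
        return DeltaST(value=float(value), sigma=sigma, mode="from_fit",
                       t_low=t_low, t_high=t_high)


def fit_soret_curve(points: Sequence[SoretPoint]) -> SoretCurveFit:
    """Fit the empirical law to measured (T, S_T) points.

    Requires at least 4 points spanning at least 15 C.  Weighted by the
    per-point sigmas when all are present and positive.
    """
    pts = list(points)
    if len(pts) < 4:
        raise ValueError(f"need >= 4 points, got {len(pts)}")
    t = np.array([p.temperature_c for p in pts])
    if t.max() - t.min() < 15.0:
        raise ValueError("points must span at least 15 C")
    y = np.array([p.s_t for p in pts])
    sig = None
    if all(p.sigma is not None and p.sigma > 0 for p in pts):
        sig = np.array([p.sigma for p in pts])
    est = SoretCurveModel().fit(t, y, sig)
    return SoretCurveFit(
        params=est.params_,
        covariance=est.covariance_,
        converged=est.converged_,
        residual_rms=est.residual_rms_,
    )


def _delta_from_points(
    points: Sequence[SoretPoint], t_low: float, t_high: float, tol: float = 0.5
) -> DeltaST:
    def _endpoint(target: float) -> Tuple[float, Optional[float]]:
        near = [p for p in points if abs(p.temperature_c - target) <= tol]
        if not near:
            raise ValueError(
                f"no measurement within {tol} C of {target} C for the "
                "point-based temperature-sensitivity statistic"
            )
        vals = np.array([p.s_t for p in near])
        mean = float(vals.mean())
        if all(p.sigma is not None for p in near):
            sd = float(np.sqrt(np.sum([p.sigma**2 for p in near])) / len(near))
        elif len(near) > 1:
            sd = float(vals.std(ddof=1) / math.sqrt(len(near)))
        else:
            sd = None
        return mean, sd

    hi, sd_hi = _endpoint(t_high)
    lo, sd_lo = _endpoint(t_low)
    sigma = None
    if sd_hi is not None and sd_lo is not None:
        sigma = math.sqrt(sd_hi**2 + sd_lo**2)
    return DeltaST(value=hi - lo, sigma=sigma, mode="from_points",
                   t_low=t_low, t_high=t_high)


def delta_st(
    source: Union[Sequence[SoretPoint], SoretCurveFit, SoretCurveModel],
    t_low: float = 15.0,
    t_high: float = 40.0,
    mode: str = "auto",
) -> DeltaST:
    """Temperature sensitivity S_T(t_high) - S_T(t_low).

    ``mode='from_points'`` requires measurements within 0.5 C of both
    endpoints and propagates their uncertainties in quadrature;
    ``mode='from_fit'`` evaluates a fitted curve with a delta-method sigma.
    ``mode='auto'`` prefers points when both endpoints are measured.
    """
    if mode not in ("auto", "from_points", "from_fit"):
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(source, SoretCurveModel):
        if mode == "from_points":
            raise ValueError("from_points mode needs measured points, not a fit")
        return source.delta_st(t_low, t_high)
    if isinstance(source, SoretCurveFit):
        if mode == "from_points":
            raise ValueError("from_points mode needs measured points, not a fit")
        est = SoretCurveModel()
        est.params_ = source.params
        est.covariance_ = source.covariance
        return est.delta_st(t_low, t_high)
    points = list(source)
    if mode in ("from_points", "auto"):
        try:
            return _delta_from_points(points, t_low, t_high)
        except ValueError:
            if mode == "from_points":
                raise
    fit = fit_soret_curve(points)
    return delta_st(fit, t_low, t_high, mode="from_fit")
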