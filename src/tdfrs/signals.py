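"""Turning averaged heterodyne traces into relaxation and transport parameters.

Workflow mirroring the experimental protocol: many individual shots are
averaged pointwise, the averaged trace is normalized to a unit thermal
plateau, split into excitation-on and excitation-off phases, each phase is
fitted with the closed-form two-mode signal model, and repeated measurements
are pooled as mean +/- standard error of the mean.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator

from .core import (
    ContrastFactors,
    GratingGeometry,
    SignalParams,
    TransportCoefficients,
    amplitude_to_soret,
    grating_modes_off,
    grating_modes_on,
    relaxation_to_diffusivity,
)

__all__ = [
    "DegenerateSignalError",
    "TraceMetadata",
    "HeterodyneTrace",
    "SignalFit",
    "PooledEstimate",
    "HeterodyneSignalModel",
    "average_shots",
    "normalize_trace",
    "split_phases",
    "fit_signal",
    "derive_transport",
    "pool_estimates",
]

_ONE_MINUS_INV_E = 1.0 - math.exp(-1.0)


class DegenerateSignalError(ValueError):
    """The trace does not contain a usable thermal rise/plateau."""


@dataclass(frozen=True)
class TraceMetadata:
    """Experimental metadata attached to a heterodyne trace."""

    temperature_c: Optional[float] = None
    ph: Optional[float] = None
    buffer_label: str = ""
    geometry: Optional[GratingGeometry] = None
    contrast: Optional[ContrastFactors] = None
    c: Optional[float] = None
    t_excitation_off_s: Optional[float] = None


@dataclass
class HeterodyneTrace:
    """Normalized heterodyne intensity versus time.

    ``times`` must be strictly increasing (seconds); ``values`` dimensionless
    intensities; ``per_point_sd`` optional per-point standard deviations of
    the shot average.
    """

    times: np.ndarray
    values: np.ndarray
    per_point_sd: Optional[np.ndarray] = None
    metadata: TraceMetadata = field(default_factory=TraceMetadata)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValueError("times and values must be one-dimensional")
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size == 0:
            raise ValueError("trace must contain at least one sample")
        if not np.all(np.isfinite(self.times)) or not np.all(np.isfinite(self.values)):
            raise ValueError("times and values must be finite")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.per_point_sd is not None:
            self.per_point_sd = np.asarray(self.per_point_sd, dtype=float)
            if self.per_point_sd.shape != self.times.shape:
                raise ValueError("per_point_sd must match times in length")
            if not np.all(np.isfinite(self.per_point_sd)) or np.any(self.per_point_sd < 0):
                raise ValueError("per_point_sd must be finite and >= 0")

    def __len__(self) -> int:
        return self.times.size

    @property
    def span(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass(frozen=True)
class SignalFit:
    """Result of fitting one trace phase with the two-mode signal model."""

    params: SignalParams
    covariance: np.ndarray
    residual_rms: float
    phase: str
    converged: bool


@dataclass(frozen=True)
class PooledEstimate:
    """Mean and standard error of the mean over repeated measurements."""

    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sem < 0:
            raise ValueError("sem must be >= 0")


def average_shots(shots: Sequence[HeterodyneTrace]) -> HeterodyneTrace:
    """Pointwise mean of identically timed shots.

    ``per_point_sd`` of the result is the pointwise sample standard deviation
    divided by sqrt(n_shots) (all zeros for a single shot).
    """
    if len(shots) < 1:
        raise ValueError("need at least one shot")
    t0 = shots[0].times
    for s in shots[1:]:
        if not np.array_equal(s.times, t0):
            raise ValueError("all shots must share an identical time grid")
    stacked = np.vstack([s.values for s in shots])
    mean = stacked.mean(axis=0)
    n = len(shots)
    if n > 1:
        sd = stacked.std(axis=0, ddof=1) / math.sqrt(n)
    else:
        sd = np.zeros_like(mean)
    return HeterodyneTrace(t0.copy(), mean, sd, shots[0].metadata)


def _estimate_rise(
    times: np.ndarray, values: np.ndarray, n_iter: int = 8
) -> Tuple[float, float]:
    """Estimate (tau_th, plateau) from the fast initial rise of a trace.

    The thermal mode rises as ``p (1 - exp(-t/tau_th))``, so the first
    crossing of (1 - 1/e) of the plateau occurs at t = tau_th.  The plateau
    itself is the median over the window [5 tau_th, 10 tau_th]; the two are
    estimated jointly by fixed-point iteration starting from the final value.
    """
    t0 = times[0]
    plateau = float(values[-1])
    if not plateau > 0:
        plateau = float(np.max(values))
    if not plateau > 0:
        raise DegenerateSignalError("no positive signal level to normalize to")
    tau_est = float("nan")
    for _ in range(n_iter):
        target = _ONE_MINUS_INV_E * plateau
        above = np.nonzero(values >= target)[0]
        if above.size == 0:
            raise DegenerateSignalError("signal never reaches (1 - 1/e) of plateau")
        tau_new = float(times[above[0]] - t0)
        if tau_new <= 0:
            # crossing at/before the first sample; resolve to first interval
            tau_new = float(times[1] - t0) if times.size > 1 else float("nan")
            if not tau_new > 0:
                raise DegenerateSignalError("thermal rise not resolved by sampling")
        window = (times - t0 >= 5.0 * tau_new) & (times - t0 <= 10.0 * tau_new)
        if not np.any(window):
            raise DegenerateSignalError(
                "trace too short: must cover >= 5x the estimated thermal time"
            )
        plateau_new = float(np.median(values[window]))
        if not plateau_new > 0:
            raise DegenerateSignalError("non-positive thermal plateau estimate")
        done = math.isclose(plateau_new, plateau, rel_tol=1e-12) and math.isclose(
            tau_new, tau_est, rel_tol=1e-12
        ) if math.isfinite(tau_est) else False
        tau_est, plateau = tau_new, plateau_new
        if done:
            break
    return tau_est, plateau


def _scaled_on_model(t, k, tau_th, tau, a0):
    theta, g = grating_modes_on(t, tau_th, tau)
    return k * (theta - a0 * g)


def normalize_trace(trace: HeterodyneTrace) -> HeterodyneTrace:
    """Rescale a trace so its thermal plateau (thermal-mode amplitude) is one.

    A first plateau estimate comes from the window [5, 10] times the thermal
    relaxation time (from the 1 - 1/e crossing of the initial rise) with the
    residual thermal shortfall 1 - exp(-t/tau_th) divided out; it is then
    refined by fitting the two-mode signal model with a free overall
    amplitude to the excitation-on samples, which separates the thermal
    plateau from the concentration mode leaking into the window.  Exact on
    noiseless conforming traces (idempotent, scale invariant); falls back to
    the windowed estimate when the model fit is not possible.
    """
    tau_est, plateau = _estimate_rise(trace.times, trace.values)
    t_rel = trace.times - trace.times[0]
    window = (t_rel >= 5.0 * tau_est) & (t_rel <= 10.0 * tau_est)
    rise = 1.0 - np.exp(-t_rel[window] / tau_est)
    corrected = float(np.median(trace.values[window] / rise))
    if corrected > 0:
        plateau = corrected
    # refine with a free-amplitude model fit restricted to the on-phase
    t_switch = trace.metadata.t_excitation_off_s
    on = np.ones(trace.times.size, dtype=bool)
    if t_switch is not None:
        on = trace.times <= t_switch
    t_on, y_on = t_rel[on], trace.values[on]
    if t_on.size >= 30:
        span = float(t_on[-1] - t_on[0])
        dt_min = float(np.min(np.diff(t_on)))
        a0_guess = 1.0 - float(y_on[-1]) / plateau
        p0 = [plateau, min(max(tau_est, dt_min), span),
              min(max(span / 3.0, dt_min), 100.0 * span),
              min(max(a0_guess, -2.0), 2.0)]
        try:
            popt, _ = curve_fit(
                _scaled_on_model, t_on, y_on, p0=p0,
                bounds=([1e-300, dt_min, dt_min, -2.0],
                        [np.inf, span, 100.0 * span, 2.0]),
                maxfev=10000,
            )
            if popt[0] > 0:
                plateau = float(popt[0])
        except RuntimeError:
            pass
    sd = None if trace.per_point_sd is None else trace.per_point_sd / plateau
    return HeterodyneTrace(trace.times.copy(), trace.values / plateau, sd, trace.metadata)


def split_phases(
    trace: HeterodyneTrace, t_excitation_off: float
) -> Tuple[HeterodyneTrace, HeterodyneTrace]:
    """Split a trace into excitation-on and excitation-off phases.

    The on-phase keeps the original time origin; the off-phase is re-zeroed
    at ``t_excitation_off``.  Samples at exactly the switch-off time belong
    to the on-phase; no sample is lost or duplicated.
    """
    t_off = float(t_excitation_off)
    if not trace.times[0] < t_off < trace.times[-1]:
        raise ValueError(
            f"t_excitation_off={t_off} must lie strictly inside the time span "
            f"[{trace.times[0]}, {trace.times[-1]}]"
        )
    on_mask = trace.times <= t_off
    off_mask = ~on_mask
    meta = dataclasses.replace(trace.metadata, t_excitation_off_s=t_off)

    def _sub(mask: np.ndarray, shift: float) -> HeterodyneTrace:
        sd = None if trace.per_point_sd is None else trace.per_point_sd[mask]
        return HeterodyneTrace(trace.times[mask] - shift, trace.values[mask], sd, meta)

    return _sub(on_mask, 0.0), _sub(off_mask, t_off)


class HeterodyneSignalModel(BaseEstimator):
    """Two-mode heterodyne signal model fitted by nonlinear least squares.

    Parameters
    ----------
    phase : {"on", "off"}
        Which closed-form branch to fit: the driven rise ("on") or the
        source-free decay after switch-off ("off").
    t_on : float, optional
        Duration of the excitation phase preceding an off-phase trace.  When
        given, the initial state (theta0, g0) of the off model is computed
        from (tau_th, tau) through the on-phase closed form; otherwise steady
        state (theta0 = g0 = 1) is assumed.
    a0_bounds : tuple of float
        Search bounds for the concentration amplitude.
    maxfev : int
        Maximum function evaluations for the optimizer.

    Attributes
    ----------
    params_ : SignalParams
        Fitted (tau_th, tau, a0).
    covariance_ : ndarray of shape (3, 3)
        Parameter covariance from the Jacobian at the optimum.
    residual_rms_ : float
        Root-mean-square fit residual.
    converged_ : bool
        False when the optimizer failed; parameters then hold the initial
        guess and the covariance is NaN (never silently imputed).
    """

    def __init__(
        self,
        phase: str = "on",
        t_on: Optional[float] = None,
        a0_bounds: Tuple[float, float] = (-2.0, 2.0),
        maxfev: int = 10000,
    ):
        self.phase = phase
        self.t_on = t_on
        self.a0_bounds = a0_bounds
        self.maxfev = maxfev

    # -- model ------------------------------------------------------------
    def _model(self, t: np.ndarray, tau_th: float, tau: float, a0: float) -> np.ndarray:
        if self.phase == "on":
            theta, g = grating_modes_on(t, tau_th, tau)
        else:
            if self.t_on is not None:
                theta0, g0 = grating_modes_on(float(self.t_on), tau_th, tau)
            else:
                theta0, g0 = 1.0, 1.0
            theta, g = grating_modes_off(t, tau_th, tau, float(theta0), float(g0))
        return theta - a0 * g

    # -- initialization heuristics ----------------------------------------
    def _initial_guess(self, t: np.ndarray, y: np.ndarray) -> Tuple[float, float, float]:
        span = float(t[-1] - t[0])
        if self.phase == "on":
            rise = y
            y_end = float(y[-1])
        else:
            # the off-phase decays; estimate the fast time from the mirrored drop
            rise = float(y[0]) - y
            y_end = float(y[-1])
        tau_th0, plateau = _estimate_rise(t, rise if self.phase == "off" else y)
        if self.phase == "on":
            a0_0 = 1.0 - y_end
        else:
            # after the thermal decay the signal is ~ -a0 * g with g near g0
            i5 = int(np.searchsorted(t, t[0] + 10.0 * tau_th0))
            i5 = min(i5, len(t) - 1)
            a0_0 = -float(y[i5])
        # slow-mode time from the 1/e decay of the late component
        t5 = t[0] + 10.0 * tau_th0
        sel = t >= t5
        tau0 = span / 3.0
        if np.count_nonzero(sel) >= 3:
            resid = y[sel] - (y_end if self.phase == "on" else 0.0)
            amp = float(resid[0])
            if abs(amp) > 1e-12:
                below = np.nonzero(np.abs(resid) <= abs(amp) / math.e)[0]
                if below.size:
                    tau0 = max(float(t[sel][below[0]] - t5), span / 100.0)
        lo, hi = self.a0_bounds
        a0_0 = min(max(a0_0, lo), hi)
        return tau_th0, tau0, a0_0

    # -- sklearn-style API -------------------------------------------------
    def fit(self, t, zeta, zeta_sd=None) -> "HeterodyneSignalModel":
        t = np.asarray(t, dtype=float).ravel()
        y = np.asarray(zeta, dtype=float).ravel()
        if t.size != y.size:
            raise ValueError("t and zeta must have equal length")
        if t.size < 30:
            raise ValueError(f"need >= 30 samples to fit, got {t.size}")
        if self.phase not in ("on", "off"):
            raise ValueError("phase must be 'on' or 'off'")
        span = float(t[-1] - t[0])
        tau_th0, tau0, a0_0 = self._initial_guess(t, y)
        if span < 3.0 * tau0:
            raise ValueError(
                f"time span {span:.3g}s shorter than 3x the initial mass-time "
                f"estimate {tau0:.3g}s"
            )
        dt_min = float(np.min(np.diff(t)))
        lower = [dt_min, dt_min, self.a0_bounds[0]]
        upper = [span, 100.0 * span, self.a0_bounds[1]]
        p0 = [
            min(max(tau_th0, lower[0]), upper[0]),
            min(max(tau0, lower[1]), upper[1]),
            a0_0,
        ]
        sigma = None
        if zeta_sd is not None:
            sigma = np.asarray(zeta_sd, dtype=float).ravel()
            if sigma.shape != t.shape:
                raise ValueError("zeta_sd must match t in length")
            if not np.all(sigma > 0):
                sigma = None  # fall back to ordinary least squares
        try:
            popt, pcov = curve_fit(
                self._model,
                t,
                y,
                p0=p0,
                sigma=sigma,
                absolute_sigma=sigma is not None,
                bounds=(lower, upper),
                maxfev=self.maxfev,
            )
            self.converged_ = True
        except RuntimeError:
            popt = np.asarray(p0, dtype=float)
            pcov = np.full((3, 3), np.nan)
            self.converged_ = False
        self.params_ = SignalParams(tau_th=popt[0], tau=popt[1], a0=popt[2])
        self.covariance_ = np.asarray(pcov, dtype=float)
        resid = y - self._model(t, *popt)
        self.residual_rms_ = float(np.sqrt(np.mean(resid**2)))
        self.n_points_ = int(t.size)
        return self

    def predict(self, t) -> np.ndarray:
        p = self.params_
        return self._model(np.asarray(t, dtype=float).ravel(), p.tau_th, p.tau, p.a0)


def fit_signal(trace: HeterodyneTrace, phase: str = "on") -> SignalFit:
    """Fit one trace phase, weighted by per-point sd when available."""
    t_on = trace.metadata.t_excitation_off_s if phase == "off" else None
    est = HeterodyneSignalModel(phase=phase, t_on=t_on)
    est.fit(trace.times, trace.values, trace.per_point_sd)
    return SignalFit(
        params=est.params_,
        covariance=est.covariance_,
        residual_rms=est.residual_rms_,
        phase=phase,
        converged=est.converged_,
    )


def derive_transport(
    fit: SignalFit,
    geometry: GratingGeometry,
    contrast: ContrastFactors,
    c: float,
) -> TransportCoefficients:
    """Transport coefficients from a fitted signal.

    ``D_th = 1/(tau_th q^2)``, ``D = 1/(tau q^2)``, ``S_T`` from the
    steady-state amplitude via the contrast factors, ``D_T = S_T D``.
    """
    d_th = relaxation_to_diffusivity(fit.params.tau_th, geometry)
    d = relaxation_to_diffusivity(fit.params.tau, geometry)
    s_t = amplitude_to_soret(fit.params.a0, contrast, c)
    return TransportCoefficients.from_soret(d=d, d_th=d_th, s_t=s_t)


def pool_estimates(values: Sequence[float]) -> PooledEstimate:
    """Mean and standard error of the mean of repeated per-fit values."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 1:
        raise ValueError("need at least one value to pool")
    if not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite")
    n = int(arr.size)
    sem = float(arr.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return PooledEstimate(mean=float(arr.mean()), sem=sem, n=n)
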