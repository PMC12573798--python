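"""Closed-form physics of the transient-grating thermodiffusion experiment.

A holographic temperature grating written into the sample drives two coupled
relaxation modes: a fast thermal mode ``theta`` (time constant ``tau_th``) and
a slow concentration mode ``g`` (time constant ``tau``) fed by the Soret
effect.  The normalized heterodyne diffraction signal is

    zeta(t) = theta(t) - A0 * g(t)

where ``A0`` is the steady-state concentration amplitude.  Relaxation times
map to diffusivities through the grating vector ``q``:
``tau_th = 1/(D_th q^2)`` and ``tau = 1/(D q^2)``, and ``A0`` maps to the
Soret coefficient through the optical contrast factors (dn/dT, dn/dc) and the
solute weight fraction ``c``.

All functions here are pure and operate in SI units (s, m, K); temperatures
at interfaces elsewhere in the package are degrees Celsius.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "TimescaleSeparationWarning",
    "SignalParams",
    "GratingGeometry",
    "ContrastFactors",
    "SampleState",
    "TransportCoefficients",
    "grating_modes_on",
    "grating_modes_off",
    "heterodyne_intensity",
    "heterodyne_intensity_off",
    "amplitude_to_soret",
    "soret_to_amplitude",
    "relaxation_to_diffusivity",
    "soret_steady_state_gradient",
    "thermal_diffusion_coefficient",
]

# Relative |tau - tau_th| threshold below which the analytic equal-time-scale
# limit replaces the (tau - tau_th)^-1 form, which loses precision there.
_EQUAL_TAU_RTOL = 1e-9


class TimescaleSeparationWarning(UserWarning):
    """Thermal and mass relaxation times are not well separated."""


def _check_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class SignalParams:
    """Lumped relaxation parameters of one grating experiment.

    Parameters
    ----------
    tau_th : float
        Thermal relaxation time in seconds (> 0).
    tau : float
        Mass (concentration) relaxation time in seconds (> 0).
    a0 : float
        Steady-state concentration amplitude, dimensionless.  May be negative
        (thermophilic solute, i.e. negative Soret coefficient).
    """

    tau_th: float
    tau: float
    a0: float

    def __post_init__(self) -> None:
        for name in ("tau_th", "tau", "a0"):
            _check_finite(name, getattr(self, name))
        if self.tau_th <= 0:
            raise ValueError(f"tau_th must be > 0, got {self.tau_th}")
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if self.tau / self.tau_th < 10:
            warnings.warn(
                f"tau/tau_th = {self.tau / self.tau_th:.3g} < 10: thermal and "
                "mass modes are poorly separated; amplitude and time-constant "
                "estimates may be strongly correlated",
                TimescaleSeparationWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class GratingGeometry:
    """Grating vector of the transient grating.

    Exactly one of ``q`` (1/m) or ``fringe_spacing`` (m) must be given; the
    other is derived through ``q = 2 pi / fringe_spacing``.
    """

    q: Optional[float] = None
    fringe_spacing: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.q is None) == (self.fringe_spacing is None):
            raise ValueError("give exactly one of q or fringe_spacing")
        if self.q is None:
            fs = _check_finite("fringe_spacing", self.fringe_spacing)
            if fs <= 0:
                raise ValueError("fringe_spacing must be > 0")
            object.__setattr__(self, "q", 2.0 * math.pi / fs)
        else:
            qv = _check_finite("q", self.q)
            if qv <= 0:
                raise ValueError("q must be > 0")
            object.__setattr__(self, "fringe_spacing", 2.0 * math.pi / qv)


@dataclass(frozen=True)
class ContrastFactors:
    """Optical contrast factors (dn/dT)_{c,p} in 1/K and (dn/dc)_{T,p}."""

    dn_dT: float
    dn_dc: float

    def __post_init__(self) -> None:
        _check_finite("dn_dT", self.dn_dT)
        _check_finite("dn_dc", self.dn_dc)
        if self.dn_dc == 0:
            raise ValueError("dn_dc must be nonzero")


@dataclass(frozen=True)
class SampleState:
    """Solution state point: weight fraction, temperature (C), pH, buffer.

    ``rho`` (kg/m^3) appears in the flux law but cancels in the steady state;
    it is optional and only used by flux-level calculations.
    """

    c: float
    temperature_c: Optional[float] = None
    ph: Optional[float] = None
    buffer_label: str = ""
    rho: Optional[float] = None

    def __post_init__(self) -> None:
        c = _check_finite("c", self.c)
        if not 0 < c < 1:
            raise ValueError(f"weight fraction c must be in (0, 1), got {c}")
        if self.rho is not None and _check_finite("rho", self.rho) <= 0:
            raise ValueError("rho must be > 0")


@dataclass(frozen=True)
class TransportCoefficients:
    """Transport coefficients at one state point.

    ``s_t = d_t / d`` is enforced to 1e-12 relative whenever both are set.
    """

    d: float          # mass diffusion coefficient, m^2/s
    d_th: float       # thermal diffusivity, m^2/s
    d_t: float        # thermal diffusion coefficient, m^2/(s K)
    s_t: float        # Soret coefficient, 1/K

    def __post_init__(self) -> None:
        for name in ("d", "d_th", "d_t", "s_t"):
            _check_finite(name, getattr(self, name))
        if self.d <= 0:
            raise ValueError("d must be > 0")
        if self.d_th <= 0:
            raise ValueError("d_th must be > 0")
        if not math.isclose(self.d_t, self.s_t * self.d, rel_tol=1e-12, abs_tol=0.0):
            raise ValueError(
                f"inconsistent coefficients: d_t={self.d_t!r} but "
                f"s_t*d={self.s_t * self.d!r}"
            )

    @classmethod
    def from_soret(cls, d: float, d_th: float, s_t: float) -> "TransportCoefficients":
        return cls(d=d, d_th=d_th, d_t=s_t * d, s_t=s_t)


def _as_time_array(t) -> Tuple[np.ndarray, bool]:
    arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("time values must be finite")
    if np.any(arr < 0):
        raise ValueError("time values must be >= 0")
    return arr, arr.ndim == 0


def grating_modes_on(t, tau_th: float, tau: float) -> Tuple[np.ndarray, np.ndarray]:
    """Thermal and concentration mode responses during excitation.

    Solves ``theta' = (1 - theta)/tau_th``, ``g' = (theta - g)/tau`` from
    rest (theta = g = 0).  Returns ``(theta, g)`` evaluated at ``t``.
    """
    t = np.asarray(t, dtype=float)
    eth = np.exp(-t / tau_th)
    theta = 1.0 - eth
    e = np.exp(-t / tau)
    if abs(tau - tau_th) < _EQUAL_TAU_RTOL * tau_th:
        # tau -> tau_th limit of (tau - tau_th)^-1 [tau(1-e^-t/tau) - ...]
        g = 1.0 - e - (t / tau) * e
    else:
        g = (tau * (1.0 - e) - tau_th * (1.0 - eth)) / (tau - tau_th)
    return theta, g


def grating_modes_off(
    t, tau_th: float, tau: float, theta0: float = 1.0, g0: float = 1.0
) -> Tuple[np.ndarray, np.ndarray]:
    """Source-free decay of the two modes after excitation switch-off.

    ``theta(t) = theta0 exp(-t/tau_th)``; ``g`` relaxes toward the decaying
    thermal mode, ``g' = (theta - g)/tau``.
    """
    t = np.asarray(t, dtype=float)
    eth = np.exp(-t / tau_th)
    e = np.exp(-t / tau)
    theta = theta0 * eth
    if abs(tau - tau_th) < _EQUAL_TAU_RTOL * tau_th:
        g = g0 * e + theta0 * (t / tau) * e
    else:
        g = g0 * e + theta0 * tau_th / (tau_th - tau) * (eth - e)
    return theta, g


def heterodyne_intensity(t, params: SignalParams):
    """Normalized heterodyne intensity zeta(t) during excitation.

    ``zeta(t) = 1 - exp(-t/tau_th)
    - A0 (tau - tau_th)^-1 [tau(1 - exp(-t/tau)) - tau_th(1 - exp(-t/tau_th))]``

    with the analytic limit used when tau and tau_th coincide to within
    1e-9 relative.
    """
    arr, scalar = _as_time_array(t)
    theta, g = grating_modes_on(arr, params.tau_th, params.tau)
    zeta = theta - params.a0 * g
    return float(zeta) if scalar else zeta


def heterodyne_intensity_off(
    t_off, params: SignalParams, state_at_off: Tuple[float, float] = (1.0, 1.0)
):
    """Normalized heterodyne intensity after the writing beams switch off.

    ``state_at_off`` is the (theta0, g0) pair at switch-off; the default
    assumes the grating reached steady state.
    """
    theta0, g0 = (float(v) for v in state_at_off)
    if not (math.isfinite(theta0) and math.isfinite(g0)):
        raise ValueError("state_at_off must be finite")
    if not 0.0 <= theta0 <= 1.0:
        raise ValueError(f"theta0 must be in [0, 1], got {theta0}")
    arr, scalar = _as_time_array(t_off)
    theta, g = grating_modes_off(arr, params.tau_th, params.tau, theta0, g0)
    zeta = theta - params.a0 * g
    return float(zeta) if scalar else zeta


def amplitude_to_soret(a0: float, contrast: ContrastFactors, c: float) -> float:
    """Convert the steady-state amplitude A0 to the Soret coefficient.

    Inverts ``A0 = (dn/dc)(dn/dT)^-1 S_T c (1 - c)``:

    ``S_T = A0 * dn_dT / (dn_dc * c * (1 - c))``  [1/K]
    """
    _check_finite("a0", a0)
    c = _check_finite("c", c)
    denom = contrast.dn_dc * c * (1.0 - c)
    if denom == 0:
        raise ZeroDivisionError("dn_dc * c * (1-c) must be nonzero")
    return a0 * contrast.dn_dT / denom


def soret_to_amplitude(s_t: float, contrast: ContrastFactors, c: float) -> float:
    """Steady-state amplitude A0 produced by Soret coefficient ``s_t``."""
    _check_finite("s_t", s_t)
    c = _check_finite("c", c)
    if contrast.dn_dT == 0:
        raise ZeroDivisionError("dn_dT must be nonzero to invert")
    return s_t * contrast.dn_dc * c * (1.0 - c) / contrast.dn_dT


def relaxation_to_diffusivity(tau_x: float, geometry: GratingGeometry) -> float:
    """Diffusivity from a grating relaxation time: ``1/(tau q^2)`` in m^2/s.

    Applied to the thermal time it yields the thermal diffusivity D_th, and
    to the mass time the diffusion coefficient D.
    """
    tau_x = _check_finite("tau_x", tau_x)
    if tau_x <= 0:
        raise ValueError("tau_x must be > 0")
    return 1.0 / (tau_x * geometry.q**2)


def soret_steady_state_gradient(s_t: float, c: float, grad_t: float) -> float:
    """Steady-state concentration gradient (1/m) for a temperature gradient.

    Setting the mass flux to zero gives
    ``grad c = -S_T c (1 - c) grad T``; for positive S_T the solute
    accumulates on the cold side.
    """
    _check_finite("s_t", s_t)
    _check_finite("c", c)
    _check_finite("grad_t", grad_t)
    return -s_t * c * (1.0 - c) * grad_t


def thermal_diffusion_coefficient(s_t: float, d: float) -> float:
    """Thermal diffusion coefficient ``D_T = S_T * D`` in m^2/(s K)."""
    _check_finite("s_t", s_t)
    _check_finite("d", d)
    return s_t * d
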