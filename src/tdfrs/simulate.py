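"""Synthetic-data generation for every stage of the analysis pipeline.

Three generators, all seeded and deterministic:

* heterodyne shot sets — the two-mode grating dynamics integrated with a
  fixed-step RK4 scheme (independent of the closed-form model used for
  fitting), plus i.i.d. Gaussian per-sample shot noise;
* S_T(T) point sets drawn from the empirical temperature law;
* condition sets with a linear delta_S_T versus helicity relation mirroring
  the apomyoglobin pH/buffer series.

The default physical constants emulate the study conditions: a ~17 kDa
globular protein (D = 1.1e-10 m^2/s) in water (D_th = 1.45e-7 m^2/s) at
7 mg/mL (weight fraction 0.007), optical contrast dn/dT = -1.0e-4 1/K and
dn/dc = 0.17, a grating with thermal relaxation time 1 ms, 3000 shots per
average and per-shot noise sd 0.01.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .conditions import ConditionRecord
from .core import ContrastFactors, GratingGeometry, SignalParams, soret_to_amplitude
from .signals import HeterodyneTrace, TraceMetadata
from .soret import SoretCurveParams, SoretPoint

__all__ = [
    "ResolutionError",
    "SimulationConfig",
    "ConditionGeneratorConfig",
    "study_geometry",
    "study_contrast",
    "study_signal_params",
    "simulate_shot_set",
    "simulate_averaged_trace",
    "generate_soret_dataset",
    "generate_condition_set",
    "DEFAULT_TEMPERATURES_C",
    "TABLE1_HELIX_VALUES",
    "TABLE1_LABELS",
]

# Study-condition constants (see docs/methods.md)
WATER_THERMAL_DIFFUSIVITY = 1.45e-7   # m^2/s
PROTEIN_DIFFUSIVITY = 1.1e-10         # m^2/s, ~17 kDa globular protein
STUDY_DN_DT = -1.0e-4                 # 1/K
STUDY_DN_DC = 0.17                    # dimensionless (per weight fraction)
STUDY_WEIGHT_FRACTION = 0.007         # 7 mg/mL
STUDY_TAU_TH = 1e-3                   # s, thermal relaxation of the grating

DEFAULT_TEMPERATURES_C = tuple(range(15, 50, 5))  # 15..45 C in 5 C steps

# Table of apomyoglobin condition labels and alpha-helix contents (percent)
TABLE1_LABELS = (
    "pH 6",
    "pH 6, 20 mM NaP",
    "pH 4",
    "pH 4, 20 mM NaAc",
    "pH 4, 10 mM NaAc",
    "pH 2",
)
TABLE1_HELIX_VALUES = (51.0, 50.0, 43.0, 34.0, 33.0, 4.0)
_TABLE1_META = {
    "pH 6": (6.0, "", 0.0),
    "pH 6, 20 mM NaP": (6.0, "NaP", 20.0),
    "pH 4": (4.0, "", 0.0),
    "pH 4, 20 mM NaAc": (4.0, "NaAc", 20.0),
    "pH 4, 10 mM NaAc": (4.0, "NaAc", 10.0),
    "pH 2": (2.0, "", 0.0),
}


class ResolutionError(ValueError):
    """Sampling interval too coarse to resolve the thermal rise."""


def study_geometry(tau_th: float = STUDY_TAU_TH) -> GratingGeometry:
    """Grating geometry whose thermal relaxation in water equals ``tau_th``."""
    q = math.sqrt(1.0 / (WATER_THERMAL_DIFFUSIVITY * tau_th))
    return GratingGeometry(q=q)


def study_contrast() -> ContrastFactors:
    return ContrastFactors(dn_dT=STUDY_DN_DT, dn_dc=STUDY_DN_DC)


def study_signal_params(s_t: float, tau_th: float = STUDY_TAU_TH) -> SignalParams:
    """Signal parameters for a given Soret coefficient at study conditions.

    The mass relaxation time follows from the physical ratio
    ``tau / tau_th = D_th / D``; the amplitude from the contrast factors and
    weight fraction.
    """
    tau = tau_th * WATER_THERMAL_DIFFUSIVITY / PROTEIN_DIFFUSIVITY
    a0 = soret_to_amplitude(s_t, study_contrast(), STUDY_WEIGHT_FRACTION)
    return SignalParams(tau_th=tau_th, tau=tau, a0=a0)


@dataclass(frozen=True)
class SimulationConfig:
    """Excitation schedule, sampling and noise of one simulated experiment."""

    params: SignalParams
    t_on: float = 0.5            # s, excitation duration
    t_off: float = 0.5           # s, observed decay after switch-off
    dt: float = 1e-4             # s, sampling interval
    noise_sd: float = 0.01       # per-shot Gaussian noise sd
    n_shots: int = 3000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.t_on <= 0 or self.t_off <= 0:
            raise ValueError("excitation durations must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_shots < 1:
            raise ValueError("n_shots must be >= 1")
        if self.dt > self.params.tau_th / 10.0:
            raise ResolutionError(
                f"dt={self.dt} does not resolve tau_th={self.params.tau_th}: "
                "need dt <= tau_th/10"
            )


def _rk4_affine_step(a: np.ndarray, b: np.ndarray, h: float) -> Tuple[np.ndarray, np.ndarray]:
    """One classical RK4 step of the linear system y' = A y + b as an affine map.

    For constant A, b the RK4 update is exactly
    ``y_{n+1} = M y_n + c`` with ``M = sum_{k=0..4} (hA)^k / k!`` and
    ``c = (h I + h^2 A/2 + h^3 A^2/6 + h^4 A^3/24) b``.
    """
    eye = np.eye(a.shape[0])
    ha = h * a
    m = eye + ha @ (eye + ha @ (eye / 2 + ha @ (eye / 6 + ha / 24)))
    c = h * (eye + ha @ (eye / 2 + ha @ (eye / 6 + ha @ eye / 24))) @ b
    return m, c


def _compose(m: np.ndarray, c: np.ndarray, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """k-fold composition of the affine map (M, c)."""
    mk = np.eye(m.shape[0])
    ck = np.zeros(m.shape[0])
    for _ in range(k):
        ck = m @ ck + c
        mk = m @ mk
    return mk, ck


def _rk4_base(config: SimulationConfig) -> Tuple[np.ndarray, np.ndarray]:
    """Noiseless zeta(t) over on + off phases by fixed-step RK4.

    Substep ``h <= tau_th/50`` aligned with the sampling grid; the switch-off
    time is snapped to the nearest sample.
    """
    p = config.params
    a = np.array([[-1.0 / p.tau_th, 0.0], [1.0 / p.tau, -1.0 / p.tau]])
    b_on = np.array([1.0 / p.tau_th, 0.0])
    b_off = np.zeros(2)
    n_on = max(int(round(config.t_on / config.dt)), 1)
    n_off = max(int(round(config.t_off / config.dt)), 1)
    n = n_on + n_off
    times = np.arange(n + 1) * config.dt
    k = max(int(math.ceil(config.dt / (p.tau_th / 50.0))), 1)
    h = config.dt / k
    m_on, c_on = _compose(*_rk4_affine_step(a, b_on, h), k)
    m_off, c_off = _compose(*_rk4_affine_step(a, b_off, h), k)
    y = np.zeros(2)
    out = np.empty((n + 1, 2))
    out[0] = y
    for i in range(1, n + 1):
        if i <= n_on:
            y = m_on @ y + c_on
        else:
            y = m_off @ y + c_off
        out[i] = y
    zeta = out[:, 0] - p.a0 * out[:, 1]
    return times, zeta


def _metadata(config: SimulationConfig) -> TraceMetadata:
    n_on = max(int(round(config.t_on / config.dt)), 1)
    return TraceMetadata(t_excitation_off_s=n_on * config.dt)


def simulate_shot_set(config: SimulationConfig) -> List[HeterodyneTrace]:
    """Simulate individual noisy shots of one grating experiment.

    Deterministic for a fixed seed; the noiseless dynamics come from the RK4
    integrator, independent of the closed-form model used for fitting.
    """
    times, zeta = _rk4_base(config)
    rng = np.random.default_rng(config.seed)
    meta = _metadata(config)
    shots = []
    noise = rng.normal(0.0, config.noise_sd, size=(config.n_shots, zeta.size)) \
        if config.noise_sd > 0 else np.zeros((config.n_shots, zeta.size))
    for i in range(config.n_shots):
        shots.append(HeterodyneTrace(times.copy(), zeta + noise[i], None, meta))
    return shots


def simulate_averaged_trace(config: SimulationConfig, chunk: int = 256) -> HeterodyneTrace:
    """Shot-averaged trace with per-point standard errors, memory-bounded.

    Statistically identical to averaging :func:`simulate_shot_set` output
    (same noise stream, consumed in chunks of shots).
    """
    times, zeta = _rk4_base(config)
    n = zeta.size
    rng = np.random.default_rng(config.seed)
    if config.noise_sd == 0:
        return HeterodyneTrace(times, zeta.copy(), np.zeros(n), _metadata(config))
    total = np.zeros(n)
    total_sq = np.zeros(n)
    remaining = config.n_shots
    while remaining > 0:
        m = min(chunk, remaining)
        block = rng.normal(0.0, config.noise_sd, size=(m, n))
        block += zeta
        total += block.sum(axis=0)
        total_sq += (block**2).sum(axis=0)
        remaining -= m
    mean = total / config.n_shots
    if config.n_shots > 1:
        var = (total_sq - config.n_shots * mean**2) / (config.n_shots - 1)
        sd = np.sqrt(np.maximum(var, 0.0) / config.n_shots)
    else:
        sd = np.zeros(n)
    return HeterodyneTrace(times, mean, sd, _metadata(config))


def generate_soret_dataset(
    true_params: SoretCurveParams,
    temperatures_c: Optional[Sequence[float]] = None,
    noise_sd: float = 0.001,
    seed: int = 0,
) -> List[SoretPoint]:
    """S_T(T) points from the empirical law plus Gaussian noise.

    Default grid 15 to 45 C in steps of 5 C (seven points).
    """
    if temperatures_c is None:
        temperatures_c = DEFAULT_TEMPERATURES_C
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    points = []
    for t in temperatures_c:
        val = true_params.s_inf + true_params.a * math.exp(-t / true_params.t0)
        if noise_sd > 0:
            val += rng.normal(0.0, noise_sd)
        points.append(SoretPoint(temperature_c=float(t), s_t=float(val),
                                 sigma=noise_sd if noise_sd > 0 else None))
    return points


@dataclass(frozen=True)
class ConditionGeneratorConfig:
    """Linear delta_S_T versus helicity generator mirroring the pH series.

    Defaults: slope 5e-4 (1/K per % helix) and intercept -2e-3 1/K span the
    few-1e-2 1/K sensitivity range typical of proteins over the Table-1 helix
    values; helicity jitter 2% and delta_S_T noise 2e-3 1/K match the
    reported measurement uncertainties.
    """

    slope: float = 5e-4          # 1/K per % helix
    intercept: float = -2e-3     # 1/K
    helix_values: Tuple[float, ...] = TABLE1_HELIX_VALUES
    labels: Tuple[str, ...] = TABLE1_LABELS
    helix_sd: float = 2.0        # %
    delta_st_sd: float = 2e-3    # 1/K
    seed: int = 0

    def __post_init__(self) -> None:
        if self.helix_sd < 0 or self.delta_st_sd < 0:
            raise ValueError("noise sds must be >= 0")
        if len(self.labels) != len(self.helix_values):
            raise ValueError("labels and helix_values must have equal length")


def generate_condition_set(config: ConditionGeneratorConfig) -> List[ConditionRecord]:
    """Condition records with a linear delta_S_T - helicity relation."""
    rng = np.random.default_rng(config.seed)
    records = []
    for label, helix_true in zip(config.labels, config.helix_values):
        ph, buffer_label, conc = _TABLE1_META.get(label, (float("nan"), "", 0.0))
        helix = helix_true
        if config.helix_sd > 0:
            helix = float(np.clip(helix_true + rng.normal(0.0, config.helix_sd), 0.0, 100.0))
        delta = config.slope * helix_true + config.intercept
        if config.delta_st_sd > 0:
            delta += rng.normal(0.0, config.delta_st_sd)
        records.append(
            ConditionRecord(
                label=label,
                ph=ph,
                buffer_label=buffer_label,
                buffer_conc_mm=conc,
                helix_pct=helix,
                helix_sd=config.helix_sd,
                delta_st=float(delta),
                delta_st_sd=config.delta_st_sd if config.delta_st_sd > 0 else None,
            )
        )
    return records
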