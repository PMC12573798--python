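"""End-to-end analysis pipeline tying the stages together.

For each trace: normalize to the thermal plateau, split into excitation-on
and -off phases, fit both phases with the two-mode model, convert to
transport coefficients; then pool repeated fits per (condition, temperature),
fit the empirical S_T(T) law per condition, compute the temperature
sensitivity delta_S_T, and correlate it against the condition table's
alpha-helical contents.  Failures are logged and counted, never fatal: an
experiment pools several fits per point and must survive individual bad
traces.
"""

from __future__ import annotations

import json
import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .conditions import ConditionRecord, correlate_conditions, rank_by_sensitivity
from .io import read_conditions, read_trace, write_conditions
from .signals import (
    HeterodyneTrace,
    derive_transport,
    fit_signal,
    normalize_trace,
    pool_estimates,
    split_phases,
)
from .soret import SoretPoint, delta_st, fit_soret_curve

__all__ = ["RunConfig", "run_pipeline", "write_report"]

logger = logging.getLogger("tdfrs")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    trace_paths: Tuple[str, ...] = ()
    conditions_path: Optional[str] = None
    out_dir: Optional[str] = None
    t_low: float = 15.0
    t_high: float = 40.0
    delta_mode: str = "auto"
    trace_defaults: Optional[Dict[str, float]] = None
    seed: int = 0
    verbose: bool = False


def _condition_key(trace: HeterodyneTrace) -> str:
    m = trace.metadata
    buf = m.buffer_label or "unbuffered"
    return f"pH {m.ph:g}, {buf}" if m.ph is not None else buf


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and return a JSON-serializable report."""
    if config.verbose:
        logging.basicConfig(level=logging.INFO)
    counts = {
        "traces_read": 0,
        "traces_failed": 0,
        "fits_converged": 0,
        "fits_flagged": 0,
        "conditions_correlated": 0,
    }
    # (condition, temperature) -> list of per-fit S_T / D values
    st_pool: Dict[Tuple[str, float], List[float]] = defaultdict(list)
    d_pool: Dict[Tuple[str, float], List[float]] = defaultdict(list)
    failures: List[dict] = []

    for path in config.trace_paths:
        try:
            trace = read_trace(path, defaults=config.trace_defaults)
            counts["traces_read"] += 1
            trace = normalize_trace(trace)
            t_switch = trace.metadata.t_excitation_off_s
            phases = []
            if t_switch is not None and trace.times[0] < t_switch < trace.times[-1]:
                on, off = split_phases(trace, t_switch)
                phases = [(on, "on"), (off, "off")]
            else:
                phases = [(trace, "on")]
            for sub, phase in phases:
                fit = fit_signal(sub, phase=phase)
                if fit.converged:
                    counts["fits_converged"] += 1
                else:
                    counts["fits_flagged"] += 1
                    continue
                m = trace.metadata
                if m.geometry is None or m.contrast is None or m.c is None:
                    raise ValueError("trace metadata incomplete for transport derivation")
                tc = derive_transport(fit, m.geometry, m.contrast, m.c)
                key = (_condition_key(trace), float(m.temperature_c))
                st_pool[key].append(tc.s_t)
                d_pool[key].append(tc.d)
        except Exception as exc:
            counts["traces_failed"] += 1
            failures.append({"trace": str(path), "error": str(exc)})
            logger.warning("trace %s failed: %s", path, exc)

    # pool and fit the temperature law per condition
    per_condition: Dict[str, dict] = {}
    points_by_condition: Dict[str, List[SoretPoint]] = defaultdict(list)
    for (cond, temp), values in sorted(st_pool.items()):
        pooled = pool_estimates(values)
        points_by_condition[cond].append(
            SoretPoint(temperature_c=temp, s_t=pooled.mean,
                       sigma=pooled.sem if pooled.sem > 0 else None)
        )
        per_condition.setdefault(cond, {"soret_points": []})
        per_condition[cond]["soret_points"].append(
            {"temperature_C": temp, "S_T": pooled.mean, "sem": pooled.sem, "n": pooled.n}
        )
        dp = pool_estimates(d_pool[(cond, temp)])
        per_condition[cond].setdefault("diffusion_points", []).append(
            {"temperature_C": temp, "D": dp.mean, "sem": dp.sem, "n": dp.n}
        )

    delta_by_condition: Dict[str, Tuple[float, Optional[float]]] = {}
    for cond, points in sorted(points_by_condition.items()):
        entry = per_condition[cond]
        temps = [p.temperature_c for p in points]
        if len(points) >= 4 and max(temps) - min(temps) >= 15.0:
            fit = fit_soret_curve(points)
            p = fit.params
            entry["curve_fit"] = {
                "S_T_inf": p.s_inf,
                "A": p.a,
                "T0": p.t0,
                "T_star": p.t_star,
                "converged": fit.converged,
                "residual_rms": fit.residual_rms,
            }
        try:
            d = delta_st(points, config.t_low, config.t_high, mode=config.delta_mode)
            entry["delta_ST"] = {"value": d.value, "sigma": d.sigma, "mode": d.mode,
                                 "t_low": d.t_low, "t_high": d.t_high}
            delta_by_condition[cond] = (d.value, d.sigma)
        except ValueError as exc:
            entry["delta_ST"] = {"error": str(exc)}
            logger.warning("delta_ST for %s failed: %s", cond, exc)

    report: dict = {"counts": counts, "failures": failures, "conditions": per_condition}

    # correlation against the helix-content table
    if config.conditions_path is not None:
        records = read_conditions(config.conditions_path)
        merged: List[ConditionRecord] = []
        for rec in records:
            if rec.delta_st is None and rec.label in delta_by_condition:
                value, sigma = delta_by_condition[rec.label]
                rec = ConditionRecord(
                    label=rec.label, ph=rec.ph, buffer_label=rec.buffer_label,
                    buffer_conc_mm=rec.buffer_conc_mm, helix_pct=rec.helix_pct,
                    helix_sd=rec.helix_sd, delta_st=value, delta_st_sd=sigma,
                )
            if rec.delta_st is not None:
                merged.append(rec)
        if len(merged) >= 3:
            rep = correlate_conditions(merged)
            counts["conditions_correlated"] = rep.n
            report["correlation"] = {
                "slope": rep.slope,
                "intercept": rep.intercept,
                "slope_sd": rep.slope_sd,
                "intercept_sd": rep.intercept_sd,
                "pearson_r": rep.pearson_r,
                "n": rep.n,
                "leave_one_out_slopes": rep.leave_one_out_slopes,
                "flagged_outliers": list(rep.flagged_outliers),
            }
            report["ranking"] = rank_by_sensitivity(merged)
        else:
            logger.warning("fewer than 3 conditions with delta_ST: no correlation")

    if not config.trace_paths:
        logger.warning("empty input set: nothing to analyze")

    logger.info(
        "pipeline: %d traces read, %d failed, %d fits converged, %d flagged, "
        "%d conditions correlated",
        counts["traces_read"], counts["traces_failed"], counts["fits_converged"],
        counts["fits_flagged"], counts["conditions_correlated"],
    )

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_report(out / "report.json", report)
    return report


def write_report(path, report: dict) -> None:
    """Write a report deterministically (sorted keys, fixed float repr)."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
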