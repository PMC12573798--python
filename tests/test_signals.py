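"""Shot averaging, normalization, phase splitting, nonlinear fitting and
pooling of heterodyne traces, checked against the seeded generator."""

import numpy as np
import pytest

from tdfrs.core import SignalParams, heterodyne_intensity
from tdfrs.signals import (
    DegenerateSignalError,
    HeterodyneSignalModel,
    HeterodyneTrace,
    average_shots,
    fit_signal,
    normalize_trace,
    pool_estimates,
    split_phases,
)
from tdfrs.simulate import SimulationConfig, simulate_averaged_trace


def make_on_trace(tau_th=1e-3, tau=0.1, a0=0.6, t_max=0.5, dt=1e-4, scale=1.0):
    p = SignalParams(tau_th=tau_th, tau=tau, a0=a0)
    t = np.arange(0.0, t_max + dt / 2, dt)
    return HeterodyneTrace(t, scale * heterodyne_intensity(t, p))


class TestAverageShots:
    def test_single_shot_identity(self):
        tr = make_on_trace()
        avg = average_shots([tr])
        assert np.array_equal(avg.values, tr.values)
        assert np.all(avg.per_point_sd == 0)

    def test_symmetric_shots_cancel(self):
        t = np.linspace(0, 1, 50)
        v = np.sin(t)
        a = HeterodyneTrace(t, v)
        b = HeterodyneTrace(t, -v)
        avg = average_shots([a, b])
        assert np.allclose(avg.values, 0.0)

    def test_standard_error_follows_shot_noise(self, rng):
        """3000 shots at noise sd 0.05 give per-point sd ~ 0.05/sqrt(3000)."""
        t = np.linspace(0, 1, 40)
        base = np.ones_like(t)
        sigma = 0.05
        shots = [HeterodyneTrace(t, base + rng.normal(0, sigma, t.size)) for _ in range(3000)]
        avg = average_shots(shots)
        expected = sigma / np.sqrt(3000)
        assert np.median(avg.per_point_sd) == pytest.approx(expected, rel=0.10)

    def test_order_invariant(self, rng):
        t = np.linspace(0, 1, 30)
        shots = [HeterodyneTrace(t, rng.normal(size=t.size)) for _ in range(10)]
        a = average_shots(shots)
        b = average_shots(shots[::-1])
        assert np.allclose(a.values, b.values)
        assert np.allclose(a.per_point_sd, b.per_point_sd)

    def test_mismatched_grids_rejected(self):
        a = HeterodyneTrace(np.linspace(0, 1, 30), np.zeros(30))
        b = HeterodyneTrace(np.linspace(0, 2, 30), np.zeros(30))
        with pytest.raises(ValueError):
            average_shots([a, b])


class TestNormalizeTrace:
    def test_unchanged_on_already_normalized_trace(self):
        tr = make_on_trace(tau=0.1, t_max=0.5)
        out = normalize_trace(tr)
        assert np.max(np.abs(out.values - tr.values)) < 1e-9

    def test_scale_invariance(self):
        tr = make_on_trace(tau=0.1, t_max=0.5)
        scaled = make_on_trace(tau=0.1, t_max=0.5, scale=3.7)
        a = normalize_trace(tr)
        b = normalize_trace(scaled)
        assert np.max(np.abs(a.values - b.values)) < 1e-9

    def test_noisy_plateau_within_one_percent(self, rng):
        tr = make_on_trace(tau=0.1, t_max=0.5, scale=1.8)
        noisy = HeterodyneTrace(tr.times, tr.values + rng.normal(0, 0.01, len(tr)))
        out = normalize_trace(noisy)
        # recovered scale (clean trace scale is 1.8) must be accurate to 1%
        scale_est = np.median(tr.values[-50:] / out.values[-50:])
        assert scale_est == pytest.approx(1.8, rel=0.01)

    def test_degenerate_signal_rejected(self):
        t = np.linspace(0, 1, 100)
        with pytest.raises(DegenerateSignalError):
            normalize_trace(HeterodyneTrace(t, -np.ones_like(t)))


class TestSplitPhases:
    def test_sample_conservation(self):
        tr = make_on_trace()
        on, off = split_phases(tr, tr.times[len(tr) // 2])
        assert len(on) + len(off) == len(tr)

    def test_prefix_preserved(self):
        tr = make_on_trace()
        on, _ = split_phases(tr, tr.times[1])
        assert np.array_equal(on.times, tr.times[:2])
        assert np.array_equal(on.values, tr.values[:2])

    def test_off_phase_rezeroed(self):
        tr = make_on_trace()
        t_switch = tr.times[100]
        _, off = split_phases(tr, t_switch)
        assert off.times[0] == pytest.approx(tr.times[101] - t_switch)
        assert off.metadata.t_excitation_off_s == t_switch

    def test_switch_time_outside_span_rejected(self):
        tr = make_on_trace(t_max=0.5)
        with pytest.raises(ValueError):
            split_phases(tr, 0.6)

    def test_on_off_fits_agree_within_two_sigma(self):
        """On- and off-phase fits of the same simulated experiment agree."""
        p = SignalParams(1e-3, 0.1, 0.6)
        cfg = SimulationConfig(params=p, t_on=0.5, t_off=0.5, dt=1e-4,
                               noise_sd=0.01, n_shots=500, seed=3)
        tr = simulate_averaged_trace(cfg)
        on, off = split_phases(tr, tr.metadata.t_excitation_off_s)
        f_on = fit_signal(on, "on")
        f_off = fit_signal(off, "off")
        for i, (a, b) in enumerate(
            zip((f_on.params.tau_th, f_on.params.tau, f_on.params.a0),
                (f_off.params.tau_th, f_off.params.tau, f_off.params.a0))
        ):
            joint = np.sqrt(f_on.covariance[i, i] + f_off.covariance[i, i])
            assert abs(a - b) < 2 * joint


class TestFitSignal:
    def test_noiseless_recovery(self):
        """Generator output refits to its own parameters (self-consistency)."""
        p = SignalParams(1e-3, 0.1, 0.6)
        cfg = SimulationConfig(params=p, t_on=0.5, t_off=0.001, dt=1e-4,
                               noise_sd=0.0, n_shots=1, seed=0)
        tr = simulate_averaged_trace(cfg)
        on, _ = split_phases(tr, tr.metadata.t_excitation_off_s)
        fit = fit_signal(on, "on")
        assert fit.converged
        assert fit.params.tau_th == pytest.approx(p.tau_th, rel=1e-4)
        assert fit.params.tau == pytest.approx(p.tau, rel=1e-4)
        assert fit.params.a0 == pytest.approx(p.a0, rel=1e-4)
        assert fit.residual_rms < 1e-8

    def test_null_amplitude_consistent_with_zero(self, rng):
        p = SignalParams(1e-3, 0.1, 1e-12)
        t = np.arange(0.0, 0.5, 1e-4)
        v = heterodyne_intensity(t, p) + rng.normal(0, 0.001, t.size)
        fit = fit_signal(HeterodyneTrace(t, v), "on")
        se_a0 = np.sqrt(fit.covariance[2, 2])
        assert abs(fit.params.a0) < 3 * se_a0

    def test_estimator_consistency_with_noise_level(self):
        """RMS parameter error shrinks as the noise level drops."""
        p = SignalParams(1e-3, 0.1, 0.6)
        truth = np.array([p.tau_th, p.tau, p.a0])
        rms = []
        bias = []
        for sigma in (0.05, 0.01, 0.002):
            errs = []
            for seed in range(50):
                cfg = SimulationConfig(params=p, t_on=0.5, t_off=0.001, dt=1e-4,
                                       noise_sd=sigma, n_shots=1, seed=seed)
                tr = simulate_averaged_trace(cfg)
                on, _ = split_phases(tr, tr.metadata.t_excitation_off_s)
                fit = fit_signal(on, "on")
                est = np.array([fit.params.tau_th, fit.params.tau, fit.params.a0])
                errs.append((est - truth) / truth)
            errs = np.array(errs)
            rms.append(np.sqrt(np.mean(errs**2, axis=0)))
            bias.append(np.abs(np.mean(errs, axis=0)))
        rms = np.array(rms)
        assert np.all(rms[0] > rms[1]) and np.all(rms[1] > rms[2])
        # bias vanishes with the noise: smallest-noise bias below largest-noise
        assert np.all(bias[2] < bias[0])

    def test_too_few_samples_rejected(self):
        t = np.linspace(0, 1, 10)
        with pytest.raises(ValueError):
            fit_signal(HeterodyneTrace(t, np.ones_like(t)), "on")

    def test_estimator_sklearn_interface(self):
        from sklearn.base import clone

        est = HeterodyneSignalModel(phase="off", t_on=0.5)
        params = est.get_params()
        assert params["phase"] == "off" and params["t_on"] == 0.5
        est2 = clone(est)
        assert est2.get_params() == params
        tr = make_on_trace()
        est3 = HeterodyneSignalModel().fit(tr.times, tr.values)
        pred = est3.predict(tr.times)
        assert np.max(np.abs(pred - tr.values)) < 1e-6


class TestPoolEstimates:
    def test_single_value(self):
        pe = pool_estimates([3.2])
        assert pe.mean == 3.2 and pe.sem == 0.0 and pe.n == 1

    def test_constant_values(self):
        pe = pool_estimates([1.0, 1.0, 1.0, 1.0])
        assert pe.mean == 1.0 and pe.sem == 0.0

    def test_textbook_sem(self):
        pe = pool_estimates([1.0, 2.0, 3.0, 4.0])
        assert pe.mean == pytest.approx(2.5)
        assert pe.sem == pytest.approx(np.std([1, 2, 3, 4], ddof=1) / 2, rel=1e-12)
        assert pe.sem == pytest.approx(0.6455, abs=1e-4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pool_estimates([])
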