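"""Velocity direction, filtering, delay estimation and the OU delay model."""

import numpy as np
import pytest
from scipy import signal as sps

from shoulderline import dynamics as dyn
from shoulderline import synthgen as sg


def _traj(vx, vy, n=120, rate=30.0, pid="p"):
    t = np.arange(n) / rate
    return dyn.Trajectory(pid, t, vx * t, vy * t)


class TestVelocityDirection:
    @pytest.mark.parametrize(
        "vx,vy,expected_deg",
        [(0.0, 1.4, 0.0), (1.4, 0.0, 90.0), (0.0, -1.4, 0.0)],
    )
    def test_reference_directions(self, vx, vy, expected_deg):
        # +y -> 0; +x -> the wrap point (+-90 is one point of P1); -y -> 0
        sig = dyn.velocity_direction(_traj(vx, vy))
        wrapped = np.rad2deg(np.abs(sig.wrapped()))
        assert np.allclose(wrapped, abs(expected_deg), atol=1e-9)

    def test_all_slow_samples_error(self):
        with pytest.raises(ValueError):
            dyn.velocity_direction(_traj(0.0, 0.001))

    def test_slow_samples_flagged(self):
        t = np.arange(200) / 30.0
        x = np.where(t < 3, 0.0, 1.3 * (t - 3))  # standing then walking
        traj = dyn.Trajectory("q", t, x, np.zeros_like(t))
        sig = dyn.velocity_direction(traj)
        assert sig.low_confidence[: 80].all()
        assert not sig.low_confidence[100:].any()


class TestLowpass:
    def test_constant_unchanged(self):
        sig = dyn.OrientationSignal(np.arange(300) / 30.0, np.full(300, 0.7), 30.0)
        out = dyn.lowpass(sig)
        assert np.allclose(out.theta, 0.7, atol=1e-9)

    def test_sinusoid_attenuation_matches_closed_form(self):
        # zero-phase (forward-backward) first-order response: gain |H(f)|^2
        rate, f0 = 30.0, 10.0
        t = np.arange(3000) / rate
        sig = dyn.OrientationSignal(t, np.sin(2 * np.pi * f0 * t), rate)
        out = dyn.lowpass(sig)
        measured = out.theta[500:-500].std() / sig.theta[500:-500].std()
        w = np.pi * f0 / (rate / 2)
        _, h = sps.sosfreqz(
            sps.butter(1, 2.0, btype="low", fs=rate, output="sos"), worN=[w]
        )
        assert measured == pytest.approx(abs(h[0]) ** 2, rel=0.02)

    def test_walking_sway_passes_with_known_gain(self):
        # 0.8 Hz sway survives the 2 Hz cutoff with the closed-form filtfilt
        # gain |H|^2 ~ 0.86 for the first-order digital filter
        rate, f0 = 30.0, 0.8
        t = np.arange(3000) / rate
        sig = dyn.OrientationSignal(t, np.sin(2 * np.pi * f0 * t), rate)
        out = dyn.lowpass(sig)
        measured = out.theta[500:-500].std() / sig.theta[500:-500].std()
        w = np.pi * f0 / (rate / 2)
        _, h = sps.sosfreqz(
            sps.butter(1, 2.0, btype="low", fs=rate, output="sos"), worN=[w]
        )
        assert measured == pytest.approx(abs(h[0]) ** 2, rel=0.02)
        assert measured > 0.8

    def test_white_noise_variance_reduced(self):
        rng = np.random.default_rng(0)
        sig = dyn.OrientationSignal(np.arange(2000) / 30.0, rng.standard_normal(2000), 30.0)
        assert dyn.lowpass(sig).theta.var() < sig.theta.var()

    def test_short_signal_rejected(self):
        sig = dyn.OrientationSignal(np.arange(40) / 30.0, np.zeros(40), 30.0)
        with pytest.raises(ValueError):
            dyn.lowpass(sig)


class TestDelayEstimation:
    def test_constructed_three_sample_shift(self):
        sig = sg.generate_orientation_signal(60, rng=5)
        shifted = np.empty_like(sig.theta)
        shifted[3:] = sig.theta[:-3]
        shifted[:3] = sig.theta[0]
        sv = dyn.OrientationSignal(sig.t, shifted, sig.rate_hz)
        est = dyn.estimate_delay(sig, sv)
        assert est.mean_s == pytest.approx(0.100, abs=0.001)

    def test_zero_shift(self):
        sig = sg.generate_orientation_signal(60, rng=6)
        est = dyn.estimate_delay(sig, sig)
        assert abs(est.mean_s) < 0.001

    def test_delay_spread_grows_with_noise_intensity(self):
        sds = []
        for xi in (0.0, 0.5, 1.85):
            params = dyn.OUDelayParams(A=1.0, xi=xi, xi_relative=True)
            pooled = []
            for s in range(10):
                sig = sg.generate_orientation_signal(60, rng=300 + s)
                tv = dyn.synthesize_velocity_direction(sig, params, rng=400 + s)
                i0 = int(round((tv.t[0] - sig.t[0]) * 30))
                base = dyn.OrientationSignal(tv.t, sig.theta[i0 : i0 + tv.t.size], 30.0)
                pooled.append(dyn.estimate_delay(base, tv).delays_s)
            sds.append(np.concatenate(pooled).std())
        assert sds[0] < sds[1] < sds[2]


class TestOUSimulation:
    def test_deterministic_relaxation_without_noise(self):
        p = dyn.OUDelayParams(d_hat_s=0.08, tau_s=1.2, xi=0.0)
        sig = dyn.simulate_ou_delay(p, 10.0, rng=0)
        # starts exactly at d_hat (stationary law collapses) -> stays there
        assert np.allclose(sig.theta, 0.08, atol=1e-12)
        # explicit off-equilibrium start relaxes with time constant tau
        d = np.empty(601)
        d[0] = 0.08 + 0.5
        dt = 1.0 / 30
        for i in range(600):
            d[i + 1] = d[i] - (d[i] - 0.08) * dt / 1.2
        k = int(round(1.2 / dt))
        assert d[k] - 0.08 == pytest.approx(0.5 * np.exp(-1.0), rel=0.02)

    def test_stationary_moments(self):
        p = dyn.OUDelayParams()  # d=0.08, tau=1.2, xi=1.85 absolute
        ds = [dyn.simulate_ou_delay(p, 500.0, rng=s).theta for s in range(6)]
        d = np.concatenate(ds)
        target_var = p.xi**2 * p.tau_s / 2
        # standard errors for an OU time average over T with 6 seeds
        se_mean = np.sqrt(target_var) * np.sqrt(2 * p.tau_s / 500.0) / np.sqrt(6)
        assert abs(d.mean() - p.d_hat_s) < 3 * se_mean
        se_var = target_var * np.sqrt(2 * 2 * p.tau_s / 500.0) / np.sqrt(6)
        assert abs(d.var() - target_var) < 3 * se_var

    def test_dt_validation(self):
        p = dyn.OUDelayParams(tau_s=1.2)
        with pytest.raises(ValueError):
            dyn.simulate_ou_delay(p, 10.0, dt_s=1.5)
        with pytest.warns(UserWarning):
            dyn.simulate_ou_delay(p, 10.0, dt_s=0.2)


class TestSynthesis:
    def test_identity_when_no_delay_no_noise(self):
        sig = sg.generate_orientation_signal(30, rng=1)
        p = dyn.OUDelayParams(A=1.0, d_hat_s=0.0, xi=0.0)
        tv = dyn.synthesize_velocity_direction(sig, p, rng=0)
        assert np.allclose(tv.theta, sig.theta[: tv.theta.size], atol=1e-12)

    def test_constant_delay_round_trip(self):
        sig = sg.generate_orientation_signal(60, rng=2)
        p = dyn.OUDelayParams(A=1.0, d_hat_s=0.1, xi=0.0)
        tv = dyn.synthesize_velocity_direction(sig, p, rng=0)
        i0 = int(round((tv.t[0] - sig.t[0]) * 30))
        base = dyn.OrientationSignal(tv.t, sig.theta[i0 : i0 + tv.t.size], 30.0)
        est = dyn.estimate_delay(base, tv)
        assert est.mean_s == pytest.approx(0.100, abs=0.002)

    def test_shift_theorem_psd_scaling(self):
        # constant delay: PSD of the output is A^2 times the PSD of the input
        sig = sg.generate_orientation_signal(120, rng=3, drift=None, sway_amp_deg=10)
        A = 1.85
        p = dyn.OUDelayParams(A=A, d_hat_s=0.1, xi=0.0)
        tv = dyn.synthesize_velocity_direction(sig, p, rng=0)
        i0 = int(round((tv.t[0] - sig.t[0]) * 30))
        base = dyn.OrientationSignal(tv.t, sig.theta[i0 : i0 + tv.t.size], 30.0)
        f, p_in = dyn.grand_average_psd([base])
        _, p_out = dyn.grand_average_psd([tv])
        k = np.argmin(abs(f - 0.8))
        band = slice(max(k - 1, 0), k + 2)
        assert p_out[band].sum() == pytest.approx(A**2 * p_in[band].sum(), rel=0.05)

    def test_amplitude_applies_to_fluctuation_not_mean(self):
        sig = sg.generate_orientation_signal(
            30, mean_heading_rad=0.7, sway_amp_deg=5, drift=None, rng=4
        )
        p = dyn.OUDelayParams(A=1.85, d_hat_s=0.0, xi=0.0)
        tv = dyn.synthesize_velocity_direction(sig, p, rng=0)
        # mean heading preserved, fluctuation amplified by A
        assert tv.theta.mean() == pytest.approx(sig.theta.mean(), abs=1e-3)
        assert tv.theta.std() == pytest.approx(1.85 * sig.theta.std(), rel=0.01)


class TestGrandAveragePSD:
    def test_parseval(self):
        sigs = [sg.generate_orientation_signal(60, rng=800 + s) for s in range(30)]
        f, p = dyn.grand_average_psd(sigs)
        var = np.mean([s.theta.var() for s in sigs])
        assert np.trapezoid(p, f) == pytest.approx(var, rel=0.05)

    def test_mixed_rates_rejected(self):
        a = dyn.OrientationSignal(np.arange(100) / 30.0, np.zeros(100), 30.0)
        b = dyn.OrientationSignal(np.arange(100) / 25.0, np.zeros(100), 25.0)
        with pytest.raises(ValueError):
            dyn.grand_average_psd([a, b])


class TestParameterRecovery:
    def test_amplitude_and_delay_recovery_round_trip(self):
        # synthesize with the reference parameters, recover A within 10% and
        # the mean delay within 15%
        params = dyn.reference_normal_walking()
        num = den = 0.0
        delays = []
        for s in range(30):
            sig = sg.generate_orientation_signal(60, rng=500 + s)
            tv = dyn.synthesize_velocity_direction(sig, params, rng=600 + s)
            yv = np.interp(sig.t, tv.t - params.d_hat_s, tv.theta)
            ok = (sig.t >= tv.t[0] - params.d_hat_s) & (sig.t <= tv.t[-1] - params.d_hat_s)
            yy = yv[ok] - yv[ok].mean()
            xx = sig.theta[ok] - sig.theta[ok].mean()
            num += np.dot(xx, yy)
            den += np.dot(xx, xx)
            i0 = int(round((tv.t[0] - sig.t[0]) * 30))
            base = dyn.OrientationSignal(tv.t, sig.theta[i0 : i0 + tv.t.size], 30.0)
            delays.append(dyn.estimate_delay(dyn.lowpass(base), dyn.lowpass(tv)).delays_s)
        assert num / den == pytest.approx(params.A, rel=0.10)
        assert np.concatenate(delays).mean() == pytest.approx(params.d_hat_s, rel=0.15)


class TestSpeedBinnedDelays:
    def test_imposed_speed_dependent_delay_recovered_monotone(self):
        # cohort with delay falling 160 -> 100 ms as speed rises
        records = []
        for k, (v_hat, d0) in enumerate([(0.7, 0.16), (1.0, 0.13), (1.3, 0.10)]):
            for s in range(4):
                sig = sg.generate_orientation_signal(60, rng=700 + 10 * k + s)
                p = dyn.OUDelayParams(A=1.0, d_hat_s=d0, xi=0.3, xi_relative=True)
                tv = dyn.synthesize_velocity_direction(sig, p, rng=900 + 10 * k + s)
                i0 = int(round((tv.t[0] - sig.t[0]) * 30))
                base = dyn.OrientationSignal(tv.t, sig.theta[i0 : i0 + tv.t.size], 30.0)
                records.append((v_hat, base, tv))
        table = dyn.delay_statistics_by_speed(records, [0.6, 0.9, 1.2, 1.5])
        assert len(table) == 3
        means = table["mean_delay_s"].to_numpy()
        assert means[0] > means[1] > means[2]
        # sd/mean column is consistent with its definition
        assert np.allclose(
            table["sd_over_mean"], table["sd_delay_s"] / table["mean_delay_s"]
        )

    def test_single_group_single_row(self):
        sig = sg.generate_orientation_signal(60, rng=40)
        p = dyn.OUDelayParams(A=1.0, d_hat_s=0.1, xi=0.0)
        tv = dyn.synthesize_velocity_direction(sig, p, rng=0)
        i0 = int(round((tv.t[0] - sig.t[0]) * 30))
        base = dyn.OrientationSignal(tv.t, sig.theta[i0 : i0 + tv.t.size], 30.0)
        table = dyn.delay_statistics_by_speed([(1.0, base, tv)], [0.8, 1.2])
        assert len(table) == 1
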