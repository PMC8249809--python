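import numpy as np
import pytest

from renmm import (
    IntegrationSpec,
    ModelParameters,
    euler_maruyama_step,
    initial_state,
    simulate,
    srk4_step,
    system_rhs,
)
from renmm.features import detect_spikes, multitaper_psd


def _classic_rk4(y, params, dt):
    """Independent textbook RK4 step built on the public system_rhs."""
    k1 = system_rhs(y, params)
    k2 = system_rhs(y + 0.5 * dt * k1, params)
    k3 = system_rhs(y + 0.5 * dt * k2, params)
    k4 = system_rhs(y + dt * k3, params)
    return y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)


class TestSteppers:
    def test_zero_noise_srk4_equals_classical_rk4(self, quiet_params,
                                                  random_state):
        """With the diffusion off the stochastic step must reproduce the
        deterministic RK4 update to machine precision."""
        y = random_state.copy()
        dt = 0.1
        for _ in range(50):
            expected = _classic_rk4(y, quiet_params, dt)
            y = srk4_step(y, quiet_params, dt, rng=None)
            np.testing.assert_allclose(y, expected, rtol=1e-13, atol=1e-13)

    def test_zero_noise_euler_matches_explicit_euler(self, quiet_params,
                                                     random_state):
        dt = 0.05
        expected = random_state + dt * system_rhs(random_state, quiet_params)
        got = euler_maruyama_step(random_state, quiet_params, dt, rng=None)
        np.testing.assert_allclose(got, expected, rtol=1e-13, atol=1e-13)

    def test_same_seed_bitwise_identical(self, nominal_params, random_state):
        for stepper in (srk4_step, euler_maruyama_step):
            a = stepper(random_state, nominal_params, 0.1,
                        np.random.default_rng(42))
            b = stepper(random_state, nominal_params, 0.1,
                        np.random.default_rng(42))
            assert np.array_equal(a, b)

    def test_small_dt_euler_converges_to_rk4_trajectory(self, quiet_params):
        y0 = initial_state(quiet_params)
        horizon = 20.0  # ms
        y_rk = y0.copy()
        for _ in range(int(horizon / 0.1)):
            y_rk = srk4_step(y_rk, quiet_params, 0.1, rng=None)
        y_em = y0.copy()
        for _ in range(int(horizon / 0.002)):
            y_em = euler_maruyama_step(y_em, quiet_params, 0.002, rng=None)
        np.testing.assert_allclose(y_em, y_rk, rtol=1e-3, atol=1e-5)


class TestDeterministicConvergence:
    def test_halving_dt_changes_trajectory_below_tolerance(self, quiet_params):
        """60-s deterministic output changes by < 1e-4 mV RMS when dt is
        halved from the working 0.1 ms.  Checked in the contracting (low
        Mg-block, high h-conductance) regime: on the mixed-regime limit
        cycle pointwise comparison is ill-posed because tiny phase shifts
        accumulate."""
        stable = quiet_params.replace(mu=0.5, g_h=0.066)
        ref = simulate(stable, IntegrationSpec(
            duration=60.0, burn_in=0.0, seed=0, dt=0.1, keep_native=True))
        fine = simulate(stable, IntegrationSpec(
            duration=60.0, burn_in=0.0, seed=0, dt=0.05, keep_native=True))
        diff = ref.aux["vp_native"] - fine.aux["vp_native"][1::2]
        rms = np.sqrt(np.mean(diff ** 2))
        assert rms < 1e-4

    def test_empirical_drift_order_at_least_three_and_a_half(self,
                                                             quiet_params):
        """Log-log slope of the endpoint error against dt on the drift."""
        y0 = initial_state(quiet_params)
        # perturb to probe a transient, not the fixed point
        y0[3] -= 10.0
        horizon = 40.0  # ms

        def endpoint(dt):
            y = y0.copy()
            for _ in range(int(round(horizon / dt))):
                y = srk4_step(y, quiet_params, dt, rng=None)
            return y

        ref = endpoint(0.003125)
        dts = np.array([0.4, 0.2, 0.1, 0.05])
        errs = np.array([np.linalg.norm(endpoint(dt) - ref) for dt in dts])
        slope = np.polyfit(np.log(dts), np.log(errs), 1)[0]
        assert slope >= 3.5

    def test_noise_free_runs_bit_identical(self, quiet_params):
        spec = IntegrationSpec(duration=15.0, burn_in=5.0, seed=3)
        a = simulate(quiet_params, spec)
        b = simulate(quiet_params, spec)
        assert np.array_equal(a.samples, b.samples)


class TestSimulate:
    def test_output_length_and_rate(self, nominal_params):
        spec = IntegrationSpec(duration=22.0, burn_in=10.0, seed=0,
                               output_rate=200.0)
        eeg = simulate(nominal_params, spec)
        assert eeg.fs == 200.0
        assert abs(len(eeg.samples) - 12.0 * 200.0) <= 1
        assert np.all(np.isfinite(eeg.samples))

    def test_seed_reproducibility_and_difference(self, nominal_params):
        spec = IntegrationSpec(duration=15.0, burn_in=10.0, seed=11)
        a = simulate(nominal_params, spec)
        b = simulate(nominal_params, spec)
        c = simulate(nominal_params,
                     IntegrationSpec(duration=15.0, burn_in=10.0, seed=12))
        assert np.array_equal(a.samples, b.samples)
        assert not np.array_equal(a.samples, c.samples)

    def test_meta_carries_provenance(self, nominal_params):
        spec = IntegrationSpec(duration=12.0, burn_in=10.0, seed=5)
        eeg = simulate(nominal_params, spec)
        assert eeg.meta["seed"] == 5
        assert eeg.meta["params"]["intrinsic"]["mu"] == 2.0

    @pytest.mark.parametrize("mu,gh", [
        (0.1, 0.046), (0.1, 0.066), (3.0, 0.046), (3.0, 0.066), (1.55, 0.056),
    ])
    def test_bounded_over_sweep_box_with_noise(self, mu, gh):
        """No state explosion at the corners of the published sweep ranges."""
        p = ModelParameters().replace(mu=mu, g_h=gh)
        for seed in range(3):
            eeg = simulate(p, IntegrationSpec(duration=20.0, burn_in=5.0,
                                              seed=seed))
            assert np.all(np.isfinite(eeg.samples))
            assert np.max(np.abs(eeg.samples)) < 150.0

    def test_invalid_spec_rejected(self, nominal_params):
        with pytest.raises(ValueError):
            simulate(nominal_params,
                     IntegrationSpec(duration=5.0, burn_in=10.0))
        with pytest.raises(ValueError):
            simulate(nominal_params, IntegrationSpec(dt=-0.1, duration=20.0))

    def test_aux_traces_align_with_burn_in(self, nominal_params):
        spec = IntegrationSpec(duration=15.0, burn_in=10.0, seed=2,
                               record_aux=True)
        eeg = simulate(nominal_params, spec)
        assert eeg.aux["t"][0] >= 0.0
        assert eeg.aux["t"][-1] <= 5.0
        assert eeg.aux["q_pv"].shape == eeg.aux["t"].shape
        # population rates stay within the sigmoid bounds
        assert np.all(eeg.aux["q_pv"] >= 0)
        assert np.all(eeg.aux["q_pv"] <= 400e-3)


class TestCrossIntegratorStatistics:
    def test_euler_small_step_matches_srk4_statistics(self, nominal_params):
        """Spike rate and sigma power from fine-step Euler-Maruyama agree
        with the working SRK4 configuration within Monte-Carlo error."""
        seeds = range(4)
        stats = {}
        for method, dt in (("srk4", 0.1), ("euler", 0.01)):
            rates, sig = [], []
            for seed in seeds:
                spec = IntegrationSpec(duration=40.0, burn_in=10.0, seed=seed,
                                       dt=dt, method=method)
                eeg = simulate(nominal_params, spec)
                rates.append(detect_spikes(eeg.samples, eeg.fs).size * 2.0)
                spec_est = multitaper_psd(eeg.samples, eeg.fs)
                sig.append(spec_est.band_power(9.0, 16.0))
            stats[method] = (np.mean(rates), np.std(rates) + 1e-9,
                             np.mean(sig), np.std(sig) + 1e-12)
        r_s, sr_s, p_s, sp_s = stats["srk4"]
        r_e, sr_e, p_e, sp_e = stats["euler"]
        # means within 3 pooled standard errors
        n = len(list(seeds))
        assert abs(r_s - r_e) < 3 * np.hypot(sr_s, sr_e) / np.sqrt(n) + 3.0
        assert abs(np.log(p_s + 1e-12) - np.log(p_e + 1e-12)) < 1.0
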