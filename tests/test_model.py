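import numpy as np
import pytest
from scipy.integrate import solve_ivp

from renmm import (
    ModelParameters,
    delay_accel,
    firing_rate,
    h_current,
    h_gating_derivatives,
    initial_state,
    lk_current,
    mg_block,
    nmda_current,
    synapse_accel,
    system_rhs,
    t_current,
)
from renmm.model import (
    IntegrationFailure,
    N_STATE,
    StateIndex as S,
    _h_minf,
)


# ---------------------------------------------------------------------------
# voltage-to-rate sigmoid
# ---------------------------------------------------------------------------

class TestFiringRate:
    def test_midpoint_and_limits(self, nominal_params):
        th = nominal_params.thalamic
        assert firing_rate(th.theta, th) == pytest.approx(th.q_max / 2)
        assert firing_rate(-1e3, th) == pytest.approx(0.0, abs=1e-12)
        assert firing_rate(1e3, th) == pytest.approx(th.q_max)

    def test_published_thalamic_midpoint(self):
        """Thalamic populations fire at 200e-3 / ms at the -58.5 mV threshold."""
        from renmm.params import PopulationParams
        pop = PopulationParams(q_max=400e-3, theta=-58.5, sigma_gain=6.0,
                               tau=20.0)
        assert firing_rate(-58.5, pop) == pytest.approx(200e-3)

    def test_monotone_and_bounded_on_grid(self, nominal_params):
        v = np.linspace(-150.0, 50.0, 1000)
        q = firing_rate(v, nominal_params.thalamic)
        assert np.all(np.diff(q) > 0)
        assert np.all(q > 0) and np.all(q < nominal_params.thalamic.q_max)

    def test_rejects_non_finite(self, nominal_params):
        with pytest.raises(ValueError):
            firing_rate(np.nan, nominal_params.thalamic)


# ---------------------------------------------------------------------------
# Mg block and currents
# ---------------------------------------------------------------------------

class TestMgBlock:
    def test_no_blocker_gives_unity(self):
        v = np.linspace(-100, 40, 50)
        assert np.allclose(mg_block(v, mu=1.7, mg_conc=0.0), 1.0)

    def test_zero_voltage_closed_form(self):
        for mu in (0.1, 1.0, 3.0):
            assert mg_block(0.0, mu, 1.5) == pytest.approx(1 / (1 + 1.5 / 3.57))

    def test_monotone_in_v_and_bounded(self):
        v = np.linspace(-120, 40, 1000)
        b = mg_block(v, mu=2.0, mg_conc=1.0)
        assert np.all(np.diff(b) > 0)
        assert np.all(b > 0) and np.all(b <= 1)

    def test_larger_mu_blocks_more_at_hyperpolarized_v(self):
        """At -60 mV a stronger voltage sensitivity closes more channels,
        lowering the NMDA current density."""
        b = [mg_block(-60.0, mu, 1.0) for mu in (0.5, 1.0, 2.0, 3.0)]
        assert np.all(np.diff(b) < 0)


class TestCurrents:
    def test_reversal_potentials_zero_current(self, nominal_params):
        p = nominal_params
        assert nmda_current(0.0, 0.7, p) == 0.0
        assert h_current(p.intrinsic.e_h, 0.4, 0.2, p) == 0.0
        assert t_current(p.intrinsic.e_ca, 0.5, p, "vpm") == 0.0
        assert lk_current(p.intrinsic.e_lk, p) == 0.0

    def test_zero_gating_zero_current(self, nominal_params):
        assert nmda_current(-60.0, 0.0, nominal_params) == 0.0
        assert h_current(-60.0, 0.0, 0.0, nominal_params) == 0.0
        assert t_current(-60.0, 0.0, nominal_params, "pv") == 0.0

    def test_nmda_is_inward_below_reversal(self, nominal_params):
        assert nmda_current(-60.0, 0.5, nominal_params) < 0.0

    def test_lk_published_arithmetic(self, nominal_params):
        assert lk_current(-60.0, nominal_params) == pytest.approx(0.042 * 40)
        assert lk_current(-50.0, nominal_params) > 0  # outward above E_LK

    def test_t_current_linear_in_conductance(self, nominal_params):
        lo = nominal_params.replace(g_t_vpm=1.6)
        hi = nominal_params.replace(g_t_vpm=2.9)
        v, h = -70.0, 0.5
        assert t_current(v, h, hi, "vpm") == pytest.approx(
            t_current(v, h, lo, "vpm") * 2.9 / 1.6)

    def test_h_current_locked_state_scaling(self, nominal_params):
        p = nominal_params
        base = h_current(-70.0, 0.3, 0.0, p)
        locked = h_current(-70.0, 0.0, 0.3, p)
        assert locked == pytest.approx(p.intrinsic.g_inc * base)


class TestHGating:
    def test_locked_fraction_decays_without_calcium(self, nominal_params):
        i = nominal_params.intrinsic
        _, dm2, _, _ = h_gating_derivatives(-70.0, 0.2, 0.5, i.ca_0, 0.0, 0.0,
                                            nominal_params)
        assert dm2 < 0

    def test_m1_relaxes_monotonically(self, nominal_params):
        v = -70.0
        target = _h_minf(v)
        for m1 in (0.0, target / 2, target * 1.5):
            dm1, _, _, _ = h_gating_derivatives(v, m1, 0.0, 2.4e-4, 0.0, 0.0,
                                                nominal_params)
            assert np.sign(dm1) == np.sign(target - m1) or dm1 == 0

    def test_hyperpolarized_steady_state_near_max(self):
        assert _h_minf(-100.0) > 0.95
        assert _h_minf(-40.0) < 0.01


# ---------------------------------------------------------------------------
# second-order synaptic and delay kernels
# ---------------------------------------------------------------------------

class TestSynapseKernel:
    def test_fixed_point(self):
        assert synapse_accel(r=2.0, r_dot=0.0, drive=2.0,
                             gamma_stiff=0.07) == 0.0

    def test_impulse_response_peaks_at_inverse_gamma(self):
        """The alpha kernel gamma^2 t e^{-gamma t} peaks at t = 1/gamma;
        integrate the ODE from the impulse state (r=0, r_dot=gamma^2)."""
        gamma = 0.07
        sol = solve_ivp(
            lambda t, y: [y[1], synapse_accel(y[0], y[1], 0.0, gamma)],
            (0.0, 100.0), [0.0, gamma ** 2], dense_output=True,
            max_step=0.25, rtol=1e-10, atol=1e-12)
        t = np.linspace(0, 100, 4001)
        r = sol.sol(t)[0]
        assert t[np.argmax(r)] == pytest.approx(1 / gamma, rel=0.02)

    def test_critically_damped_no_oscillation(self):
        gamma = 0.1
        sol = solve_ivp(
            lambda t, y: [y[1], synapse_accel(y[0], y[1], 0.0, gamma)],
            (0.0, 200.0), [1.0, 0.0], max_step=0.5, rtol=1e-10)
        assert np.all(sol.y[0] >= -1e-12)          # never undershoots
        assert np.all(np.diff(sol.y[0]) <= 1e-12)  # monotone decay

    def test_constant_drive_convergence(self):
        """Each subsystem converges to the drive value (rel err < 1e-6
        after 50/gamma)."""
        for stiff, damp in ((0.07, None), (0.1, None), (0.1, 0.03)):
            gamma_eff = damp or stiff
            sol = solve_ivp(
                lambda t, y: [y[1], synapse_accel(y[0], y[1], 3.0, stiff,
                                                  damp)],
                (0.0, 50.0 / min(stiff, gamma_eff)), [0.0, 0.0],
                max_step=2.0, rtol=1e-12, atol=1e-14)
            assert abs(sol.y[0][-1] - 3.0) / 3.0 < 1e-6

    def test_invalid_gamma(self):
        with pytest.raises(ValueError):
            synapse_accel(0.0, 0.0, 1.0, -0.1)


class TestDelayKernel:
    def test_converges_to_constant_source(self):
        nu = 0.1
        sol = solve_ivp(lambda t, y: [y[1], delay_accel(y[0], y[1], 0.25, nu)],
                        (0.0, 50.0 / nu), [0.0, 0.0], max_step=2.0, rtol=1e-12)
        assert sol.y[0][-1] == pytest.approx(0.25, rel=1e-6)

    def test_step_response_velocity_peaks_at_inverse_nu(self):
        nu = 0.1
        sol = solve_ivp(lambda t, y: [y[1], delay_accel(y[0], y[1], 1.0, nu)],
                        (0.0, 100.0), [0.0, 0.0], dense_output=True,
                        max_step=0.25, rtol=1e-10)
        t = np.linspace(0, 100, 4001)
        eta_dot = sol.sol(t)[1]
        assert t[np.argmax(eta_dot)] == pytest.approx(1 / nu, rel=0.02)

    def test_zero_source_stays_zero(self):
        assert delay_accel(0.0, 0.0, 0.0, 0.1) == 0.0


# ---------------------------------------------------------------------------
# assembled right-hand side
# ---------------------------------------------------------------------------

def _numeric_jacobian(y0, params, eps=1e-6):
    f0 = system_rhs(y0, params)
    jac = np.empty((N_STATE, N_STATE))
    for j in range(N_STATE):
        y = y0.copy()
        y[j] += eps
        jac[:, j] = (system_rhs(y, params) - f0) / eps
    return jac


class TestSystemRhs:
    def test_rejects_non_finite_state(self, nominal_params):
        y = initial_state(nominal_params)
        y[0] = np.inf
        with pytest.raises(IntegrationFailure):
            system_rhs(y, nominal_params)

    def test_mu_only_enters_reticular_equations(self, nominal_params,
                                                random_state):
        """The Mg-block factor acts on PV/SOM only; cortical and relay
        derivatives are unchanged at identical state."""
        d1 = system_rhs(random_state, nominal_params.replace(mu=0.5))
        d2 = system_rhs(random_state, nominal_params.replace(mu=2.5))
        unchanged = [S.V_P, S.V_VPM, S.V_VPL]
        assert np.allclose(d1[unchanged], d2[unchanged], rtol=0, atol=0)
        assert not np.allclose(d1[[S.V_PV, S.V_SOM]], d2[[S.V_PV, S.V_SOM]])

    def test_zero_trn_inhibition_drives_relay_gaba_to_zero(self,
                                                           nominal_params):
        """With all reticular->relay projections removed the relay GABA
        states decay toward zero."""
        p = nominal_params.replace(n_t1r1=0.0, n_t2r1=0.0, n_t2r2=0.0)
        y = initial_state(p)
        y[S.R_IVPM] = 0.8
        y[S.R_IVPL] = 0.6
        dy = system_rhs(y, p)
        gn = p.synapse.gamma_N
        assert dy[S.RD_IVPM] == pytest.approx(-gn ** 2 * 0.8)
        assert dy[S.RD_IVPL] == pytest.approx(-gn ** 2 * 0.6)

    def test_jacobian_sparsity_matches_circuit(self, nominal_params,
                                               random_state):
        """Membrane equations couple only to their own synaptic inputs and
        gating; the cortical drive sees only the delayed thalamic rates."""
        jac = _numeric_jacobian(random_state, nominal_params)
        tol = 1e-9

        def deps(row):
            return set(np.flatnonzero(np.abs(jac[row]) > tol))

        # cortex: leak + its AMPA conductance only
        assert deps(S.V_P) <= {S.V_P, S.R_EP}
        # relay membranes: own V, own AMPA/GABA, own gating
        assert deps(S.V_VPM) <= {S.V_VPM, S.R_EVPM, S.R_IVPM, S.HT_VPM,
                                 S.MH1_VPM, S.MH2_VPM}
        assert deps(S.V_VPL) <= {S.V_VPL, S.R_EVPL, S.R_IVPL, S.HT_VPL,
                                 S.MH1_VPL, S.MH2_VPL}
        # reticular membranes: own V, AMPA, NMDA, GABA, T gating
        assert deps(S.V_PV) <= {S.V_PV, S.R_EPV, S.R_ENPV, S.R_IPV, S.HT_PV}
        assert deps(S.V_SOM) <= {S.V_SOM, S.R_ESOM, S.R_ENSOM, S.R_ISOM,
                                 S.HT_SOM}
        # cortical AMPA drive: self-excitation + the two delayed relay rates
        assert deps(S.RD_EP) <= {S.V_P, S.ETA_T1, S.ETA_T2, S.R_EP, S.RD_EP}
        # relay GABA drives come from the reticular populations only
        assert deps(S.RD_IVPM) <= {S.V_PV, S.R_IVPM, S.RD_IVPM}
        assert deps(S.RD_IVPL) <= {S.V_PV, S.V_SOM, S.R_IVPL, S.RD_IVPL}
        # delay lines track a single source rate each
        assert deps(S.ETAD_P) <= {S.V_P, S.ETA_P, S.ETAD_P}
        assert deps(S.ETAD_T1) <= {S.V_VPM, S.ETA_T1, S.ETAD_T1}
        assert deps(S.ETAD_T2) <= {S.V_VPL, S.ETA_T2, S.ETAD_T2}

    def test_strict_as_printed_changes_som_gaba_target(self, nominal_params,
                                                       random_state):
        corrected = system_rhs(random_state, nominal_params)
        strict_params = nominal_params.copy()
        strict_params.strict_as_printed = True
        strict = system_rhs(random_state, strict_params)
        changed = np.flatnonzero(corrected != strict)
        assert set(changed) == {S.RD_ISOM}


def test_initial_state_gating_is_steady(quiet_params):
    """At the initial condition every gating derivative vanishes."""
    y = initial_state(quiet_params)
    dy = system_rhs(y, quiet_params)
    gating = [S.HT_PV, S.HT_SOM, S.HT_VPM, S.HT_VPL,
              S.MH1_VPM, S.MH2_VPM, S.MH1_VPL, S.MH2_VPL]
    assert np.allclose(dy[gating], 0.0, atol=1e-10)
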