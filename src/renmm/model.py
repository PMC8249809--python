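"""Deterministic right-hand side of the five-population thalamocortical model.

State layout (one flat float64 vector, time unit ms, potentials in mV):

* 5 membrane potentials: PY, PV, SOM, VPM, VPL;
* 11 second-order synaptic pairs (r, r_dot): AMPA onto PY/VPM/VPL/PV/SOM,
  NMDA onto PV/SOM, GABA onto VPM/VPL/PV/SOM;
* 3 second-order conduction-delay pairs (eta, eta_dot) carrying the PY, VPM
  and VPL firing rates between the cortical and thalamic modules;
* intrinsic gating: T-current inactivation h_T for the four thalamic
  populations, and for each relay population (VPM, VPL) the h-current open
  fraction m_h1, calcium-locked fraction m_h2, intracellular [Ca2+] and the
  bound-messenger fraction P.

The hot path (:func:`_rhs`) is numba-compiled and operates on the packed
parameter vector from :mod:`renmm.params`; the public operations wrap it (or
the shared scalar kernels) with validation for interactive use and testing.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .params import ModelParameters, pack_params
from .params import *  # noqa: F401,F403 - packed-vector index constants (P_MU, ...)

__all__ = [
    "N_STATE",
    "StateIndex",
    "firing_rate",
    "mg_block",
    "nmda_current",
    "h_current",
    "h_gating_derivatives",
    "t_current",
    "lk_current",
    "synapse_accel",
    "delay_accel",
    "system_rhs",
    "initial_state",
    "IntegrationFailure",
]


class IntegrationFailure(RuntimeError):
    """Raised when the system produced a non-finite state/derivative."""

    def __init__(self, message: str, state: np.ndarray | None = None):
        super().__init__(message)
        self.state = None if state is None else np.asarray(state).copy()


# ---------------------------------------------------------------------------
# state indices
# ---------------------------------------------------------------------------

class StateIndex:
    """Named indices into the flat state vector."""

    V_P, V_PV, V_SOM, V_VPM, V_VPL = 0, 1, 2, 3, 4
    # (r, r_dot) pairs
    R_EP, RD_EP = 5, 6
    R_EVPM, RD_EVPM = 7, 8
    R_EVPL, RD_EVPL = 9, 10
    R_EPV, RD_EPV = 11, 12
    R_ESOM, RD_ESOM = 13, 14
    R_ENPV, RD_ENPV = 15, 16
    R_ENSOM, RD_ENSOM = 17, 18
    R_IVPM, RD_IVPM = 19, 20
    R_IVPL, RD_IVPL = 21, 22
    R_IPV, RD_IPV = 23, 24
    R_ISOM, RD_ISOM = 25, 26
    # delayed firing rates
    ETA_P, ETAD_P = 27, 28
    ETA_T1, ETAD_T1 = 29, 30
    ETA_T2, ETAD_T2 = 31, 32
    # T-current inactivation
    HT_PV, HT_SOM, HT_VPM, HT_VPL = 33, 34, 35, 36
    # h-current gating (relay populations only)
    MH1_VPM, MH2_VPM, CA_VPM, PB_VPM = 37, 38, 39, 40
    MH1_VPL, MH2_VPL, CA_VPL, PB_VPL = 41, 42, 43, 44


N_STATE = 45
S = StateIndex
# flatten the indices to module scope so the numba kernels see plain ints
globals().update({_k: _v for _k, _v in vars(StateIndex).items()
                  if not _k.startswith("_")})

# number of auxiliary observables emitted by the rhs
N_AUX = 9
AUX_Q_P, AUX_Q_PV, AUX_Q_SOM, AUX_Q_VPM, AUX_Q_VPL = 0, 1, 2, 3, 4
AUX_INMDA_PV, AUX_INMDA_SOM, AUX_IH_VPM, AUX_IH_VPL = 5, 6, 7, 8


# ---------------------------------------------------------------------------
# scalar kernels (shared between the compiled rhs and the public operations)
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=False)
def _sigmoid_rate(v, q_max, theta, sigma):
    return q_max / (1.0 + np.exp(-(v - theta) / sigma))


@njit(cache=True, fastmath=False)
def _mg_block(v, mu, mg_conc):
    return 1.0 / (1.0 + mg_conc * np.exp(-mu * 0.062 * v) / 3.57)


@njit(cache=True, fastmath=False)
def _t_minf_relay(v):
    return 1.0 / (1.0 + np.exp(-(v + 59.0) / 6.2))


@njit(cache=True, fastmath=False)
def _t_hinf_relay(v):
    return 1.0 / (1.0 + np.exp((v + 81.0) / 4.0))


@njit(cache=True, fastmath=False)
def _t_tauh_relay(v, tadj):
    return (30.8 + (211.4 + np.exp((v + 115.2) / 5.0))
            / (1.0 + np.exp((v + 86.0) / 3.2))) / tadj


@njit(cache=True, fastmath=False)
def _t_minf_reticular(v):
    return 1.0 / (1.0 + np.exp(-(v + 52.0) / 7.4))


@njit(cache=True, fastmath=False)
def _t_hinf_reticular(v):
    return 1.0 / (1.0 + np.exp((v + 80.0) / 5.0))


@njit(cache=True, fastmath=False)
def _t_tauh_reticular(v, tadj):
    return (85.0 + 1.0 / (np.exp((v + 48.0) / 4.0)
                          + np.exp(-(v + 407.0) / 50.0))) / tadj


@njit(cache=True, fastmath=False)
def _h_minf(v):
    return 1.0 / (1.0 + np.exp((v + 75.0) / 5.5))


@njit(cache=True, fastmath=False)
def _h_taum(v):
    return 20.0 + 1000.0 / (np.exp((v + 71.5) / 14.6)
                            + np.exp(-(v + 89.0) / 11.6))


# ---------------------------------------------------------------------------
# full system right-hand side (drift only; noise is added by the integrator)
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=False)
def _rhs(y, p, dy, aux):
    """Write the drift derivative of state ``y`` into ``dy`` (both length
    N_STATE) and observables into ``aux`` (length N_AUX)."""
    v_p = y[0]; v_pv = y[1]; v_som = y[2]; v_vpm = y[3]; v_vpl = y[4]

    q_p = _sigmoid_rate(v_p, p[P_Q_MAX_P], p[P_THETA_P], p[P_SIGMA_GAIN_P])
    qmax_y = p[P_Q_MAX_Y]; th_y = p[P_THETA_Y]; sg_y = p[P_SIGMA_GAIN_Y]
    q_pv = _sigmoid_rate(v_pv, qmax_y, th_y, sg_y)
    q_som = _sigmoid_rate(v_som, qmax_y, th_y, sg_y)
    q_vpm = _sigmoid_rate(v_vpm, qmax_y, th_y, sg_y)
    q_vpl = _sigmoid_rate(v_vpl, qmax_y, th_y, sg_y)

    g_ampa = p[P_G_AMPA]; g_nmda = p[P_G_NMDA]; g_gaba = p[P_G_GABA]
    e_ampa = p[P_E_AMPA]; e_nmda = p[P_E_NMDA]; e_gaba = p[P_E_GABA]
    e_lp = p[P_E_LEAK_CORTEX]; e_lt = p[P_E_LEAK_THALAMUS]
    tau_p = p[P_TAU_P]; tau_y = p[P_TAU_Y]
    c_m = p[P_C_M]
    g_lk = p[P_G_LK]; e_lk = p[P_E_LK]; e_ca = p[P_E_CA]; e_h = p[P_E_H]
    mu = p[P_MU]; mg = p[P_MG_CONC]

    # ---- cortex (leak + AMPA only) ----
    i_l_p = v_p - e_lp
    i_ampa_p = g_ampa * y[R_EP] * (v_p - e_ampa)
    dy[0] = (-i_l_p - i_ampa_p) / tau_p

    # ---- PV (reticular) ----
    i_ampa_pv = g_ampa * y[R_EPV] * (v_pv - e_ampa)
    b_pv = _mg_block(v_pv, mu, mg)
    i_nmda_pv = g_nmda * y[R_ENPV] * b_pv * (v_pv - e_nmda)
    i_gaba_pv = g_gaba * y[R_IPV] * (v_pv - e_gaba)
    i_lk_pv = g_lk * (v_pv - e_lk)
    m_pv = _t_minf_reticular(v_pv)
    i_t_pv = p[P_G_T_PV] * m_pv * m_pv * y[HT_PV] * (v_pv - e_ca)
    dy[1] = ((-(v_pv - e_lt) - i_ampa_pv - i_nmda_pv - i_gaba_pv) / tau_y
             - (i_lk_pv + i_t_pv) / c_m)

    # ---- SOM (reticular) ----
    i_ampa_som = g_ampa * y[R_ESOM] * (v_som - e_ampa)
    b_som = _mg_block(v_som, mu, mg)
    i_nmda_som = g_nmda * y[R_ENSOM] * b_som * (v_som - e_nmda)
    i_gaba_som = g_gaba * y[R_ISOM] * (v_som - e_gaba)
    i_lk_som = g_lk * (v_som - e_lk)
    m_som = _t_minf_reticular(v_som)
    i_t_som = p[P_G_T_SOM] * m_som * m_som * y[HT_SOM] * (v_som - e_ca)
    dy[2] = ((-(v_som - e_lt) - i_ampa_som - i_nmda_som - i_gaba_som) / tau_y
             - (i_lk_som + i_t_som) / c_m)

    # ---- VPM (relay) ----
    i_ampa_vpm = g_ampa * y[R_EVPM] * (v_vpm - e_ampa)
    i_gaba_vpm = g_gaba * y[R_IVPM] * (v_vpm - e_gaba)
    i_lk_vpm = g_lk * (v_vpm - e_lk)
    m_vpm = _t_minf_relay(v_vpm)
    i_t_vpm = p[P_G_T_VPM] * m_vpm * m_vpm * y[HT_VPM] * (v_vpm - e_ca)
    i_h_vpm = p[P_G_H] * (v_vpm - e_h) * (y[MH1_VPM]
                                            + p[P_G_INC] * y[MH2_VPM])
    dy[3] = ((-(v_vpm - e_lt) - i_ampa_vpm - i_gaba_vpm) / tau_y
             - (i_lk_vpm + i_t_vpm + i_h_vpm) / c_m)

    # ---- VPL (relay) ----
    i_ampa_vpl = g_ampa * y[R_EVPL] * (v_vpl - e_ampa)
    i_gaba_vpl = g_gaba * y[R_IVPL] * (v_vpl - e_gaba)
    i_lk_vpl = g_lk * (v_vpl - e_lk)
    m_vpl = _t_minf_relay(v_vpl)
    i_t_vpl = p[P_G_T_VPL] * m_vpl * m_vpl * y[HT_VPL] * (v_vpl - e_ca)
    i_h_vpl = p[P_G_H] * (v_vpl - e_h) * (y[MH1_VPL]
                                            + p[P_G_INC] * y[MH2_VPL])
    dy[4] = ((-(v_vpl - e_lt) - i_ampa_vpl - i_gaba_vpl) / tau_y
             - (i_lk_vpl + i_t_vpl + i_h_vpl) / c_m)

    # ---- synaptic second-order systems ----
    ge = p[P_GAMMA_E]; gg = p[P_GAMMA_G]; gn = p[P_GAMMA_N]
    gN = p[P_GAMMA_N_CAP]
    ge2 = ge * ge; gN2 = gN * gN
    phi0 = p[P_PHI_MEAN]
    eta_p = y[ETA_P]; eta_t1 = y[ETA_T1]; eta_t2 = y[ETA_T2]

    # AMPA onto PY (cortical noise input)
    drive = (p[P_N_PP] * q_p + p[P_N_PT1] * eta_t1
             + p[P_N_PT2] * eta_t2 + phi0)
    dy[R_EP] = y[RD_EP]
    dy[RD_EP] = ge2 * (drive - y[R_EP]) - 2.0 * ge * y[RD_EP]

    # AMPA onto VPM (relay noise input)
    drive = p[P_N_T1P] * eta_p + p[P_N_T1T2] * q_vpl + phi0
    dy[R_EVPM] = y[RD_EVPM]
    dy[RD_EVPM] = ge2 * (drive - y[R_EVPM]) - 2.0 * ge * y[RD_EVPM]

    # AMPA onto VPL
    drive = p[P_N_T2P] * eta_p + p[P_N_T2T1] * q_vpm
    dy[R_EVPL] = y[RD_EVPL]
    dy[RD_EVPL] = ge2 * (drive - y[R_EVPL]) - 2.0 * ge * y[RD_EVPL]

    # AMPA onto PV
    drive_pv = (p[P_N_R1P] * eta_p + p[P_N_R1T1] * q_vpm
                + p[P_N_R1T2] * q_vpl)
    dy[R_EPV] = y[RD_EPV]
    dy[RD_EPV] = ge2 * (drive_pv - y[R_EPV]) - 2.0 * ge * y[RD_EPV]

    # AMPA onto SOM (reticular noise input)
    drive_som = p[P_N_R2T2] * q_vpl + phi0
    dy[R_ESOM] = y[RD_ESOM]
    dy[RD_ESOM] = ge2 * (drive_som - y[R_ESOM]) - 2.0 * ge * y[RD_ESOM]

    # NMDA onto PV / SOM: asymmetric gamma_g*gamma_n stiffness, 2*gamma_n damping
    dy[R_ENPV] = y[RD_ENPV]
    dy[RD_ENPV] = gg * gn * (drive_pv - y[R_ENPV]) - 2.0 * gn * y[RD_ENPV]
    dy[R_ENSOM] = y[RD_ENSOM]
    dy[RD_ENSOM] = (gg * gn * (p[P_N_R2T2] * q_vpl - y[R_ENSOM])
                      - 2.0 * gn * y[RD_ENSOM])

    # GABA onto VPM / VPL (the reticular->relay inhibition under study)
    dy[R_IVPM] = y[RD_IVPM]
    dy[RD_IVPM] = (gN2 * (p[P_N_T1R1] * q_pv - y[R_IVPM])
                     - 2.0 * gN * y[RD_IVPM])
    dy[R_IVPL] = y[RD_IVPL]
    dy[RD_IVPL] = (gN2 * (p[P_N_T2R1] * q_pv + p[P_N_T2R2] * q_som
                            - y[R_IVPL]) - 2.0 * gN * y[RD_IVPL])

    # GABA onto PV (self + SOM->PV)
    dy[R_IPV] = y[RD_IPV]
    dy[RD_IPV] = (gN2 * (p[P_N_RR] * q_pv + p[P_N_R1R2] * q_som
                           - y[R_IPV]) - 2.0 * gN * y[RD_IPV])

    # GABA onto SOM (self-inhibition); the strict-as-printed variant relaxes
    # toward the PV GABA state instead of its own.
    dy[R_ISOM] = y[RD_ISOM]
    if p[P_STRICT] > 0.5:
        target = y[R_IPV]
    else:
        target = y[R_ISOM]
    dy[RD_ISOM] = (gN2 * (p[P_N_RR2] * q_som - target)
                     - 2.0 * gN * y[RD_ISOM])

    # ---- conduction delays (alpha-function second-order systems) ----
    nu = p[P_NU]; nu2 = nu * nu
    dy[ETA_P] = y[ETAD_P]
    dy[ETAD_P] = nu2 * (q_p - eta_p) - 2.0 * nu * y[ETAD_P]
    dy[ETA_T1] = y[ETAD_T1]
    dy[ETAD_T1] = nu2 * (q_vpm - eta_t1) - 2.0 * nu * y[ETAD_T1]
    dy[ETA_T2] = y[ETAD_T2]
    dy[ETAD_T2] = nu2 * (q_vpl - eta_t2) - 2.0 * nu * y[ETAD_T2]

    # ---- T-current inactivation ----
    tadj = p[P_TADJ_T]
    dy[HT_PV] = (_t_hinf_reticular(v_pv) - y[HT_PV]) / _t_tauh_reticular(v_pv, tadj)
    dy[HT_SOM] = (_t_hinf_reticular(v_som) - y[HT_SOM]) / _t_tauh_reticular(v_som, tadj)
    dy[HT_VPM] = (_t_hinf_relay(v_vpm) - y[HT_VPM]) / _t_tauh_relay(v_vpm, tadj)
    dy[HT_VPL] = (_t_hinf_relay(v_vpl) - y[HT_VPL]) / _t_tauh_relay(v_vpl, tadj)

    # ---- calcium-regulated h-current gating (relay populations) ----
    a_ca = p[P_ALPHA_CA]; ca0 = p[P_CA_0]; tau_ca = p[P_TAU_CA]
    k1 = p[P_K1]; k2 = p[P_K2]; k3 = p[P_K3]; k4 = p[P_K4]

    for (iv, i_t, mh1, mh2, ca, pb) in (
        (3, i_t_vpm, MH1_VPM, MH2_VPM, CA_VPM, PB_VPM),
        (4, i_t_vpl, MH1_VPL, MH2_VPL, CA_VPL, PB_VPL),
    ):
        v = y[iv]
        dy[mh1] = (_h_minf(v) * (1.0 - y[mh2]) - y[mh1]) / _h_taum(v)
        dy[mh2] = k3 * y[pb] * y[mh1] - k4 * y[mh2]
        dy[ca] = a_ca * i_t - (y[ca] - ca0) / tau_ca
        ca4 = y[ca] ** 4
        dy[pb] = k1 * ca4 * (1.0 - y[pb]) - k2 * y[pb]

    aux[AUX_Q_P] = q_p
    aux[AUX_Q_PV] = q_pv
    aux[AUX_Q_SOM] = q_som
    aux[AUX_Q_VPM] = q_vpm
    aux[AUX_Q_VPL] = q_vpl
    aux[AUX_INMDA_PV] = i_nmda_pv
    aux[AUX_INMDA_SOM] = i_nmda_som
    aux[AUX_IH_VPM] = i_h_vpm
    aux[AUX_IH_VPL] = i_h_vpl


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def firing_rate(v, pop) -> np.ndarray | float:
    """Sigmoid voltage-to-rate transfer Q(V) = q_max / (1 + exp(-(V-theta)/sigma)).

    Parameters
    ----------
    v : float or array, membrane potential (mV).
    pop : PopulationParams.
    """
    pop.validate()
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite membrane potential")
    out = pop.q_max / (1.0 + np.exp(-(v - pop.theta) / pop.sigma_gain))
    return float(out) if out.ndim == 0 else out


def mg_block(v, mu: float, mg_conc: float):
    """Voltage-dependent open fraction of the NMDA channel under Mg2+ block."""
    if mg_conc < 0:
        raise ValueError("mg_conc must be >= 0")
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite membrane potential")
    out = 1.0 / (1.0 + mg_conc * np.exp(-mu * 0.062 * v) / 3.57)
    return float(out) if out.ndim == 0 else out


def nmda_current(v: float, r_en: float, params: ModelParameters) -> float:
    """NMDA current onto a reticular population: g_N * r * B(V) * (V - E_N)."""
    i = params.intrinsic
    s = params.synapse
    return s.g_nmda * r_en * mg_block(v, i.mu, i.mg_conc) * (v - s.e_nmda)


def h_current(v: float, m_h1: float, m_h2: float, params: ModelParameters) -> float:
    """Anomalous-rectifier current I_h = g_h (V - E_h)(m_h1 + g_inc m_h2)."""
    i = params.intrinsic
    return i.g_h * (v - i.e_h) * (m_h1 + i.g_inc * m_h2)


def h_gating_derivatives(v: float, m_h1: float, m_h2: float, ca: float,
                         pb: float, i_t: float, params: ModelParameters):
    """Time derivatives of the calcium-regulated h-current gating scheme.

    Returns (dm_h1, dm_h2, d_ca, d_pb).  The voltage-gated open fraction
    m_h1 relaxes toward m_inf(V)(1 - m_h2); calcium entering through the
    T-current binds a messenger P which locks open channels into m_h2.
    """
    i = params.intrinsic
    dm1 = (_h_minf(v) * (1.0 - m_h2) - m_h1) / _h_taum(v)
    dm2 = i.k3 * pb * m_h1 - i.k4 * m_h2
    dca = i.alpha_ca * i_t - (ca - i.ca_0) / i.tau_ca
    dpb = i.k1 * ca ** 4 * (1.0 - pb) - i.k2 * pb
    return dm1, dm2, dca, dpb


def t_current(v: float, h_t: float, params: ModelParameters, pop: str) -> float:
    """Low-threshold calcium current I_T = g_T m_inf(V)^2 h_T (V - E_Ca)."""
    i = params.intrinsic
    if pop in ("pv", "som"):
        minf = _t_minf_reticular(v)
        g_t = i.g_t_pv if pop == "pv" else i.g_t_som
    elif pop in ("vpm", "vpl"):
        minf = _t_minf_relay(v)
        g_t = i.g_t_vpm if pop == "vpm" else i.g_t_vpl
    else:
        raise ValueError(f"unknown thalamic population {pop!r}")
    return g_t * minf * minf * h_t * (v - i.e_ca)


def lk_current(v: float, params: ModelParameters) -> float:
    """Potassium leak current I_LK = g_LK (V - E_LK) (thalamic populations)."""
    i = params.intrinsic
    return i.g_lk * (v - i.e_lk)


def synapse_accel(r: float, r_dot: float, drive: float,
                  gamma_stiff: float, gamma_damp: float | None = None) -> float:
    """Second derivative of an open-channel proportion.

    r_ddot = gamma_stiff * gamma_damp * (drive - r) - 2 * gamma_damp * r_dot.
    With ``gamma_damp is None`` the kernel is critically damped
    (gamma_stiff used for both), which is the AMPA/GABA case; the NMDA
    pairs pass the asymmetric (gamma_g, gamma_n) combination.
    """
    if gamma_damp is None:
        gamma_damp = gamma_stiff
    if gamma_stiff <= 0 or gamma_damp <= 0:
        raise ValueError("synaptic rate constants must be > 0")
    return gamma_stiff * gamma_damp * (drive - r) - 2.0 * gamma_damp * r_dot


def delay_accel(eta: float, eta_dot: float, q_source: float, nu: float) -> float:
    """Second derivative of the alpha-function conduction delay state."""
    if nu <= 0:
        raise ValueError("nu must be > 0")
    return nu * nu * (q_source - eta) - 2.0 * nu * eta_dot


def system_rhs(state: np.ndarray, params: ModelParameters,
               return_aux: bool = False):
    """Full drift derivative of the model at ``state``.

    Raises :class:`IntegrationFailure` when the input or the resulting
    derivative is non-finite.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (N_STATE,):
        raise ValueError(f"state must have shape ({N_STATE},)")
    if not np.all(np.isfinite(state)):
        raise IntegrationFailure("non-finite state passed to system_rhs", state)
    p = pack_params(params)
    dy = np.empty(N_STATE)
    aux = np.empty(N_AUX)
    _rhs(state, p, dy, aux)
    if not np.all(np.isfinite(dy)):
        raise IntegrationFailure("system_rhs produced a non-finite derivative",
                                 state)
    return (dy, aux) if return_aux else dy


def initial_state(params: ModelParameters) -> np.ndarray:
    """Default initial condition: potentials at their leak reversals, all
    synaptic/delay states at rest, gating at steady state for the initial V."""
    i = params.intrinsic
    y = np.zeros(N_STATE)
    y[V_P] = params.synapse.e_leak_cortex
    for idx in (V_PV, V_SOM, V_VPM, V_VPL):
        y[idx] = params.synapse.e_leak_thalamus
    y[HT_PV] = _t_hinf_reticular(y[V_PV])
    y[HT_SOM] = _t_hinf_reticular(y[V_SOM])
    y[HT_VPM] = _t_hinf_relay(y[V_VPM])
    y[HT_VPL] = _t_hinf_relay(y[V_VPL])
    pb0 = i.k1 * i.ca_0 ** 4 / (i.k1 * i.ca_0 ** 4 + i.k2)
    for (mh1, mh2, ca, pb, iv) in (
        (MH1_VPM, MH2_VPM, CA_VPM, PB_VPM, V_VPM),
        (MH1_VPL, MH2_VPL, CA_VPL, PB_VPL, V_VPL),
    ):
        y[ca] = i.ca_0
        y[pb] = pb0
        # joint steady state of (m_h1, m_h2) at fixed V and messenger pb0
        ratio = i.k3 * pb0 / i.k4
        m1 = _h_minf(y[iv]) / (1.0 + _h_minf(y[iv]) * ratio)
        y[mh1] = m1
        y[mh2] = ratio * m1
    return y
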