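"""Stochastic time-stepping of the thalamocortical model.

The system is an SDE with additive noise: white-noise background inputs enter
the second-order synaptic equations of the cortical (PY), relay (VPM) and
reticular (SOM) AMPA drives, i.e. the diffusion acts on the three r_dot
components with constant amplitude gamma_e^2 * sd.

Two schemes are provided:

* :func:`srk4_step` — additive-noise stochastic Runge-Kutta: the classical
  RK4 tableau on the drift plus the exact Gaussian increment g*dW of the
  (state-independent) diffusion.  At zero noise it reduces *exactly* to
  classical RK4; with noise it is strong order 1.0, which is exact for the
  diffusion part of an additive-noise system.
* :func:`euler_maruyama_step` — the standard order-0.5/1.0 reference scheme,
  used as an independent cross-check at small step sizes.

The default integration step is dt = 0.1 ms; the cortical output V_p is
low-pass filtered (8th-order zero-phase Butterworth) and decimated to the
requested output rate after discarding the burn-in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.signal
from numba import njit

from . import model as M
from .model import IntegrationFailure, N_STATE, initial_state
from .params import ModelParameters, pack_params
from .params import P_GAMMA_E, P_PHI_P_SD, P_PHI_T_SD, P_PHI_N_SD

log = logging.getLogger("renmm.integrator")

__all__ = [
    "IntegrationSpec",
    "SimulatedEEG",
    "simulate",
    "srk4_step",
    "euler_maruyama_step",
]

# state indices receiving the three independent noise streams (PY, VPM, SOM)
_NOISE_IDX = np.array([M.RD_EP, M.RD_EVPM, M.RD_ESOM], dtype=np.int64)


@dataclass
class IntegrationSpec:
    """How to integrate: step size (ms), duration/burn-in (s), seeding and
    the output sampling rate (Hz)."""

    dt: float = 0.1
    duration: float = 70.0
    burn_in: float = 10.0
    seed: int = 0
    output_rate: float = 200.0
    method: str = "srk4"  # or "euler"
    record_aux: bool = False
    aux_stride: int = 50  # record firing-rate traces every this many steps
    keep_native: bool = False  # also return the undecimated V_p trace

    def validate(self) -> "IntegrationSpec":
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if not (self.duration > self.burn_in >= 0):
            raise ValueError("duration must exceed burn_in >= 0")
        if self.method not in ("srk4", "euler"):
            raise ValueError(f"unknown integration method {self.method!r}")
        return self


@dataclass
class SimulatedEEG:
    """Cortical output V_p after burn-in, with sampling metadata."""

    samples: np.ndarray          # mV
    fs: float                    # Hz
    meta: dict = field(default_factory=dict)
    aux: dict = field(default_factory=dict)
    final_state: np.ndarray | None = None

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


def _noise_amplitudes(p: np.ndarray) -> np.ndarray:
    ge2 = p[P_GAMMA_E] ** 2
    return ge2 * np.array([p[P_PHI_P_SD], p[P_PHI_T_SD], p[P_PHI_N_SD]])


@njit(cache=True)
def _step_srk4(y, p, dt, dw, k1, k2, k3, k4, tmp, aux):
    M._rhs(y, p, k1, aux)
    for i in range(y.size):
        tmp[i] = y[i] + 0.5 * dt * k1[i]
    M._rhs(tmp, p, k2, aux)
    for i in range(y.size):
        tmp[i] = y[i] + 0.5 * dt * k2[i]
    M._rhs(tmp, p, k3, aux)
    for i in range(y.size):
        tmp[i] = y[i] + dt * k3[i]
    M._rhs(tmp, p, k4, aux)
    for i in range(y.size):
        y[i] += dt * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i]) / 6.0
    y[M.RD_EP] += dw[0]
    y[M.RD_EVPM] += dw[1]
    y[M.RD_ESOM] += dw[2]


@njit(cache=True)
def _step_euler(y, p, dt, dw, k1, aux):
    M._rhs(y, p, k1, aux)
    for i in range(y.size):
        y[i] += dt * k1[i]
    y[M.RD_EP] += dw[0]
    y[M.RD_EVPM] += dw[1]
    y[M.RD_ESOM] += dw[2]


@njit(cache=True)
def _integrate(y, p, dt, n_steps, noise, g_amp, use_srk4, burn_steps,
               vp_trace, aux_stride, aux_trace, aux_sums):
    """Advance ``n_steps`` in place.

    noise: (n_steps, 3) standard normals; the per-step increment is
    g_amp * sqrt(dt) * noise.  vp_trace collects V_p at every step
    (length n_steps).  aux_trace (n_aux_rec, N_AUX) records observables
    every aux_stride steps; aux_sums accumulates post-burn-in means of
    [|I_NMDA|, |I_h|, Q_pv, Q_som, Q_vpm, Q_vpl, count].

    Returns 0 on success, or the 1-based step index at which the state
    became non-finite.
    """
    k1 = np.empty(N_STATE); k2 = np.empty(N_STATE)
    k3 = np.empty(N_STATE); k4 = np.empty(N_STATE)
    tmp = np.empty(N_STATE)
    aux = np.empty(M.N_AUX)
    dw = np.empty(3)
    sqdt = np.sqrt(dt)
    n_aux_rec = aux_trace.shape[0]
    for n in range(n_steps):
        for j in range(3):
            dw[j] = g_amp[j] * sqdt * noise[n, j]
        if use_srk4:
            _step_srk4(y, p, dt, dw, k1, k2, k3, k4, tmp, aux)
        else:
            _step_euler(y, p, dt, dw, k1, aux)
        vp = y[0]
        vp_trace[n] = vp
        if not np.isfinite(vp):
            return n + 1
        # refresh observables at the updated state for recording/averaging
        if n >= burn_steps or (n_aux_rec > 0 and n % aux_stride == 0):
            M._rhs(y, p, k1, aux)
        if n_aux_rec > 0 and n % aux_stride == 0:
            idx = n // aux_stride
            if idx < n_aux_rec:
                for j in range(M.N_AUX):
                    aux_trace[idx, j] = aux[j]
        if n >= burn_steps:
            aux_sums[0] += 0.5 * (abs(aux[M.AUX_INMDA_PV])
                                  + abs(aux[M.AUX_INMDA_SOM]))
            aux_sums[1] += 0.5 * (abs(aux[M.AUX_IH_VPM])
                                  + abs(aux[M.AUX_IH_VPL]))
            aux_sums[2] += aux[M.AUX_Q_PV]
            aux_sums[3] += aux[M.AUX_Q_SOM]
            aux_sums[4] += aux[M.AUX_Q_VPM]
            aux_sums[5] += aux[M.AUX_Q_VPL]
            aux_sums[6] += 1.0
    return 0


def _single_step(state, params, dt, rng, use_srk4):
    y = np.array(state, dtype=float)
    if y.shape != (N_STATE,):
        raise ValueError(f"state must have shape ({N_STATE},)")
    p = pack_params(params)
    g_amp = _noise_amplitudes(p)
    xi = rng.standard_normal(3) if rng is not None else np.zeros(3)
    dw = g_amp * np.sqrt(dt) * xi
    k1 = np.empty(N_STATE); aux = np.empty(M.N_AUX)
    if use_srk4:
        k2 = np.empty(N_STATE); k3 = np.empty(N_STATE)
        k4 = np.empty(N_STATE); tmp = np.empty(N_STATE)
        _step_srk4(y, p, dt, dw, k1, k2, k3, k4, tmp, aux)
    else:
        _step_euler(y, p, dt, dw, k1, aux)
    if not np.all(np.isfinite(y)):
        raise IntegrationFailure("integration step produced non-finite state", y)
    return y


def srk4_step(state, params: ModelParameters, dt: float,
              rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """One additive-noise SRK step (classical RK4 drift tableau + g dW)."""
    return _single_step(state, params, dt, rng, True)


def euler_maruyama_step(state, params: ModelParameters, dt: float,
                        rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """One Euler-Maruyama reference step."""
    return _single_step(state, params, dt, rng, False)


def _decimate(vp_full: np.ndarray, fs_native: float, fs_out: float) -> np.ndarray:
    """Anti-aliased decimation of the native-rate trace to fs_out."""
    factor = fs_native / fs_out
    k = int(round(factor))
    if abs(factor - k) > 1e-9:
        raise ValueError(
            f"output_rate {fs_out} must divide the native rate {fs_native}")
    if k == 1:
        return vp_full.copy()
    sos = scipy.signal.butter(8, 0.8 * (fs_out / 2), btype="low",
                              fs=fs_native, output="sos")
    filtered = scipy.signal.sosfiltfilt(sos, vp_full)
    return np.ascontiguousarray(filtered[::k])


def simulate(params: ModelParameters, spec: IntegrationSpec,
             y0: Optional[np.ndarray] = None) -> SimulatedEEG:
    """Integrate the model and return the simulated EEG (V_p after burn-in).

    ``aux`` always carries post-burn-in time averages of the NMDA and
    h-current magnitudes and population firing rates; with
    ``spec.record_aux`` it additionally carries firing-rate traces at
    ``spec.aux_stride`` sub-sampling (no anti-alias filter; averages use the
    full-rate sums).
    """
    params.validate()
    spec.validate()
    p = pack_params(params)
    dt = spec.dt
    n_steps = int(round(spec.duration * 1000.0 / dt))
    burn_steps = int(round(spec.burn_in * 1000.0 / dt))
    y = initial_state(params) if y0 is None else np.array(y0, dtype=float)

    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal((n_steps, 3))
    g_amp = _noise_amplitudes(p)

    vp_trace = np.empty(n_steps)
    n_aux_rec = (n_steps - 1) // spec.aux_stride + 1 if spec.record_aux else 0
    aux_trace = np.empty((n_aux_rec, M.N_AUX))
    aux_sums = np.zeros(7)

    bad = _integrate(y, p, dt, n_steps, noise, g_amp,
                     spec.method == "srk4", burn_steps,
                     vp_trace, spec.aux_stride, aux_trace, aux_sums)
    if bad:
        t_bad = (bad - 1) * dt / 1000.0
        raise IntegrationFailure(
            f"state became non-finite at t = {t_bad:.4f} s "
            f"(step {bad}, dt = {dt} ms)", y)

    fs_native = 1000.0 / dt
    vp_out = _decimate(vp_trace, fs_native, spec.output_rate)
    keep = int(round(spec.burn_in * spec.output_rate))
    samples = vp_out[keep:]

    n_avg = max(aux_sums[6], 1.0)
    aux_out = {
        "mean_abs_i_nmda": aux_sums[0] / n_avg,
        "mean_abs_i_h": aux_sums[1] / n_avg,
        "mean_q_pv": aux_sums[2] / n_avg,
        "mean_q_som": aux_sums[3] / n_avg,
        "mean_q_vpm": aux_sums[4] / n_avg,
        "mean_q_vpl": aux_sums[5] / n_avg,
    }
    if spec.keep_native:
        aux_out["vp_native"] = vp_trace
    if spec.record_aux:
        t_aux = np.arange(n_aux_rec) * spec.aux_stride * dt / 1000.0
        sel = t_aux >= spec.burn_in
        aux_out["t"] = t_aux[sel] - spec.burn_in
        for name, col in (("q_p", M.AUX_Q_P), ("q_pv", M.AUX_Q_PV),
                          ("q_som", M.AUX_Q_SOM), ("q_vpm", M.AUX_Q_VPM),
                          ("q_vpl", M.AUX_Q_VPL)):
            aux_out[name] = aux_trace[sel, col]

    log.info("simulated %.1f s (burn-in %.1f s) seed=%d method=%s",
             spec.duration, spec.burn_in, spec.seed, spec.method)
    meta = {
        "seed": spec.seed,
        "dt_ms": dt,
        "duration_s": spec.duration,
        "burn_in_s": spec.burn_in,
        "method": spec.method,
        "params": params.to_dict(),
    }
    return SimulatedEEG(samples=samples, fs=spec.output_rate,
                        meta=meta, aux=aux_out, final_state=y)
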