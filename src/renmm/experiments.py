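"""In-silico experiments: parameter sweeps, spike/spindle competition,
population ablation, and current-density profiles.

Each grid cell simulates the model for a fixed epoch (default 60 s after a
10 s burn-in, matching 1-minute clinical scoring epochs) for a small set of
seeds, runs both event detectors on the cortical output, and records
per-minute rates.  Published sweeps use 41-point axes; every operation here
accepts arbitrary (reduced) grids, and results are invariant to the order
in which cells are evaluated because every cell derives its seed stream
from (base_seed, cell index).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .features import (
    SpikeDetectorConfig,
    SpindleDetectorConfig,
    extract_events,
)
from .integrator import IntegrationSpec, simulate
from .params import ModelParameters

log = logging.getLogger("renmm.experiments")

__all__ = [
    "SweepResult",
    "CompetitionSummary",
    "AblationResult",
    "run_cell",
    "sweep_mu_gh",
    "sweep_trn_inhibition",
    "trn_diagonal",
    "competition_fit",
    "nmda_spindle_check",
    "ablate_population",
    "current_density_profiles",
    "MIXED_REGIME",
    "SPINDLE_REGIME",
    "SPIKE_REGIME",
]

# Canonical operating points.  The mixed regime is the published
# spike+spindle quadruple; the spike regime is its strongest-spiking
# neighbour; the spindle regime is the reduced-Mg-block member of the same
# family whose detected events carry the canonical sigma frequency
# (see docs/methods.md).
MIXED_REGIME = dict(mu=2.0, g_h=0.058, g_t_pv=2.9, g_t_som=2.9,
                    g_t_vpm=2.9, g_t_vpl=2.9, g_lk=0.042)
SPIKE_REGIME = dict(MIXED_REGIME, mu=2.0, g_h=0.056)
SPINDLE_REGIME = dict(MIXED_REGIME, mu=1.75)


@dataclass
class SweepResult:
    """Event rates over a parameter grid.

    ``spike_rate``/``spindle_rate`` have shape grid_shape + (n_seeds,),
    in events per minute.
    """

    axes: dict[str, np.ndarray]
    seeds: list[int]
    spike_rate: np.ndarray
    spindle_rate: np.ndarray
    epoch: float   # scored epoch length (s)
    meta: dict = field(default_factory=dict)

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return tuple(len(v) for v in self.axes.values())

    def mean_over_seeds(self, which: str = "spike") -> np.ndarray:
        arr = self.spike_rate if which == "spike" else self.spindle_rate
        return arr.mean(axis=-1)

    def to_dataframe(self) -> pd.DataFrame:
        names = list(self.axes)
        rows = []
        for idx in itertools.product(*(range(len(self.axes[n])) for n in names)):
            for j, seed in enumerate(self.seeds):
                row = {n: self.axes[n][i] for n, i in zip(names, idx)}
                row["seed"] = seed
                row["spike_rate"] = self.spike_rate[idx + (j,)]
                row["spindle_rate"] = self.spindle_rate[idx + (j,)]
                rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class CompetitionSummary:
    """Least-squares line of spike rate against spindle rate."""

    slope: float
    intercept: float
    correlation: float
    n_points: int
    degenerate: bool = False


@dataclass
class AblationResult:
    rates: dict[str, dict[str, float]]          # mode -> mean rates
    per_seed: dict[str, dict[str, list[float]]]
    firing_traces: dict[str, dict[str, np.ndarray]]  # mode -> {q_pv, q_som, t}
    kruskal: dict[str, tuple[float, float]]     # H statistic, p per rate type


def _cell_seed(base_seed: int, cell_index: int, seed_index: int) -> int:
    """Deterministic, order-independent per-cell seed (< 2^31)."""
    return int((base_seed * 1_000_003 + cell_index * 7919 + seed_index)
               % (2 ** 31 - 1))


def run_cell(params: ModelParameters, seed: int, epoch: float = 60.0,
             burn_in: float = 10.0,
             spike_cfg: SpikeDetectorConfig | None = None,
             spindle_cfg: SpindleDetectorConfig | None = None,
             record_aux: bool = False):
    """Simulate one cell and score events; returns (spike/min, spindle/min,
    SimulatedEEG)."""
    spec = IntegrationSpec(duration=epoch + burn_in, burn_in=burn_in,
                           seed=seed, record_aux=record_aux)
    eeg = simulate(params, spec)
    ev = extract_events(eeg.samples, eeg.fs, spike_cfg, spindle_cfg)
    return ev.spike_rate, ev.spindle_rate, eeg


def _sweep(base_params: ModelParameters, axes: dict[str, np.ndarray],
           seeds: list[int], epoch: float, meta: dict | None = None,
           **cell_kw) -> SweepResult:
    names = list(axes)
    shape = tuple(len(axes[n]) for n in names)
    spike = np.full(shape + (len(seeds),), np.nan)
    spindle = np.full(shape + (len(seeds),), np.nan)
    failures = []
    for flat, idx in enumerate(itertools.product(*(range(s) for s in shape))):
        p = base_params.replace(**{n: float(axes[n][i])
                                   for n, i in zip(names, idx)})
        for j, seed in enumerate(seeds):
            try:
                spk, spn, _ = run_cell(p, _cell_seed(seed, flat, j),
                                       epoch=epoch, **cell_kw)
                spike[idx + (j,)] = spk
                spindle[idx + (j,)] = spn
            except Exception as err:  # cell failures recorded, not fatal
                failures.append({"cell": idx, "seed": seed, "error": str(err)})
    meta = dict(meta or {})
    meta["failures"] = failures
    log.info("sweep %s: %s cells x %d seeds, epoch %.0f s, %d failures",
             meta.get("plan", "?"), shape, len(seeds), epoch, len(failures))
    return SweepResult(axes={n: np.asarray(axes[n], dtype=float) for n in names},
                       seeds=list(seeds), spike_rate=spike,
                       spindle_rate=spindle, epoch=epoch, meta=meta)


def sweep_mu_gh(mu_values, gh_values, base_params: ModelParameters | None = None,
                seeds=(0, 1, 2), epoch: float = 60.0, **cell_kw) -> SweepResult:
    """Spike/spindle rates over the Mg-block factor x h-conductance plane
    (published full scale: 41 x 41 over [0.1, 3] x [0.046, 0.066])."""
    base = base_params or ModelParameters()
    return _sweep(base, {"mu": np.asarray(mu_values),
                         "g_h": np.asarray(gh_values)},
                  list(seeds), epoch, meta={"plan": "mu_gh"}, **cell_kw)


def sweep_trn_inhibition(n_t1r1_values, n_t2r1_values, n_t2r2_values,
                         base_params: ModelParameters | None = None,
                         seeds=(0, 1, 2), epoch: float = 60.0,
                         **cell_kw) -> SweepResult:
    """Rates over the three reticular->relay inhibition strengths at the
    mixed spike+spindle operating point (published: 41^3 over
    [1, 5.5] x [1, 2] x [1, 2])."""
    base = (base_params or ModelParameters()).replace(**MIXED_REGIME)
    return _sweep(base, {"n_t1r1": np.asarray(n_t1r1_values),
                         "n_t2r1": np.asarray(n_t2r1_values),
                         "n_t2r2": np.asarray(n_t2r2_values)},
                  list(seeds), epoch, meta={"plan": "trn"}, **cell_kw)


def trn_diagonal(n_points: int = 5, base_params: ModelParameters | None = None,
                 seeds=(0, 1, 2), epoch: float = 60.0, **cell_kw) -> SweepResult:
    """Joint main diagonal of the 3-D inhibition grid: all three projection
    strengths increased simultaneously from their weakest to strongest
    published values."""
    base = (base_params or ModelParameters()).replace(**MIXED_REGIME)
    d = np.linspace(0.0, 1.0, n_points)
    axes = {"diag": d}
    shape = (n_points,)
    spike = np.full(shape + (len(seeds),), np.nan)
    spindle = np.full(shape + (len(seeds),), np.nan)
    for i, t in enumerate(d):
        p = base.replace(n_t1r1=1.0 + 4.5 * t, n_t2r1=1.0 + 1.0 * t,
                         n_t2r2=1.0 + 1.0 * t)
        for j, seed in enumerate(seeds):
            spk, spn, _ = run_cell(p, _cell_seed(seed, i, j), epoch=epoch,
                                   **cell_kw)
            spike[i, j] = spk
            spindle[i, j] = spn
    return SweepResult(axes=axes, seeds=list(seeds), spike_rate=spike,
                       spindle_rate=spindle, epoch=epoch,
                       meta={"plan": "trn_diagonal"})


def competition_fit(result: SweepResult) -> CompetitionSummary:
    """Least-squares line of spike rate vs spindle rate over all cells/seeds."""
    x = result.spindle_rate.ravel()
    y = result.spike_rate.ravel()
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("competition fit needs >= 3 paired points")
    if np.std(x) == 0:
        return CompetitionSummary(slope=float("nan"), intercept=float("nan"),
                                  correlation=float("nan"), n_points=x.size,
                                  degenerate=True)
    fit = scipy.stats.linregress(x, y)
    return CompetitionSummary(slope=float(fit.slope),
                              intercept=float(fit.intercept),
                              correlation=float(fit.rvalue),
                              n_points=int(x.size))


def nmda_spindle_check(mu_values=None, base_params: ModelParameters | None = None,
                       seeds=(0, 1, 2), epoch: float = 60.0, **cell_kw) -> dict:
    """Spindle rate as a function of the Mg-block factor at the mixed
    operating point; tests near-constancy of spindle rate under NMDA
    changes."""
    mu_values = np.linspace(0.1, 3.0, 9) if mu_values is None \
        else np.asarray(mu_values, dtype=float)
    base = (base_params or ModelParameters()).replace(**MIXED_REGIME)
    res = _sweep(base, {"mu": mu_values}, list(seeds), epoch,
                 meta={"plan": "nmda_spindle"}, **cell_kw)
    per_mu = res.mean_over_seeds("spindle")
    mu_rep = np.repeat(mu_values, len(res.seeds))
    rho, p = scipy.stats.spearmanr(mu_rep, res.spindle_rate.ravel())
    # R^2 of the linear trend of the per-mu means
    if np.std(per_mu) > 0:
        r2 = float(scipy.stats.linregress(mu_values, per_mu).rvalue ** 2)
    else:
        r2 = 0.0
    return {
        "mu": mu_values,
        "spindle_rate": res.spindle_rate,
        "per_mu_mean": per_mu,
        "mean": float(per_mu.mean()),
        "sd": float(per_mu.std()),
        "trend_spearman_rho": float(rho),
        "trend_spearman_p": float(p),
        "trend_r2": r2,
        "sweep": res,
    }


_PV_PROJECTIONS = ("n_t1r1", "n_t2r1", "n_rr", "n_r1p", "n_r1r2",
                   "n_r1t1", "n_r1t2")
_SOM_PROJECTIONS = ("n_t2r2", "n_rr2", "n_r2t2", "n_r1r2")


def _ablated(params: ModelParameters, mode: str) -> ModelParameters:
    mode = mode.lower().replace("_", "-")
    if mode in ("pv+som", "full"):
        return params.copy()
    if mode == "pv-only":
        removed = _SOM_PROJECTIONS
    elif mode == "som-only":
        removed = _PV_PROJECTIONS
    else:
        raise ValueError(f"unknown ablation mode {mode!r}")
    return params.replace(**{n: 0.0 for n in removed})


def ablate_population(params: ModelParameters | None = None, seeds=(0, 1, 2),
                      epoch: float = 60.0, modes=("pv+som", "pv-only",
                                                  "som-only")) -> AblationResult:
    """Compare event rates and reticular firing with one inhibitory
    population removed (all its incoming and outgoing projections zeroed)."""
    base = params or ModelParameters()
    rates, per_seed, traces = {}, {}, {}
    for mode_idx, mode in enumerate(modes):
        p = _ablated(base, mode)
        spk_list, spn_list = [], []
        q_pv = q_som = t = None
        for j, seed in enumerate(seeds):
            spk, spn, eeg = run_cell(p, _cell_seed(seed, mode_idx, j),
                                     epoch=epoch, record_aux=(j == 0))
            spk_list.append(spk)
            spn_list.append(spn)
            if j == 0:
                q_pv, q_som, t = eeg.aux["q_pv"], eeg.aux["q_som"], eeg.aux["t"]
        rates[mode] = {"spike_rate": float(np.mean(spk_list)),
                       "spindle_rate": float(np.mean(spn_list)),
                       "mean_q_pv": float(np.mean(q_pv)),
                       "mean_q_som": float(np.mean(q_som))}
        per_seed[mode] = {"spike_rate": spk_list, "spindle_rate": spn_list}
        traces[mode] = {"q_pv": q_pv, "q_som": q_som, "t": t}
    kw = {}
    for which in ("spike_rate", "spindle_rate"):
        groups = [per_seed[m][which] for m in modes]
        try:
            h, p_val = scipy.stats.kruskal(*groups)
        except ValueError:  # all-identical groups
            h, p_val = 0.0, 1.0
        kw[which] = (float(h), float(p_val))
    return AblationResult(rates=rates, per_seed=per_seed,
                          firing_traces=traces, kruskal=kw)


def current_density_profiles(param_name: str, values,
                             base_params: ModelParameters | None = None,
                             seeds=(0, 1), epoch: float = 60.0) -> pd.DataFrame:
    """Time-averaged |I_NMDA|, |I_h| and reticular/relay firing rates along a
    one-parameter sweep (the mechanism profiles behind the spike-rate map)."""
    base = base_params or ModelParameters()
    rows = []
    for i, v in enumerate(np.asarray(values, dtype=float)):
        p = base.replace(**{param_name: float(v)})
        acc = []
        for j, seed in enumerate(seeds):
            spec = IntegrationSpec(duration=epoch + 10.0, burn_in=10.0,
                                   seed=_cell_seed(seed, i, j))
            eeg = simulate(p, spec)
            acc.append([eeg.aux["mean_abs_i_nmda"], eeg.aux["mean_abs_i_h"],
                        eeg.aux["mean_q_pv"] + eeg.aux["mean_q_som"],
                        eeg.aux["mean_q_vpm"] + eeg.aux["mean_q_vpl"]])
        m = np.mean(acc, axis=0)
        rows.append({param_name: v, "mean_abs_i_nmda": m[0],
                     "mean_abs_i_h": m[1], "q_trn": m[2], "q_vb": m[3]})
    return pd.DataFrame(rows)
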