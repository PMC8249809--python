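"""Bayesian parameter estimation from EEG features.

The posterior over a parameter subset theta (by default the Mg-block factor
mu and the h-conductance g_h) combines two likelihoods:

* a multitaper spectral likelihood: each observed power bin P_i is treated
  as Gamma(K, Pbar_i(theta)/K) distributed around the model spectrum
  Pbar(theta), K being the taper count — the standard asymptotic law of a
  K-taper average of exponentially distributed periodogram bins;
* an ISI-histogram likelihood: independent Gaussians with SD sigma around
  the model histogram bins.

The forward model is stochastic, so model features are averaged over a
small number of replicate simulations with seeds held fixed across theta
(common random numbers), which makes the log-posterior a deterministic
function of theta and keeps random-walk Metropolis well behaved.  The MAP
estimate is the chain sample with the largest stored log-posterior.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .features import (
    isi_histogram,
    likelihood_grid_power,
    multitaper_psd,
    detect_spikes,
    SpikeDetectorConfig,
)
from .integrator import IntegrationSpec, simulate
from .params import ModelParameters, MU_RANGE, GH_RANGE

__all__ = [
    "FeatureVector",
    "PriorSpec",
    "ChainConfig",
    "PosteriorChain",
    "extract_features",
    "ForwardModel",
    "spectral_log_likelihood",
    "isi_log_likelihood",
    "log_posterior",
    "mcmc_sample",
    "map_estimate",
]

log = logging.getLogger("renmm.inference")

_DEFAULT_BOUNDS = {"mu": MU_RANGE, "g_h": GH_RANGE}


@dataclass
class FeatureVector:
    """The two fitted features of one EEG epoch."""

    power: np.ndarray          # on the integer-Hz likelihood grid
    isi: np.ndarray            # histogram probabilities (M bins)
    fs: float
    epoch: float               # s
    n_tapers: int
    n_bins: int
    n_spikes: int = 0


@dataclass
class PriorSpec:
    """Independent uniform priors within the physical parameter ranges."""

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in _DEFAULT_BOUNDS.items()})

    @property
    def names(self) -> list[str]:
        return list(self.bounds)

    def log_prior(self, theta: np.ndarray) -> float:
        for value, (lo, hi) in zip(theta, self.bounds.values()):
            if not (lo <= value <= hi):
                return -math.inf
        return -sum(math.log(hi - lo) for lo, hi in self.bounds.values())

    def midpoint(self) -> np.ndarray:
        return np.array([(lo + hi) / 2 for lo, hi in self.bounds.values()])

    def widths(self) -> np.ndarray:
        return np.array([hi - lo for lo, hi in self.bounds.values()])


@dataclass
class ChainConfig:
    n_steps: int = 2000
    proposal_scale: float = 0.15   # fraction of each prior width
    seed: int = 0
    n_rep: int = 3                 # forward replicates per theta
    sigma_isi: float | None = None  # None -> estimated at the prior midpoint
    isi_bins: int = 20
    isi_range: tuple[float, float] = (0.0, 5.0)
    epoch: float = 60.0            # forward epoch length (s)
    burn_in: float = 10.0


@dataclass
class PosteriorChain:
    samples: np.ndarray        # (n_steps, n_params)
    log_posterior: np.ndarray  # (n_steps,)
    names: list[str]
    acceptance_rate: float
    seed: int
    meta: dict = field(default_factory=dict)


def extract_features(signal: np.ndarray, fs: float, n_bins: int = 20,
                     isi_range: tuple[float, float] = (0.0, 5.0),
                     spike_cfg: SpikeDetectorConfig | None = None,
                     ) -> FeatureVector:
    """Multitaper spectrum (integer-Hz grid) + ISI histogram of one epoch."""
    x = np.asarray(signal, dtype=float)
    spec = multitaper_psd(x, fs)
    power = likelihood_grid_power(spec, fs)
    spikes = detect_spikes(x, fs, spike_cfg)
    hist = isi_histogram(spikes, n_bins=n_bins, t_range=isi_range)
    return FeatureVector(power=power, isi=hist.probabilities, fs=fs,
                         epoch=x.size / fs, n_tapers=spec.n_tapers,
                         n_bins=n_bins, n_spikes=int(spikes.size))


class ForwardModel:
    """theta -> averaged FeatureVector from replicate simulations.

    Replicate seeds are derived once from ``base_seed`` and reused for every
    theta (common random numbers).  Results are memoized per theta.
    """

    def __init__(self, base_params: ModelParameters, names: list[str],
                 fs: float = 200.0, epoch: float = 60.0, burn_in: float = 10.0,
                 n_rep: int = 3, base_seed: int = 0, n_bins: int = 20,
                 isi_range: tuple[float, float] = (0.0, 5.0)):
        self.base_params = base_params
        self.names = list(names)
        self.fs = fs
        self.epoch = epoch
        self.burn_in = burn_in
        self.n_bins = n_bins
        self.isi_range = isi_range
        self.seeds = [int((base_seed * 9973 + 7 * r + 1) % (2 ** 31 - 1))
                      for r in range(n_rep)]
        self._cache: dict[tuple, FeatureVector] = {}
        self.n_evaluations = 0

    def __call__(self, theta) -> FeatureVector:
        key = tuple(np.round(np.asarray(theta, dtype=float), 12))
        if key in self._cache:
            return self._cache[key]
        p = self.base_params.replace(**dict(zip(self.names, theta)))
        powers, hists, n_spk = [], [], 0
        for seed in self.seeds:
            spec = IntegrationSpec(duration=self.epoch + self.burn_in,
                                   burn_in=self.burn_in, seed=seed,
                                   output_rate=self.fs)
            eeg = simulate(p, spec)
            fv = extract_features(eeg.samples, eeg.fs, n_bins=self.n_bins,
                                  isi_range=self.isi_range)
            powers.append(fv.power)
            hists.append(fv.isi)
            n_spk += fv.n_spikes
        out = FeatureVector(power=np.mean(powers, axis=0),
                            isi=np.mean(hists, axis=0), fs=self.fs,
                            epoch=self.epoch, n_tapers=fv.n_tapers,
                            n_bins=self.n_bins, n_spikes=n_spk)
        self._cache[key] = out
        self.n_evaluations += 1
        return out


def spectral_log_likelihood(p_obs: np.ndarray, p_model: np.ndarray,
                            n_tapers: int, eps: float = 1e-12) -> float:
    """Gamma(K, Pbar/K) log likelihood of the observed spectrum.

    log p = sum_i [K log K - log Gamma(K) + (K-1) log P_i
                   - K log Pbar_i - K P_i / Pbar_i]
    Model bins are floored at ``eps`` to keep the density defined.
    """
    if n_tapers < 1:
        raise ValueError("taper count must be >= 1")
    p_obs = np.asarray(p_obs, dtype=float)
    p_model = np.maximum(np.asarray(p_model, dtype=float), eps)
    if p_obs.shape != p_model.shape:
        raise ValueError("observed and model spectra must share one grid")
    k = float(n_tapers)
    po = np.maximum(p_obs, eps)
    ll = (k * math.log(k) - math.lgamma(k)) * p_obs.size \
        + (k - 1.0) * np.log(po).sum() \
        - k * np.log(p_model).sum() - k * (p_obs / p_model).sum()
    return float(ll)


def isi_log_likelihood(d_obs: np.ndarray, d_model: np.ndarray,
                       sigma: float) -> float:
    """Independent-Gaussian log likelihood over histogram bins."""
    d_obs = np.asarray(d_obs, dtype=float)
    d_model = np.asarray(d_model, dtype=float)
    if d_obs.shape != d_model.shape:
        raise ValueError("observed and model histograms must share binning")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    resid = d_obs - d_model
    n = d_obs.size
    return float(-0.5 * np.sum(resid ** 2) / sigma ** 2
                 - n * math.log(math.sqrt(2 * math.pi) * sigma))


def log_posterior(theta, features_obs: FeatureVector, priors: PriorSpec,
                  forward: ForwardModel, sigma_isi: float,
                  weights: tuple[float, float] = (1.0, 1.0)) -> float:
    """Unnormalized log posterior: spectral + ISI log likelihoods + log prior."""
    theta = np.asarray(theta, dtype=float)
    lp = priors.log_prior(theta)
    if not np.isfinite(lp):
        return -math.inf
    fv = forward(theta)
    ll_spec = spectral_log_likelihood(features_obs.power, fv.power,
                                      features_obs.n_tapers)
    ll_isi = isi_log_likelihood(features_obs.isi, fv.isi, sigma_isi)
    return float(weights[0] * ll_spec + weights[1] * ll_isi + lp)


def estimate_isi_sigma(forward: ForwardModel, priors: PriorSpec,
                       floor: float = 0.02) -> float:
    """Empirical SD of histogram bins across the forward replicates at the
    prior midpoint (floored to avoid a degenerate likelihood)."""
    theta0 = priors.midpoint()
    p = forward.base_params.replace(**dict(zip(forward.names, theta0)))
    hists = []
    for seed in forward.seeds:
        spec = IntegrationSpec(duration=forward.epoch + forward.burn_in,
                               burn_in=forward.burn_in, seed=seed,
                               output_rate=forward.fs)
        eeg = simulate(p, spec)
        fv = extract_features(eeg.samples, eeg.fs, n_bins=forward.n_bins,
                              isi_range=forward.isi_range)
        hists.append(fv.isi)
    sd = float(np.std(np.asarray(hists), axis=0).mean())
    return max(sd, floor)


def mcmc_sample(features_obs: FeatureVector, priors: PriorSpec | None = None,
                chain_cfg: ChainConfig | None = None,
                base_params: ModelParameters | None = None,
                forward: ForwardModel | None = None,
                likelihood_off: bool = False) -> PosteriorChain:
    """Random-walk Metropolis over the chosen parameter subset.

    ``likelihood_off`` samples the prior alone (smoke test).  Acceptance
    rates outside [1%, 99%] trigger a warning in the chain metadata.
    """
    priors = priors or PriorSpec()
    cfg = chain_cfg or ChainConfig()
    names = priors.names
    if forward is None:
        forward = ForwardModel(base_params or ModelParameters(), names,
                               fs=features_obs.fs if features_obs else 200.0,
                               epoch=cfg.epoch, burn_in=cfg.burn_in,
                               n_rep=cfg.n_rep, base_seed=cfg.seed,
                               n_bins=cfg.isi_bins, isi_range=cfg.isi_range)
    if likelihood_off:
        def logp(theta):
            return priors.log_prior(theta)
    else:
        sigma = cfg.sigma_isi if cfg.sigma_isi is not None \
            else estimate_isi_sigma(forward, priors)

        def logp(theta):
            return log_posterior(theta, features_obs, priors, forward, sigma)

    rng = np.random.default_rng(cfg.seed)
    step = cfg.proposal_scale * priors.widths()
    theta = priors.midpoint()
    lp = logp(theta)
    samples = np.empty((cfg.n_steps, len(names)))
    lps = np.empty(cfg.n_steps)
    n_acc = 0
    for i in range(cfg.n_steps):
        prop = theta + step * rng.standard_normal(len(names))
        lp_prop = logp(prop)
        if math.log(rng.random()) < lp_prop - lp:
            theta, lp = prop, lp_prop
            n_acc += 1
        samples[i] = theta
        lps[i] = lp
    acc = n_acc / cfg.n_steps
    log.info("chain finished: %d steps, acceptance %.2f, %d forward evals",
             cfg.n_steps, acc, forward.n_evaluations)
    meta = {"n_forward_evaluations": forward.n_evaluations if not likelihood_off else 0}
    if not likelihood_off and not (0.01 <= acc <= 0.99):
        meta["warning"] = f"acceptance rate {acc:.3f} outside [0.01, 0.99]"
    return PosteriorChain(samples=samples, log_posterior=lps, names=names,
                          acceptance_rate=acc, seed=cfg.seed, meta=meta)


def map_estimate(chain: PosteriorChain) -> dict[str, float]:
    """Chain sample with the largest stored log posterior."""
    if chain.samples.size == 0:
        raise ValueError("empty chain")
    i = int(np.argmax(chain.log_posterior))
    return dict(zip(chain.names, chain.samples[i]))
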