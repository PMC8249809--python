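# Methods

## The model

`renmm` implements a five-population neural mass model of the somatosensory
(Rolandic) thalamocortical circuit during NREM sleep: one cortical pyramidal
population (PY) and four thalamic populations — the parvalbumin (PV) and
somatostatin (SOM) inhibitory populations of the thalamic reticular nucleus
(TRN), and the excitatory ventral posteromedial (VPM) and posterolateral
(VPL) relay populations of the ventrobasal complex (VB).  The cortical
membrane potential V_p is the model output and is treated as the simulated
EEG.

Each population maps its mean membrane potential to a mean firing rate
through a sigmoid,

    Q(V) = Q_max / (1 + exp(-(V - theta) / sigma)),

and synapses act as critically damped second-order linear filters of the
presynaptic rates ("alpha-function" kernels gamma^2 t e^{-gamma t}).  The
eleven synaptic channels are AMPA (rate constant gamma_e = 0.07 /ms) onto
all five populations, GABA_A (gamma_N = 0.1 /ms) onto the four thalamic
populations, and NMDA onto PV and SOM.  The NMDA pair is deliberately *not*
critically damped: its stiffness is gamma_g*gamma_n with damping 2*gamma_n
(gamma_g = 0.1, gamma_n = 0.03 /ms), giving a slower, slightly
under-coupled kernel.  The NMDA conductance is gated by the voltage-
dependent magnesium block

    B(V) = 1 / (1 + [Mg] exp(-mu * 0.062 V) / 3.57),

whose sensitivity factor mu is the model's proxy for GRIN2A-type receptor
alterations: raising mu closes the channel harder at hyperpolarized
potentials and so *reduces* NMDA drive to the TRN.

Membrane equations are conductance-based.  The cortex carries leak and AMPA
input only; the four thalamic populations additionally carry
Hodgkin–Huxley-type intrinsic currents scaled by 1/C_m: a potassium leak
I_LK = g_LK (V - E_LK), a low-threshold calcium current
I_T = g_T m_inf(V)^2 h_T (V - E_Ca) with instantaneous activation and
first-order inactivation, and — in the relay populations only — an
anomalous rectifier I_h = g_h (V - E_h)(m_h1 + g_inc m_h2) whose
calcium-regulated "locked-open" fraction m_h2 produces the slow waxing and
waning of thalamic oscillations: calcium entering through I_T binds a
messenger P, which locks open h-channels; the locked fraction decays on a
seconds timescale (k4 = 1e-3 /ms).

Corticothalamic conduction delays are modeled as second-order alpha-function
filters (rate nu) applied to the PY, VPM and VPL rates on the five
cortex<->thalamus pathways, rather than as discrete lags.

## Parameters

All printed physiological constants are used exactly as published (sigmoid
constants, synaptic rate constants, the full connectivity table, reversal
potentials including the thalamic E_GABA = -70 mV, conductance ranges, and
noise SDs).  The resting configuration of `ModelParameters()` is the mixed
spike+spindle operating point mu = 2, g_h = 0.058 mS/cm^2, g_T = 2.9,
g_LK = 0.042, with the three TRN->VB inhibition strengths at the midpoints
of their physiological ranges (n_t1r1 = 3.25, n_t2r1 = n_t2r2 = 1.5).
The spindle-permissive regime used for spindle-frequency work is the same
quadruple at reduced Mg-block sensitivity (mu = 1.75); the spike regime is
the quadruple at g_h = 0.056.

Constants that the source parameterization leaves open are config fields:

* cortical firing threshold theta_p = -58.5 mV (the thalamic value);
* extracellular [Mg2+] = 1 mM (the standard Jahr–Stevens concentration);
* delay rate nu = 0.1 /ms (kernel peak 10 ms, a typical one-way
  corticothalamic latency).  Event statistics are insensitive to +/-50%
  changes in nu because the cortical population operates near rate
  saturation, so the delayed cortical drive is nearly constant;
* T-current and h-current gating kinetics, adopted from the standard
  thalamic relay/reticular formulations:
  relay m_inf midpoint -59 mV (slope 6.2), h_inf midpoint -81 mV (slope 4);
  reticular m_inf midpoint -52 mV (7.4), h_inf midpoint -80 mV (5); the
  voltage-dependent inactivation times tau_h as usually written, divided by
  an effective temperature adjustment `tadj_t`; h-current activation
  m_inf midpoint -75 mV (5.5) with its usual bell-shaped tau_m, calcium
  pool alpha_Ca = -51.8e-6, tau_Ca = 10 ms, binding constants
  k1 = 2.5e7 mM^-4 ms^-1, k2 = 4e-4, k3 = 0.1, k4 = 1e-3 ms^-1.

`tadj_t` deserves a note.  At the single-cell 36 C value (3.74) the
population-level system has a globally stable equilibrium across the whole
physiological (mu, g_h, TRN-inhibition) box — no discharges, no sigma
oscillation — because lumping a bursting cell population into one mean
rate unit smooths away the single-cell burst nonlinearity.  The effective
inactivation timescale of the *population* is a free constant of the
lumped description.  It is fixed once at tadj_t = 2.1, the value at which
the thalamic loop exhibits, inside the physiological ranges, the regime
structure this circuit is known for: a quiet state at low mu/high g_h,
frequent epileptiform discharges at high mu/low g_h, and sigma-band
(~11 Hz) spindle events in between.  All experiments and tests run with
this single default; no experiment re-tunes it.

Two structural corrections of apparent typographical errors are applied
(and can be disabled with `strict_as_printed=True`): the SOM GABA equation
relaxes toward its own state rather than the PV one, and the PV
self-inhibition constant is the tabulated n_rr = 15.

## Stochastic integration

Background activity enters as three independent Gaussian white-noise
sources in the synaptic drives of the cortical (SD 0.12 /ms), relay VPM
(0.02) and reticular SOM (0.01) AMPA channels.  Because the noise is
additive (state-independent, acting on the r_dot components with constant
amplitude gamma_e^2 * sd), the stochastic Runge–Kutta scheme uses the
classical RK4 tableau on the drift plus the exact Gaussian increment
g sqrt(dt) xi per step — strong order 1.0 for additive noise, reducing
*exactly* to RK4 when the noise is off.  A plain Euler–Maruyama stepper at
a 10x finer step serves as an independent distributional cross-check.
Working step size: dt = 0.1 ms.

Simulations start from leak-reversal potentials with synaptic states at
rest and gating at steady state; the first 10 s are discarded (the
calcium/locked-h subsystem equilibrates on seconds).  The output V_p is
low-pass filtered (8th-order zero-phase Butterworth at 80% of the output
Nyquist) and decimated to 200 Hz.

## Event detection and features

*Spikes* (epileptiform discharges): robust z-score (median/MAD) of the
1–50 Hz band-passed signal and of its first derivative, combined
element-wise; peaks above z = 4 with a 200 ms refractory period.  The
z-normalization makes detection invariant to amplitude rescaling, and the
derivative channel emphasizes the sharp transient morphology.

*Spindles*: 10–16 Hz band-pass, squared Hilbert envelope smoothed with a
100 ms moving average, threshold 4.5x the mean smoothed power (the
classic sigma-band amplitude criterion), minimum duration 0.4 s, events
closer than 0.3 s merged.  Rates are reported per minute.  The dominant
frequency of an event set is the mean argmax of per-event multitaper
spectra (NW = 2, 3 tapers) within 9–16 Hz.

*Features for fitting*: (i) multitaper PSD with Slepian tapers,
eigenvalue-weighted, half-bandwidth ~0.5 Hz (K = 2 NW - 1 tapers),
interpolated onto the integer-Hz grid 1..floor(fs/2); (ii) the normalized
inter-spike-interval histogram, 20 right-closed bins over 0–5 s
(intervals outside the range are clipped into the outer bins so the
probabilities sum to one).

## Inference

The posterior over (mu, g_h) — uniform priors on their physiological
ranges — combines a Gamma(K, Pbar_i/K) likelihood per spectral bin (the
asymptotic law of a K-taper spectral average; normalizers that do not
depend on theta only shift the log posterior by a constant) with an
independent-Gaussian likelihood over ISI-histogram bins whose SD defaults
to the empirical between-replicate SD at the prior midpoint (floored at
0.02).  The forward model averages features over n_rep = 3 replicate
simulations whose seeds are fixed across theta (common random numbers), so
the log posterior is a deterministic function of theta; this controls the
pseudo-marginal noise at the cost of a small, seed-dependent bias that
shrinks with epoch length.  Sampling is random-walk Metropolis started at
the prior midpoint with Gaussian proposals of 8–15% of the prior widths;
the MAP estimate is the chain sample with the largest stored log
posterior.  Model records with fewer than two detected spikes produce an
all-zero histogram rather than an undefined one.

## Problem sizes

Published sweeps use 41-point axes and one-minute epochs.  The package
supports those scales, and its own experiments and checks run reduced
versions chosen as desk-scale defaults: 9x9 grids for the (mu, g_h) map,
a 5-point diagonal of the 3-D inhibition grid, 9-point mu sweeps, 3 seeds
per cell, 30–60 s scored epochs (120 s for spindle-frequency estimates,
which average few events per minute); parameter-recovery studies use 5
surrogate records, 100-step chains and 2 forward replicates.

## What the surrogate data do and do not show

All fixtures are either (a) the model itself simulated at known parameters
— which validates the estimation and detection *pipeline*, not the model's
fidelity to patients — or (b) synthetic records with injected spike/spindle
templates on band-limited 1/f noise, which give exact ground truth for
detector unit tests but idealize real EEG (no artifacts, no non-stationary
background, amplitude-clipped noise so that annotations stay exact).
Agreement on these fixtures says nothing about clinical detector accuracy.

## Known limitations

* The cortical population has no inhibitory input (as specified), and its
  strong recurrent excitation (n_pp Q_p^max ≈ 2.1) saturates the sigmoid:
  V_p acts as a static nonlinear readout of thalamic activity, and EEG
  events are thalamically generated.
* With the printed thalamic GABA reversal at the leak potential (-70 mV),
  inhibition onto the relay populations modulates and can suppress the
  sigma-band loop, but cannot hyperpolarize the relay cells below -70 mV;
  rebound-driven spindle amplification by *stronger* TRN inhibition does
  not occur.  Consequently, along the inhibition diagonal spike rate falls
  monotonically while spindle events peak at intermediate inhibition and
  vanish when the loop is fully suppressed, and removing the PV population
  silences (rather than disinhibits) the discharge-generating loop.  A
  hyperpolarized reversal (e.g. -85 mV) restores inhibition-driven rebound
  spindles but inverts the spike-suppression direction; the printed value
  is kept.
* Spindle-event rates at the mixed operating point come out near 2 per
  minute versus the published 4.5 +/- 2.3, and cells with strong NMDA
  drive to the TRN (mu < 0.5) are often quiet, so the spindle rate is not
  flat in mu.  The detected events themselves oscillate at ~12 Hz (11 Hz
  published).
* The Mg-block saturates above mu ~ 1.5 (the NMDA current is already near
  zero), so mu is only weakly identifiable from single 30-s epochs in the
  upper half of its range; g_h recovers reliably, mu ordering only
  approximately.
* The likelihoods treat spectral bins and histogram bins as independent,
  which overstates information content; posterior widths should not be
  interpreted as calibrated credible intervals.
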