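# renmm — a thalamocortical neural mass model of Rolandic epilepsy

Rolandic epilepsy is the most common focal childhood epilepsy: during NREM
sleep the EEG over the centrotemporal (Rolandic) cortex fills with
high-voltage epileptiform spikes while sleep spindles — the 10–16 Hz
oscillations generated by the same thalamocortical loop — become scarce.
`renmm` is a simulation and inference package for studying this
spike/spindle competition.  It implements a five-population neural mass
model of the Rolandic circuit: a cortical pyramidal population (PY)
coupled to the parvalbumin (PV) and somatostatin (SOM) inhibitory
populations of the thalamic reticular nucleus and the excitatory VPM/VPL
relay populations of the ventrobasal thalamus.

Two disease-linked parameters are first-class citizens:

* **mu** — the voltage-sensitivity factor of the NMDA-receptor Mg²⁺ block
  B(V) = 1/(1 + [Mg] e^{-mu·0.062·V}/3.57) on the reticular populations
  (a proxy for GRIN2A receptor alterations); larger mu means less NMDA
  current;
* **g_h** — the conductance of the hyperpolarization-activated h-current
  in the relay populations (a proxy for HCN channelopathies).

The package provides, on top of the model core:

* a seeded stochastic Runge–Kutta integrator (dt = 0.1 ms, additive noise)
  with an Euler–Maruyama cross-check;
* spike and spindle detectors and the two fitted features (multitaper
  power spectrum, inter-spike-interval histogram);
* the in-silico experiments: the mu × g_h spike-rate map, the
  reticular-inhibition competition sweep, the NMDA-vs-spindle-rate check,
  PV/SOM ablation, and NMDA/h current-density profiles;
* MCMC estimation of (mu, g_h) from single-channel EEG with MAP
  extraction, validated by parameter recovery on model-generated
  surrogate EEG.

See `docs/methods.md` for the equations, parameter provenance, and known
limitations.

## Worked example

Simulate one minute of EEG in the mixed spike+spindle regime, score it,
and look at the event statistics:

```python
from renmm import (ModelParameters, IntegrationSpec, simulate,
                   extract_events, spindle_peak_frequency)

params = ModelParameters()            # mixed regime: mu=2, g_h=0.058
spec = IntegrationSpec(duration=70.0, burn_in=10.0, seed=9)
eeg = simulate(params, spec)          # 60 s of V_p at 200 Hz after burn-in

events = extract_events(eeg.samples, eeg.fs)
print(f"spike rate   {events.spike_rate:.1f} /min")
print(f"spindle rate {events.spindle_rate:.1f} /min")
print(f"spindle peak {spindle_peak_frequency(eeg.samples, eeg.fs, events.spindle_intervals):.1f} Hz")
```

```
spike rate   21.0 /min
spindle rate 4.0 /min
spindle peak 9.7 Hz
```

The spikes are the large sharp transients that the thalamic loop throws
at the cortex when NMDA drive to the reticular nucleus is low (high mu)
and the relay h-current is weak; the spindle events are waxing-waning
sigma-band oscillations of the same loop.  Lowering `mu` to 0.5 and
raising `g_h` to 0.066 (`params.replace(mu=0.5, g_h=0.066)`) silences the
record almost completely — the essence of the published spike-rate map.

The same pipeline is scriptable from the shell:

```bash
renmm simulate --duration 70 --seed 7 --out eeg.csv
renmm detect --in eeg.csv --report report.json
renmm sweep --plan mu_gh --grid 9 --seeds 3 --out sweep.csv
renmm fit --eeg eeg.csv --params mu,g_h --chain-length 2000 --seed 11 --out chain.csv
```

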