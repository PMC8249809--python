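"""Configuration files, EEG I/O, logging setup, and fixture generation.

CSV is the lossless interchange format (columns time_s, vp_mV).  EDF+ is
supported as the clinical-interchange format: files are read through mne's
EDF reader; writing uses a minimal single-channel 16-bit EDF writer
implemented here (no EDF-writing backend ships with the scientific stack
this package targets), validated round-trip against the mne reader.

Fixtures are model-generated surrogate EEG epochs at known parameter
settings (spike / spindle / mixed regimes), or synthetic records with
injected spike and spindle templates on 1/f background noise carrying
exact ground-truth annotations for detector tests.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.signal
import yaml

from .features import SpikeDetectorConfig, SpindleDetectorConfig
from .integrator import IntegrationSpec, SimulatedEEG, simulate
from .params import ModelParameters
from . import experiments

__all__ = [
    "RunConfig",
    "Fixture",
    "load_config",
    "save_config",
    "read_eeg",
    "write_eeg",
    "make_fixture",
    "setup_logging",
]

log = logging.getLogger("renmm")


def setup_logging(verbosity: int = 0) -> None:
    level = [logging.WARNING, logging.INFO, logging.DEBUG][min(verbosity, 2)]
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s")


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    model: ModelParameters = field(default_factory=ModelParameters)
    integration: IntegrationSpec = field(default_factory=IntegrationSpec)
    spike_detector: SpikeDetectorConfig = field(default_factory=SpikeDetectorConfig)
    spindle_detector: SpindleDetectorConfig = field(default_factory=SpindleDetectorConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "integration": dataclasses.asdict(self.integration),
            "spike_detector": dataclasses.asdict(self.spike_detector),
            "spindle_detector": dataclasses.asdict(self.spindle_detector),
            "seed": self.seed,
        }


def _build_section(cls, data: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    bad = set(data) - known
    if bad:
        raise ValueError(f"unknown keys in config section {section!r}: "
                         f"{sorted(bad)}")
    kwargs = {}
    for k, v in data.items():
        kwargs[k] = tuple(v) if isinstance(v, list) else v
    return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML/JSON run configuration; missing keys fall back to the
    published defaults, unknown keys raise."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        return RunConfig()
    if path.suffix in (".yml", ".yaml"):
        data = yaml.safe_load(text) or {}
    else:
        data = json.loads(text)
    known = {"model", "integration", "spike_detector", "spindle_detector",
             "seed"}
    bad = set(data) - known
    if bad:
        raise ValueError(f"unknown top-level config keys: {sorted(bad)}")
    cfg = RunConfig()
    if "model" in data:
        cfg.model = ModelParameters.from_dict(data["model"])
    if "integration" in data:
        cfg.integration = _build_section(IntegrationSpec, data["integration"],
                                         "integration").validate()
    if "spike_detector" in data:
        cfg.spike_detector = _build_section(SpikeDetectorConfig,
                                            data["spike_detector"],
                                            "spike_detector")
    if "spindle_detector" in data:
        cfg.spindle_detector = _build_section(SpindleDetectorConfig,
                                              data["spindle_detector"],
                                              "spindle_detector")
    if "seed" in data:
        cfg.seed = int(data["seed"])
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    path = Path(path)
    data = cfg.to_dict()
    if path.suffix in (".yml", ".yaml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2))


# ---------------------------------------------------------------------------
# EEG file I/O
# ---------------------------------------------------------------------------

def write_eeg(path: str | Path, eeg: SimulatedEEG) -> Path:
    """Write a single-channel record; format chosen by extension
    (.csv or .edf)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.DataFrame({"time_s": eeg.times, "vp_mV": eeg.samples})
        with open(path, "w") as fh:
            # provenance header: the record is regenerable from this line
            fh.write("# renmm-meta: "
                     + json.dumps(eeg.meta, default=str) + "\n")
            df.to_csv(fh, index=False)
    elif path.suffix.lower() == ".edf":
        _write_edf(path, eeg)
    else:
        raise ValueError(f"unsupported EEG format {path.suffix!r}")
    log.info("wrote %s (%d samples at %g Hz)", path, len(eeg.samples), eeg.fs)
    return path


def read_eeg(path: str | Path) -> SimulatedEEG:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        meta = {"source": str(path)}
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("# renmm-meta: "):
            meta.update(json.loads(first[len("# renmm-meta: "):]))
        df = pd.read_csv(path, comment="#")
        t = df["time_s"].to_numpy()
        fs = 1.0 / np.median(np.diff(t)) if t.size > 1 else 1.0
        return SimulatedEEG(samples=df["vp_mV"].to_numpy(),
                            fs=float(round(fs, 6)), meta=meta)
    if path.suffix.lower() == ".edf":
        import mne
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data()[0] * 1e3  # mne returns Volts; channel is in mV
        return SimulatedEEG(samples=np.asarray(data, dtype=float),
                            fs=float(raw.info["sfreq"]),
                            meta={"source": str(path)})
    raise ValueError(f"unsupported EEG format {path.suffix!r}")


def _write_edf(path: Path, eeg: SimulatedEEG, label: str = "VP-SIM") -> None:
    """Minimal single-channel EDF+C writer (16-bit, 1-s data records)."""
    fs = eeg.fs
    spr = int(round(fs))  # samples per 1-s record
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    x = np.asarray(eeg.samples, dtype=float)
    n_rec = int(np.ceil(x.size / spr))
    padded = np.zeros(n_rec * spr)
    padded[:x.size] = x
    phys_min, phys_max = float(padded.min()), float(padded.max())
    if phys_max - phys_min < 1e-9:
        phys_max = phys_min + 1.0
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((padded - phys_min) * scale + dig_min).astype("<i2")

    def pad(s: str, n: int) -> bytes:
        return s[:n].ljust(n).encode("ascii")

    header = b"".join([
        pad("0", 8),                              # version
        pad("X X X X", 80),                       # patient id
        pad("Startdate X X X X", 80),             # recording id
        pad("01.01.00", 8), pad("00.00.00", 8),   # date, time
        pad(str(256 + 256), 8),                   # header bytes (1 signal)
        pad("EDF+C", 44),
        pad(str(n_rec), 8),
        pad("1", 8),                              # record duration (s)
        pad("1", 4),                              # number of signals
        # per-signal fields
        pad(label, 16),
        pad("simulated EEG", 80),
        pad("mV", 8),
        pad(f"{phys_min:.4f}"[:8], 8),
        pad(f"{phys_max:.4f}"[:8], 8),
        pad(str(dig_min), 8),
        pad(str(dig_max), 8),
        pad("", 80),                              # prefiltering
        pad(str(spr), 8),
        pad("", 32),                              # reserved
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(digital.tobytes())


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@dataclass
class Fixture:
    """Surrogate EEG with known generating parameters and annotations."""

    eeg: SimulatedEEG
    kind: str
    true_params: dict
    spike_times: np.ndarray | None = None        # exact, injected kinds only
    spindle_intervals: list | None = None


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude noise, unit SD, amplitude-clipped at 3.5 SD so that
    injected transients are the only super-threshold events (keeps the
    fixture's ground-truth annotations exact)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    x /= x.std()
    return np.clip(x, -3.5, 3.5)


def _spike_template(fs: float) -> np.ndarray:
    """Biphasic sharp transient (~70 ms) resembling an epileptiform spike."""
    t = np.arange(int(0.07 * fs)) / fs
    return (np.exp(-((t - 0.02) / 0.006) ** 2)
            - 0.45 * np.exp(-((t - 0.038) / 0.012) ** 2))


def make_fixture(kind: str, seed: int = 0, duration: float = 60.0,
                 fs: float = 200.0, spikes_per_min: float = 12.0,
                 spindles_per_min: float = 4.0) -> Fixture:
    """Generate a surrogate EEG epoch.

    kinds: 'spike_regime' (model at mu=2, g_h=0.056), 'spindle_regime'
    (model at the spindle-permissive point), 'mixed' (the mixed-regime
    quadruple), 'injected_events' (templates on 1/f noise with exact
    annotations).
    """
    if kind in ("spike_regime", "spindle_regime", "mixed"):
        regime = {"spike_regime": experiments.SPIKE_REGIME,
                  "spindle_regime": experiments.SPINDLE_REGIME,
                  "mixed": experiments.MIXED_REGIME}[kind]
        params = ModelParameters().replace(**regime)
        spec = IntegrationSpec(duration=duration + 10.0, burn_in=10.0,
                               seed=seed, output_rate=fs)
        eeg = simulate(params, spec)
        return Fixture(eeg=eeg, kind=kind, true_params=dict(regime))

    if kind != "injected_events":
        raise ValueError(f"unknown fixture kind {kind!r}")

    rng = np.random.default_rng(seed)
    n = int(duration * fs)
    from .features import _bandpass
    # confine the background to the detector's 1-50 Hz band so that the
    # robust-z scale seen by the detector matches the injected amplitudes
    x = _bandpass(_pink_noise(n, rng), fs, (1.0, 50.0))
    x /= x.std()
    x = np.clip(x, -3.5, 3.5)

    n_spikes = int(round(spikes_per_min * duration / 60.0))
    template = _spike_template(fs)
    # jittered regular spacing keeps exact counts and a refractory gap
    slots = np.linspace(0.5, duration - 1.0, max(n_spikes, 1))
    jitter = rng.uniform(-0.2, 0.2, size=slots.size)
    spike_times = np.sort(slots + jitter)[:n_spikes]
    for t0 in spike_times:
        i0 = int(t0 * fs)
        seg = template * 12.0  # ~12 SD amplitude
        x[i0:i0 + seg.size] += seg[:max(0, n - i0)]

    n_spin = int(round(spindles_per_min * duration / 60.0))
    spindle_intervals = []
    starts = np.linspace(2.0, duration - 3.0, max(n_spin, 1)) \
        + rng.uniform(-0.4, 0.4, size=max(n_spin, 1))
    for s in starts[:n_spin]:
        dur = rng.uniform(0.8, 1.4)
        tt = np.arange(int(dur * fs)) / fs
        burst = (np.sin(2 * np.pi * 11.5 * tt)
                 * scipy.signal.windows.tukey(tt.size, 0.5) * 3.2)
        i0 = int(s * fs)
        x[i0:i0 + burst.size] += burst[:max(0, n - i0)]
        spindle_intervals.append((float(s), float(s + dur)))

    eeg = SimulatedEEG(samples=x, fs=fs,
                       meta={"kind": kind, "seed": seed})
    return Fixture(eeg=eeg, kind=kind, true_params={},
                   spike_times=spike_times,
                   spindle_intervals=spindle_intervals)
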