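"""Parameter containers for the Rolandic-epilepsy thalamocortical neural mass model.

The model couples one cortical pyramidal population (PY) to four thalamic
populations: two inhibitory reticular-nucleus populations (PV, SOM) and two
excitatory ventrobasal relay populations (VPM, VPL).  Every physiological
constant carries its unit in the field docstring; defaults are the nominal
values of the published parameter table, with the mixed spike+spindle regime
(mu = 2, g_h = 0.058, g_T = 2.9, g_LK = 0.042) as the model's resting point.

All parameters are plain dataclasses that can be packed into a flat float64
vector (see :func:`pack_params`) for the compiled right-hand side.
"""

from __future__ import annotations

import copy
import dataclasses
import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import numpy as np
import yaml

__all__ = [
    "PopulationParams",
    "SynapseParams",
    "ConnectivityParams",
    "IntrinsicChannelParams",
    "NoiseParams",
    "DelayParams",
    "ModelParameters",
    "pack_params",
    "NPAR",
]

# Physical sweep ranges of the published parameter table.  Used for config
# validation and as default uniform prior bounds.
MU_RANGE = (0.1, 3.0)
GH_RANGE = (0.046, 0.066)
GT_RANGE = (1.6, 2.9)
N_T1R1_RANGE = (1.0, 5.5)
N_T2R1_RANGE = (1.0, 2.0)
N_T2R2_RANGE = (1.0, 2.0)


@dataclass
class PopulationParams:
    """Sigmoid rate function and membrane time constant of one population.

    q_max   maximal firing rate (ms^-1)
    theta   firing threshold (mV)
    sigma_gain  inverse neural gain (mV)
    tau     membrane time constant (ms)
    """

    q_max: float
    theta: float
    sigma_gain: float
    tau: float

    def validate(self) -> None:
        if not (self.q_max > 0 and self.sigma_gain > 0 and self.tau > 0):
            raise ValueError(
                "PopulationParams requires q_max > 0, sigma_gain > 0, tau > 0; "
                f"got {self}"
            )


@dataclass
class SynapseParams:
    """Second-order synaptic kinetics and reversal potentials.

    Rate constants are in ms^-1; the NMDA pair uses the asymmetric
    gamma_g*gamma_n stiffness with 2*gamma_n damping.  The synaptic input
    rates g_* are dimensionless scale factors applied to the open-channel
    proportion r.
    """

    gamma_e: float = 70e-3   # AMPA rate constant (ms^-1)
    gamma_g: float = 100e-3  # NMDA stiffness partner (ms^-1)
    gamma_n: float = 30e-3   # NMDA damping rate (ms^-1)
    gamma_N: float = 100e-3  # GABA rate constant (ms^-1)
    g_ampa: float = 1.0
    g_nmda: float = 1.0
    g_gaba: float = 1.0
    e_ampa: float = 0.0      # mV
    e_nmda: float = 0.0      # mV
    e_gaba: float = -70.0    # mV
    e_leak_cortex: float = -64.0    # mV
    e_leak_thalamus: float = -70.0  # mV

    def validate(self) -> None:
        for name in ("gamma_e", "gamma_g", "gamma_n", "gamma_N"):
            if getattr(self, name) <= 0:
                raise ValueError(f"synaptic rate constant {name} must be > 0")


@dataclass
class ConnectivityParams:
    """Connectivity constants N_{target,source} (dimensionless).

    Population codes: p = PY (cortex), r1 = PV, r2 = SOM (reticular nucleus),
    t1 = VPM, t2 = VPL (ventrobasal relay).  The three reticular->relay
    inhibitory strengths (n_t1r1, n_t2r1, n_t2r2) are the competition sweep
    axes; their defaults sit at the midpoints of the published sweep ranges.
    """

    n_pp: float = 70.0
    n_pt1: float = 3.0
    n_pt2: float = 2.0
    n_t1p: float = 3.0
    n_t1t2: float = 1.0
    n_t2p: float = 2.1
    n_t2t1: float = 1.0
    n_r1p: float = 2.6
    n_r1r2: float = 2.1
    n_r1t1: float = 4.0
    n_r1t2: float = 3.0
    n_rr: float = 15.0
    n_rr2: float = 25.0
    n_r2t2: float = 1.5
    n_t1r1: float = 3.25  # sweep range [1, 5.5]
    n_t2r1: float = 1.5   # sweep range [1, 2]
    n_t2r2: float = 1.5   # sweep range [1, 2]

    def validate(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"connectivity constant {f.name} must be >= 0")


@dataclass
class IntrinsicChannelParams:
    """Intrinsic (HH-type) thalamic currents and the NMDA Mg-block.

    Conductances are in mS/cm^2, potentials in mV, capacitance in uF/cm^2.
    mu scales the voltage sensitivity of the Mg2+ block (GRIN2A proxy) and
    g_h the h-current density (channelopathy proxy).  The gating-kinetics
    block (alpha_ca .. k4) parameterizes the calcium-regulated two-state
    h-current scheme and is documented in docs/methods.md.
    """

    g_lk: float = 0.042
    g_t_pv: float = 2.9
    g_t_som: float = 2.9
    g_t_vpm: float = 2.9
    g_t_vpl: float = 2.9
    g_h: float = 0.058
    g_inc: float = 2.0
    mu: float = 2.0
    mg_conc: float = 1.0   # extracellular [Mg2+] (mM)
    e_lk: float = -100.0
    e_ca: float = 120.0
    e_h: float = -40.0
    c_m: float = 1.0
    # calcium-regulated h-current kinetics
    alpha_ca: float = -51.8e-6  # Ca influx per unit I_T (mM cm^2 / (uA ms))
    ca_0: float = 2.4e-4        # resting intracellular [Ca2+] (mM)
    tau_ca: float = 10.0        # Ca decay time constant (ms)
    k1: float = 2.5e7           # Ca binding rate (mM^-4 ms^-1)
    k2: float = 4e-4            # Ca unbinding rate (ms^-1)
    k3: float = 0.1             # locking rate (ms^-1)
    k4: float = 1e-3            # unlocking rate (ms^-1)
    # temperature adjustment dividing the T-current inactivation time
    # constant (1 = the in-vitro kinetics as recorded; ~3.74 = 36 C).
    # The default is the population-level effective value at which the
    # thalamic loop exhibits sigma-band (spindle) oscillations and
    # spike events inside the published parameter ranges.
    tadj_t: float = 2.1

    def validate(self) -> None:
        for name in ("g_lk", "g_t_pv", "g_t_som", "g_t_vpm", "g_t_vpl", "g_h"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be >= 0")
        if not (MU_RANGE[0] <= self.mu <= MU_RANGE[1]):
            raise ValueError(
                f"mu = {self.mu} outside the physical range {MU_RANGE}"
            )
        if self.mg_conc < 0:
            raise ValueError("mg_conc must be >= 0")
        if self.c_m <= 0:
            raise ValueError("c_m must be > 0")


@dataclass
class NoiseParams:
    """Additive background-noise inputs (firing-rate units, ms^-1).

    phi_mean is the common mean; the three SDs drive the cortical (PY),
    relay (VPM) and reticular (SOM) synaptic inputs respectively.
    """

    phi_mean: float = 0.0
    phi_p_sd: float = 120e-3
    phi_t_sd: float = 20e-3
    phi_n_sd: float = 10e-3

    def validate(self) -> None:
        if min(self.phi_p_sd, self.phi_t_sd, self.phi_n_sd) < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass
class DelayParams:
    """Corticothalamic conduction delay, modeled as an alpha-function kernel.

    nu (ms^-1) is the kernel rate constant; the kernel peaks at 1/nu after
    the input, i.e. the default nu = 0.1 puts the bulk of the delayed input
    ~10 ms behind the source firing rate, a typical one-way corticothalamic
    latency.
    """

    nu: float = 0.1

    def validate(self) -> None:
        if self.nu <= 0:
            raise ValueError("delay rate constant nu must be > 0")


def _default_cortex() -> PopulationParams:
    return PopulationParams(q_max=30e-3, theta=-58.5, sigma_gain=4.7, tau=30.0)


def _default_thalamic() -> PopulationParams:
    return PopulationParams(q_max=400e-3, theta=-58.5, sigma_gain=6.0, tau=20.0)


@dataclass
class ModelParameters:
    """Complete parameter set of the five-population model."""

    cortex: PopulationParams = field(default_factory=_default_cortex)
    thalamic: PopulationParams = field(default_factory=_default_thalamic)
    synapse: SynapseParams = field(default_factory=SynapseParams)
    connectivity: ConnectivityParams = field(default_factory=ConnectivityParams)
    intrinsic: IntrinsicChannelParams = field(default_factory=IntrinsicChannelParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    delay: DelayParams = field(default_factory=DelayParams)
    # Reproduce the printed (structurally inconsistent) form of the SOM
    # self-inhibition equation instead of the corrected one.
    strict_as_printed: bool = False

    def validate(self) -> "ModelParameters":
        for f in fields(self):
            v = getattr(self, f.name)
            if hasattr(v, "validate"):
                v.validate()
        return self

    def copy(self) -> "ModelParameters":
        return copy.deepcopy(self)

    def replace(self, **flat: float) -> "ModelParameters":
        """Return a copy with flat parameter names changed.

        Accepts any leaf field name, e.g. ``replace(mu=0.5, g_h=0.066,
        n_t1r1=5.5)``.  Unknown names raise ``KeyError``.
        """
        out = self.copy()
        for name, value in flat.items():
            out._set_flat(name, value)
        return out

    # -- flat-name access ------------------------------------------------
    _FLAT_ALIASES = {
        "q_p_max": ("cortex", "q_max"),
        "theta_p": ("cortex", "theta"),
        "sigma_p": ("cortex", "sigma_gain"),
        "tau_p": ("cortex", "tau"),
        "q_y_max": ("thalamic", "q_max"),
        "theta_y": ("thalamic", "theta"),
        "sigma_y": ("thalamic", "sigma_gain"),
        "tau_z": ("thalamic", "tau"),
    }

    def _groups(self):
        return {
            f.name: getattr(self, f.name)
            for f in fields(self)
            if dataclasses.is_dataclass(getattr(self, f.name))
        }

    def _locate(self, name: str):
        if name in self._FLAT_ALIASES:
            grp, fld = self._FLAT_ALIASES[name]
            return getattr(self, grp), fld
        hits = [
            (obj, name)
            for obj in self._groups().values()
            if any(f.name == name for f in fields(obj))
        ]
        if not hits:
            raise KeyError(f"unknown model parameter {name!r}")
        if len(hits) > 1:  # pragma: no cover - no ambiguous names by design
            raise KeyError(f"ambiguous model parameter {name!r}")
        return hits[0]

    def _set_flat(self, name: str, value: float) -> None:
        if name == "strict_as_printed":
            self.strict_as_printed = bool(value)
            return
        obj, fld = self._locate(name)
        setattr(obj, fld, float(value))

    def get_flat(self, name: str) -> float:
        if name == "strict_as_printed":
            return self.strict_as_printed
        obj, fld = self._locate(name)
        return getattr(obj, fld)

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelParameters":
        """Build from a nested dict; missing keys fall back to defaults,
        unknown keys raise ``ValueError``."""
        out = cls()
        group_names = {f.name for f in fields(cls)}
        for key, val in d.items():
            if key == "strict_as_printed":
                out.strict_as_printed = bool(val)
                continue
            if key in group_names:
                obj = getattr(out, key)
                known = {f.name for f in fields(obj)}
                for k2, v2 in val.items():
                    if k2 not in known:
                        raise ValueError(f"unknown key {key}.{k2} in parameter config")
                    setattr(obj, k2, float(v2))
            else:
                # allow flat leaf names at top level
                try:
                    out._set_flat(key, val)
                except KeyError as e:
                    raise ValueError(str(e)) from e
        out.validate()
        _check_table_ranges(out)
        return out

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelParameters":
        path = Path(path)
        text = path.read_text()
        if not text.strip():
            return cls()
        if path.suffix in (".yml", ".yaml"):
            data = yaml.safe_load(text) or {}
        else:
            data = json.loads(text)
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = self.to_dict()
        if path.suffix in (".yml", ".yaml"):
            path.write_text(yaml.safe_dump(data, sort_keys=False))
        else:
            path.write_text(json.dumps(data, indent=2))


def _check_table_ranges(p: ModelParameters) -> None:
    """Enforce the published physical ranges on the swept parameters."""
    checks = [
        ("mu", p.intrinsic.mu, MU_RANGE),
        ("g_h", p.intrinsic.g_h, GH_RANGE),
    ]
    for name, value, (lo, hi) in checks:
        if not (lo <= value <= hi):
            raise ValueError(f"{name} = {value} outside physical range [{lo}, {hi}]")


# ---------------------------------------------------------------------------
# Flat packing for the compiled core.  Index constants are consumed by
# renmm.model; keep the two lists in lockstep.
# ---------------------------------------------------------------------------

_PACK_ORDER = [
    ("cortex", "q_max"), ("thalamic", "q_max"),
    ("cortex", "theta"), ("thalamic", "theta"),
    ("cortex", "sigma_gain"), ("thalamic", "sigma_gain"),
    ("cortex", "tau"), ("thalamic", "tau"),
    ("synapse", "gamma_e"), ("synapse", "gamma_g"),
    ("synapse", "gamma_n"), ("synapse", "gamma_N"),
    ("synapse", "g_ampa"), ("synapse", "g_nmda"), ("synapse", "g_gaba"),
    ("synapse", "e_ampa"), ("synapse", "e_nmda"), ("synapse", "e_gaba"),
    ("synapse", "e_leak_cortex"), ("synapse", "e_leak_thalamus"),
    ("connectivity", "n_pp"), ("connectivity", "n_pt1"), ("connectivity", "n_pt2"),
    ("connectivity", "n_t1p"), ("connectivity", "n_t1t2"),
    ("connectivity", "n_t2p"), ("connectivity", "n_t2t1"),
    ("connectivity", "n_r1p"), ("connectivity", "n_r1r2"),
    ("connectivity", "n_r1t1"), ("connectivity", "n_r1t2"),
    ("connectivity", "n_rr"), ("connectivity", "n_rr2"),
    ("connectivity", "n_r2t2"),
    ("connectivity", "n_t1r1"), ("connectivity", "n_t2r1"),
    ("connectivity", "n_t2r2"),
    ("intrinsic", "g_lk"),
    ("intrinsic", "g_t_pv"), ("intrinsic", "g_t_som"),
    ("intrinsic", "g_t_vpm"), ("intrinsic", "g_t_vpl"),
    ("intrinsic", "g_h"), ("intrinsic", "g_inc"),
    ("intrinsic", "mu"), ("intrinsic", "mg_conc"),
    ("intrinsic", "e_lk"), ("intrinsic", "e_ca"), ("intrinsic", "e_h"),
    ("intrinsic", "c_m"),
    ("delay", "nu"),
    ("intrinsic", "alpha_ca"), ("intrinsic", "ca_0"), ("intrinsic", "tau_ca"),
    ("intrinsic", "k1"), ("intrinsic", "k2"), ("intrinsic", "k3"),
    ("intrinsic", "k4"), ("intrinsic", "tadj_t"),
    ("noise", "phi_mean"),
    ("noise", "phi_p_sd"), ("noise", "phi_t_sd"), ("noise", "phi_n_sd"),
]

NPAR = len(_PACK_ORDER) + 1  # +1 for the strict_as_printed flag

# generated index constants, e.g. P_MU, P_G_H, P_GAMMA_E ...
_seen: dict[str, int] = {}
for _i, (_grp, _fld) in enumerate(_PACK_ORDER):
    if _fld in ("q_max", "theta", "sigma_gain", "tau"):
        _suffix = "P" if _grp == "cortex" else "Y"
        _name = f"P_{_fld.upper()}_{_suffix}"
    elif _fld == "gamma_N":  # distinguish from gamma_n after upper-casing
        _name = "P_GAMMA_N_CAP"
    else:
        _name = f"P_{_fld.upper()}"
    globals()[_name] = _i
    _seen[_name] = _i
P_STRICT = len(_PACK_ORDER)
_seen["P_STRICT"] = P_STRICT
__all__ += sorted(_seen)


def pack_params(p: ModelParameters) -> np.ndarray:
    """Flatten a :class:`ModelParameters` into the compiled core's vector."""
    out = np.empty(NPAR, dtype=np.float64)
    for i, (grp, fld) in enumerate(_PACK_ORDER):
        out[i] = float(getattr(getattr(p, grp), fld))
    out[P_STRICT] = 1.0 if p.strict_as_printed else 0.0
    return out
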