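"""Voltage-gated and leak conductances of the octopus-cell model.

The complement is the standard ventral-cochlear-nucleus set: fast Na+
(m^3 h), fast transient K+ (KA, a^4 b c), high-threshold K+ (KHT, a
0.85*n^2 + 0.15*p mixture), low-voltage-activated K+ (KLT, w^4 z),
hyperpolarization-activated cation current (HCN, first-order r), and a
voltage-independent leak.  Kinetics follow the Rothman & Manis VCN
formulation at a 22 degC reference temperature with Q10 = 3; every channel
carries a per-channel scaling factor ``scl`` multiplying its base maximal
density, which is how pharmacological block is emulated (scl -> 0 for the
Kv and HCN conductances, mimicking 4-AP + ZD 7288).

KLT and HCN are both substantially open near rest; together with the leak
they set the octopus cell's hallmark very low input resistance (a few
megaohms), which is what confines dendritic inhibitory potentials to the
dendrites.  HCN is restricted to the dendrites; all other conductances are
distributed uniformly over soma and dendrites.

Base densities (``GBAR_BASE``) are not independently measured quantities;
they were calibrated once, with the published scl multipliers applied, so
that the full model's somatic responses to a -200 pA step match the
recorded 0.7 mV (control) and 8.8 mV (Kv+HCN block) deflections.  The leak
reversal is left to be solved at model-build time so the resting potential
relaxes to -65 mV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np

__all__ = [
    "GatingVariable",
    "ChannelModel",
    "ReversalSet",
    "TemperatureConfig",
    "SCL_DEFAULTS",
    "GBAR_BASE",
    "default_channels",
    "gating_kinetics",
    "channel_current_density",
    "apply_pharmacology",
]

ArrayLike = float | np.ndarray


@dataclass(frozen=True)
class GatingVariable:
    """One Hodgkin-Huxley gating particle.

    ``steady_state`` and ``time_constant`` map membrane potential (mV) to
    the particle's equilibrium value (dimensionless, in [0, 1]) and
    relaxation time (ms, at the 22 degC reference temperature).
    ``exponent`` is the power the particle enters the conductance with.
    """

    name: str
    steady_state: Callable[[ArrayLike], ArrayLike]
    time_constant: Callable[[ArrayLike], ArrayLike]
    exponent: int = 1


@dataclass(frozen=True)
class ChannelModel:
    """A conductance species: density, scaling factor, reversal, gates.

    The effective maximal density is ``gbar_base * scl`` (S/cm^2).  The
    high-threshold K+ conductance is represented as two entries sharing the
    name "KHT" (the n^2 branch at 85% of the base density and the p branch
    at 15%), so each entry keeps the simple product form
    g = gbar * scl * prod(gate^exponent).
    """

    name: str  # Na | KA | KHT | KLT | HCN | leak
    gbar_base: float  # S/cm^2
    scl: float  # dimensionless scaling factor
    e_rev: float  # mV
    gates: tuple[GatingVariable, ...] = ()
    distribution: str = "everywhere"  # "everywhere" | "dendrites_only"

    def __post_init__(self) -> None:
        if self.gbar_base * self.scl < 0:
            raise ValueError(f"{self.name}: effective density must be >= 0")
        if self.distribution not in ("everywhere", "dendrites_only"):
            raise ValueError(f"{self.name}: bad distribution {self.distribution!r}")

    @property
    def gbar(self) -> float:
        """Effective maximal density gbar_base * scl (S/cm^2)."""
        return self.gbar_base * self.scl


@dataclass(frozen=True)
class ReversalSet:
    """Ionic reversal potentials (mV).  e_leak is a calibration parameter:
    ``None`` means "solve at model build so the cell rests at v_init"."""

    e_h: float = -38.0
    e_na: float = 50.0
    e_k: float = -70.0
    e_leak: float | None = None


@dataclass(frozen=True)
class TemperatureConfig:
    """Q10 handling.  The kinetics reference temperature is 22 degC and the
    default simulation temperature is also 22 degC, so no rate scaling is
    applied unless a different ``t_sim`` is configured."""

    q10: float = 3.0
    t_ref: float = 22.0
    t_sim: float = 22.0

    def __post_init__(self) -> None:
        if self.q10 <= 0:
            raise ValueError("q10 must be positive")

    @property
    def rate_factor(self) -> float:
        """Factor dividing time constants: q10 ** ((t_sim - t_ref) / 10)."""
        return self.q10 ** ((self.t_sim - self.t_ref) / 10.0)


# Published per-channel scaling factors (dimensionless).
SCL_DEFAULTS: dict[str, float] = {
    "Na": 0.83,
    "KA": 0.07,
    "KHT": 0.1875,
    "KLT": 0.75,
    "HCN": 0.07,
    "leak": 0.0017,
}

# Base maximal densities (S/cm^2) before scl.  Calibrated once against the
# -200 pA somatic step responses (0.7 mV control, 8.8 mV under Kv+HCN
# block) on the reference morphology; see docs/methods.md.
GBAR_BASE: dict[str, float] = {
    "Na": 0.05,
    "KA": 0.05,
    "KHT": 0.05,
    "KLT": 0.067,
    "HCN": 0.0347,
    "leak": 0.03,
}


def _sig(v: ArrayLike, vhalf: float, k: float) -> ArrayLike:
    """Rising Boltzmann 1 / (1 + exp(-(v - vhalf) / k))."""
    return 1.0 / (1.0 + np.exp(-(np.asarray(v, float) - vhalf) / k))


# ---- Rothman-Manis VCN kinetics (22 degC) --------------------------------

def _na_m_inf(v):
    return _sig(v, -38.0, 7.0)

def _na_m_tau(v):
    v = np.asarray(v, float)
    return 10.0 / (5.0 * np.exp((v + 60.0) / 18.0)
                   + 36.0 * np.exp(-(v + 60.0) / 25.0)) + 0.04

def _na_h_inf(v):
    return 1.0 - _sig(v, -65.0, 6.0)

def _na_h_tau(v):
    v = np.asarray(v, float)
    return 100.0 / (7.0 * np.exp((v + 60.0) / 11.0)
                    + 10.0 * np.exp(-(v + 60.0) / 25.0)) + 0.6

def _kht_n_inf(v):
    return _sig(v, -15.0, 5.0) ** 0.5

def _kht_n_tau(v):
    v = np.asarray(v, float)
    return 100.0 / (11.0 * np.exp((v + 60.0) / 24.0)
                    + 21.0 * np.exp(-(v + 60.0) / 23.0)) + 0.7

def _kht_p_inf(v):
    return _sig(v, -23.0, 6.0)

def _kht_p_tau(v):
    v = np.asarray(v, float)
    return 100.0 / (4.0 * np.exp((v + 60.0) / 32.0)
                    + 5.0 * np.exp(-(v + 60.0) / 22.0)) + 5.0

def _klt_w_inf(v):
    return _sig(v, -48.0, 6.0) ** 0.25

def _klt_w_tau(v):
    v = np.asarray(v, float)
    return 100.0 / (6.0 * np.exp((v + 60.0) / 6.0)
                    + 16.0 * np.exp(-(v + 60.0) / 45.0)) + 1.5

def _klt_z_inf(v):
    return 0.5 + 0.5 * (1.0 - _sig(v, -71.0, 10.0))

def _klt_z_tau(v):
    v = np.asarray(v, float)
    return 1000.0 / (np.exp((v + 60.0) / 20.0)
                     + np.exp(-(v + 60.0) / 8.0)) + 50.0

def _ka_a_inf(v):
    return _sig(v, -31.0, 6.0) ** 0.25

def _ka_a_tau(v):
    v = np.asarray(v, float)
    return 100.0 / (7.0 * np.exp((v + 60.0) / 14.0)
                    + 29.0 * np.exp(-(v + 60.0) / 24.0)) + 0.1

def _ka_b_inf(v):
    return (1.0 - _sig(v, -66.0, 7.0)) ** 0.5

def _ka_b_tau(v):
    v = np.asarray(v, float)
    return 1000.0 / (14.0 * np.exp((v + 60.0) / 27.0)
                     + 29.0 * np.exp(-(v + 60.0) / 24.0)) + 1.0

def _ka_c_tau(v):
    v = np.asarray(v, float)
    return 90.0 / (1.0 + np.exp((-66.0 - v) / 17.0)) + 10.0

def _hcn_r_inf(v):
    return 1.0 - _sig(v, -76.0, 7.0)

def _hcn_r_tau(v):
    v = np.asarray(v, float)
    return 1e5 / (237.0 * np.exp((v + 60.0) / 12.0)
                  + 17.0 * np.exp(-(v + 60.0) / 14.0)) + 25.0


def default_channels(
    reversals: ReversalSet | None = None,
    gbar_base: Mapping[str, float] | None = None,
    scl: Mapping[str, float] | None = None,
) -> tuple[ChannelModel, ...]:
    """Assemble the default channel complement.

    Overrides for individual base densities or scaling factors may be
    passed as partial mappings.  The leak reversal defaults to 0 mV as a
    placeholder when unresolved; the model builder replaces it with the
    calibrated value.
    """
    rev = reversals or ReversalSet()
    gb = dict(GBAR_BASE)
    gb.update(gbar_base or {})
    sc = dict(SCL_DEFAULTS)
    sc.update(scl or {})
    e_leak = rev.e_leak if rev.e_leak is not None else 0.0

    na_gates = (
        GatingVariable("m", _na_m_inf, _na_m_tau, 3),
        GatingVariable("h", _na_h_inf, _na_h_tau, 1),
    )
    kht_n = (GatingVariable("n", _kht_n_inf, _kht_n_tau, 2),)
    kht_p = (GatingVariable("p", _kht_p_inf, _kht_p_tau, 1),)
    klt_gates = (
        GatingVariable("w", _klt_w_inf, _klt_w_tau, 4),
        GatingVariable("z", _klt_z_inf, _klt_z_tau, 1),
    )
    ka_gates = (
        GatingVariable("a", _ka_a_inf, _ka_a_tau, 4),
        GatingVariable("b", _ka_b_inf, _ka_b_tau, 1),
        GatingVariable("c", _ka_b_inf, _ka_c_tau, 1),  # c_inf == b_inf
    )
    hcn_gates = (GatingVariable("r", _hcn_r_inf, _hcn_r_tau, 1),)

    return (
        ChannelModel("Na", gb["Na"], sc["Na"], rev.e_na, na_gates),
        ChannelModel("KA", gb["KA"], sc["KA"], rev.e_k, ka_gates),
        ChannelModel("KHT", 0.85 * gb["KHT"], sc["KHT"], rev.e_k, kht_n),
        ChannelModel("KHT", 0.15 * gb["KHT"], sc["KHT"], rev.e_k, kht_p),
        ChannelModel("KLT", gb["KLT"], sc["KLT"], rev.e_k, klt_gates),
        ChannelModel("HCN", gb["HCN"], sc["HCN"], rev.e_h, hcn_gates,
                     distribution="dendrites_only"),
        ChannelModel("leak", gb["leak"], sc["leak"], e_leak),
    )


def gating_kinetics(
    gate: GatingVariable, v: ArrayLike, temp: TemperatureConfig | None = None
) -> tuple[ArrayLike, ArrayLike]:
    """Equilibrium value and temperature-corrected time constant at ``v``.

    The time constant is divided by q10 ** ((t_sim - t_ref) / 10); at the
    default simulation temperature (the 22 degC reference) it is returned
    unchanged.
    """
    t = temp or TemperatureConfig()
    return gate.steady_state(v), gate.time_constant(v) / t.rate_factor


def channel_current_density(
    ch: ChannelModel, v: ArrayLike, gate_states: Mapping[str, ArrayLike] | None = None
) -> ArrayLike:
    """Membrane current density i = gbar * prod(gate^exp) * (V - e_rev).

    Units: mA/cm^2 for gbar in S/cm^2 and V in mV.  Leak takes no gates.
    """
    open_frac: ArrayLike = 1.0
    for gate in ch.gates:
        if gate_states is None or gate.name not in gate_states:
            raise KeyError(f"{ch.name}: missing state for gate {gate.name!r}")
        x = gate_states[gate.name]
        open_frac = open_frac * np.asarray(x, float) ** gate.exponent
    return ch.gbar * open_frac * (np.asarray(v, float) - ch.e_rev)


#: Conductances silenced by the Kv + HCN block condition.
BLOCKED_BY_KV_HCN = frozenset({"KA", "KHT", "KLT", "HCN"})


def apply_pharmacology(
    channels: tuple[ChannelModel, ...], condition: str
) -> tuple[ChannelModel, ...]:
    """Scale channel densities for a pharmacological condition.

    ``control`` multiplies the Kv and HCN scaling factors by 1 (identity);
    ``kv_hcn_block`` sets them to 0, emulating 4-AP + ZD 7288.  Na and
    leak are untouched in both conditions.  Idempotent.
    """
    if condition == "control":
        return tuple(channels)
    if condition == "kv_hcn_block":
        return tuple(
            replace(ch, scl=0.0) if ch.name in BLOCKED_BY_KV_HCN else ch
            for ch in channels
        )
    raise ValueError(f"unknown pharmacology condition {condition!r}")
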