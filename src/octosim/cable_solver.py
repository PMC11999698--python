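"""Implicit solver for the branched cable equation with HH-type membranes.

The dendritic tree is discretized into frustum segments (the soma is a
single isopotential compartment).  Each time step solves

    C_m dV/dt = -(g_pas + sum_ch g_ch(x))(V - E) - g_syn(t)(V - E_syn)
                + I_inj / A + axial coupling

implicitly on the tree: gating variables are advanced by the exact
exponential (Rush-Larsen) update, staggered from the voltage step, and the
voltage system is solved in O(n) per step by Hines-ordered elimination
(children are numbered after their parents, so one backward sweep folds
every branch into the root and one forward sweep back-substitutes).
Backward Euler (default) and Crank-Nicolson are available; both are
unconditionally stable at the 25 us default step.

Membrane at rest has two background terms: the passive membrane
conductance 1/R_m (reversal = the calibrated leak reversal) and whatever
channel complement the model carries.  Setting every channel's scaling
factor to zero therefore leaves a purely passive membrane whose input
resistance scales with R_m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .channels import ChannelModel, TemperatureConfig, ReversalSet
from .morphology import Morphology, TreeLocation
from .synapses import SynapseEvent, waveform_peak_time

__all__ = [
    "PassiveParams",
    "SolverConfig",
    "CurrentStep",
    "CompartmentalModel",
    "RestState",
    "VoltageTrace",
    "SimResult",
    "SimulationError",
    "find_rest",
    "integrate",
    "holding_current",
    "solve_e_leak",
    "with_e_leak",
]


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class PassiveParams:
    r_a: float = 150.0  # ohm*cm, axial resistivity
    r_m: float = 5.0  # kohm*cm^2, specific membrane resistance
    c_m: float = 0.9  # uF/cm^2
    v_init: float = -65.0  # mV

    def __post_init__(self) -> None:
        if min(self.r_a, self.r_m, self.c_m) <= 0:
            raise ValueError("passive parameters must be positive")
        if not -100.0 <= self.v_init <= 0.0:
            raise ValueError("v_init out of range")


@dataclass(frozen=True)
class SolverConfig:
    dt: float = 0.025  # ms
    method: str = "backward_euler"  # or "crank_nicolson"
    t_stop: float = 100.0  # ms
    record: tuple[TreeLocation, ...] = ()

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.method not in ("backward_euler", "crank_nicolson"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass(frozen=True)
class CurrentStep:
    """Constant current injected at a tree location over [t_start, t_stop)."""

    location: TreeLocation
    amplitude_pa: float
    t_start: float = 0.0
    t_stop: float = math.inf


@dataclass
class CompartmentalModel:
    """Morphology + membrane + synapses: the simulated object."""

    morphology: Morphology
    passive: PassiveParams
    channels: tuple[ChannelModel, ...]
    reversals: ReversalSet = field(default_factory=ReversalSet)
    synapses: tuple[SynapseEvent, ...] = ()
    holding_pa: float = 0.0  # constant somatic current, pA
    temperature: TemperatureConfig = field(default_factory=TemperatureConfig)

    def soma_location(self) -> TreeLocation:
        return TreeLocation(self.morphology.soma.id, 0.5)


@dataclass
class RestState:
    v: np.ndarray  # mV per compartment
    gates: list[np.ndarray]  # aligned with the discretization's gate list
    max_dvdt: float  # mV/ms at termination


@dataclass
class VoltageTrace:
    location: TreeLocation
    times: np.ndarray  # ms
    values: np.ndarray  # mV
    condition: str = ""


@dataclass
class SimResult:
    times: np.ndarray
    traces: dict[TreeLocation, np.ndarray]
    final_v: np.ndarray
    final_gates: list[np.ndarray]

    def trace(self, loc: TreeLocation) -> np.ndarray:
        return self.traces[loc]

    def voltage_traces(self, condition: str = "") -> list[VoltageTrace]:
        return [
            VoltageTrace(loc, self.times, vals, condition)
            for loc, vals in self.traces.items()
        ]


# --------------------------------------------------------------------------


class _Discretization:
    """Compartment arrays for one model: geometry, axial graph, channels."""

    def __init__(self, model: CompartmentalModel):
        m = model.morphology
        pas = model.passive
        soma = m.soma

        comp_sec: list[int] = []
        comp_f0: list[float] = []
        comp_f1: list[float] = []
        parent: list[int] = []
        g_ax: list[float] = []  # uS to parent (0 for root)
        area: list[float] = []  # cm^2
        is_dend: list[bool] = []

        # index 0: soma (isopotential, closed surface)
        comp_sec.append(soma.id)
        comp_f0.append(0.0)
        comp_f1.append(1.0)
        parent.append(-1)
        g_ax.append(0.0)
        area.append(soma.membrane_area() * 1e-8)
        is_dend.append(False)

        #: (section_id, local segment index) -> compartment index
        self.seg_index: dict[tuple[int, int], int] = {(soma.id, 0): 0}

        def half_res_mohm(sec, fa, fb) -> float:
            """Axial resistance (Mohm) of the frustum between two fracs."""
            d1, d2 = sec.diam_at(fa), sec.diam_at(fb)
            l_cm = sec.length * abs(fb - fa) * 1e-4
            return 4.0 * pas.r_a * l_cm / (math.pi * d1 * d2 * 1e-8) / 1e6

        def add_section(sec, parent_comp: int) -> None:
            n = sec.nseg
            prev = parent_comp
            prev_half = 0.0 if parent_comp == 0 else None  # soma: no internal res.
            for j in range(n):
                f0, f1 = j / n, (j + 1) / n
                fm = (f0 + f1) / 2.0
                idx = len(comp_sec)
                comp_sec.append(sec.id)
                comp_f0.append(f0)
                comp_f1.append(f1)
                parent.append(prev)
                area.append(sec.lateral_area(f0, f1) * 1e-8)
                is_dend.append(True)
                r_prox = half_res_mohm(sec, f0, fm)
                r_parent_half = prev_half if prev_half is not None else _last_half[prev]
                g_ax.append(1.0 / (r_parent_half + r_prox))
                _last_half[idx] = half_res_mohm(sec, fm, f1)
                self.seg_index[(sec.id, j)] = idx
                prev = idx
                prev_half = None
            for child in m.children(sec.id):
                add_section(child, prev)

        _last_half: dict[int, float] = {0: 0.0}
        for child in m.children(soma.id):
            add_section(child, 0)

        self.n = len(comp_sec)
        self.sec_of = np.array(comp_sec)
        self.parent = np.array(parent)
        self.g_axial = np.array(g_ax)  # uS, edge to parent
        self.area_cm2 = np.array(area)
        self.is_dendrite = np.array(is_dend)
        self.c_nf = pas.c_m * self.area_cm2 * 1e3  # nF
        # passive membrane conductance, uS
        g_pas_density = 1.0 / (pas.r_m * 1000.0)  # S/cm^2
        self.g_pas = g_pas_density * self.area_cm2 * 1e6
        e_leak = model.reversals.e_leak
        self.e_pas = pas.v_init if e_leak is None else e_leak

        # static axial diagonal: sum of edge conductances at each node
        self.ax_diag = np.zeros(self.n)
        for i in range(1, self.n):
            self.ax_diag[i] += self.g_axial[i]
            self.ax_diag[self.parent[i]] += self.g_axial[i]

        # channels: per entry, max conductance uS per compartment + gates
        self.ch_entries = []  # (gmax_uS array, e_rev, [gate indices])
        self.gates = []  # flat list of GatingVariable
        for ch in model.channels:
            mask = np.ones(self.n) if ch.distribution == "everywhere" else \
                self.is_dendrite.astype(float)
            gmax = ch.gbar * self.area_cm2 * 1e6 * mask
            idxs = []
            for gate in ch.gates:
                idxs.append(len(self.gates))
                self.gates.append(gate)
            self.ch_entries.append((gmax, ch.e_rev, idxs))

        self._nseg_of_sec = {s.id: s.nseg for s in m.sections.values()}

    def comp_of(self, loc: TreeLocation) -> int:
        nseg = self._nseg_of_sec[loc.section_id]
        j = min(int(loc.frac * nseg), nseg - 1)
        return self.seg_index[(loc.section_id, j)]

    def axial_product(self, v: np.ndarray) -> np.ndarray:
        """(A v)_i = sum_j g_ij (v_i - v_j) over tree edges."""
        out = self.ax_diag * v
        p = self.parent[1:]
        g = self.g_axial[1:]
        out[1:] -= g * v[p]
        np.subtract.at(out, p, g * v[1:])
        return out


def _hines_solve(diag, off, rhs, parent):
    """Solve the symmetric tree system in O(n); parent[i] < i for i > 0."""
    d = diag.copy()
    b = rhs.copy()
    n = d.shape[0]
    for i in range(n - 1, 0, -1):
        p = parent[i]
        f = off[i] / d[i]
        d[p] -= f * off[i]
        b[p] -= f * b[i]
    v = np.empty(n)
    v[0] = b[0] / d[0]
    for i in range(1, n):
        v[i] = (b[i] - off[i] * v[parent[i]]) / d[i]
    return v


class _Sim:
    def __init__(self, model: CompartmentalModel, dt: float, method: str,
                 stimuli: Sequence[CurrentStep] = ()):
        self.model = model
        self.disc = _Discretization(model)
        self.dt = dt
        self.theta = 1.0 if method == "backward_euler" else 0.5
        d = self.disc

        self.v = np.full(d.n, model.passive.v_init)
        self.gate_x = [np.asarray(g.steady_state(self.v)) * np.ones(d.n)
                       for g in d.gates]
        self.rate_factor = model.temperature.rate_factor

        # synapse arrays
        ev = model.synapses
        self.syn_comp = np.array([d.comp_of(e.location) for e in ev], dtype=int)
        self.syn_onset = np.array([e.onset for e in ev])
        self.syn_gmax = np.array([e.kinetics.gmax for e in ev])  # nS
        self.syn_tr = np.array([e.kinetics.tau_rise for e in ev])
        self.syn_td = np.array([e.kinetics.tau_decay for e in ev])
        self.syn_e = np.array([e.kinetics.e_rev for e in ev])
        self.syn_alpha = np.array([e.kinetics.is_alpha for e in ev], dtype=bool)
        if len(ev):
            with np.errstate(divide="ignore", invalid="ignore"):
                tp = np.array([waveform_peak_time(e.kinetics) for e in ev])
                self.syn_norm = np.where(
                    self.syn_alpha,
                    1.0,
                    1.0 / (np.exp(-tp / self.syn_td) - np.exp(-tp / self.syn_tr)),
                )
        else:
            self.syn_norm = np.empty(0)

        # stimuli (constant holding + steps), nA
        stims = list(stimuli)
        if model.holding_pa:
            stims.append(CurrentStep(model.soma_location(), model.holding_pa))
        self.stim_comp = np.array([d.comp_of(s.location) for s in stims], dtype=int)
        self.stim_amp = np.array([s.amplitude_pa * 1e-3 for s in stims])  # nA
        self.stim_t0 = np.array([s.t_start for s in stims])
        self.stim_t1 = np.array([s.t_stop for s in stims])

    def set_state(self, rest: RestState) -> None:
        self.v = rest.v.copy()
        self.gate_x = [x.copy() for x in rest.gates]

    def get_state(self, max_dvdt: float = math.nan) -> RestState:
        return RestState(self.v.copy(), [x.copy() for x in self.gate_x], max_dvdt)

    def _membrane_conductances(self):
        """Total channel conductance (uS) and g*e sums per compartment."""
        d = self.disc
        g_tot = d.g_pas.copy()
        ge_tot = d.g_pas * d.e_pas
        for gmax, e_rev, idxs in d.ch_entries:
            open_frac = 1.0
            for i in idxs:
                gate = d.gates[i]
                open_frac = open_frac * self.gate_x[i] ** gate.exponent
            g = gmax * open_frac
            g_tot = g_tot + g
            ge_tot = ge_tot + g * e_rev
        return g_tot, ge_tot

    def _syn_conductances(self, t: float):
        d = self.disc
        g = np.zeros(d.n)
        ge = np.zeros(d.n)
        if len(self.syn_comp):
            dt_on = np.maximum(t - self.syn_onset, 0.0)
            dexp = self.syn_norm * (np.exp(-dt_on / self.syn_td)
                                    - np.exp(-dt_on / self.syn_tr))
            alpha = (dt_on / self.syn_tr) * np.exp(1.0 - dt_on / self.syn_tr)
            gs = np.where(
                t - self.syn_onset > 0.0,
                self.syn_gmax * np.where(self.syn_alpha, alpha, dexp),
                0.0,
            ) * 1e-3  # nS -> uS
            np.add.at(g, self.syn_comp, gs)
            np.add.at(ge, self.syn_comp, gs * self.syn_e)
        return g, ge

    def _injected(self, t: float) -> np.ndarray:
        d = self.disc
        out = np.zeros(d.n)
        if len(self.stim_comp):
            active = (t >= self.stim_t0) & (t < self.stim_t1)
            np.add.at(out, self.stim_comp, np.where(active, self.stim_amp, 0.0))
        return out

    def step(self, t: float) -> None:
        """Advance from t to t + dt."""
        d = self.disc
        dt = self.dt
        th = self.theta
        # staggered Rush-Larsen gate update (exact for frozen V)
        for i, gate in enumerate(d.gates):
            x_inf = gate.steady_state(self.v)
            tau = gate.time_constant(self.v) / self.rate_factor
            self.gate_x[i] = x_inf + (self.gate_x[i] - x_inf) * np.exp(-dt / tau)

        t_eval = t + dt if th == 1.0 else t + dt / 2.0
        g_m, ge_m = self._membrane_conductances()
        g_s, ge_s = self._syn_conductances(t_eval)
        inj = self._injected(t_eval)

        g_tot = g_m + g_s
        b = ge_m + ge_s + inj
        c_dt = d.c_nf / dt

        diag = c_dt + th * (g_tot + d.ax_diag)
        off = -th * d.g_axial
        rhs = c_dt * self.v + b
        if th != 1.0:
            rhs -= (1.0 - th) * (g_tot * self.v + d.axial_product(self.v))
        v_new = _hines_solve(diag, off, rhs, d.parent)
        if not np.all(np.isfinite(v_new)):
            raise SimulationError(f"non-finite voltage at t = {t + dt:.4f} ms")
        self.v = v_new


def integrate(
    model: CompartmentalModel,
    config: SolverConfig,
    rest: RestState | None = None,
    stimuli: Sequence[CurrentStep] = (),
) -> SimResult:
    """Integrate the model and return traces at the requested locations.

    If ``rest`` is given the simulation starts from that state (voltages and
    gate values); otherwise it starts from ``v_init`` with gates at their
    steady-state values for that voltage.
    """
    sim = _Sim(model, config.dt, config.method, stimuli)
    if rest is not None:
        sim.set_state(rest)
    nsteps = int(round(config.t_stop / config.dt))
    times = np.arange(nsteps + 1) * config.dt
    rec_idx = [sim.disc.comp_of(loc) for loc in config.record]
    out = np.empty((len(rec_idx), nsteps + 1))
    out[:, 0] = sim.v[rec_idx]
    for k in range(nsteps):
        sim.step(k * config.dt)
        out[:, k + 1] = sim.v[rec_idx]
    traces = {loc: out[i] for i, loc in enumerate(config.record)}
    return SimResult(times, traces, sim.v.copy(), [x.copy() for x in sim.gate_x])


def find_rest(
    model: CompartmentalModel,
    tol_dvdt: float = 1e-4,
    dt_relax: float = 5.0,
    t_max: float = 20000.0,
) -> RestState:
    """Relax the model (no synaptic events) to its resting state.

    Uses large implicit steps: the fixed point of the implicit update is
    the exact steady state, so coarse steps converge to the same rest as
    fine integration.  Raises if max |dV/dt| stays above ``tol_dvdt``
    (mV/ms) after ``t_max`` ms of simulated relaxation.
    """
    if model.synapses:
        model = replace(model, synapses=())
    sim = _Sim(model, dt_relax, "backward_euler")
    t = 0.0
    while t < t_max:
        v_prev = sim.v.copy()
        sim.step(t)
        t += dt_relax
        max_dvdt = float(np.max(np.abs(sim.v - v_prev)) / dt_relax)
        if max_dvdt < tol_dvdt:
            return sim.get_state(max_dvdt)
    raise SimulationError(
        f"no steady state within {t_max} ms (max |dV/dt| = {max_dvdt:.2e})"
    )


def _somatic_rest(model: CompartmentalModel) -> float:
    rest = find_rest(model)
    disc = _Discretization(model)
    return float(rest.v[disc.comp_of(model.soma_location())])


def holding_current(
    model: CompartmentalModel, v_target: float, tol: float = 0.1,
    max_pa: float = 2000.0,
) -> float:
    """Constant somatic current (pA) holding the resting soma at ``v_target``.

    Secant iteration on the relaxed somatic potential, clamped to
    [-max_pa, +max_pa]; raises if the target is unreachable in that range.
    """
    def rest_at(i_pa: float) -> float:
        return _somatic_rest(replace(model, holding_pa=model.holding_pa + i_pa))

    i0, i1 = 0.0, 100.0
    r0 = rest_at(i0)
    if abs(r0 - v_target) < tol:
        return model.holding_pa + i0
    r1 = rest_at(i1)
    for _ in range(25):
        if abs(r1 - r0) < 1e-12:
            break
        i2 = i1 + (v_target - r1) * (i1 - i0) / (r1 - r0)
        i2 = min(max(i2, -max_pa), max_pa)
        r2 = rest_at(i2)
        if abs(r2 - v_target) < tol:
            return model.holding_pa + i2
        i0, r0, i1, r1 = i1, r1, i2, r2
    raise SimulationError(
        f"holding current for {v_target} mV not found within +/-{max_pa} pA"
    )


def with_e_leak(model: CompartmentalModel, e_leak: float) -> CompartmentalModel:
    """Copy of ``model`` with the leak reversal (channel + passive) set."""
    channels = tuple(
        replace(ch, e_rev=e_leak) if ch.name == "leak" else ch
        for ch in model.channels
    )
    reversals = replace(model.reversals, e_leak=e_leak)
    return replace(model, channels=channels, reversals=reversals)


def solve_e_leak(
    model: CompartmentalModel,
    v_target: float | None = None,
    tol: float = 0.05,
    bracket: tuple[float, float] = (-95.0, -10.0),
) -> float:
    """Leak reversal for which the soma rests at ``v_target`` (bisection).

    The somatic resting potential is monotone in the leak reversal, so
    bisection on the bracket converges unconditionally.
    """
    target = model.passive.v_init if v_target is None else v_target
    lo, hi = bracket
    f_lo = _somatic_rest(with_e_leak(model, lo)) - target
    f_hi = _somatic_rest(with_e_leak(model, hi)) - target
    if f_lo * f_hi > 0:
        raise SimulationError("resting target not bracketed by e_leak range")
    for _ in range(40):
        mid = (lo + hi) / 2.0
        f_mid = _somatic_rest(with_e_leak(model, mid)) - target
        if abs(f_mid) < tol:
            return mid
        if f_lo * f_mid <= 0:
            hi, f_hi = mid, f_mid
        else:
            lo, f_lo = mid, f_mid
    return (lo + hi) / 2.0
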