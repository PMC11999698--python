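"""Virtual experiments on the model octopus cell.

The protocols mirror the slice and modelling experiments around dendritic
glycinergic inhibition:

* hyperpolarizing current steps under control and Kv+HCN-block conditions
  (the block is emulated by zeroing the Kv/HCN scaling factors, with a
  holding current restoring the control resting potential, as in the
  recordings);
* somatic visibility of dendritic IPSPs as a function of glycine
  conductance and pharmacology;
* locally measured IPSCs at proximal and distal dendritic sites;
* steady-state transfer impedance between dendrite and soma;
* the excitation-inhibition distance sweep: a lumped AMPA conductance is
  moved along a dendrite relative to a fixed glycinergic conductance, and
  the somatic EPSP is compared with and without coincident inhibition.

"Proximal" and "distal" reference sites are fixed at 10% and 90% of the
longest dendrite's path length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .cable_solver import (
    CompartmentalModel,
    CurrentStep,
    PassiveParams,
    RestState,
    SolverConfig,
    find_rest,
    holding_current,
    integrate,
    solve_e_leak,
    with_e_leak,
)
from .channels import (
    ReversalSet,
    TemperatureConfig,
    apply_pharmacology,
    default_channels,
)
from .metrics import PSPMetrics, peak_advance, percent_change, psp_metrics
from .morphology import (
    Morphology,
    MorphologyParams,
    TreeLocation,
    build_octopus_morphology,
    locate_at_normalized_distance,
    longest_dendrite_path,
)
from .synapses import AMPA_DEFAULT, GLYCINE_DEFAULT, SynapseEvent

__all__ = [
    "PharmacologyCondition",
    "SweepSpec",
    "StepResult",
    "PROXIMAL_FRAC",
    "DISTAL_FRAC",
    "build_reference_model",
    "calibrated_reference",
    "reference_site",
    "run_current_step",
    "run_ipsp_visibility",
    "run_local_ipsc",
    "run_transfer_impedance",
    "epsp_with_inhibition",
    "run_epsp_inhibition_sweep",
]

PROXIMAL_FRAC = 0.1
DISTAL_FRAC = 0.9

#: Somatic IPSPs below this (mV) count as invisible to a somatic electrode.
NEGLIGIBLE_IPSP_MV = 0.5


@dataclass(frozen=True)
class PharmacologyCondition:
    name: str = "control"  # "control" | "kv_hcn_block"
    restore_rest: bool = True  # hold the soma at the control rest after block


@dataclass(frozen=True)
class SweepSpec:
    """Grid for the excitation-inhibition distance sweep."""

    mode: str = "inhibition_proximal"  # or "inhibition_distal"
    d_grid: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    g_gly_grid: tuple[float, ...] = (1.0, 2.0, 4.0, 6.0, 8.0, 10.0)  # nS
    g_ampa: float = 5.0  # nS (5 for amplitude runs, 2 for timing runs)

    def __post_init__(self) -> None:
        if self.mode not in ("inhibition_proximal", "inhibition_distal"):
            raise ValueError(f"unknown sweep mode {self.mode!r}")
        if not self.d_grid or not self.g_gly_grid:
            raise ValueError("sweep grids must be nonempty")
        if self.g_ampa < 0 or min(self.g_gly_grid) < 0:
            raise ValueError("conductances must be >= 0")


@dataclass
class StepResult:
    times: np.ndarray
    soma_trace: np.ndarray
    delta_vm: float  # mV, |steady state - baseline|
    r_n: float  # Mohm
    steady: bool  # slope criterion met at end of step


def build_reference_model(
    morphology_params: MorphologyParams | None = None,
    e_leak: float | None = None,
    gbar_base=None,
    scl=None,
    passive: PassiveParams | None = None,
    temperature: TemperatureConfig | None = None,
) -> CompartmentalModel:
    """Assemble the full-complement model on the reference morphology.

    If ``e_leak`` is ``None`` the leak reversal is left unresolved; use
    :func:`octosim.cable_solver.solve_e_leak` (or
    :func:`calibrated_reference`) to pin the resting potential.
    """
    morph = build_octopus_morphology(morphology_params)
    reversals = ReversalSet(e_leak=e_leak)
    channels = default_channels(reversals, gbar_base=gbar_base, scl=scl)
    return CompartmentalModel(
        morphology=morph,
        passive=passive or PassiveParams(),
        channels=channels,
        reversals=reversals,
        temperature=temperature or TemperatureConfig(),
    )


_REFERENCE_CACHE: dict[str, tuple[CompartmentalModel, RestState]] = {}


def calibrated_reference(
    condition: str = "control", use_cache: bool = True
) -> tuple[CompartmentalModel, RestState]:
    """The calibrated default model and its resting state for a condition.

    Control: the leak reversal is solved so the soma rests at -65 mV.
    Kv+HCN block: the control-calibrated cell with the Kv/HCN scaling
    factors zeroed and a holding current returning the soma to the control
    resting potential (the in vitro procedure).  Results are cached per
    condition within the process.
    """
    if use_cache and condition in _REFERENCE_CACHE:
        return _REFERENCE_CACHE[condition]

    if condition == "control":
        model = build_reference_model()
        e_leak = solve_e_leak(model)
        model = with_e_leak(model, e_leak)
        rest = find_rest(model)
    elif condition == "kv_hcn_block":
        ctrl, ctrl_rest = calibrated_reference("control", use_cache)
        soma_idx = _soma_index(ctrl)
        v_ctrl = float(ctrl_rest.v[soma_idx])
        blocked = replace(ctrl, channels=apply_pharmacology(ctrl.channels, "kv_hcn_block"))
        hold = holding_current(blocked, v_target=v_ctrl)
        blocked = replace(blocked, holding_pa=hold)
        rest = find_rest(blocked)
        model = blocked
    else:
        raise ValueError(f"unknown condition {condition!r}")

    if use_cache:
        _REFERENCE_CACHE[condition] = (model, rest)
    return model, rest


def _soma_index(model: CompartmentalModel) -> int:
    from .cable_solver import _Discretization

    return _Discretization(model).comp_of(model.soma_location())


def reference_site(m: Morphology, which: str) -> TreeLocation:
    """The fixed proximal (10%) or distal (90%) site on the longest dendrite."""
    path = longest_dendrite_path(m)
    total = sum(m.section(i).length for i in path)
    frac_of_total = {"proximal": PROXIMAL_FRAC, "distal": DISTAL_FRAC}[which]
    origin = TreeLocation(path[0], 0.0)
    # distance measured from the dendrite origin toward the tip
    target = frac_of_total * total
    run = 0.0
    for sid in path:
        sec = m.section(sid)
        if target <= run + sec.length:
            return TreeLocation(sid, (target - run) / sec.length)
        run += sec.length
    return TreeLocation(path[-1], 1.0)


def run_current_step(
    model: CompartmentalModel,
    rest: RestState,
    amplitude_pa: float = -200.0,
    duration: float = 200.0,
    pre: float = 20.0,
    dt: float = 0.025,
    method: str = "backward_euler",
) -> StepResult:
    """Somatic current step; steady-state deflection and input resistance.

    ``delta_vm`` is |mean V over the last 10 ms of the step - baseline|;
    ``r_n`` = delta_vm / |amplitude|.  ``steady`` flags whether the trace
    slope over the last 20 ms of the step is below 1 uV/ms.
    """
    soma = model.soma_location()
    step = CurrentStep(soma, amplitude_pa, t_start=pre, t_stop=pre + duration)
    cfg = SolverConfig(dt=dt, method=method, t_stop=pre + duration + 20.0,
                       record=(soma,))
    res = integrate(model, cfg, rest=rest, stimuli=(step,))
    t, v = res.times, res.trace(soma)
    baseline = float(v[(t >= pre - 10.0) & (t < pre)].mean())
    tail = (t >= pre + duration - 10.0) & (t < pre + duration)
    v_ss = float(v[tail].mean())
    last20 = (t >= pre + duration - 20.0) & (t < pre + duration)
    slope = float(np.polyfit(t[last20], v[last20], 1)[0])
    delta_vm = abs(v_ss - baseline)
    r_n = delta_vm / abs(amplitude_pa * 1e-3) if amplitude_pa else 0.0
    return StepResult(t, v, delta_vm, r_n, steady=abs(slope) < 1e-3)


def _psp_run(
    model: CompartmentalModel,
    rest: RestState,
    events: Sequence[SynapseEvent],
    record: Sequence[TreeLocation],
    onset: float = 10.0,
    t_stop: float = 35.0,
    dt: float = 0.025,
    method: str = "backward_euler",
):
    mod = replace(model, synapses=tuple(events))
    cfg = SolverConfig(dt=dt, method=method, t_stop=t_stop, record=tuple(record))
    return integrate(mod, cfg, rest=rest)


def run_ipsp_visibility(
    conditions: Sequence[str] = ("control", "kv_hcn_block"),
    g_gly_grid: Sequence[float] = tuple(range(1, 11)),
    location: TreeLocation | None = None,
    onset: float = 10.0,
) -> pd.DataFrame:
    """Somatic IPSP magnitude vs glycine conductance and pharmacology.

    A single glycinergic conductance is activated at a dendritic site (the
    distal reference site by default) and the peak somatic hyperpolarization
    is measured, together with each condition's input resistance.  Columns:
    condition, g_gly_ns, ipsp_mv (magnitude), local_ipsp_mv, r_n_mohm,
    negligible (below the somatic detectability threshold).
    """
    rows = []
    for condition in conditions:
        model, rest = calibrated_reference(condition)
        loc = location or reference_site(model.morphology, "distal")
        soma = model.soma_location()
        step = run_current_step(model, rest)
        for g in g_gly_grid:
            kin = replace(GLYCINE_DEFAULT, gmax=float(g))
            ev = SynapseEvent(loc, onset, kin)
            res = _psp_run(model, rest, [ev], [soma, loc], onset=onset)
            som = psp_metrics(res.times, res.trace(soma), onset, expect="IPSP")
            locm = psp_metrics(res.times, res.trace(loc), onset, expect="IPSP")
            amp = abs(som.peak_amplitude)
            rows.append(
                {
                    "condition": condition,
                    "g_gly_ns": float(g),
                    "ipsp_mv": amp,
                    "local_ipsp_mv": abs(locm.peak_amplitude),
                    "r_n_mohm": step.r_n,
                    "negligible": amp < NEGLIGIBLE_IPSP_MV,
                }
            )
    return pd.DataFrame(rows)


def run_local_ipsc(
    conditions: Sequence[str] = ("control", "kv_hcn_block"),
    g_gly_grid: Sequence[float] = tuple(range(1, 11)),
    onset: float = 10.0,
) -> pd.DataFrame:
    """Peak glycinergic current magnitude at proximal and distal sites.

    The synaptic current is g(t) * (V_local(t) - E_gly) during the
    free-running simulation (nS * mV = pA).  Columns: condition, site,
    g_gly_ns, ipsc_pa.
    """
    from .synapses import conductance_waveform

    rows = []
    for condition in conditions:
        model, rest = calibrated_reference(condition)
        for site in ("proximal", "distal"):
            loc = reference_site(model.morphology, site)
            for g in g_gly_grid:
                kin = replace(GLYCINE_DEFAULT, gmax=float(g))
                ev = SynapseEvent(loc, onset, kin)
                res = _psp_run(model, rest, [ev], [loc], onset=onset)
                g_t = conductance_waveform(kin, res.times - onset)
                i_t = g_t * (res.trace(loc) - kin.e_rev)  # pA
                rows.append(
                    {
                        "condition": condition,
                        "site": site,
                        "g_gly_ns": float(g),
                        "ipsc_pa": float(np.max(np.abs(i_t))),
                    }
                )
    return pd.DataFrame(rows)


def run_transfer_impedance(
    model: CompartmentalModel,
    rest: RestState,
    source: TreeLocation,
    target: TreeLocation,
    amplitude_pa: float = 10.0,
    duration: float = 150.0,
    dt: float = 0.05,
) -> float:
    """DC transfer impedance Z_T = dV_ss(target) / I(source), in Mohm.

    Uses a small-amplitude step so the active membrane stays in its
    small-signal regime.
    """
    pre = 20.0
    step = CurrentStep(source, amplitude_pa, t_start=pre, t_stop=pre + duration)
    cfg = SolverConfig(dt=dt, t_stop=pre + duration, record=(target,))
    res = integrate(model, cfg, rest=rest, stimuli=(step,))
    t, v = res.times, res.trace(target)
    baseline = float(v[(t >= pre - 10.0) & (t < pre)].mean())
    v_ss = float(v[(t >= pre + duration - 10.0) & (t < pre + duration)].mean())
    return abs(v_ss - baseline) / abs(amplitude_pa * 1e-3)


def epsp_with_inhibition(
    model: CompartmentalModel,
    rest: RestState,
    excitation: TreeLocation,
    inhibition: TreeLocation,
    g_ampa: float,
    g_gly: float,
    onset: float = 10.0,
    dt: float = 0.025,
    method: str = "backward_euler",
) -> tuple[PSPMetrics, PSPMetrics]:
    """Somatic EPSP metrics without and with coincident inhibition.

    Excitation and inhibition are lumped point conductances activated
    simultaneously.  Returns (without, with).
    """
    soma = model.soma_location()
    exc = SynapseEvent(excitation, onset, replace(AMPA_DEFAULT, gmax=g_ampa))
    res0 = _psp_run(model, rest, [exc], [soma], onset=onset, dt=dt, method=method)
    m0 = psp_metrics(res0.times, res0.trace(soma), onset, expect="EPSP")
    if g_gly == 0.0:
        return m0, m0
    inh = SynapseEvent(inhibition, onset, replace(GLYCINE_DEFAULT, gmax=g_gly))
    res1 = _psp_run(model, rest, [exc, inh], [soma], onset=onset, dt=dt,
                    method=method)
    m1 = psp_metrics(res1.times, res1.trace(soma), onset, expect="EPSP")
    return m0, m1


def run_epsp_inhibition_sweep(
    model: CompartmentalModel,
    rest: RestState,
    spec: SweepSpec,
) -> pd.DataFrame:
    """Excitation-inhibition distance sweep on the longest dendrite.

    Inhibition sits at the proximal (10%) or distal (90%) reference site
    according to ``spec.mode``; excitation is placed at normalized distance
    d from it (d = 1 is maximal separation along the dendrite) and both are
    activated simultaneously.  For each (d, g_gly) the somatic EPSP is
    compared against the excitation-alone run at the same placement.
    Columns: mode, d, g_gly_ns, pct_epsp_change (negative = reduced),
    peak_shift_us (positive = advanced), epsp_without_mv, epsp_with_mv.
    """
    m = model.morphology
    path = longest_dendrite_path(m)
    site = "proximal" if spec.mode == "inhibition_proximal" else "distal"
    inh_loc = reference_site(m, site)

    soma = model.soma_location()
    onset = 10.0
    rows = []
    for d in spec.d_grid:
        exc_loc = locate_at_normalized_distance(m, path, d, inh_loc)
        exc = SynapseEvent(exc_loc, onset, replace(AMPA_DEFAULT, gmax=spec.g_ampa))
        res0 = _psp_run(model, rest, [exc], [soma], onset=onset)
        m0 = psp_metrics(res0.times, res0.trace(soma), onset, expect="EPSP")
        for g in spec.g_gly_grid:
            if g == 0.0:
                m1, pct, shift = m0, 0.0, 0.0
            else:
                inh = SynapseEvent(inh_loc, onset,
                                   replace(GLYCINE_DEFAULT, gmax=float(g)))
                res1 = _psp_run(model, rest, [exc, inh], [soma], onset=onset)
                m1 = psp_metrics(res1.times, res1.trace(soma), onset, expect="EPSP")
                pct = percent_change(m1, m0)
                shift = peak_advance(m1, m0)
            rows.append(
                {
                    "mode": spec.mode,
                    "d": float(d),
                    "g_gly_ns": float(g),
                    "pct_epsp_change": pct,
                    "peak_shift_us": shift,
                    "epsp_without_mv": m0.peak_amplitude,
                    "epsp_with_mv": m1.peak_amplitude,
                }
            )
    return pd.DataFrame(rows)
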