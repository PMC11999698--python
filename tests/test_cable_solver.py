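import math

import numpy as np
import pytest
from scipy.linalg import expm

from octosim.cable_solver import (
    CompartmentalModel,
    CurrentStep,
    PassiveParams,
    SimulationError,
    SolverConfig,
    _Discretization,
    find_rest,
    holding_current,
    integrate,
    solve_e_leak,
    with_e_leak,
)
from octosim.channels import ReversalSet
from octosim.morphology import Morphology, Section, TreeLocation


def _passive_model(sections, e_leak=-65.0, passive=None):
    return CompartmentalModel(
        Morphology(sections),
        passive or PassiveParams(),
        channels=(),
        reversals=ReversalSet(e_leak=e_leak),
    )


@pytest.fixture
def soma_only():
    return _passive_model({0: Section(0, None, "soma", 20.0, 20.0, 20.0, 1)})


@pytest.fixture
def toy_tree():
    """Three-compartment passive tree (soma + two dendrite frusta)."""
    return _passive_model(
        {
            0: Section(0, None, "soma", 15.0, 15.0, 15.0, 1),
            1: Section(1, 0, "dendrite", 50.0, 3.0, 2.0, 1),
            2: Section(2, 1, "dendrite", 50.0, 2.0, 1.0, 1),
        }
    )


class TestPassiveOracles:
    def test_rc_charging_time_constant_and_amplitude(self, soma_only):
        """Isopotential RC: tau = Rm*Cm = 4.5 ms, dV_ss = I*R_N."""
        model = soma_only
        soma = model.soma_location()
        area = model.morphology.soma.membrane_area() * 1e-8  # cm^2
        r_n = model.passive.r_m * 1000.0 / area / 1e6  # Mohm
        tau = model.passive.r_m * model.passive.c_m  # ms
        assert tau == pytest.approx(4.5)
        rest = find_rest(model)
        step = CurrentStep(soma, -100.0, 0.0, math.inf)
        cfg = SolverConfig(dt=0.005, t_stop=60.0, record=(soma,))
        res = integrate(model, cfg, rest=rest, stimuli=(step,))
        dv_ss = -0.1 * r_n
        expected = -65.0 + dv_ss * (1.0 - np.exp(-res.times / tau))
        assert np.max(np.abs(res.trace(soma) - expected)) < 0.01
        assert res.trace(soma)[-1] == pytest.approx(-65.0 + dv_ss, abs=2e-4)

    def test_cylinder_input_resistance_matches_coth_formula(self):
        """Sealed-end cable: R_N = R_inf * coth(L / lambda) within 1%."""
        diam, length = 2.0, 500.0
        model = _passive_model(
            {
                0: Section(0, None, "soma", 1.0, 1e-3, 1e-3, 1),  # vanishing soma
                1: Section(1, 0, "dendrite", length, diam, diam, 200),
            }
        )
        origin = TreeLocation(1, 0.0)
        rest = find_rest(model)
        cfg = SolverConfig(dt=0.1, t_stop=400.0, record=(origin,))
        res = integrate(
            model, cfg, rest=rest, stimuli=(CurrentStep(origin, 100.0),)
        )
        r_sim = abs(res.trace(origin)[-1] + 65.0) / 0.1
        rm = model.passive.r_m * 1000.0
        ra = model.passive.r_a
        lam = math.sqrt(rm * diam * 1e-4 / (4.0 * ra))  # cm
        r_inf = 2.0 * math.sqrt(rm * ra) / (math.pi * (diam * 1e-4) ** 1.5) / 1e6
        r_theory = r_inf / math.tanh(length * 1e-4 / lam)
        assert r_sim == pytest.approx(r_theory, rel=0.01)

    def test_tree_solver_matches_matrix_exponential(self, toy_tree):
        """Implicit solve on the toy tree vs dense expm, within 1 uV."""
        model = toy_tree
        disc = _Discretization(model)
        n = disc.n
        C = np.diag(disc.c_nf)
        A = np.zeros((n, n))
        for i in range(1, n):
            p, g = disc.parent[i], disc.g_axial[i]
            A[i, i] += g
            A[p, p] += g
            A[i, p] -= g
            A[p, i] -= g
        G = np.diag(disc.g_pas)
        inj = np.zeros(n)
        inj[2] = 0.05  # 50 pA at the distal compartment
        M = -np.linalg.solve(C, G + A)
        b = np.linalg.solve(C, disc.g_pas * (-65.0) + inj)
        v0 = np.full(n, -65.0)
        v_inf = np.linalg.solve(G + A, disc.g_pas * (-65.0) + inj)

        tip = TreeLocation(2, 0.9)
        soma = model.soma_location()
        rest = find_rest(model)
        cfg = SolverConfig(
            dt=0.025, method="crank_nicolson", t_stop=20.0, record=(soma, tip)
        )
        res = integrate(model, cfg, rest=rest, stimuli=(CurrentStep(tip, 50.0),))
        for t_check in (1.0, 5.0, 20.0):
            k = int(round(t_check / 0.025))
            v_exact = v_inf + expm(M * t_check) @ (v0 - v_inf)
            assert abs(res.trace(soma)[k] - v_exact[0]) < 1e-3  # 1 uV
            assert abs(res.trace(tip)[k] - v_exact[2]) < 1e-3

    def test_linearity_in_passive_limit(self, toy_tree):
        tip = TreeLocation(2, 0.5)
        rest = find_rest(toy_tree)
        cfg = SolverConfig(dt=0.025, t_stop=10.0, record=(tip,))
        r1 = integrate(toy_tree, cfg, rest=rest, stimuli=(CurrentStep(tip, 20.0),))
        r2 = integrate(toy_tree, cfg, rest=rest, stimuli=(CurrentStep(tip, 40.0),))
        dv1 = r1.trace(tip) + 65.0
        dv2 = r2.trace(tip) + 65.0
        mask = np.abs(dv1) > 1e-9
        assert np.allclose(dv2[mask] / dv1[mask], 2.0, rtol=1e-6)


class TestRestAndHolding:
    def test_passive_rest_equals_leak_reversal_exactly(self, toy_tree):
        rest = find_rest(toy_tree)
        assert np.allclose(rest.v, -65.0, atol=1e-9)
        assert rest.max_dvdt < 1e-4

    def test_calibrated_rest_near_minus_65(self, control_setup):
        model, rest = control_setup
        disc = _Discretization(model)
        soma_v = rest.v[disc.comp_of(model.soma_location())]
        assert soma_v == pytest.approx(-65.0, abs=0.5)
        assert rest.max_dvdt < 1e-4

    def test_gates_stay_in_unit_interval(self, control_setup):
        model, rest = control_setup
        soma = model.soma_location()
        cfg = SolverConfig(dt=0.025, t_stop=30.0, record=(soma,))
        res = integrate(
            model, cfg, rest=rest, stimuli=(CurrentStep(soma, -500.0, 5.0, 20.0),)
        )
        for x in res.final_gates:
            assert np.all(x >= 0.0) and np.all(x <= 1.0)

    def test_holding_zero_for_target_at_rest(self, toy_tree):
        assert holding_current(toy_tree, -65.0) == pytest.approx(0.0, abs=20.0)

    def test_holding_follows_ohms_law_on_passive_soma(self, soma_only):
        area = soma_only.morphology.soma.membrane_area() * 1e-8
        r_n = soma_only.passive.r_m * 1000.0 / area / 1e6  # Mohm
        i = holding_current(soma_only, -64.0)  # +1 mV from rest
        assert i == pytest.approx(1.0 / r_n * 1000.0, rel=0.05)

    def test_blocked_model_needs_depolarizing_hold_when_leak_is_negative(
        self, blocked_setup, control_setup
    ):
        """Sign oracle: holding sign matches the rest displacement it fixes."""
        blocked, _ = blocked_setup
        unheld = find_rest(
            CompartmentalModel(
                blocked.morphology,
                blocked.passive,
                blocked.channels,
                blocked.reversals,
                holding_pa=0.0,
            )
        )
        ctrl_model, ctrl_rest = control_setup
        disc = _Discretization(blocked)
        v_unheld = unheld.v[disc.comp_of(blocked.soma_location())]
        v_ctrl = ctrl_rest.v[disc.comp_of(blocked.soma_location())]
        if v_unheld < v_ctrl:
            assert blocked.holding_pa > 0
        else:
            assert blocked.holding_pa < 0

    def test_e_leak_solver_pins_somatic_rest(self, toy_tree):
        target = -70.0
        e = solve_e_leak(toy_tree, v_target=target)
        rest = find_rest(with_e_leak(toy_tree, e))
        assert rest.v[0] == pytest.approx(target, abs=0.1)


class TestStability:
    def test_traces_bounded_in_subthreshold_protocols(self, control_setup):
        model, rest = control_setup
        soma = model.soma_location()
        cfg = SolverConfig(dt=0.025, t_stop=50.0, record=(soma,))
        res = integrate(
            model, cfg, rest=rest, stimuli=(CurrentStep(soma, -1000.0, 5.0, 45.0),)
        )
        v = res.trace(soma)
        assert v.min() > -120.0 and v.max() < 80.0

    def test_dt_halving_self_convergence(self, control_setup):
        """Halving dt changes the somatic EPSP trace by < 10 uV RMS."""
        from dataclasses import replace as _r

        from octosim.synapses import AMPA_DEFAULT, GLYCINE_DEFAULT, SynapseEvent

        model, rest = control_setup
        soma = model.soma_location()
        events = (
            SynapseEvent(TreeLocation(1, 0.5), 10.0, _r(AMPA_DEFAULT, gmax=5.0)),
            SynapseEvent(TreeLocation(1, 0.1), 10.0, _r(GLYCINE_DEFAULT, gmax=8.0)),
        )
        mod = _r(model, synapses=events)
        res1 = integrate(mod, SolverConfig(dt=0.025, t_stop=30.0, record=(soma,)),
                         rest=rest)
        res2 = integrate(mod, SolverConfig(dt=0.0125, t_stop=30.0, record=(soma,)),
                         rest=rest)
        rms_mv = np.sqrt(np.mean((res1.trace(soma) - res2.trace(soma)[::2]) ** 2))
        assert rms_mv < 0.010

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SolverConfig(dt=0.0)
        with pytest.raises(ValueError):
            SolverConfig(method="forward_euler")
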