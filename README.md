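# octosim

A compartmental biophysical model of **octopus cells** of the ventral
cochlear nucleus, built to study how **dendritic glycinergic inhibition**
shapes the cell's submillisecond coincidence detection.

Octopus cells read out coincident firing across auditory-nerve (spiral
ganglion, SGN) fibers with a temporal precision of tens of microseconds.
They achieve this with an extremely low input resistance near rest
(R_N ≈ 4 MΩ), set by a large low-threshold potassium conductance (KLT) and
a dendritic HCN conductance. The same leakiness electrically confines
dendritic inhibitory potentials: glycinergic synapses cover the dendrites
at substantial density, yet their IPSPs are nearly invisible to a somatic
electrode. This package implements the model used to ask what those
"hidden" synapses do: they act locally, attenuating and *temporally
advancing* excitatory potentials before the soma integrates them.

## What is inside

| module | content |
| --- | --- |
| `octosim.morphology` | synthetic octopus-cell tree (soma + 4 unidirectional tapered dendrites), areas solved from the measured synapse budget; SWC I/O; the normalized-distance axis used in placement sweeps |
| `octosim.channels` | Rothman–Manis-type VCN conductances (Na m³h, KA a⁴bc, KHT 0.85n²+0.15p, KLT w⁴z, HCN r, leak) with per-channel scaling factors `scl`; Kv+HCN block = `scl → 0` |
| `octosim.synapses` | peak-normalized AMPA (τ = 0.3 ms) and glycine (τ = 3 ms) conductances; measured puncta-density table; seeded synapse placement (expected or Poisson counts) with tonotopic ranks |
| `octosim.cable_solver` | implicit branched-cable integrator (Hines-ordered O(n) solve, backward Euler default, Crank–Nicolson optional, Rush–Larsen gating, dt = 25 µs) |
| `octosim.metrics` | PSP amplitude/timing with sub-sample (parabolic) peak interpolation |
| `octosim.protocols` | the virtual experiments: current steps under pharmacology, IPSP visibility, local IPSCs, transfer impedance, excitation–inhibition distance sweeps |
| `octosim.config` | YAML/JSON run configuration and `run_from_config` |
| `analysis/` | numbered drivers reproducing the study's figures as CSV tables under `results/` |

The membrane equation per compartment is

```
C_m dV/dt = −g_pas(V−E_leak) − Σ_ch ḡ_ch·scl_ch·∏x^p (V−E_ch)
            − g_syn(t)(V−E_syn) + I_inj/A + axial coupling,
```

with passive parameters R_a = 150 Ω·cm, R_m = 5 kΩ·cm², C_m = 0.9 µF/cm²,
rest −65 mV, and reversals E_Na = 50, E_K = −70, E_h = −38, E_AMPA = 0,
E_gly = −80 mV. Scaling factors are ḡ-multipliers Na 0.83, KA 0.07,
KHT 0.1875, KLT 0.75, HCN 0.07 (dendrites only), leak 0.0017.

## Worked example

```python
from octosim.protocols import calibrated_reference, run_current_step, \
    epsp_with_inhibition, reference_site
from octosim.morphology import TreeLocation
from octosim.metrics import percent_change, peak_advance

model, rest = calibrated_reference("control")
step = run_current_step(model, rest, amplitude_pa=-200.0)
print(f"control step: {step.delta_vm:.3f} mV, R_N {step.r_n:.2f} MOhm")

blocked, brest = calibrated_reference("kv_hcn_block")
print(f"blocked step: {run_current_step(blocked, brest).delta_vm:.3f} mV")

exc = TreeLocation(1, 0.5)                         # mid-dendrite AMPA
inh = reference_site(model.morphology, "proximal")  # glycine at 10%
m0, m1 = epsp_with_inhibition(model, rest, exc, inh, g_ampa=5.0, g_gly=8.0)
print(f"EPSP {m0.peak_amplitude:.3f} -> {m1.peak_amplitude:.3f} mV "
      f"({-percent_change(m1, m0):.1f}% reduction, "
      f"{peak_advance(m1, m0):.0f} us advance)")
```

prints

```
control step: 0.701 mV, R_N 3.50 MOhm
blocked step: 8.836 mV
EPSP 0.779 -> 0.617 mV (20.8% reduction, 76 us advance)
```

— a −200 pA step barely moves the control soma (0.7 mV) but deflects the
Kv+HCN-blocked cell 8.8 mV, and a coincident 8 nS dendritic glycine
conductance trims a mid-dendrite EPSP by ~21% while advancing its somatic
peak by tens of microseconds.

The analysis pipeline runs the full figure-level experiments:

```bash
python analysis/01_build_anatomy.py
python analysis/02_current_step_calibration.py
python analysis/03_inhibition_visibility.py
python analysis/04_epsp_inhibition_sweep.py
```

each writing CSV tables (and the SWC morphology) under `results/`.

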