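# Model and methods

## The cell and the question

Octopus cells monitor the entire tonotopic array of auditory-nerve fibers
through a handful of thick, unidirectionally oriented dendrites, and fire
only when many fibers spike within a submillisecond window. Two
conductances open at rest — low-threshold potassium (KLT) and dendritic
HCN — give the cell an input resistance of only a few megaohms, a
membrane time constant of a few hundred microseconds, and strong
electrotonic isolation of the dendrites from the soma. Glycinergic
synapses are abundant on those dendrites, yet produce almost no somatic
deflection. The model asks what such electrically "invisible" inhibition
does to the excitatory signal en route to the soma.

## Morphology

The morphology is synthetic: one isopotential soma (a closed cylinder
with length = diameter) and four unbranched, linearly tapering dendrites
(5 → 1.5 µm). It is calibrated to the anatomy rather than to a
reconstruction: the soma and dendrite membrane areas (1526 and 7775 µm²)
are the unique solution for which the measured synaptic puncta densities
(SGN 13.3/10.7 per 100 µm² on soma/dendrite; glycinergic 1.8/4.2)
reproduce the measured totals (~1035 SGN and ~354 glycinergic synapses).
Given the fixed taper, each dendrite's length is then solved from its
area share, giving ~190 µm per dendrite. Compartments are ≤ 10 µm
(matching the 10 µm bins in which dendritic puncta densities are
tabulated) and always well below 0.1 λ at 100 Hz.

Two sites on the longest dendrite anchor the inhibition experiments:
"proximal" at 10% and "distal" at 90% of its path length. The
normalized-distance axis d used in placement sweeps is 0 at the
inhibitory synapse and 1 at the end of the dendrite farthest from it.

## Membrane

Channel kinetics follow the standard ventral-cochlear-nucleus
(Rothman–Manis-type) formulations at their 22 °C reference temperature:
fast Na (m³h), fast transient K (KA, a⁴bc), high-threshold K (KHT,
0.85 n² + 0.15 p, represented internally as two product-form entries),
low-threshold K (KLT, w⁴z), and HCN (first-order r, dendrites only). A
Q10 of 3 is applied to rate constants when a different simulation
temperature is configured; the default stays at 22 °C, matching the
temperature at which the kinetics are specified. Each channel's density
is `gbar_base × scl`, where the dimensionless `scl` values (Na 0.83,
KA 0.07, KHT 0.1875, KLT 0.75, HCN 0.07, leak 0.0017) are the published
model's per-channel multipliers. Pharmacological removal of Kv and HCN
conductances (4-AP + ZD 7288 in the slice) is emulated by `scl → 0` for
KA, KHT, KLT, and HCN.

The base densities are not printed anywhere, so they are calibration
parameters of this package. They were fixed once against the two printed
step responses — a −200 pA somatic step must deflect the control soma
≈ 0.7 mV and the Kv+HCN-blocked soma ≈ 8.8 mV — giving (S/cm²) Na 0.05,
KA 0.05, KHT 0.05, KLT 0.067, HCN 0.0347, leak 0.03. Two features of the
calibration are worth noting. First, the control response is dominated
by the *slope* conductance of KLT and HCN around rest (their
voltage-dependent opening roughly doubles the chord conductance), which
is why the fitted densities differ from a naive chord estimate. Second,
the blocked response is governed almost entirely by the passive membrane
(1/R_m, with R_m = 5 kΩ·cm²) plus the small leak channel, so the leak
base density is effectively the blocked-state dial. The membrane always
carries the passive conductance 1/R_m in addition to the channel set;
zeroing every channel therefore leaves a passive cell whose input
resistance scales with R_m.

The leak reversal E_leak (shared by the passive conductance and the leak
channel) is solved at model-build time by bisection so the relaxed
somatic rest sits at −65 ± 0.1 mV; with the default densities it lands
near −63 mV. Rest is found by large-step implicit relaxation (the fixed
point of the implicit update is the exact steady state, so coarse steps
converge to the same rest as fine integration; HCN's multi-hundred-ms
time constants make this the expensive part). For the blocked condition
a constant somatic holding current (secant iteration, ±2 nA range)
returns the soma to the control resting potential before any protocol
runs, mirroring the experimental procedure; with the default calibration
this is a −45 pA hold.

## Synapses

Synaptic conductances are peak-normalized alpha functions
g(t) = gmax·(t/τ)·exp(1 − t/τ): AMPA with τ = 0.3 ms and reversal 0 mV,
glycine with τ = 3 ms and reversal −80 mV. The source description of the
kinetics ("rise and decay … tuned to 0.3 ms and 3 ms respectively")
admits two readings — one time constant per receptor, or rise/decay
shared by both receptors. This package adopts the per-receptor reading,
for two reasons. Physiologically, octopus-cell AMPA receptors are among
the fastest known (submillisecond EPSCs), while glycinergic IPSCs decay
over several milliseconds; a shared 0.3 ms rise / 3 ms decay would make
excitation as slow as inhibition. Mechanistically, only a glycinergic
conductance that *outlasts* the AMPA conductance clips the decaying
flank of the EPSP and thereby advances its peak — the signature
experimental effect. With shared kinetics the model produces peak
*delays* for on-path inhibition, contradicting the measured direction.
The general double-exponential waveform (distinct rise and decay, peak
normalized) is retained for non-default kinetics.

Anatomical placement converts the packaged density table into synapse
positions: counts per compartment class are `round(density × area/100)`
("expected" mode) or Poisson with that mean; dendritic placements fall
into 10 µm path bins with probability proportional to bin membrane area,
uniform within a bin; somatic placements are uniform. SGN placements
carry a tonotopic rank increasing with path distance from the soma
(distal = higher sound frequency), and Ia-subtype density is derived by
subtracting Ib/c from total SGN density. A single seed makes placement
reproducible. For the PSP experiments, excitation and inhibition are
delivered as single lumped point conductances at specified locations;
the placement generator serves anatomy reporting and distributed-drive
extensions.

## Numerics

The branched cable equation is discretized into frustum compartments and
integrated implicitly: gating variables advance by the exact exponential
(Rush–Larsen) update, staggered from the voltage solve; the voltage
system — tridiagonal-plus-branches — is solved in O(n) per step by
Hines-ordered elimination (parents numbered before children; one
child-into-parent sweep, one back-substitution). Backward Euler at
dt = 25 µs is the default; Crank–Nicolson is available and is used where
second-order accuracy matters (it matches a dense matrix-exponential
reference on a three-compartment passive tree to ~0.01 µV, versus
~15 µV transient error for backward Euler at the same step). Halving the
default step changes a somatic EPSP trace by ~1 µV RMS. Axial
resistance between compartments uses the exact frustum integral
4R_a l/(π d₁ d₂); the soma contributes no internal axial resistance.
Synaptic and injected currents enter as point terms in the compartment
containing their location, evaluated at the implicit time level.

PSP peaks are located by fitting a parabola through the sampled extremum
and its neighbours, resolving peak-time shifts well below the 25 µs
step (the measured effect, ~57 µs, is barely two samples). Baseline is
the mean over 5 ms ending 0.5 ms before onset; deflections under 10 µV
count as "no event". When coincident inhibition adds a slow
hyperpolarizing component to a fast EPSP, EPSP height is measured as the
depolarizing extremum (`expect="EPSP"`), matching the experimental
definition.

## What the virtual experiments show

With the default calibration the model reproduces, without further
tuning: R_N ≈ 3.5 MΩ (control) vs ≈ 44 MΩ (block); somatic IPSPs below
0.3 mV for glycine conductances up to 10 nS in control but up to ~3 mV
under block, always attenuated relative to the local dendritic IPSP;
local IPSC magnitudes that *decrease* under block (the larger local IPSP
erodes its own driving force), most strongly at the distal site; distal
dendrite → soma transfer impedance rising from ~1 MΩ to ~43 MΩ under
block; and EPSP reduction monotone in glycine conductance with the peak
always advanced. Within the 6–10 nS glycine band the sweep surfaces
overlap the experimentally measured ranges for both amplitude
(25.2 ± 9.0% reduction) and timing (57.5 ± 26 µs advance).

## Limitations

* The morphology is an area-calibrated stand-in, not a reconstruction.
  Its single unbranched cable per dendrite makes on-path (proximal)
  inhibition maximally effective, so the measured preference for
  inhibition placed *distal* to excitation is reproduced only near
  colocalization (separations ≲ 0.2 of the dendrite); at larger matched
  separations the synthetic cell shows the classic on-path advantage
  instead. A branched arbor with high-impedance terminal segments would
  be needed to recover the full asymmetry.
* For the same reason the synthetic cell filters dendritic EPSPs
  somewhat more than a reconstructed octopus cell, and the peak-time
  advance at the fixed proximal-inhibition/mid-dendrite configuration
  with a 2 nS AMPA input runs ~2× the experimental mean, although
  in-range advances occur broadly across the sweep surfaces.
* Subthreshold regime only: no spike mechanism is exercised, no
  short-term plasticity, no calcium dynamics, and optogenetic drive is
  idealized as timed conductance events.
* Simulated problem sizes: the reference cell discretizes to 81
  compartments; protocol runs are 30–220 ms at dt = 25 µs; sweep grids
  use 4–5 separations × 3–6 conductances.
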