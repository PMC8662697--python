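# Model and methods

`hepatocal` simulates glucose mobilization by a liver lobule during physical
exercise, under joint control of circulating hormones, direct sympathetic
innervation, and intercellular Ca²⁺ signaling. This note describes the model,
its parameterization, the calibration of the constants that are not fixed a
priori, and the known limitations of the approach.

## Architecture

The lobule is a one-dimensional porto-central chain of N = 15 hepatocyte
layers, each paired with a sinusoidal blood compartment. Blood enters at the
periportal (PP) end, flows compartment-to-compartment at rate
`bf = 0.15·N s⁻¹` (2.25 s⁻¹ at N = 15), and exits the pericentral (PC) end
into a systemic compartment `s = 5·N` times larger. The systemic compartment
closes the loop through four organ models:

* **Pancreas** — glucagon is secreted when systemic glucose (in reference
  units, `GB/G_au_scale` with `G_au_scale = 2500 µM/a.u.`) falls below the
  reference `G_ref = 2`, insulin when it rises above; each rate is a Hill
  function (exponent 2) of `|ln(G_ref/GB_au)|`.
* **CNS** — hypothalamic activation `CNSAct = (G_symp − GB)/(Km_symp +
  (G_symp − GB))` switches on below `G_symp = 4500 µM` (`Km_symp = 500 µM`).
* **Adrenal glands** — epinephrine and norepinephrine release at basal rates
  0.5 and 1.5 nM·s⁻¹, amplified `(1 + X·CNSAct)`-fold (X = 6 and 14) in the
  main model variant; the alternative variant holds them constant (adrenal
  denervation) and instead adds a CNS-driven term to glucagon secretion.
* **Muscle** — a constant glucose uptake, stepped up 3.5-fold during the
  exercise window (t = 500 s to 4100 s by default).

Each hepatocyte carries a closed-cell IP₃–Ca²⁺ cross-coupling oscillator
(four states: free receptor fraction r, IP₃, cytosolic Ca²⁺, free IP₃R
fraction g) driven by the local catecholamine stimulus, and a metabolic
backbone (glycogen store, intracellular free glucose). Adjacent cells
exchange only IP₃, by linear mass transfer with coefficient `G_ij`
(0 / 2.5 / 5 s⁻¹ = uncoupled / weak / strong) and no-flux chain ends. Cell
heterogeneity is deterministic: the receptor recycling rate `k_r`
(0.5 → 1.0 s⁻¹) and IP₃ synthesis rate `k_IP3` (0.5 → 0.6 s⁻¹) increase
linearly from PP to PC, reflecting pericentral enrichment of α₁-adrenergic
signaling; the glycogenolytic capacity weight decreases linearly 1.0 → 0.5
from PP to PC, imposing the periportal bias of glycogenolysis.

Glycogen breakdown is Michaelis–Menten in the store (Km 100 mM, Hill
exponent 4) and phosphate (held at its half-saturation 4000 µM), scaled by
the glucagon/insulin ratio `K_Phos_max = (Glu + 45 pM)/(Ins + 26.66 pM)`
sensed from the local sinusoid, and potentiated `(1 + 3·v_GPK)`-fold by
cytosolic Ca²⁺ through glycogen phosphorylase kinase: `v_GPK` is basal
(0.05) below a 0.44 µM Ca²⁺ amplitude threshold and saturating above it.
Broken-down glucosyl units feed intracellular free glucose, which exchanges
with the local sinusoid at 0.1 s⁻¹ (fast relative to `bf`, so hepatic
glucose release is transport-limited). There is no glycogen synthesis:
the model describes an exercise bout, not a feeding cycle.

## Unit bridges and structural choices

Several couplings require unit conventions the rate laws do not pin down:

* **Glucose**: the pancreas senses glucose in reference units; systemic and
  sinusoidal glucose are stored in µM and divided by `G_au_scale` at the
  pancreas interface, mapping normoglycemia (~5000 µM) onto the reference
  point.
* **Catecholamines**: adrenal secretion is treated as a lobule-referred flux
  and divided by the body/hepatic volume ratio `s` in the systemic balance.
  This places basal systemic catecholamines at ~0.5–2 nM — the only range in
  which the receptor binding constant (`k_Hr = 1 nM⁻¹s⁻¹`) and the 2 nM
  synaptic norepinephrine stimulus are both meaningful; applied at face
  value as a systemic concentration rate, 0.5 nM·s⁻¹ of basal secretion
  against a liver-only clearance bounded by the flow throughput `bf/s`
  would force systemic catecholamines into the hundreds of nM, where every
  α₁ receptor saturates and no scenario contrast can exist.
* **IP₃ synthesis**: the numeric nM value of the stimulus enters the
  synthesis term directly, yielding µM-scale IP₃ as required by the 1 µM
  half-saturation of store release.
* **Ca²⁺ potentiation**: the Michaelis constant of the Ca²⁺-induced increase
  in glycogen phosphorylase activity defaults to `Km_CaI = 0.6 µM`
  (switchable to the 3 µM constant via `use_Km_CaI=False`). Simulated spike
  amplitudes are 0.6–1 µM; with a 3 µM constant the potentiation never
  exceeds ~1.2-fold and the calibrated Ca²⁺ contribution to glycogenolysis
  (below) would be unreachable.
* **Hormone clearance**: insulin, glucagon and catecholamines are cleared
  only in the hepatic compartments, first-order. Glucagon and insulin use
  separate constants: the glucagon pool must track the exercise deficit on a
  ~400 s time scale while the insulin background must stay near-constant
  over the hour; no single constant does both.

## Calibration

Five constants are calibrated rather than fixed a priori:
`k_clear_glucagon = 0.012 s⁻¹`, `k_clear_insulin = 2·10⁻⁴ s⁻¹`,
`k_clear_cat = 0.03 s⁻¹`, the resting insulin level `Ins_B0 = 15 nM`, and
the resting glucagon/glucose pair (`Glu_B0 = 1.37 nM` at `GB0 = 4600 µM`,
chosen as the fixed point at which pancreatic secretion exactly balances
hepatic glucagon clearance, so the no-exercise control is stationary from
t = 0). The anchors are: a ~2-fold exercise increase of systemic
epinephrine, norepinephrine and glucagon at t = 4000 s, a ~13% contribution
of catecholamine-induced Ca²⁺ signaling to cumulative glycogenolysis, a flat
no-exercise control, and sustained hepatocyte spiking during exercise with
inter-spike intervals near 100 s. `scripts/calibrate.py` reruns the sweep.

Basal muscle glucose uptake `u_G_basal` is not a free constant: it is
computed at startup as the uptake that exactly balances hepatic export at
the resting state, and it is always derived from the normotensive resting
state so that portal-hypertensive scenarios face the same systemic demand as
their normotensive counterparts.

The single-cell reference stimulus (`CALIBRATED_STIMULUS = 4 nM`) drives an
isolated mid-lobular hepatocyte at an inter-spike interval of ~92 s; the
oscillation onset for mid-lobular parameters lies near 2.2 nM, and the ISI
is non-monotonic in the stimulus (shortest just above onset), which is why
wave leadership in the coupled chain depends delicately on the stimulus
operating point.

## Numerics

The 170-state system (6 hepatocyte states and 5 blood species per layer,
plus 5 systemic states) is integrated with the SciPy BDF stiff solver at
`rtol = 10⁻⁶`, `atol = 10⁻⁹`, with a supplied Jacobian sparsity pattern and
dense output on a 1 s grid. The exercise step is handled exactly by
restarting the integrator at the window boundaries, so the uptake rate is
constant within each solver segment. The IP₃R equation drives its state
below zero at low Ca²⁺ (inactivation `E·CaI⁴` falls below the constant
reactivation F); well-posedness requires clamping, implemented by zeroing
outward rates at the state bounds (r, g in [0, 1]; concentrations ≥ 0)
inside the right-hand side, with residual excursions on the output grid
counted, clipped, and aborted on if they exceed 0.1% of samples. Halving
the tolerances changes cumulative glucose output by < 3·10⁻⁵ relative.
The model contains no randomness; identical configurations give
bit-identical trajectories.

Default problem sizes: 15 layers and a 4100 s horizon (500 s baseline +
1 h exercise), matching the protocol behind the t = 4000 s readouts; a full
scenario integrates in a few seconds, and engine-level convergence tests use
shortened horizons (600–1500 s) since they probe the integrator, not the
protocol.

## Analysis conventions

Ca²⁺ spikes are maxima above 0.44 µM (the glycogenolysis activation
threshold, so detected spikes are exactly the metabolically relevant ones)
with ≥ 0.1 µM prominence and ≥ 20 s separation. Wave metrics use the
pericentral cell as reference: each other cell's spikes are matched to the
nearest reference spike within 0.45 periods; the signed lag is the mean
matched offset of the extreme PP cell (positive = PC fires first, a PC→PP
wave), the velocity `(N−1)/|lag|` cells·s⁻¹ (×25 µm for a conventional
hepatocyte diameter if µm/s are wanted), and a run is classified
unsynchronized ("none") when matching is sparse or the lag jitter exceeds
20% of the period. Metrics are computed over the final 1100 s of a run:
spiking ignites only after CNS activation mid-exercise, and earlier windows
mix the ignition transient into the lag. Glucose outputs are trapezoidal
time integrals of the per-layer hepatocyte→sinusoid export flux.

## Behavior and limitations

With the shipped calibration the model reproduces: ~2-fold exercise
increases of systemic catecholamines and glucagon at t = 4000 s; a ~16%
Ca²⁺-signaling contribution to cumulative glycogenolysis; synchronized
PC→PP waves under human-like innervation with coupling (velocity increasing
with `G_ij`), unsynchronized spiking when uncoupled; periportally dominated
zonal glucose output in every scenario; higher output with more extensive
innervation at matched strong coupling; and, under portal-hypertensive
(3-fold Poiseuille) flow, the pericentral redistribution of catecholamines
and glucose output and the weak-coupling optimum of the human-innervated
hypertensive lobule.

Two behaviors are known not to match the target phenomenology, and are
asserted as expected-to-fail in the acceptance tests rather than papered
over:

1. **Baseline rodent/denervated wave direction.** With the shipped
   parameter gradients the pericentral IP₃ drive exceeds the periportal
   drive at every reachable stimulus level (a PP-led wave would need a
   ~10:1 porto-central catecholamine gradient, but gradient steepness and
   absolute level are locked together through the single clearance
   constant), so coupled waves are PC-led in all innervation schemes, not
   only the human-like and adrenally amplified ones.
2. **Micro-margin total-output orderings.** The closed glucose loop is
   demand-clamped: cumulative hepatic output ≈ cumulative muscle uptake
   plus body-store drain, so scenario contrasts in supply capacity surface
   mainly in systemic glucose and hormone levels, and some total-output
   comparisons (strong vs. weak coupling, normotensive vs. hypertensive)
   differ only at the 0.02–0.1% level, sometimes inverted.

Other limitations: the lobule is one-dimensional (no 2-D/3-D neighbor
topology); only IP₃ crosses gap junctions; the metabolic backbone collapses
the G6P intermediate and carries no gluconeogenesis, glycolysis, lipid or
FFA pathways, so only the glucose half of exercise demand is modeled; blood
pressure enters only as a proportional flow scaling; and all cell-intrinsic
parameters are deterministic, so the cell-to-cell variability of real
hepatocyte Ca²⁺ spiking (and any "island" patterns it produces at weak
coupling) is under-represented. Simulated behavior therefore speaks to
mechanistic trends, not to quantitative prediction for real tissue.
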