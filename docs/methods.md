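# Methods

## Cell model

The myocyte model is the Courtemanche–Ramirez–Nattel (CRN) human atrial
action potential model (21 states: V, 12 voltage-dependent gates, the
Ca-dependent `fca` gate, three sarcoplasmic-reticulum release gates and five
intracellular/SR concentrations), with three extensions that make the
extracellular milieu a first-class input:

1. **Reversal potentials** `ENa`, `EK` (and, under the `variable_eca` flag,
   the ICaL driving term) are recomputed by the Nernst equation from the
   extracellular concentration each current sees. By default ICaL keeps the
   original fixed +65 mV driving term; the variable-`ECa` formulation is a
   documented variant because the original model's calcium handling assumes
   the fixed constant.
2. **Potassium dependence of inward rectification.** `GK1` and `GKr` are
   multiplied by `(Ko / 5.4 mM) ** 0.5`. The square-root conductance scaling
   anchored at the original model's 5.4 mM is the standard description of the
   cross-over effect of extracellular K⁺ on inward-rectifier channels; both
   anchor and exponent are configuration (`CellParameters.k_anchor`,
   `k_exponent`), so an alternative functional form can be substituted
   without code changes. The scaling reproduces the qualitative behaviour the
   analysis needs: hypokalaemia hyperpolarises the resting potential strongly
   and nonlinearly, hyperkalaemia depolarises it.
3. **Per-current electrolyte override mask.** Every current can be told to
   see either the "perturbed" or the "reference" electrolyte set. With the
   all-perturbed mask the model is bitwise identical to the unmasked model.
   The mask is the primitive behind per-current attribution: varying [Na⁺]ₒ
   only in the Na⁺/Ca²⁺-exchanger expression, say, isolates that current's
   contribution to an output's variance.

Fibrosis remodelling multiplies `GNa` by 0.60, `GK1` by 0.50 and `GCaL` by
0.50, with apply-once semantics (`fibrotic` flag). Fibroblast–myocyte
electrotonic coupling is deliberately not modelled. Temperature is fixed at
310 K. Accepted simulation ranges are Ko ∈ [2, 10], Nao ∈ [80, 200],
Cao ∈ [0.5, 5] mM; the reference set is (4.5, 140, 1.8) mM.

## Numerics

The production integrator is a fixed-step scheme: Rush–Larsen exponential
updates for all gates, forward Euler for concentrations and voltage, with the
voltage-dependent gate steady states, rate coefficients (pre-exponentiated
per time step) and current factors tabulated on a 0.025-mV grid over
[−120, 80] mV and linearly interpolated (numba-compiled). Defaults: dt
0.025 ms for single cells, 0.02 ms for 1-D strands (100 µm), 0.05 ms for 2-D
sheets (500 µm). An adaptive-solver path (`integrate_adaptive`, scipy LSODA
at rtol 1e-8 over the pure-numpy right-hand side) exists as an independent
numerical cross-check; at the baseline limit cycle the two integrators agree
on APD90 within 2 ms. State layout and update order are frozen so traces are
bitwise reproducible.

The monodomain scaling is `D = sigma / (beta * Cm)` with β = 1400 cm⁻¹ and
Cm = 1 µF/cm²; the healthy longitudinal conductivity (0.28 S/m, D ≈ 0.2
mm²/ms) was set once so the healthy strand at reference electrolytes
conducts at 0.6–0.8 m/s (measured 0.65 m/s at CL 1000 ms). The six-region
conductivity table (longitudinal/transverse pairs, decreasing with image
intensity class, fibrotic rows reduced) is a declared default, fully
overridable; the true per-region values belong to the imaging cohort and are
not claimed here. Diffusion uses second-order central differences with
arithmetic face averaging, no-flux boundaries, and an explicit stability
check before stepping. Only axis-aligned fibres are supported (σ_l along x,
σ_t along y).

Tolerances and tie-breaks: LAT is the time of maximum dV/dt with 3-point
parabolic sub-sample refinement; nodes with activation amplitude < 40 mV are
invalid; CV-map gradients below 1e-3 ms/mm (plateaus/blocks) are masked;
percentiles interpolate linearly between order statistics; APD thresholds
are crossed by linear interpolation.

## Protocols

* **Pre-pacing**: trains at fixed cycle length from the published resting
  state; the full protocol is 15 min (900 beats at CL 1000 ms), the desk
  default is 100 beats. The limit-cycle residual (max-norm of the
  scale-normalised state difference between the starts of the last two
  beats) is reported but not enforced, because intracellular Na⁺ in this
  model drifts on a many-minute horizon. All electrolyte *comparisons* are
  made at matched beat counts, which the sensitivity analyses require; the
  absolute biomarkers keep a slow trend (e.g. baseline APD90 is 287 ms after
  100 beats and 204 ms after 900).
* **Stimulus**: rectangular, 2 ms, 23 pA/pF in 0-D (twice the diastolic
  threshold of 11.4 pA/pF found once by bisection at reference conditions);
  60 pA/pF on tissue node sets.
* **Strand CV**: 1-cm strand, 100-µm nodes, pre-paced 0-D state broadcast to
  all nodes, end pacing; CV = 5 mm / (LAT(0.75 cm) − LAT(0.25 cm)) on the
  final beat, at cycle lengths 400/500/700/1000 ms. Conduction block is a
  flag, never a number.
* **Activation maps**: two stimuli at CL 1000 ms in the coronary-sinus
  analogue box; maps are computed from the second activation. Runs that
  self-sustain after a single stimulus are screened out of QoI tables and
  flagged with their electrolyte context.
* **Arrhythmia induction**: burst pacing (5 S1 at CL 700 ms; 400 ms pause
  measured from the last S1 — the anchoring is stated explicitly because the
  protocol phrasing is ambiguous; then 5 stimuli at CL 160 ms at the
  appendage or roof analogue), or a four-spiral phase-map initial state after
  CL-300 pre-pacing. Episodes are tracked 5 s beyond the final stimulus.
  Episode criteria (defaults, configurable): induced = any node with ≥ 3
  activations after the final stimulus at mean cycle length < 500 ms;
  terminated = induced and no activation plus all V < RMP + 10 mV over the
  final 200 ms. Dominant frequency is the reciprocal of the mean
  inter-activation interval over active nodes — interval-based rather than
  spectral because 5-s records give poor spectral resolution.
* **Spiral initial condition**: 2 × 2 Archimedean spiral phase maps with
  alternating chirality; each node's state is sampled along its region's
  CL-300 limit-cycle trajectory at the phase-proportional time offset. The
  radial pitch default is 6 cm, of the order of the healthy tissue
  wavelength (CV × APD ≈ 10 cm); a much smaller pitch leaves the sheet
  almost everywhere refractory and the construction collapses immediately.

## Synthetic substrates

The generator emulates the statistical structure of an imaging-derived
cohort, not its anatomy: a Gaussian random field smoothed to a 5-mm
correlation length (patchy-fibrosis stand-in), transformed to a log-normal
image-intensity-ratio (IIR) marginal (log-sd 0.18, range ≈ 0.5–2), with the
field median chosen by quantile matching so the fraction of nodes above the
1.22 fibrotic threshold equals a draw from the clipped normal cohort
distribution (mean 21 %, sd 15 %, clipped to [0, 70] %). Five increasing
cut-points (0.9, 1.0, 1.1, 1.22, 1.4 by default) define six tissue classes;
classes above 1.22 receive remodelled cell parameters and reduced
conductivities. Stimulus boxes sit at fixed normalised sheet coordinates
(coronary-sinus analogue 0.5–0.7 × 0.8–0.9, appendage analogue 0.9–0.91 ×
0.9–0.91, roof analogue 0.48–0.49 × 0.48–0.49); normalised sheet coordinates
are an *analogy* to universal atrial coordinates, not an implementation.
Sheet default: 5 × 5 cm at 500 µm, per-substrate size jittered (lognormal,
sd 0.08) to provide the surface-area feature.

What the generator does **not** emulate: real atrial geometry and wall
curvature, fibre architecture, anatomical obstacles (veins, appendage),
inter-patient conduction heterogeneity beyond the six-class table. Passing
tests therefore demonstrate the machinery and its calibrated statistics, not
clinical validity on patient anatomies.

## Sensitivity analysis

Inputs are uniform over the clinical ranges (Ko 3–6, Nao 105–175, Cao
1.35–2.25 mM; the analysis-design choice is uniform weighting). Designs are
plain Latin hypercubes (one sample per equal-probability stratum per
column), 30 rows by default, with the reference combination appended as a
31st baseline row. One Gaussian-process emulator (anisotropic RBF + nugget,
inputs scaled to the unit cube, marginal-likelihood fit with seeded
restarts) is fitted per quantity of interest; Sobol indices are estimated on
the emulator mean by the Saltelli pick-freeze scheme (first order:
Saltelli-2010 estimator; total order: Jansen; second order via the
complementary BA_i matrices) on scrambled quasi-random A/B samples, N a
power of two (default 1024). Raw estimates are reported; clamping of small
negative values happens only in the normalised "doughnut" fractions, which
sum to one. Direct simulation instead of the emulator is available through
the same entry point at reduced N. Per-current attribution evaluates the
0-D biomarker pipeline with the override mask on a uniform grid over one
electrolyte's range and normalises the resulting output variances across
currents.

## Machine learning

Endpoint classifiers (logistic regression, random forest, gradient
boosting; random forest is the reporting default) are trained only when
both outcome classes have ≥ 2 samples. The reported score is the
coefficient of determination of the predicted class-1 probability against
the binary labels — the score's target is ambiguous in the source protocol,
so accuracy and AUROC are reported alongside. Permutation importance is the
mean ± sd score drop over 100 per-column permutations. Shapley values are
computed exactly by enumerating all coalitions of the ≤ 5 features with the
interventional value function (complement features marginalised over a
background sample); local accuracy (base + Σφ = prediction) holds to
machine precision by construction. Per-substrate mode trains one classifier
per substrate on its 31 electrolyte rows; cohort mode pools all rows and
augments the features with fibrosis fraction and surface area.

## Scale profiles and known limitations

Desk-scale defaults (100-beat pre-pacing, 30-row designs, 5-cm sheets,
N = 1024 emulator-mediated Sobol) run on one CPU in minutes; the "paper"
profile (`PipelineConfig.paper_profile()`: 900-beat trains, 100 substrates)
is for cluster use. Problem sizes used by the test suite are smaller still
and are stated in the tests.

Known limitations:

* Functional re-entry on desk-scale sheets rotates faster (~5 Hz mean
  activation rate) than organised whole-atrium arrhythmias, whose re-entrant
  paths are anatomically long; dominant-frequency statistics from small
  sheets are therefore biased high, and on 5-cm sheets the four-spiral state
  generally fails to sustain at all because the healthy tissue wavelength
  (~10 cm) exceeds the domain. The scaled-down frequency check in the
  acceptance suite documents this bias rather than hiding it.
* The slow intracellular Na⁺ drift of the cell model means absolute APDs
  depend on pre-pacing duration; comparisons are made at matched beat
  counts.
* The exact potassium dependence of the modified IK1/IKr, the per-region
  conductivity table, and the arrhythmia-identification criteria of the
  source protocol are not public; the implementations here are documented,
  configurable defaults, not claims about those values.
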