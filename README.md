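# atrisim

Multiscale simulation and analysis of how clinically relevant changes in
extracellular electrolyte concentrations — potassium ([K⁺]ₒ), sodium
([Na⁺]ₒ) and calcium ([Ca²⁺]ₒ) — alter human atrial electrophysiology and
arrhythmia behaviour. The package is aimed at computational
electrophysiologists who want a desk-scale, fully synthetic test bed for
electrolyte-sensitivity questions: no patient data is required; statistically
calibrated synthetic substrates stand in for an imaging-derived cohort.

## What is inside

* **Cell model** (`atrisim.ionic`): the Courtemanche–Ramirez–Nattel (CRN)
  human atrial myocyte model, extended so every extracellular concentration
  acts on the currents that physically see it (Nernst potentials recomputed
  per beat; `IK1`/`IKr` conductances scale as `(Ko/5.4 mM)^0.5`, reproducing
  the strong [K⁺]ₒ dependence of inward rectification). Fibrosis remodelling:
  `GNa ×0.6`, `GK1 ×0.5`, `GCaL ×0.5`. A per-current override mask can feed
  a perturbed electrolyte into a single current while every other current
  sees the reference value — the primitive behind per-current attribution.
* **0-D protocols** (`protocols0d`): constant-CL pacing to a limit cycle,
  AP biomarkers (RMP, APD70/90, plateau peak, dV/dt max).
* **Monodomain tissue** (`monodomain`): `Cm ∂V/∂t = −I_ion + ∇·(D∇V)` on
  1-D strands and 2-D sheets, explicit finite differences with Rush–Larsen
  reaction steps, no-flux boundaries. Strand CV is measured as
  `0.5 cm / (LAT(0.75 cm) − LAT(0.25 cm))`.
* **Maps and QoIs** (`biomarkers`): LAT (argmax ∂V/∂t), LRT (90 % recovery),
  APD90 = LRT − LAT, CV = 1/|∇LAT|; medians `mAPD`, `mCV` and 2.5–97.5
  inter-percentile ranges `DAPD`, `DCV`, plus relative variations against a
  baseline run.
* **Synthetic substrates** (`substrate`): correlated log-normal
  image-intensity-ratio (IIR) fields segmented into six tissue classes
  (fibrotic above IIR 1.22), calibrated so the cohort fibrotic fraction is
  21 % ± 15 % (clipped to 0–70 %), with stimulus boxes at normalised-
  coordinate analogues of the coronary sinus, left atrial appendage and roof.
* **Sensitivity analysis** (`gsa`): Latin-hypercube electrolyte designs over
  [K⁺]ₒ = 4.5 ± 1.5, [Na⁺]ₒ = 140 ± 35, [Ca²⁺]ₒ = 1.8 ± 0.45 mM; Gaussian-
  process emulators per quantity of interest; Sobol first/second/total-order
  indices by the Saltelli pick-freeze scheme.
* **Arrhythmia induction** (`induction`): burst pacing at the appendage or
  roof analogue (5 × CL 700 ms, 400 ms pause, 5 × CL 160 ms), a four-spiral
  phase-map initial condition, 5-s episode tracking, binary endpoints
  (induced/terminated) and interval-based dominant frequency.
* **Machine learning** (`ml`): seeded logit / random-forest /
  gradient-boost endpoint classifiers (random forest reports), permutation
  feature importance (n = 100 permutations) and *exact* interventional
  Shapley values by subset enumeration over the ≤ 5 features.
* **Orchestration** (`pipeline`, `cli`): seeded, manifest-tracked runners
  `run_cell_gsa`, `run_strand_cv`, `run_cohort`; CLI subcommands
  `atrisim cell-gsa | strand-cv | substrate | induce | cohort | classify |
  report`.

## Worked example

```python
from atrisim import CellParameters, ElectrolyteSet, REFERENCE_ELECTROLYTES
from atrisim.protocols0d import limit_cycle_ap

params = CellParameters()
for label, es in [("baseline ", REFERENCE_ELECTROLYTES),
                  ("low Na+  ", ElectrolyteSet(4.5, 105.0, 1.8)),
                  ("low K+   ", ElectrolyteSet(3.0, 140.0, 1.8))]:
    bm, trace, pre = limit_cycle_ap(params, es, cl_ms=1000.0, n_prepace=100)
    print(f"{label} RMP {bm.rmp:7.2f} mV  APD70 {bm.apd70:6.1f} ms  "
          f"APD90 {bm.apd90:6.1f} ms")
```

prints

```
baseline  RMP  -85.70 mV  APD70  219.8 ms  APD90  287.1 ms
low Na+   RMP  -87.63 mV  APD70  143.3 ms  APD90  206.0 ms
low K+    RMP  -95.36 mV  APD70  210.9 ms  APD90  270.3 ms
```

Lowering [Na⁺]ₒ by 25 % collapses the plateau and shortens APD70 by ~77 ms,
while lowering [K⁺]ₒ mainly hyperpolarises the resting potential by ~10 mV
with comparatively little APD change — the two signature electrolyte effects,
at the cell scale, that drive the tissue-level conduction and arrhythmia
results.

A strand conduction-velocity check:

```python
from atrisim.monodomain import strand_cv_protocol
cv, blocked, _ = strand_cv_protocol(params, REFERENCE_ELECTROLYTES,
                                    cl_ms=1000.0, n_prepace=100)
print(f"healthy strand CV {cv:.3f} m/s")   # -> healthy strand CV 0.648 m/s
```

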