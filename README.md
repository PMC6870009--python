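# gatenet

Analysis pipeline for **P50 sensory gating** in the paired-click EEG
paradigm, aimed at three-group staging of psychosis: first-episode
schizophrenia (FESZ), ultra-high-risk individuals (UHR) and healthy
controls (HC).

Two identical clicks are presented 500 ms apart (S1, S2). In healthy
listeners the response to S2 is suppressed; the P50 — the maximum positive
deflection 30–90 ms after each click — quantifies this gating via the
difference S1−S2 and the ratio S2/S1. Beyond the scalar ERP measures, the
pipeline characterises the *networks* engaged by gating: condition segments
(S1, S2 and the pointwise gating response S1−S2) are projected to 80
cortical regions with an eLORETA-style weighted minimum-norm inverse,
pairwise coupling is estimated with normalized mutual information, the
resulting 80×80 weighted graphs are summarised by graph metrics, groups are
compared edge-wise with permutation tests, and a pruned decision tree
stages subjects from 24 features.

Because no public dataset accompanies this design, the package ships a
first-class synthetic cohort generator with known ground truth (planted
amplitudes and planted cross-region couplings), so every stage is testable
end to end.

## Methods at a glance

* **ERP stage** — average reference, zero-phase 1–40 Hz band-pass,
  −200…0 ms baseline correction, amplitude-based trial rejection; P50 scored
  as the maximum positive peak in the 30–90 ms window on a vertex-channel
  average; subjects with S1 < 0.5 µV flagged invalid.
* **Inverse** — eLORETA-style weights from the fixed-point iteration
  `w_i ← sqrt(k_iᵀ (K W⁻¹ Kᵀ + αH)⁺ k_i)`; the resulting kernel has zero
  localization error for noiseless point sources (verified for all 80
  sources in the tests).
* **Connectivity** — `MI(S,Q) = H(S) + H(Q) − H(S,Q)` from equal-width
  histograms; `NMI = MI / sqrt(H(S)·H(Q)) ∈ [0,1]`, computed for all
  C(80,2) = 3160 region pairs.
* **Graph metrics** — characteristic path length `L` (mean shortest-path
  length, edge length 1/weight), average clustering coefficient `C` on a
  proportionally thresholded binary graph, global efficiency
  `E_global` (mean reciprocal shortest-path length).
* **Group statistics** — edge-wise two-sided permutation test on the
  difference of group means (9480 edge tests over the three group pairs),
  node-degree summaries of significant edges, Kruskal–Wallis with
  Bonferroni post hocs for scalar measures.
* **Staging** — decision tree with cost-complexity post-pruning selected by
  internal cross-validation; evaluated by 101 random 20 %-per-group splits
  (median accuracy) and stratified fivefold cross-validation; impurity
  importances aggregated into the four feature classes (ERP / NET / DEM /
  MCCB).

## Worked example

```python
import numpy as np
from gatenet import SynthConfig, generate_cohort, run_pipeline
from gatenet.pipeline import compare_stage

cfg = SynthConfig(n_per_group={"FESZ": 8, "UHR": 8, "HC": 8}, n_trials=40, seed=0)
cohort = generate_cohort(cfg)
result = run_pipeline(cohort)

erp = result.erp_table
for group in ("FESZ", "UHR", "HC"):
    sub = erp[(erp.group == group) & erp.valid]
    print(f"{group}: S1 = {sub.s1_amp.mean():.2f} uV, S2 = {sub.s2_amp.mean():.2f} uV, "
          f"S2/S1 = {sub.ratio.mean():.2f}")

tests = compare_stage(result.networks, result.labels, n_perm=2000, seed=0)
for pair in (("FESZ", "HC"), ("UHR", "HC"), ("FESZ", "UHR")):
    r = tests[("S1-S2", *pair)]
    print(f"gating network {pair[0]} vs {pair[1]}: {r.n_significant} significant edges")
```

prints

```
FESZ: S1 = 1.33 uV, S2 = 0.80 uV, S2/S1 = 0.70
UHR: S1 = 1.48 uV, S2 = 0.83 uV, S2/S1 = 0.55
HC: S1 = 1.72 uV, S2 = 0.76 uV, S2/S1 = 0.50
gating network FESZ vs HC: 208 significant edges
gating network UHR vs HC: 224 significant edges
gating network FESZ vs UHR: 125 significant edges
```

The group-mean P50 amplitudes recover the generator's per-group parameters
(µV); the gating-network comparison shows the planted pattern — both
patient groups differ from HC on many more edges than they differ from each
other, because the generator plants elevated cross-region coupling shared
by FESZ and UHR but absent in HC.

A thin CLI mirrors the stages: `gatenet synth`, `gatenet erp`,
`gatenet connect`, `gatenet compare`, `gatenet classify`
(see `gatenet --help`).

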