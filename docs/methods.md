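# Methods

This note documents the models, the numerical choices and the limits of
what the synthetic experiments can show. It accompanies the code; nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The paired-click paradigm and the ERP stage

Each trial presents two identical clicks 500 ms apart; epochs span
−200…+1000 ms around the first click at 1000 Hz. Preprocessing is
average re-referencing, zero-phase band-pass filtering (Butterworth order
4, run forward and backward as second-order sections; default band
1–40 Hz), baseline correction by the mean of the −200…0 ms window, and
amplitude-based trial rejection. Rejection operates on the *unfiltered*
(average-referenced) data, because a brief large artifact is smeared below
any reasonable threshold by the band-pass; the default threshold is 100 µV.
The band-pass order was chosen so that a 60 Hz line component is attenuated
by well over 20 dB with the 1–40 Hz band.

The P50 is the maximum positive sample in the 30–90 ms window after each
click (window endpoints inclusive — 61 samples at 1000 Hz; ties break to
the earliest latency), measured on the mean of a small vertex-channel
subset (3 channels nearest the vertex by default), after trial averaging.
Amplitude is the baseline-corrected peak value, not peak-to-trough.
Gating is summarised by the difference S1−S2 and the ratio S2/S1; the
ratio is undefined when S1 ≤ 0 and such subjects are flagged. Subjects
whose S1 amplitude is below 0.5 µV are marked invalid and excluded from
group statistics (the threshold is configurable; at typical ~1 µV
amplitudes a millivolt-scale threshold would exclude nobody, so the
microvolt reading is the operative one). The exclusion rule is applied to
the reported S1 amplitude, i.e. after channel averaging.

Three condition segments per subject — S1 (30–90 ms after S1), S2
(30–90 ms after S2) and the pointwise gating response S1−S2 — feed the
network stages.

## eLORETA-style inverse

The inverse is a weighted minimum-norm with depth weights from the
fixed-point iteration

    w_i ← sqrt( k_iᵀ (K W⁻¹ Kᵀ + αH)⁺ k_i ),   W = diag(w_i²),

where `K` is the row-centered lead field (`H = I − 11ᵀ/n` is the
average-reference operator), `⁺` a pseudoinverse with relative
singular-value cutoff 1e−10, and `α` expressed as a fraction of the mean
eigenvalue of `K W⁻¹ Kᵀ` (default 0.05; tol 1e−6; max 300 iterations).
Two numerical points matter:

* The update is homogeneous of degree 1 in `w`, so only the weight
  *direction* is determined; the implementation renormalizes to geometric
  mean 1 each iteration, otherwise the scale drifts geometrically and the
  convergence criterion never fires even though the kernel (which is
  scale-invariant) has converged.
* Localization uses the variance-standardized power `(w_i ŝ_i)²`, not the
  raw current density. By Cauchy–Schwarz, `|k_iᵀ M k_j| ≤ w_i w_j` with
  equality only at `i = j`, so the standardized statistic has provably
  zero localization error for noiseless point sources; the raw estimate
  does not (it over-weights sources with small weights) and empirically
  misassigns deep sources on correlated spherical lead fields.

Dipoles have fixed orientation (one scalar time course per source), since
the region-level pipeline needs one signal per node. Each atlas region is
represented by its designated centroid source ("central voxel" rule); with
the default one-source-per-region space the extraction is the identity,
and a dense mode (k sources per region, centroid flagged) exercises the
rule properly. A voxel-level cortical grid is deliberately not reproduced;
any user lead field can be supplied.

## NMI connectivity

For two signals S, Q: plug-in entropies from equal-width histograms over
each signal's own observed range (empty bins contribute zero),
`MI = H(S) + H(Q) − H(S,Q)`, and

    NMI = MI / sqrt(H(S) · H(Q)) ∈ [0, 1].

The geometric-mean denominator is the only choice of the common
normalizations for which identical signals give exactly 1 (an
arithmetic-mean variant is available by flag). Entropies are reported in
bits; NMI itself is base-invariant. A pair involving a constant signal has
undefined normalization and is reported as 0 with a warning.

Bin count default: `ceil(sqrt(n))`, which is 8 for the 61-sample
segments, capped at 32 — the plug-in MI bias grows like `(bins−1)²/(2n)`,
so an uncapped square-root rule would keep the bias roughly constant
instead of letting it vanish for long signals. The small-sample bias at
n = 61 with 8 bins is real and positive (the suite quantifies it against a
long-sample oracle: on the order of +0.2 in NMI units for independent
Gaussians); it is a property of the estimator, uniform across subjects and
groups, and therefore cancels in the between-group comparisons, but
absolute NMI values at this segment length should not be over-interpreted.

All C(80,2) = 3160 unordered pairs are computed per subject and condition
(one-hot tensor contraction, no Python pair loop), giving a symmetric
matrix with zero diagonal. Matrices are per subject — group comparison by
subject-label permutation requires subject-level networks, so no
grand-average network is formed.

## Graph metrics

Edge length is the reciprocal weight, 1/w (conventional for
similarity-weighted brain graphs; a −log(w) mapping would also be
defensible but is not used). Characteristic path length `L` is the mean
shortest-path length over ordered pairs; pairs in different components are
excluded from the mean with a warning, and a fully disconnected graph is
an error. Global efficiency is the mean *reciprocal* shortest-path length
with disconnected pairs contributing 0 — reciprocal-distance efficiency is
the standard definition and is the one implemented, treating a printed
formula that would make efficiency identical to `L` as a typo.

`L` and `E_global` use the full weighted graph. The clustering coefficient
uses binary adjacency by definition (`C_i = E_i / (k_i(k_i−1))` with `E_i`
the ordered-pair triangle count, `C_i = 0` for degree < 2), so the
weighted matrix is first binarized by proportional threshold: the top
`density · C(n,2)` strongest edges are kept (default density 0.2; ties at
the threshold break by stable edge-index order). Whether the original
analysis also thresholded before `L` and `E` is not documented; the
full-weighted choice here is a recorded divergence risk. Per subject and
condition this yields the 9 staging features `{S1,S2,S1_S2} × {CLU (C),
CHA (L), EFF (E_global)}`.

## Group statistics

Edge-wise comparison of two groups uses the difference of group means per
edge — a simple, exchangeability-valid statistic — with a null from random
relabelings of the pooled subjects and the two-sided estimate
`p = (1 + #{|null| ≥ |obs|}) / (1 + n_perm)` (default 5000 permutations;
exact enumeration of all label assignments whenever there are at most
20000). P-values are reported per edge at α = 0.05 with no cross-edge
correction, matching the per-edge reporting convention of this analysis
style; a correction flag exists but is off by default. Node degrees of
significant edges are tabulated per region and hemisphere, sorted
descending. Scalar measures use Kruskal–Wallis (tie-corrected, k−1
degrees of freedom) with pairwise rank tests Bonferroni-adjusted by the
number of pairs.

## Staging classifier

The 24 features in four classes — ERP (S1 amplitude, S2 amplitude, S1−S2,
S2/S1), NET (the 9 graph metrics), DEM (gender, age, education), MCCB
(8 cognitive scores) — are joined per subject. Trees are scale-invariant,
so no feature scaling is applied; gender is a binary indicator; an
undefined gating ratio is encoded as 0.

The classifier is a CART-style tree with cost-complexity post-pruning: the
pruning path is computed on the training set and the penalty chosen by
internal stratified 5-fold cross-validation, ties resolved toward the
strongest pruning (simplest tree). Evaluation mirrors the staging
experiments: 101 independent splits taking 20 % of each group for testing
(25/23/19 → 5/5/4 test subjects, 53 train), summarised by the median of
the 101 accuracies (the 51st order statistic) and the confusion matrix of
the median repetition; and a stratified fivefold cross-validation
(67 subjects → folds of 13/13/13/14/14). Each repetition re-runs the
pruning CV independently. Feature-class importances are impurity
importances summed within class and normalized to 100 %.

## Synthetic cohorts: what they emulate, and what they do not

Defaults reproduce the study conditions: 25/23/19 subjects, 80 click pairs
at 1000 Hz, epochs −200…+1000 ms, S2 at +500 ms, 32 sensors (configurable
up to 128), 80 regions (40 per hemisphere, AAL-style names).

* **Forward model.** Sensors on the upper unit hemisphere; fixed-oriented
  dipoles on an inner shell (radius 0.85) under the cap; homogeneous-medium
  dipole potentials with unit-norm columns — an analytic quasi-spherical
  stand-in whose neighbouring columns are correlated, as on a head. An
  i.i.d. Gaussian lead field is available for unit tests. Skull
  conductivity layers and realistic geometry are not modelled.
* **P50 bursts.** Gaussian-windowed bursts (peak 50 ms after each click,
  σ = 8 ms) injected into one "auditory" region per hemisphere — chosen as
  the regions projecting most strongly to the vertex channels, where the
  P50 is measured. Per-subject S1/S2 amplitudes are drawn from the
  published per-group means/SDs (µV), truncated away from zero, and the
  injection is calibrated so that a unit source amplitude appears as
  ~1 µV on the average-referenced vertex-channel mean. The measured group
  means therefore recover the parameters up to three understood, small
  biases: band-pass attenuation of the burst (negative), peak-picking on
  residual noise (positive), and the S1 ≥ 0.5 µV validity exclusion
  (positive, largest for the widest amplitude distribution).
* **Background.** Each source carries trial-locked 1/f-shaped background
  (spectral exponent 1, SD 0.3) — the "evoked background" that survives
  averaging and gives the MI estimator realistically autocorrelated
  inputs — plus per-trial white source noise and white sensor noise that
  average away.
* **Planted coupling.** Ground-truth connectivity is planted by mixing a
  shared trial-locked latent signal (1/f, SD 3.0, Hann-tapered) into both
  regions of each planted edge during the two 30–90 ms windows, scaled by
  a per-group coupling in [0, 1]. The two windows use independent
  latents, so the effect survives the S1−S2 subtraction. By default 5
  interhemispheric edges are planted with coupling 0.8 in both patient
  groups and 0.1 in HC — patient-vs-HC comparisons carry signal, FESZ vs
  UHR does not. Default edges are auto-selected among the regions with the
  *weakest* vertex projection, keeping the connectivity manipulation
  spatially orthogonal to the vertex-measured amplitudes. The latent SD
  was set so the planted coupling survives the severe mixing of an
  underdetermined inverse (80 sources from ~31 spatial degrees of
  freedom); with weak latents the reconstruction cross-talk floor swallows
  the effect entirely.
* **Covariates.** Age, education, gender and the 8 MCCB scores are drawn
  from per-group normals (scores clipped at 0), independent of amplitudes
  given group — no amplitude-by-gender or cognition-by-amplitude structure
  is simulated. `connectivity_only_config` replaces all per-group
  covariate and amplitude parameters by the HC values, producing cohorts
  whose *only* group difference is the planted coupling; this is the
  correct substrate for testing that network features add discriminative
  information, since with fully informative cognitive covariates the 9
  global metrics are often redundant.

What passing tests show: each stage is numerically correct against
independent oracles, the inverse localizes exactly, the permutation test
is calibrated, and the full pipeline recovers planted amplitude and
coupling differences at realistic sample sizes. What they do not show:
performance on real EEG — no eye-blink/EMG structure beyond optional
amplitude-burst artifacts, no volume-conduction confounds beyond the
linear forward model, no non-stationarity across trials, and no claim that
the real-data accuracy tables are reproducible (they depend on an
unavailable clinical dataset).

## Problem sizes used in the shipped experiments

The test suite and the acceptance script run the full default cohort
(67 subjects, 80 trial pairs, 32 sensors, 80 regions), edge-wise
permutation tests with 1000–2000 permutations (5000 is the library
default), classifier evaluations with 101 repetitions, and calibration
simulations with 50 seeds × 500 permutations on 30-node graphs — sizes
chosen to keep a complete run in minutes on one CPU while leaving the
estimators in their intended regimes.
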