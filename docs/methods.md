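# Methods

This note documents the models, conventions and design choices behind
`pzmap`, in the order the pipeline runs them.

## Intensity standardization

Landmark standardization assumes that within one modality the slice
histograms differ mainly by a monotone intensity warp. For each slice the
landmarks are the minimum (0th percentile), the median *m* and the 99.8th
percentile, computed with linear interpolation between order statistics.
Training (once per modality) maps each slice's median onto the standard
scale [s₁, s₂] by the two-point map [p_low, p_high] → [s₁, s₂] and averages
the mapped medians into μ_s. Transformation maps each slice
piecewise-linearly: [p_low, m] → [s₁, μ_s] and [m, p_high] → [μ_s, s₂], so
every slice's median lands exactly on μ_s and the across-slice variance of
mapped medians is zero by construction.

Conventions: s₁ = 1, s₂ = 4095 by default (a 12-bit-like range following
the landmark-standardization literature); values outside [p_low, p_high]
are linearly extrapolated on their segment (clamping available); landmarks
are computed inside the region-of-interest mask when one is supplied, since
the analysis is restricted to the peripheral zone; z-scoring uses the
population standard deviation (divide by n) — on whole images the
distinction from the sample convention is negligible, and fixing one makes
runs reproducible. Degenerate slices (zero intensity range) are skipped
with a warning during training and collapse to μ_s during transformation.

## Feature extraction

All texture derives from the structural channel; functional channels
contribute raw intensities only. The default stack has 32 columns:
3 intensities + 5 first-order + 5 NGTDM + 3 NGLDM + 16 RI-LPQ.

**First-order (window 5×5).** Median, population standard deviation, third
central moment Σ(z−m̄)³p(z), energy Σp(z)² and entropy −Σp(z)log₂p(z), with
p(z) the empirical distribution of the window's values. On continuous
intensities that distribution is uniform over n distinct values, collapsing
energy to 1/n and entropy to log₂n for every window; the pipeline therefore
computes energy and entropy on the gray-level-quantized channel and the
three moment statistics on the continuous intensities. An optional second
window size appends five more columns (37 total).

**Gray-level quantization.** Equal-width binning of the masked intensity
range into 32 levels (0..31). 32 levels balance matrix sparsity against
discrimination for 8-to-12-bit-like data. NGTDM/NGLDM are invariant to
adding a constant before quantization (the bins shift together).

**NGTDM (sliding 9×9 window, 3×3 neighborhood).** For each gray level i,
s(i) = Σ|i − Ā| over the window's interior pixels of level i, where Ā is
the mean of the 3×3 neighborhood excluding the center; p(i) is the level's
occurrence probability among interior pixels. The five Amadasun–King
operators follow, with sums restricted to occupied levels:
coarseness = [ε+Σpᵢsᵢ]⁻¹; contrast = [ΣΣpᵢpⱼ(i−j)²/(N(N−1))]·[Σsᵢ/n];
busyness = Σpᵢsᵢ / ΣΣ|i·pᵢ−j·pⱼ|; complexity =
ΣΣ(|i−j|/(n(pᵢ+pⱼ)))(pᵢsᵢ+pⱼsⱼ); strength = ΣΣ(pᵢ+pⱼ)(i−j)²/(ε+Σsᵢ).
ε = 10⁻¹² guards the coarseness/strength denominators; any exactly-zero
denominator yields 0. The complexity normalization uses n (the interior
pixel count); variants in the literature use n² — the choice is fixed here
and mirrored by the brute-force oracle in the test suite.

**NGLDM (sliding 9×9 window, Chebyshev distance d = 1).** Q(c, r) counts
interior pixels of level c with exactly r of their (2d+1)²−1 neighbors
within the similarity tolerance a. The tolerance is specified on the
standard scale (default a = 10 on [1, 4095]) and converted to level units
as a·n_levels/(s₂−s₁) ≈ 0.08, i.e. effectively exact-level matching — an
absolute tolerance would be meaningless after z-scoring. Operators: number
nonuniformity Σᵣ(ΣcQ)²/N_s, second moment ΣΣQ²/N_s, entropy
−ΣΣ(Q/N_s)log₂(Q/N_s).

**RI-LPQ (k = 3 neighborhood, 36 candidate angles, 7×7 histogram
window).** A characteristic orientation per pixel is the phase of the first
circular-harmonic response (Gaussian window σ = k/4, center weight zero),
snapped to the nearest of 36 angles with ties broken toward the smaller
angle. The STFT is evaluated at the four standard low-frequency points
(radius 1/k) rotated into that frame; the sign of each imaginary part
(sign(0) = +, bit set) packs into a 4-bit code in 0..15. The local 16-bin
code histogram, normalized to sum 1, supplies the 16 features. Because the
window is isotropic and the frequency rotation is exact on the grid for 90°
multiples, code histograms are invariant under 90° image rotation up to
boundary effects.

Numerical determinism: orientation snapping and sign binarization apply a
relative 10⁻⁹ deadzone, because integer-valued images routinely produce
exact orientation ties (45° multiples) and exactly-zero imaginary responses
whose floating-point sign depends on summation order.

Border handling: first-order and RI-LPQ use symmetric (edge-mirror)
padding; NGTDM/NGLDM windows use only pixels whose full neighborhood lies
inside the (symmetrically padded) window, per the matrix definitions.

## Feature selection

The Spearman filter scans columns in order and drops any feature whose
|ρ| ≥ 0.60 against an already-kept feature (average ranks for ties;
constant columns dropped first). The rule is greedy and therefore
order-dependent — documented, deterministic behavior. Sequential forward
selection adds the feature maximizing a held-out criterion (typically AUC)
and stops when the best addition improves it by less than δ = 0.005 for
`patience` (default 1) consecutive steps; this quantifies "no significant
improvement", for which no standard test exists at per-pixel sample sizes.
The subset found most useful on the clinical-style data this design targets
(first-order standard deviation, third moment, energy) ships as a preset,
not a default.

## Incremental ensemble

Base learner: soft-margin RBF SVM (C, γ), solved by libsvm through
scikit-learn. Each hypothesis standardizes its input columns to the
training-subset mean/sd — RBF distances are meaningless across the
heterogeneous scales of the feature stack (NGTDM coarseness alone spans
twelve orders of magnitude when windows are locally constant). Decision
values are signed distances to the hyperplane.

Hyperparameters maximize stratified k-fold CV AUC over a coarse grid
(C ∈ 2^{−3..10}, γ ∈ 2^{−10..3}, step 2²) whose best point seeds a
Nelder–Mead search in (log₂C, log₂γ). Among grid ties the point nearest
the grid center is preferred: on a plateau (e.g. separable data, AUC = 1
everywhere) extreme corners mean badly under- or over-fit models. The
search runs once per increment on the first drawn training half and is
reused across that increment's iterations; the tuned values move little
between resamples of one batch, and the option `optimize_every="iteration"`
restores per-iteration search.

The increment loop on batch S_k (m points): initialize uniform weights;
per iteration normalize D_t = w/Σw, draw ⌈m/2⌉ training points by weighted
sampling without replacement, train, and accept the hypothesis only if its
D_t-weighted error on all of S_k is below ½ (minimum training accuracy 0.5
also enforced; 10 redraws before the increment stops early with a warning).
All hypotheses so far — including earlier increments' — vote with weights
log(1/β); the composite error E_t must also be below ½; weights of
correctly composite-classified points shrink by B_t = E_t/(1−E_t).

Two deliberate numerical guards: β is floored at 10⁻¹² inside the vote
weight so a perfect learner dominates with a large finite weight instead of
producing ∞−∞ margins; and when E_t = 0 the weight update is skipped, which
equals the uniform shrink that cancels in the normalization. Vote ties go
to the negative (non-lesion) class — conservative for a screening map.

A structural note on strong base learners: the weight update makes the
current composite's weighted error exactly ½ on the next distribution (the
boosting fixed point). When the base learner already sits at the Bayes
error of a stationary batch — typical for a tuned SVM on overlapping
Gaussians — later iterations on that batch are rejected and the increment
saturates after one or a few hypotheses. This is expected behavior, not
failure: progress then comes from new increments, which reset the weights
on their own batch.

The random-subspace variant draws L = 5 feature subsets (r = 50% or 75% of
the columns) per iteration, trains one learner per subset, and scores each
by the mean square error between its Platt-calibrated probability and the
{0,1}-encoded label; β = mse/(1−mse), same voting rule.

Data cleaning (optional, per class per patient): a one-class SVM (ν = 0.05)
drops points outside the learned support; classes below 20 points pass
through unchanged. Class balancing (per patient): undersample the majority
and oversample the minority with replacement to the geometric mean of the
two class counts — the symmetric meeting point that neither discards most
of the majority nor duplicates the minority excessively.

## Probability maps and calibration

Platt calibration fits P(y=+1|f) = 1/(1+exp(Af+B)) to a hypothesis'
decision values by Newton iterations with backtracking on the regularized
likelihood (smoothed targets t₊ = (N₊+1)/(N₊+2), t₋ = 1/(N₋+2)). The
ensemble posterior is the vote-weighted average Σv_t P_t(+1|x)/Σv_t with
v_t = log(1/β_t) — the combination rule is a package design choice, chosen
so a unanimous confident ensemble yields the same confident probability and
the map stays in [0, 1] by construction. Calibration parameter recovery is
verified on stratified synthetic scores (labels at each score value match
the sigmoid's expected frequency), which isolates the optimizer's recovery
error from Bernoulli label noise.

## Evaluation

TPR = TP/(TP+FN), SPC = TN/(TN+FP), PPV = TP/(TP+FP); 0/0 is reported as
undefined (NaN), never as 0. ROC AUC is computed from average ranks (the
tie-adjusted Mann–Whitney concordance) and must match the trapezoidal area
of the threshold-swept curve to 10⁻¹⁰, which is asserted at runtime. The PR
area integrates the real operating points over recall and extends
constantly to recall 0, excluding the conventional (0, 1) anchor — constant
scores then give area = positive prevalence, the correct baseline. The
working threshold θ* maximizes BAC over the grid 0.05..0.95 (step 0.05,
ties to the smaller θ). Nested CV splits by patient (outer k = 3 by
default; leave-one-patient-out via outer_k = n_patients) with inner CV for
tuning on the training pool only; AUC confidence intervals use a
patient-level percentile bootstrap (1000 resamples). The Friedman test for
comparing models is delegated to scipy.

## The phantom

The generator emulates the statistical structure the pipeline assumes:
textured background vs. lesions differing in mean (default 100 vs 130,
marginal sd 20) and in spatial autocorrelation (Gaussian smoothing 0.6 px
vs 1.8 px — the texture contrast that NGTDM/NGLDM/RI-LPQ exploit); lesions
as random ellipses deformed by smoothed noise (cancerous structures have no
canonical shape, and circles would be trivially separable), disjoint,
inside a half-annulus ROI standing in for the peripheral zone, each at
least 25 px (the analogue of a minimum-lesion-area rule at phantom
resolution); a smooth multiplicative bias field (±10%); per-slice gain/
offset distortions (non-standardness); heavy class imbalance (lesions
~10–15% of the ROI); optional label flips. Functional channels carry half
the mean contrast (one positive, one negative) and no autocorrelation
difference. Identical spec and seed give bit-identical output.

What the phantom does *not* emulate: anatomy-dependent texture gradients,
registration error between channels, partial-volume effects at lesion
boundaries, scanner-specific noise spectra, or inter-patient biological
variability. Passing tests on the phantom therefore demonstrate the
correctness and the qualitative behavior of the pipeline (e.g. that texture
features add discrimination beyond intensities), not clinical performance.

The incremental-learning probe uses three Gaussian clusters,
A = (0,0) (negative, present in both batches), B = (5,−1) and C = (6,2)
(positive), sd 0.7, 120 points each: C is a new positive phenotype
compatible with, but absent from, the first batch — the scenario
incremental learning is for. A plain retrain on the second batch alone
would misclassify a third of B; the ensemble keeps B within a few points
while classifying C correctly.

## Problem sizes and defaults

The pipeline defaults are desk-scale by design: 6 phantom slices of 64×64
(each slice playing one patient), a stratified cap of 400 pixels per slice,
T = 5 iterations per increment with 3-fold inner CV in the pipeline config
(the library-level ensemble default is T = 20 with 10-fold inner CV), so a
full run completes in about a minute on one CPU. All stochastic steps
derive their generators from the single configured seed; reruns are
bit-identical.

## Known limitations

- The Spearman filter's keep-first rule depends on column order; a
  graph-based variant (drop the higher-mean-correlation member of each
  pair) is not implemented.
- Per-pixel sliding-window NGTDM/NGLDM at large windows is memory-bound
  (the vectorized implementation materializes per-window level histograms).
- Texture is strictly 2-D; no volumetric operators, Gabor or wavelet
  features.
- Increments saturate early on stationary batches when the base learner is
  strong (see above); the ensemble's benefit shows across batches, not
  within one.
- One-class SVM cleaning is sensitive to γ and ν at small sample sizes;
  very small ν (≤10⁻³) is numerically unreliable in libsvm and should be
  avoided.
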