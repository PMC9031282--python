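# Methods

This note documents the models, numerical choices and deliberate
simplifications behind `ramancellmap`, in the order data flows through the
pipeline.

## Synthetic measurement model

The generator (`ramancellmap.synthdata`) emulates fast confocal Raman
mapping of living cells in PBS buffer.  An observed spectrum is

```
observed(ν) = Σ_c a_c · s_c(ν) + b(ν) + ε(ν) + spikes(ν)
```

with components *c* ∈ {nucleic-acid, protein, lipid, pbs-buffer}:

* **Component spectra** `s_c` are sums of Lorentzian bands, the usual
  condensed-phase Raman line shape, with default FWHM 12 cm⁻¹ (typical of
  cellular bands at this resolution) and positions/assignments following
  the conventional mammalian-cell band table (749 nucleic acids/Trp, 1003
  phenylalanine, 1126 cytochrome C, 1340 amide III, 1451 lipid CH₂, 1580
  adenine/guanine, plus buffer bands at 634, 808, 916 cm⁻¹).  The default
  axis is 466–1667 cm⁻¹ in 1022 even steps, matching the emulated
  grating/detector configuration.
* **Abundances** `a_c` are lognormal per spectrum (or per pixel):
  CV 0.15 for cell components — the between-cell biological variability —
  and CV 0.05 for the buffer, which is homogeneous.
* **Fluorescence baseline** `b` is a random degree-5 polynomial,
  positivity-enforced, with mean amplitude 8× the unit band height and
  both its shape coefficients and amplitude jittered per spectrum by 30%
  ("spot-varying" background).
* **Noise** `ε` is additive white Gaussian with σ = 0.35 in unit-peak
  units; **cosmic spikes** arrive as a Poisson process (0.1 per spectrum),
  1–2 channels wide, amplitudes uniform in [10σ, 50σ].
* **Class effect**: the cancer-like class (`cell-A`) multiplies the
  amplitudes of the 749/1003/1126/1340/1451 cm⁻¹ bands by 0.55; the 1580
  cm⁻¹ band is unaffected.  The healthy-like class (`cell-B`) is
  unmodified.

### How the preset was fixed

The noise and effect levels are phenomenological: no quantitative noise
floor or effect magnitude is available to fit, so the preset is defined by
the two regimes it must reproduce and was calibrated once to them, then
frozen.  (i) *Masked bands*: on raw spectra, locating 749/1003/1451 by
argmax within ±25 cm⁻¹ succeeds for fewer than 90% of spectra (measured:
5–31%), i.e. naive peak picking fails before processing.  (ii) *Strong
but imperfect class separation*: after the full pipeline, 15-PC features
support ≥ 90% test accuracy for every standard classifier family, the
regime reported for real melanoma-vs-myoblast discrimination.  Under the
preset the per-component log-intensity separation is |ln 0.55|/0.15 ≈ 4
standard deviations spread over three partially informative components,
which lands in that regime while leaving a few percent of irreducible
error.

What the generator deliberately omits: optical physics (confocal PSF,
grating response), photobleaching and heating kinetics, wavelength
miscalibration, within-cell organelle structure (cell pixels are
homogeneous up to lognormal jitter), and non-Gaussian detector noise.
Passing tests therefore demonstrate correctness of the *algorithms* under
a realistic contamination model, not instrument-level fidelity.

Scenes place non-overlapping rotated ellipses by rejection sampling
(≤ 500 attempts per cell, then a diagnostic failure): elongated cells
have axis ratio ≥ 3, round cells ≤ 1.3, alternating.

## Purification

* **Despiking** uses a running-median (window 7) detector: a channel is
  flagged when |x − median| exceeds 8 × the MAD-based scale of its own
  spectrum's deviations.  Two refinements keep it a *cosmic-ray* detector:
  contiguous flagged runs wider than 2 channels are left untouched (sharp
  genuine bands on coarse grids would otherwise be clipped on noiseless
  spectra), and the half-window edge channels are never flagged (the
  reflected median is biased there).  Flagged channels are replaced by the
  local median.
* **Baseline correction** is the modified-polyfit iteration: fit a
  degree-9 polynomial, clip the fit target to `min(target, fit)`, refit;
  stop when the maximum absolute change between successive fits, divided
  by the spectrum's maximum magnitude, is below 10⁻³, or after 100
  iterations (defaults as published for this workflow).  The fit runs on
  the channel grid affinely mapped to [−1, 1]; degree 9 on raw
  wavenumbers is numerically ill-conditioned, and the mapping is
  invisible in the output.  All spectra of a matrix are fitted
  simultaneously (one pseudoinverse, vectorized clipping).  Negative
  residuals after subtraction are *kept*: clipping them would bias band
  integrals upward.  On noisy spectra the converged baseline tracks the
  lower noise envelope, leaving a small positive offset in the corrected
  spectra; band quantities are therefore measured relative to local
  background where it matters.
* **Normalization** divides each spectrum by the trapezoidal integral of
  the 910–920 cm⁻¹ buffer band (closed window, channels inside it).  It
  is idempotent and scale-invariant; a non-positive integral raises a
  dedicated error because it signals a spectrum with no buffer signal.
  Order of operations is despike → baseline → normalize → (optionally)
  denoise; the normalization stage can be disabled per call.

## PCA denoising and rank selection

`fit_pca` is a centered (not variance-scaled — channels share units) full
SVD decomposition; loadings are orthonormal, explained variance
non-increasing.  `reconstruct(model, k)` returns the rank-k reconstruction
and the discarded "noise spectra" (the two add back to the input exactly).
k = 0 (mean only) is allowed as a degenerate case.

**Elbow rule.**  The automatic rank is the knee of the *cumulative*
explained-variance curve: the index maximizing its height above the chord
joining the curve's endpoints, which is equivalently the last component
whose variance fraction exceeds the chord slope (the mean variance of the
remaining components), ties broken toward the larger index with a 10⁻⁹
relative tolerance.  On a scree with a flat noise floor this selects
exactly the last signal component — a rule defined on the decreasing
scree itself peaks one later, at the first noise component.  The rule
needs the full variance sequence; on matrices with aspect ratio near 1
and weak signal the scree has no knee and the rule degrades gracefully
but meaninglessly, so a manual override (`k=...`) preserves the
pick-by-inspection workflow throughout the API and CLI.

**Comparator smoothers.**  Kernel smoothing is Gaussian-weighted local
averaging; "bandwidth 10" uses the quartile-bandwidth convention (kernel
quartiles at ±0.25·bandwidth, i.e. sd ≈ 0.371 bandwidths) with bandwidth
in channels, since the original unit is unstated.  Savitzky–Golay uses
length 51 / order 4 / derivative 0.  Both reflect-pad the spectrum ends,
which changes endpoint values and is stated here for that reason.
`peak_fidelity` quantifies what a processing step does to each band:
argmax shift within ±25 cm⁻¹ of the nominal center, height ratio at the
true peak channel, and residual-SD-based SNR gain when a raw reference is
supplied.

## Imaging

Band maps take the per-pixel peak height (default) or trapezoidal
integral within center ± 8 cm⁻¹ (single nominal wavenumbers are published
for the bands; the window width is this package's choice).  Values can be
negative after baseline correction and are not clipped.  Otsu
backgrounding is guarded by the normalized between-class variance η at
the chosen threshold: below η = 0.8 the map is treated as unimodal
(all background) instead of speckling the noise floor — pure Gaussian
noise gives η ≈ 0.64, well-separated cells ≥ 0.9.  The quantile rule is
provided as the affine-invariant alternative.  Merged RGB images scale
all three channels by one min-max computed over foreground pixels, so
colors encode *relative* band intensity (per-channel scaling would
stretch near-zero maps to full brightness); background is black, order
R = nucleic acids, G = proteins, B = lipids.

## Semi-quantification

Band intensity is the peak height (or integral) in the same ±8 cm⁻¹
window on purified, denoised spectra.  Group comparison is one-way
fixed-effects ANOVA; with two groups F equals the squared pooled-variance
t statistic.  Zero within-group variance is reported as F = ∞ (p = 0)
when means differ and as a "degenerate" verdict when they do not.
Significance tiers: ns > 0.05 ≥ * > 0.01 ≥ ** > 0.001 ≥ *** > 0.0001 ≥
****.  No multiple-testing correction is applied across bands by default,
matching how such panels are conventionally reported; a Bonferroni
option exists.  Group SDs use ddof = 1, with SD ≡ 0 for singleton groups.

## Classification protocol

Features are the first 15 PC scores (reusing the denoising decomposition)
or a 2-D t-SNE embedding (perplexity 30 unless set; must be < (n−1)/3).
Reduction is fitted on the full labeled dataset *before* splitting,
replicating the published order of operations; the leakage this implies
is deliberate and documented, and a fit-on-training-only mode exists for
PCA (the t-SNE backend has no out-of-sample transform).

The split draws `round-half-up(n × 0.75)` training rows — the only
rounding consistent with 2530 → 1898/632.  (The published description
also mentions 2539 observations, which is inconsistent with its own
1650 + 880 = 2530 = 1898 + 632 arithmetic; this package follows the
consistent 2530 figure.)  An optional stratified mode preserves class
proportions to within one observation per class.  No resampling is done
for class imbalance.

Each family is tuned by 10-fold × 5-repeat stratified CV over a small
grid (the original grids are unpublished): SVM-RBF C ∈ {1,10,100} ×
γ ∈ {scale, 0.1, 0.01}; SVM-linear C ∈ {0.1,1,10}; random forest 200
trees, max_features ∈ {√p, 0.5}; QDA regularization ∈ {0, 10⁻³}; PLS-DA
components ∈ {2,4,8}; k-NN k ∈ {3,5,7,9}; "nnet" is a single hidden
layer ∈ {3,5,8} with weight decay 10⁻³ (mirroring the classic
single-layer-with-decay family); "mlp" is a two-layer perceptron
∈ {(10,5), (8,4)}; LDA and Gaussian NB have no grid.  Distance- and
gradient-based families are wrapped with feature standardization.
PLS-DA regresses one-hot class indicators and predicts the argmax
column.  Metrics use the cancer-like class as positive:
accuracy = (TP+TN)/N, sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP).

## Pipeline and reproducibility

`run_pipeline` executes simulate → purify → denoise → image/stats/
classify from a validated `PipelineConfig` (YAML-loadable), derives every
stage's seed deterministically from one root seed
(`stage_seed(root, name) = (root·10007 + crc32(name)) mod 2³¹`), and
writes a manifest with the package version, resolved config, seeds and
SHA-256 of every artifact; reruns with the same config reproduce
identical hashes.  Misconfigurations (e.g. classification requested
without labeled simulation) fail before any computation.

## Problem sizes used in tests and the acceptance script

Unit tests run mostly on a 300-channel axis spanning the same range with
tens-to-hundreds of spectra; the denoising-dominance and imaging checks
reconstruct at the generator's known mixture rank (4) because the elbow
is undefined on near-square low-signal matrices (see above).  The
acceptance protocols use the full 1022-channel grid: the classifier
benchmark generates 1000 spectra per class, the planted-rank check a
1000 × 1022 matrix with 17 components and 5% noise, and the
band-recovery check 300 spectra per class on a 1 cm⁻¹-spaced grid
(466–1667, 1202 channels) so the nominal centers lie exactly on the
grid.  These sizes were chosen to make each protocol's expected behavior
unambiguous at desk scale.

## Known limitations

* The elbow rule is only meaningful when signal components stand clear of
  the noise floor; use the manual rank otherwise.
* The despiker will not repair spikes at the outermost 3 channels or
  spikes wider than 2 channels.
* Baseline correction leaves a noise-dependent positive offset
  (lower-envelope bias) in corrected spectra.
* t-SNE features cannot be produced for unseen spectra (no out-of-sample
  transform); classification with t-SNE therefore always uses the
  leaky fit-before-split protocol.
* The synthetic preset's effect sizes are phenomenological, not fitted
  to any measured dataset; absolute accuracies on real data will differ.
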