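# Methods

This note records the models, estimators, parameter choices and numerical
conventions behind `fibertex`, and what the synthetic benchmark does and
does not establish about real SHG tissue images.

## Synthetic fiber-image model

A field is a superposition of fiber centerlines drawn as correlated random
walks:

* **Orientation.** Fiber orientation is axial (a fiber at θ and at θ + π is
  the same fiber), so the initial tangent is drawn by sampling a von Mises
  law on doubled angles, 2θ ~ vM(2θ̄, κ), and halving back onto [0, π).
  κ = 0 is the uniform (isotropic) limit; larger κ concentrates fibers
  about the mean axis θ̄.  In the labeled-dataset generator θ̄ itself is
  uniform per crop — the orientation of a tissue section on the slide is
  arbitrary; only the concentration is class-specific.
* **Path.** The walk advances in one-pixel arc steps; each step perturbs
  the tangent angle by N(0, `wiggle_sigma`) (radians/step).  This makes
  chord/arc straightness a monotone function of `wiggle_sigma`, with
  straightness exactly 1 in the zero-noise limit.  Arc length and full
  width are lognormal; `length_mu`/`width_mu` are the medians in µm and the
  `*_sigma` parameters the standard deviations of the log.
* **Rendering.** Fibers composite additively in a density field with a
  Gaussian cross-section in true perpendicular distance to the centerline,
  truncated at ±1.5 σ with σ = width/3, so the stated width spans the
  rendered support.  The emitted intensity is a saturating response
  `1 − exp(−3·density)`, i.e. flat-topped fibers with a crisp edge whose
  visible width equals the drawn width.  This was chosen over unbounded
  additive Gaussian rendering because it makes three quantities mutually
  consistent that the analysis treats as one thing: the ground-truth
  coverage (noiseless signal above background), the Otsu-threshold packing
  coefficient, and the distance-transform fiber width.  With smooth
  unbounded profiles the Otsu threshold lands mid-profile and packing
  under-reads coverage by ~0.3; with the flat-top model packing reproduces
  coverage to well under 0.05 at moderate density.
* **Brightness structure.** Two optional multiplicative layers create the
  intensity heterogeneity of real tissue: per-fiber lognormal amplitudes
  (`amp_sigma`) and a smooth "mottle" field (`mottle_sigma`, correlation
  length one third of the field) standing in for tissue-scale brightness
  variation.  The mottle is deliberately band-limited below the spatial
  frequencies the spectral features examine.
* **Channels and noise.** The forward channel is the rendered signal scaled
  to `photon_budget_fwd` plus a flat background, Poisson sampled — photon
  counting, so per-pixel variance equals the mean (verified on background
  regions).  The backward channel shares the geometry and mottle but is
  additionally modulated by fine-scale speckle (contrast 0.15, correlation
  length ≈ 0.75 px) and scaled to the smaller `photon_budget_bwd`,
  emulating the weaker backward emission that reveals smaller, more
  disordered features.
* **Geometry.** Defaults follow the acquisition geometry the package
  targets: 512 × 512 px over 180 × 180 µm (0.352 µm/px), crops of
  128 px = 45 µm, stacks of ≤ 10 independent 2D sections (no 3D fiber
  continuity).

### Class presets

The four presets (`CLASS_PRESETS`) encode the qualitative remodeling
directions reported for HGSOC relative to distal normal stroma: denser
coverage, higher orientation concentration (κ 8 vs 0.6), straighter fibers
(wiggle 0.07 vs 0.22 rad/step), slightly thinner fibers (2.4 vs 3.2 µm),
brighter and more heterogeneous signal (larger photon budgets, amplitude
and mottle spread).  p53-signature and STIC presets sit roughly 20 % and
40 % of the way from normal to HGSOC.  The magnitudes are the package's own
choice, tuned once so that each of the expected between-class feature
trends (entropy ↑, correlation ↑, contrast ↓, alignment ↑ in both
channels, time constant ↑, straightness ↑ for HGSOC vs normal) is
reproduced with rank-sum p < 0.05 at 30 crops/class; real effect sizes for
the precursor classes are not quantitatively established anywhere, so no
attempt is made to match them.  Consequently the synthetic classes separate
far more cleanly than real tissue (near-perfect AUROCs at 30 crops/class,
versus ~0.6–0.7 reported on tissue), and passing classification benchmarks
here demonstrates the correctness of the pipeline, not clinical
performance.  Features the presets do not emulate at all: depth-dependent
attenuation, optical sectioning blur, polarization effects, coherent
inter-fiber interference, and within-stack correlation between sections.

## Feature definitions and conventions

* **Texture (per channel).** Intensities are linearly quantized to
  G = 64 levels over the crop's own [min, max] (64 rather than 256 keeps
  the co-occurrence matrix of a 128-px crop well occupied; configurable).
  Pair counting pools the four distance-1 offsets (0°, 45°, 90°, 135°),
  symmetric, removing the orientation dependence that would confound the
  spectral alignment feature; counting is delegated to
  `skimage.feature.graycomatrix` and verified against brute-force
  enumeration.  Features: ASM Σp², entropy −Σp·ln p (natural log,
  0·log 0 := 0), IDM Σp/(1+(i−j)²), contrast Σ(i−j)²p, correlation
  Σ(i−µᵢ)(j−µⱼ)p/σᵢσⱼ.  Correlation is undefined on a flat crop and is
  emitted as missing; records with any missing feature are excluded from
  model fitting with a logged warning.
* **Spectral (per channel).** Mean-subtracted, Hann-tapered squared-
  magnitude 2D FFT, DC centered.  The angular profile sums power per
  orientation bin (90 bins on [0, π), annulus from 2 bins to Nyquist);
  alignment is the circular order parameter on doubled angles,
  |ΣP·e^{2iθ}|/ΣP ∈ [0, 1] — chosen because the estimator is bounded,
  threshold-free and standard for axial data; recorded in output metadata
  as `alignment_op2`.  The radial profile is the mean power in unit-width
  radius bins (DC excluded); `P(r) = A·exp(−r/TC)` is fitted by nonlinear
  least squares in linear space (log-linear closed form for initialization
  only, so low-power high-frequency bins are not over-weighted).  The
  default fit range is bin 4 to 0.8 × Nyquist: mean subtraction removes
  only the exact DC term, and large-scale brightness variation (slide-scale
  gradients; the generator's mottle) leaks into the first few annuli
  through the window kernel strongly enough to flip the fitted TC, so
  bins 1–3 are excluded.  TC is reported in frequency-bin units with the
  cycles/µm-per-bin conversion stored alongside.  A decay-free profile
  drives TC to its bound and is flagged as a boundary fit.
* **Fiber morphometry (forward channel only).** The curvelet-based
  denoising of the reference fiber-extraction tool is replaced by
  difference-of-Gaussians band-pass enhancement (σ 1–10 px bracketing
  expected fiber half-widths): its role in this pipeline is fiber-scale
  band selection, and the substitution keeps the stage dependency-light and
  directly testable.  Tracing: Otsu threshold on the non-zero response →
  binary mask → Euclidean distance transform → skeletonization → branch
  decomposition at junction pixels → greedy linking of segment ends whose
  outward tangents are anti-parallel within 30° across gaps < 5 px (gaps
  re-interpolated so point spacing stays ≤ 2 px) → fibers shorter than
  20 px (≈ 7 µm) discarded.  Per-point radius is the distance-transform
  value on the path; width = 2 × mean radius; straightness = chord/arc;
  per-crop stats are unweighted means over fibers.  Tracing runs on the
  forward channel only (the backward channel is too photon-starved for
  reliable tracing); the packing coefficient — fraction of pixels strictly
  above the crop's Otsu threshold, 0 for an all-zero crop — is computed on
  both channels and also supplies the 70 % coverage gate.
* **Crops.** 0-based, row-major, half-open indexing; physical sizes
  converted with round-half-even; edge remainders discarded rather than
  padded (padding would bias texture and spectral statistics).  Forward and
  backward channels of one physical crop are paired by (stack, section,
  origin); a crop is used only if both channels exist.  One observation =
  one crop; crops from one stack are not pooled, a simplification that
  ignores within-stack correlation.

## Selection and classification

Forward stepwise discriminant analysis with classical semantics: at each
step every remaining candidate is scored by Wilks' Λ = det(W)/det(W+B) of
the augmented subset, converted to the partial
F = ((n−g−p)/(g−1))·(Λ_p/Λ_{p+1} − 1) on (g−1, n−g−p) df; the largest-F
candidate enters if its p-value ≤ α = 0.35 (significance-to-enter), and
selection stops otherwise.  Forward-only, no removal step; ties break
lexicographically by feature name for reproducibility; candidates with
singular total scatter are skipped with a warning.  Under a global null the
probability that nothing enters is (1−α)^m for m candidates, which the
tests verify by simulation.

The classifier is LDA with a pooled within-class covariance Σ = W/(n−g)
applied through its SVD with singular values below 10⁻⁸ × the largest
truncated (pseudo-inverse behavior on near-singular problems), priors
proportional to class sizes, and discriminant scores
δ_k = xᵀΣ⁻¹µ_k − ½µ_kᵀΣ⁻¹µ_k + ln π_k with softmax posteriors.  Features
are z-scored inside the estimator (they span counts, µm and unitless
scales), which also makes predictions invariant to affine rescaling of any
feature.  Canonical variables are the eigenvectors of W⁻¹B, computed by
whitening W and solving a symmetric eigenproblem; projections are centered
on the grand mean, and per-class 95 % confidence ellipses use the χ²₂
quantile.  With two classes there is a single canonical axis; the second
plot coordinate is zero-filled with a notice.

Both stages are scikit-learn estimators and are cross-validated as a
pipeline.  Evaluation is one-vs-rest: stratified five-fold CV, the full
pipeline refit in every training fold (selection inside CV by default; an
`outside` mode selects once globally, mirroring analyses that report a
single selected-feature set, at the cost of selection leakage), held-out
positive-class posteriors pooled into a single ROC per class, AUROC by
trapezoid.  F1 is the harmonic mean of precision TP/(TP+FP) and recall
TP/(TP+FN), reported on the 0–100 scale, 0 by convention when TP = 0;
accuracy is (TP+TN)/n of the binarized problem.  Classes too small to
stratify k folds degrade to fit-only (resubstitution) metrics with an
explicit caveat.  The aggregated model relabels both precursor classes as
one group and reruns the identical binary pipeline.

## Problem sizes and numerical conventions

The synthetic study runs at 30 crops/class (128-px crops), five folds, and
the package's default parameters; oracle and recovery checks use 10–50
seeds per property and permutation tests 39–59 permutations — sizes at
which every stochastic acceptance margin was comfortably stable across
re-seeding.  Determinism: every stochastic routine takes a seed or a
`numpy` Generator; the dataset generator is bit-reproducible for a given
seed.  Degenerate inputs follow one rule: analysis functions raise on
contract violations (non-square crop, oversized offset, singular scatter),
while the featurization path converts per-crop degeneracies (flat crop, no
fibers) into flagged missing values so one bad crop cannot abort a run.

## Known limitations

* The synthetic generator validates the measurement chain, not biology;
  preset effect sizes are directional only (see above).
* The fiber tracer is a skeleton-based stand-in for curvelet + FIRE
  tracing: it reports the same three morphometrics but is not a
  re-implementation, and heavily overlapping mats (coverage ≳ 0.9) fragment
  into shorter fibers, biasing length downward there.
* TC units are frequency bins of the crop size; comparisons are only valid
  between equal-sized crops (the pipeline enforces a single crop size).
* With α = 0.35 and 21 features, null entries are common by design
  (significance-to-enter is deliberately permissive); the selected set
  should be read as a ranking, not as a set of individually significant
  features.
* p53-signature-sized classes (n ≈ 6) cannot support stratified five-fold
  ROC; the suite degrades to fit-only metrics for them, and the aggregated
  precursor model is the recommended readout in that regime.
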