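# Methods

## Measure definition and preprocessing

The analysis operates on a normalized mass distribution derived from a 2D
slice. The default measure is the *binary mask*: after contrast stretching
(percentiles 1–99 by default, optional histogram equalization and integer
bicubic upsampling) the image is thresholded — Otsu on a 256-bin histogram
by default, or a fixed threshold in [0, 1] — and each foreground pixel
receives mass `1/n`. Foreground is strictly above the threshold, so
threshold ties deterministically go to background. An intensity-weighted
measure (`measure_from_gray`) is available for users who prefer analyzing
grayscale texture directly; the staging pipeline binarizes because the
apparent-area feature requires a mask anyway.

The apparent area is defined operationally as foreground pixel count ×
`pixel_spacing²`. No physical spacing is assumed (default 1.0, so areas are
in pixel² units); supplying a spacing in mm yields mm². No connected-
component cleanup is applied by default; a largest-component filter exists
but is off, since the staging signal partly lives in disconnected fragments.

## Box-counting estimator

* **Scales.** Dyadic box sides `r ∈ {2, 4, …, min(H, W)/4}`, grid anchored
  at the top-left corner, bottom/right zero-padded to multiples of `r`.
  Zero-mass padding provably changes no moment sum, so the estimate is
  translation-insensitive up to grid alignment. Grid-offset averaging is
  not performed: it would smooth single-image estimates but changes the
  estimator's meaning; all defaults favor the simplest reproducible rule.
* **Moments.** For each scale, occupied-box probabilities with boxes below
  `1e-12` mass treated as empty — required for finite negative-q moments.
  `ln Σ P^q` is computed by `logsumexp` on `q·ln P` for stability at large
  `|q|`; the q = 1 column stores the Shannon sum `Σ P ln P` instead.
* **Fits.** `D_q` is the OLS slope of `ln Σ P^q` on `ln r` divided by
  `(q−1)`; at q = 1 the entropy sum's slope is `D_1` directly. Per-q `R²`
  is reported and a warning fires when any fit drops below 0.98 (masks with
  rough boundaries routinely trigger it; the warning flags a limited
  scaling range, not an error). At least 3 scales are required; an optional
  fit window restricts the ladder.
* **q grid.** Default −5…+5 in steps of 0.25. The grid must contain
  {0, 1, 2} exactly so `D_0/D_1/D_2` are table lookups, and must be uniform
  for the finite-difference Legendre transform (central differences
  interior, one-sided ends). `α_min`/`α_max` are extrema over the *finite*
  grid and therefore depend on its range; they are reported as such.
* **Identities.** `τ(q) = (q−1)D_q` makes `τ(1) = 0` exact and
  `f(α(0)) = D_0` exact (`f = −τ` at q = 0), both asserted in tests. On
  deterministic dyadic cascades the whole chain is exact to machine
  precision because the log-moments are perfectly linear in `ln r`.

A degenerate case worth knowing: for binary-mask measures the negative-q
branch is governed by minimal-mass boxes (single foreground pixels), whose
mass does not scale with `r`. Irregular boundaries therefore drag `α` at
very negative q toward 0 and broaden the spectrum — this is precisely the
mechanism by which boundary irregularity raises the width feature, but it
also means width values are estimator conventions, not intrinsic Hölder
exponents of a continuum measure.

## Feature vector

Ten features in fixed serialization order: `D1, D2, alpha0, alpha_min,
f_alpha_min, alpha_max, f_alpha_max, width, shift, area`. The symmetrical
shift has no universally agreed formula; it is defined here as
`|α_0 − (α_min+α_max)/2|`, the offset of the apex from the midpoint of the
spectrum support, which reproduces the worked value for a spectrum with
endpoints 1.673/2.66 and apex 1.78 (shift 0.3865). When several grid points
tie for an α extremum, the one with larger `|q|` is used for the `f` value.

## KNN classifier

Training stores the z-scored feature matrix (mean/SD fitted on the training
split only). Standardization is essential: the area feature is two orders
of magnitude larger than the spectrum-shape features and would otherwise
dominate Euclidean distances. Defaults: k = 5, Euclidean distance. k is
conventionally odd but not enforced; both tie rules are deterministic —
equal distances resolve by training-row order (stable sort), vote ties by
the class of the nearest neighbor among the tied classes. Evaluation draws,
per class, a seeded random split (defaults 100 train / 40 test for the
four-stage scheme; 80/20 for the three-stage scheme) and averages metrics
over 7 runs.

## Synthetic data

* **Cascades** subdivide mass recursively into quadrants by four fixed
  weights; `D_q = log2(Σ p^q)/(1−q)`, `α = −Σ p^q log2 p / Σ p^q` in closed
  form. The shuffled variant permutes quadrant assignment per cell with a
  seeded generator; moment sums are permutation-invariant, so the closed
  form still applies.
* **Phantoms** are schematic, not anatomical: a noisy bright disk on a dark
  background with punched-out elliptical gaps. Stage progression (4 stages)
  shrinks the disk radius fraction 0.42 → 0.36, raises the gap count
  0 → 45 with growing log-normal sizes, and raises a random-harmonic
  boundary-roughness amplitude 0 → 0.07 (harmonics 3–26). The roughness
  term exists because gap count alone does not move the spectrum width
  monotonically — the negative-q branch responds to boundary fragmentation,
  not to removed interior area. With this profile, stage means over 10
  seeds are strictly monotone (area ↓, width ↑).
* **Feature tables** draw each feature independently from per-stage
  Gaussians using the packaged `table2_parameters.csv` (both the four-stage
  and the three-stage label schemes). Feature *correlations* are not
  modeled — the source statistics are marginal means and SDs only — so the
  sampler likely overstates class separability relative to real images; a
  passing classifier benchmark on these tables demonstrates the protocol
  and the published effect sizes, not real-MRI performance.

What the phantoms do not emulate: anatomy, bias fields, partial-volume
effects, acquisition noise spectra, or 3D structure. Passing tests
demonstrate correct estimators and direction-of-effect under controlled
geometry, not clinical validity.

## Problem sizes

Default verification sizes were chosen to keep every check analytic-scale:
cascades at depth 7 (128×128), phantoms at 256×256 with 10 seeds per stage,
classifier tables at 140 rows per stage. All are the package's standard
demonstration sizes; estimates converge with depth/size and the tolerances
in the tests reflect the chosen sizes.

## Known limitations

* Spectrum endpoints depend on the q-grid range; comparisons are only valid
  at a fixed grid.
* The binary-mask measure makes width partly a boundary-digitization
  statistic (see above); grayscale measures behave differently.
* The Hartley-style variance-homogeneity p-value uses a plain
  `F(n_max−1, n_min−1)` upper-tail approximation that ignores selection of
  the extreme variances over k groups; use the provided Levene alternative
  when that matters.
* Per-stage feature Gaussians are independent and unimodal; real feature
  distributions are neither.
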