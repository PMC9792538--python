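# mfbrain

Multifractal-geometry staging of 2D brain-section images.

Brain atrophy in Alzheimer's disease changes the geometry of a section
image: the apparent tissue area shrinks, cerebrospinal-fluid gaps multiply,
and the tissue boundary grows irregular. A single fractal dimension cannot
summarize such heterogeneous structure; a *spectrum* of dimensions can.
`mfbrain` estimates that spectrum for a binarized brain slice by
box-counting, reduces it to ten shape features, and stages images with a
from-scratch K-Nearest-Neighbor classifier — aimed at researchers in
quantitative neuroimaging and medical image analysis who want a transparent,
fully testable alternative to black-box staging models.

## The method

For a normalized mass distribution covered by boxes of side `r` with box
probabilities `P_i(r)`, the generalized dimension of moment order `q` is

    D_q = 1/(q-1) · lim_{r→0} ln Σ_i P_i(r)^q / ln r        (q ≠ 1)
    D_1 =          lim_{r→0} Σ_i P_i(r) ln P_i(r) / ln r

estimated here as ordinary least-squares slopes over a dyadic scale ladder.
`D_0` is the capacity (box-counting) dimension, `D_1` the information
dimension, `D_2` the correlation dimension; `D_0 > D_1 > D_2` signals
multifractality. The mass exponent `τ(q) = (q−1) D_q` is Legendre-transformed
to the singularity spectrum

    α(q) = dτ/dq,     f(α) = q·α(q) − τ(q)

via central finite differences. Ten features summarize the result: `D_1`,
`D_2`, `α_0` (the apex exponent at q = 0), the endpoints `α_min`/`α_max`
with their `f` values, the width `W = α_max − α_min`, the symmetrical shift
`|α_0 − (α_min+α_max)/2|`, and the apparent section area `A`. A broader,
right-shifted spectrum with smaller `D_1`, `D_2` and `A` marks advancing
atrophy. Staging is a k = 5 Euclidean KNN on z-scored features, evaluated
by repeated seeded per-class splits with sensitivity / specificity /
precision / accuracy and one-vs-rest ROC/AUC.

All verification runs on synthetic inputs with known answers: quadrant
multiplicative cascades (closed-form `D_q` and `f(α)`), stage-parameterized
brain phantoms, and Gaussian feature tables at published per-stage effect
sizes. No image dataset is downloaded.

## Worked example

```sh
python examples/01_cascade_spectrum.py
```

prints (exact values; the deterministic cascade is dyadic-exact):

```
D0 = 2.0000  (exact 2.0: every quadrant carries mass)
D1 = 1.8464  (closed form 1.8464)
D2 = 1.7370  (closed form 1.7370)
max |D_q - closed form| over q in [-3,3]: 2.00e-15
alpha range: [1.545, 3.121] (broad range = multifractal; a uniform measure would give width ~0)
```

`D1 < D0` and `D2 < D1` confirm the cascade is multifractal, and the
estimator reproduces the analytic `log2(Σ p_i^q)/(1−q)` to machine
precision. The other examples stage phantoms (`02`), classify synthetic
feature tables (`03` — mean accuracy 99.57% over 7 runs), and screen feature
significance (`04`). A thin CLI mirrors the library:

```sh
mfbrain simulate phantom --outdir scratch/phantoms
mfbrain extract scratch/phantoms --label very_mild --out scratch/features.csv
mfbrain simulate features --outdir scratch/sim
mfbrain evaluate scratch/sim/features.csv --outdir scratch/metrics
```

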