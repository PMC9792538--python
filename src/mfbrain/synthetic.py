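"""Synthetic inputs with known ground truth.

Three generators back the test bench:

* **Multiplicative cascades** — recursive quadrant subdivision of mass by
  four fixed weights. These have closed-form generalized dimensions
  D_q = log2(sum p_i^q)/(1 - q) and an analytic singularity spectrum, so
  they serve as the exact oracle for the box-counting estimators.
* **Stage phantoms** — bright disks with stage-dependent shrinkage and
  punched-out elliptical gaps, emulating the atrophy progression of brain
  sections: foreground area falls and structural heterogeneity (hence
  spectrum width) rises with stage. The geometry is deliberately schematic,
  not anatomical.
* **Gaussian feature tables** — per-stage feature vectors drawn from the
  packaged stage-wise mean/SD fixture, for exercising the classifier and
  statistics modules at realistic effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES
from .image_prep import GrayImage
from .knn import STAGE_SCHEMES, LabeledDataset
from .multifractal import MeasureGrid

__all__ = [
    "CascadeSpec",
    "cascade_measure",
    "cascade_closed_form",
    "PhantomStage",
    "KAGGLE_PHANTOM_PROFILE",
    "brain_phantom",
    "load_table2_parameters",
    "sample_feature_table",
]

_MAX_GRID_SIDE = 4096


@dataclass(frozen=True)
class CascadeSpec:
    """Four quadrant weights (summing to 1), recursion depth, shuffle flag."""

    weights: tuple[float, float, float, float]
    depth: int
    shuffle: bool = False

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (4,) or (w < 0).any():
            raise ValueError("weights must be 4 nonnegative numbers")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1, got {w.sum()!r}")
        if not (isinstance(self.depth, (int, np.integer)) and self.depth >= 1):
            raise ValueError("depth must be a positive integer")
        if 2**self.depth > _MAX_GRID_SIDE:
            raise ValueError(f"depth {self.depth} exceeds the {_MAX_GRID_SIDE}-pixel grid cap")

    @property
    def side(self) -> int:
        return 2**self.depth


def cascade_measure(spec: CascadeSpec, seed: int | None = None) -> MeasureGrid:
    """Generate the cascade measure on a 2^depth square grid.

    With ``shuffle=False`` the weight-to-quadrant assignment is fixed
    (row-major), giving the deterministic cascade whose moments match the
    closed form exactly at dyadic scales. With ``shuffle=True`` each
    subdivided cell receives an independent seeded permutation of the
    weights; moment sums are unchanged (they are permutation-invariant) but
    the spatial arrangement randomizes.
    """
    rng = np.random.default_rng(seed)
    w = np.asarray(spec.weights, dtype=float)
    m = np.ones((1, 1))
    for _ in range(spec.depth):
        s = m.shape[0]
        if spec.shuffle:
            blocks = rng.permuted(np.tile(w, (s * s, 1)), axis=1)
        else:
            blocks = np.tile(w, (s * s, 1))
        pattern = (
            blocks.reshape(s, s, 2, 2).transpose(0, 2, 1, 3).reshape(2 * s, 2 * s)
        )
        m = np.kron(m, np.ones((2, 2))) * pattern
    return MeasureGrid(m / m.sum())


def cascade_closed_form(weights, q_grid) -> pd.DataFrame:
    """Analytic D_q, tau, alpha, f for a quadrant cascade.

    D_q = log2(sum p^q)/(1-q), with the Shannon limit -sum p log2 p at q=1;
    tau = (q-1) D_q; alpha = -sum p^q log2 p / sum p^q; f = q*alpha - tau.
    Zero weights are excluded from all sums.
    """
    p = np.asarray(weights, dtype=float)
    if (p < 0).any():
        raise ValueError("weights must be nonnegative")
    p = p[p > 0]
    q = np.asarray(q_grid, dtype=float)
    log2p = np.log2(p)
    d_q = np.empty_like(q)
    alpha = np.empty_like(q)
    for i, qi in enumerate(q):
        pq = p**qi
        z = pq.sum()
        alpha[i] = -(pq @ log2p) / z
        if qi == 1.0:
            d_q[i] = -(p @ log2p)
        else:
            d_q[i] = np.log2(z) / (1.0 - qi)
    tau = (q - 1.0) * d_q
    f = q * alpha - tau
    return pd.DataFrame({"q": q, "D_q": d_q, "tau": tau, "alpha": alpha, "f": f})


@dataclass(frozen=True)
class PhantomStage:
    """Geometry of one disease stage: disk size, gaps, boundary roughness.

    ``rough_amp`` is the relative amplitude of a random-harmonic radial
    perturbation of the disk boundary (harmonics 3..3+n_harmonics). Boundary
    irregularity is what broadens the negative-q branch of the singularity
    spectrum of a binary mask, so it grows with stage alongside the gaps.
    """

    radius_frac: float  # disk radius as a fraction of image side
    n_gaps: int
    gap_mu: float  # log-normal location of gap semi-axis, pixels at size=256
    gap_sigma: float
    rough_amp: float = 0.0
    n_harmonics: int = 24
    noise: float = 0.04

    def __post_init__(self) -> None:
        if not 0 < self.radius_frac < 0.5:
            raise ValueError("radius_frac must lie in (0, 0.5)")
        if self.n_gaps < 0:
            raise ValueError("n_gaps must be nonnegative")
        if min(self.gap_sigma, self.rough_amp, self.noise) < 0:
            raise ValueError("gap_sigma, rough_amp and noise must be nonnegative")


# Stage progression: shrinking foreground disk, more and larger CSF-like
# gaps, and an increasingly irregular boundary, mirroring atrophy from the
# no-dementia through the moderate stage.
KAGGLE_PHANTOM_PROFILE: tuple[PhantomStage, ...] = (
    PhantomStage(radius_frac=0.42, n_gaps=0, gap_mu=0.0, gap_sigma=0.0, rough_amp=0.0),
    PhantomStage(radius_frac=0.40, n_gaps=12, gap_mu=1.0, gap_sigma=0.4, rough_amp=0.012),
    PhantomStage(radius_frac=0.38, n_gaps=25, gap_mu=1.25, gap_sigma=0.4, rough_amp=0.032),
    PhantomStage(radius_frac=0.36, n_gaps=45, gap_mu=1.5, gap_sigma=0.4, rough_amp=0.07),
)


def brain_phantom(
    stage: int,
    seed: int,
    size: int = 256,
    profile: tuple[PhantomStage, ...] = KAGGLE_PHANTOM_PROFILE,
) -> GrayImage:
    """Render one stage phantom: noisy bright disk with dark elliptical gaps.

    Foreground intensity ~0.8, background ~0.1; gap centers fall inside the
    disk, sizes are log-normal, orientations uniform. Fully determined by
    ``(stage, seed, size, profile)``.
    """
    if not 0 <= stage < len(profile):
        raise ValueError(f"stage must be in [0, {len(profile) - 1}]")
    p = profile[stage]
    rng = np.random.default_rng(seed)
    scale = size / 256.0
    radius = p.radius_frac * size
    yy, xx = np.mgrid[0:size, 0:size]
    cy = cx = size / 2.0
    img = np.full((size, size), 0.1)
    if p.rough_amp > 0 and p.n_harmonics > 0:
        theta = np.arctan2(yy - cy, xx - cx)
        amps = rng.normal(0.0, 1.0, p.n_harmonics)
        phases = rng.uniform(0.0, 2 * np.pi, p.n_harmonics)
        pert = np.zeros_like(theta)
        for k, (a, ph) in enumerate(zip(amps, phases), start=3):
            pert += a * np.cos(k * theta + ph)
        local_radius = radius * (1.0 + p.rough_amp * pert / np.sqrt(p.n_harmonics))
    else:
        local_radius = radius
    disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= local_radius**2
    img[disk] = 0.8

    gap_area = 0.0
    for _ in range(p.n_gaps):
        # Gap center uniform in the disk (rejection-free polar sampling).
        rho = radius * 0.85 * np.sqrt(rng.uniform())
        theta = rng.uniform(0, 2 * np.pi)
        gy, gx = cy + rho * np.sin(theta), cx + rho * np.cos(theta)
        a = rng.lognormal(p.gap_mu, p.gap_sigma) * scale
        b = a * rng.uniform(0.4, 1.0)
        phi = rng.uniform(0, np.pi)
        gap_area += np.pi * a * b
        cphi, sphi = np.cos(phi), np.sin(phi)
        u = (xx - gx) * cphi + (yy - gy) * sphi
        v = -(xx - gx) * sphi + (yy - gy) * cphi
        ellipse = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        img[ellipse & disk] = 0.1
    if gap_area > np.pi * radius**2:
        raise ValueError("total gap area exceeds the disk area; reduce gaps")

    if p.noise > 0:
        img = img + rng.normal(0.0, p.noise, img.shape)
    return GrayImage(np.clip(img, 0.0, 1.0))


def load_table2_parameters() -> pd.DataFrame:
    """The packaged per-scheme/stage/feature mean-SD fixture."""
    with resources.files("mfbrain.data").joinpath("table2_parameters.csv").open() as fh:
        df = pd.read_csv(fh)
    expected = {"scheme", "stage", "feature", "mean", "sd"}
    if set(df.columns) != expected:
        raise ValueError(f"fixture columns {set(df.columns)} != {expected}")
    return df


def sample_feature_table(
    scheme: str = "kaggle",
    n_per_stage: int = 140,
    seed: int = 0,
) -> LabeledDataset:
    """Draw independent per-stage Gaussian feature vectors from the fixture.

    Features are sampled independently (the fixture carries no correlation
    information); rows are grouped by stage in scheme order.
    """
    if scheme not in STAGE_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; options: {sorted(STAGE_SCHEMES)}")
    if n_per_stage < 1:
        raise ValueError("n_per_stage must be >= 1")
    params = load_table2_parameters()
    params = params[params["scheme"] == scheme].set_index(["stage", "feature"])
    rng = np.random.default_rng(seed)
    stages = STAGE_SCHEMES[scheme]
    blocks, labels = [], []
    for stage in stages:
        cols = []
        for feat in FEATURE_NAMES:
            mean, sd = params.loc[(stage, feat), ["mean", "sd"]]
            cols.append(rng.normal(float(mean), float(sd), n_per_stage))
        blocks.append(np.column_stack(cols))
        labels.extend([stage] * n_per_stage)
    return LabeledDataset(np.vstack(blocks), np.array(labels))
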