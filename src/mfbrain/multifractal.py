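"""Box-counting multifractal analysis of 2D measures.

The analysis follows the moment (partition-function) method. A normalized
mass distribution mu on a pixel grid is covered with boxes of side r; for
each moment order q the log moment sum

    ln I(q, r) = ln sum_i P_i(r)^q          (occupied boxes only)

scales linearly in ln r, and the generalized dimension is the fitted slope
divided by (q - 1):

    D_q = 1/(q-1) * d ln I(q, r) / d ln r        (q != 1)
    D_1 =           d [sum_i P_i ln P_i] / d ln r

D_0 is the capacity (box-counting) dimension, D_1 the information dimension
and D_2 the correlation dimension; D_0 > D_1 > D_2 signals multifractality.
The mass exponent tau(q) = (q - 1) D_q is Legendre-transformed to the
singularity spectrum: alpha(q) = d tau / d q (finite differences) and
f(alpha) = q * alpha - tau.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .image_prep import BinaryMask, GrayImage

__all__ = [
    "MeasureGrid",
    "ScaleTable",
    "GeneralizedSpectrum",
    "SingularitySpectrum",
    "measure_from_mask",
    "measure_from_gray",
    "default_q_grid",
    "default_scales",
    "box_partition",
    "generalized_dimensions",
    "mass_exponent",
    "legendre_spectrum",
    "analyze_measure",
    "spectrum_frame",
]

# Box masses below this are treated as empty; keeps negative-q moments finite.
_MASS_EPS = 1e-12


@dataclass(frozen=True)
class MeasureGrid:
    """A nonnegative 2D mass distribution normalized to total mass 1."""

    mass: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mass, dtype=float)
        if m.ndim != 2 or m.size == 0:
            raise ValueError(f"measure must be a non-empty 2D array, got {m.shape}")
        if (m < 0).any():
            raise ValueError("measure has negative mass")
        total = m.sum()
        if not np.isfinite(total) or total <= 0:
            raise ValueError("measure has no mass")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"measure mass must sum to 1, got {total!r}")
        # Remove residual float error so downstream sums are exactly on scale.
        object.__setattr__(self, "mass", m / total)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mass.shape


def measure_from_mask(mask: BinaryMask) -> MeasureGrid:
    """Uniform measure over the foreground: each foreground pixel carries 1/n."""
    mask.require_nonempty()
    return MeasureGrid(mask.pixels / mask.foreground_count)


def measure_from_gray(img: GrayImage) -> MeasureGrid:
    """Intensity-weighted measure: pixel mass proportional to intensity."""
    total = img.pixels.sum()
    if total <= 0:
        raise ValueError("image has zero total intensity")
    return MeasureGrid(img.pixels / total)


def default_q_grid(q_min: float = -5.0, q_max: float = 5.0, q_step: float = 0.25) -> np.ndarray:
    """Uniform moment-order grid; must bracket 0 and contain {0, 1, 2}."""
    n = int(round((q_max - q_min) / q_step)) + 1
    q = np.linspace(q_min, q_max, n)
    # Snap near-integers so D0/D1/D2 lookups are exact.
    q[np.isclose(q, np.round(q))] = np.round(q[np.isclose(q, np.round(q))])
    for needed in (0.0, 1.0, 2.0):
        if not np.any(q == needed):
            raise ValueError(f"q grid must contain {needed}")
    return q


def default_scales(shape: tuple[int, int]) -> list[int]:
    """Dyadic box sides 2, 4, ..., min(H, W)/4."""
    rmax = min(shape) // 4
    scales = []
    r = 2
    while r <= rmax:
        scales.append(r)
        r *= 2
    if len(scales) < 3:
        raise ValueError(f"grid of shape {shape} too small for a 3-scale dyadic fit")
    return scales


@dataclass(frozen=True)
class ScaleTable:
    """Per-scale box statistics.

    ``log_moments[i, j]`` holds ln sum P^q at scale ``scales[i]`` and moment
    ``q_grid[j]`` — except at q = 1, where the column stores the entropy sum
    sum P ln P (whose slope in ln r is D_1 directly). ``entropy_sum`` repeats
    that Shannon term for convenience and ``n_boxes`` counts occupied boxes.
    """

    scales: np.ndarray
    q_grid: np.ndarray
    log_moments: np.ndarray
    entropy_sum: np.ndarray
    n_boxes: np.ndarray


def _box_probabilities(mass: np.ndarray, r: int) -> np.ndarray:
    h, w = mass.shape
    ph = (-h) % r
    pw = (-w) % r
    if ph or pw:
        mass = np.pad(mass, ((0, ph), (0, pw)))
    hh, ww = mass.shape
    box = mass.reshape(hh // r, r, ww // r, r).sum(axis=(1, 3)).ravel()
    return box[box > _MASS_EPS]


def box_partition(
    measure: MeasureGrid,
    scales: list[int] | None = None,
    q_grid: np.ndarray | None = None,
) -> ScaleTable:
    """Cover the measure with top-left-anchored box grids and collect moments.

    The grid at each scale r is anchored at the top-left corner and padded
    with zero mass on the bottom/right so both sides are multiples of r.
    Empty boxes are excluded from every sum.
    """
    if scales is None:
        scales = default_scales(measure.shape)
    if q_grid is None:
        q_grid = default_q_grid()
    q_grid = np.asarray(q_grid, dtype=float)
    scales = [int(r) for r in scales]
    side = min(measure.shape)
    for r in scales:
        if r < 1 or r > side:
            raise ValueError(f"scale {r} outside [1, {side}]")

    n_r, n_q = len(scales), len(q_grid)
    log_moments = np.empty((n_r, n_q))
    entropy = np.empty(n_r)
    n_boxes = np.empty(n_r, dtype=int)
    for i, r in enumerate(scales):
        p = _box_probabilities(measure.mass, r)
        lnp = np.log(p)
        n_boxes[i] = p.size
        entropy[i] = float(p @ lnp)
        for j, q in enumerate(q_grid):
            if q == 1.0:
                log_moments[i, j] = entropy[i]
            else:
                log_moments[i, j] = logsumexp(q * lnp)
    return ScaleTable(
        scales=np.array(scales),
        q_grid=q_grid,
        log_moments=log_moments,
        entropy_sum=entropy,
        n_boxes=n_boxes,
    )


@dataclass(frozen=True)
class GeneralizedSpectrum:
    """D_q over a moment-order grid with per-q regression diagnostics."""

    q_grid: np.ndarray
    d_q: np.ndarray
    slope: np.ndarray
    intercept: np.ndarray
    r_squared: np.ndarray

    def _at(self, q: float) -> float:
        idx = np.flatnonzero(self.q_grid == q)
        if idx.size == 0:
            raise ValueError(f"q = {q} not on the grid")
        return float(self.d_q[idx[0]])

    @property
    def d0(self) -> float:
        """Capacity (box-counting) dimension."""
        return self._at(0.0)

    @property
    def d1(self) -> float:
        """Information dimension."""
        return self._at(1.0)

    @property
    def d2(self) -> float:
        """Correlation dimension."""
        return self._at(2.0)


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    if sxx <= 0:
        raise ValueError("degenerate regressor: scales give zero ln r variance")
    sxy = ((x - xm) * (y - ym)).sum()
    slope = sxy / sxx
    intercept = ym - slope * xm
    syy = ((y - ym) ** 2).sum()
    r2 = 1.0 if syy == 0 else min(1.0, max(0.0, (sxy * sxy) / (sxx * syy)))
    return slope, intercept, r2


def generalized_dimensions(
    table: ScaleTable,
    fit_range: tuple[float, float] | None = None,
    r2_warn: float = 0.98,
) -> GeneralizedSpectrum:
    """Fit ln-moment scaling over ln r and report D_q per moment order.

    For q != 1 the slope of ln sum P^q against ln r is divided by (q - 1);
    at q = 1 the entropy sum's slope is D_1 itself. ``fit_range`` restricts
    the scales used (inclusive bounds, in pixels); at least 3 must remain.
    """
    sel = np.ones(len(table.scales), dtype=bool)
    if fit_range is not None:
        lo, hi = fit_range
        sel = (table.scales >= lo) & (table.scales <= hi)
    if sel.sum() < 3:
        raise ValueError("need at least 3 scales inside the fit range")
    x = np.log(table.scales[sel].astype(float))

    n_q = len(table.q_grid)
    d_q = np.empty(n_q)
    slopes = np.empty(n_q)
    intercepts = np.empty(n_q)
    r2s = np.empty(n_q)
    for j, q in enumerate(table.q_grid):
        y = table.log_moments[sel, j]
        slope, intercept, r2 = _ols(x, y)
        d_q[j] = slope if q == 1.0 else slope / (q - 1.0)
        slopes[j], intercepts[j], r2s[j] = slope, intercept, r2
    spec = GeneralizedSpectrum(
        q_grid=table.q_grid.copy(),
        d_q=d_q,
        slope=slopes,
        intercept=intercepts,
        r_squared=r2s,
    )
    if (r2s < r2_warn).any():
        import warnings

        worst = float(r2s.min())
        warnings.warn(
            f"log-log fits below R^2 = {r2_warn} (worst {worst:.4f}); "
            "scaling range may be inadequate",
            stacklevel=2,
        )
    return spec


def mass_exponent(spec: GeneralizedSpectrum) -> np.ndarray:
    """Mass exponent tau(q) = (q - 1) D_q; tau(1) = 0 identically."""
    return (spec.q_grid - 1.0) * spec.d_q


@dataclass(frozen=True)
class SingularitySpectrum:
    """tau(q), the Hoelder exponent alpha(q), and f(alpha(q)) on one q grid."""

    q_grid: np.ndarray
    tau: np.ndarray
    alpha: np.ndarray
    f_alpha: np.ndarray


def legendre_spectrum(tau: np.ndarray, q_grid: np.ndarray) -> SingularitySpectrum:
    """Legendre transform of tau(q) by finite differences.

    alpha = d tau / d q uses central differences in the interior and
    one-sided differences at the ends; f(alpha) = q * alpha - tau. The grid
    must be uniformly spaced with at least 5 points.
    """
    q = np.asarray(q_grid, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if q.size < 5:
        raise ValueError("need at least 5 q points")
    dq = np.diff(q)
    if not np.allclose(dq, dq[0], rtol=1e-9, atol=1e-12):
        raise ValueError("q grid must be uniformly spaced")
    alpha = np.gradient(tau, q)
    f = q * alpha - tau
    return SingularitySpectrum(q_grid=q, tau=tau, alpha=alpha, f_alpha=f)


def analyze_measure(
    measure: MeasureGrid,
    q_grid: np.ndarray | None = None,
    scales: list[int] | None = None,
    fit_range: tuple[float, float] | None = None,
    r2_warn: float = 0.98,
) -> tuple[GeneralizedSpectrum, SingularitySpectrum]:
    """Full pipeline: box partition -> D_q fit -> Legendre spectrum."""
    table = box_partition(measure, scales=scales, q_grid=q_grid)
    gen = generalized_dimensions(table, fit_range=fit_range, r2_warn=r2_warn)
    sing = legendre_spectrum(mass_exponent(gen), gen.q_grid)
    return gen, sing


def spectrum_frame(gen: GeneralizedSpectrum, sing: SingularitySpectrum) -> pd.DataFrame:
    """Tabular export: columns q, D_q, R2, tau, alpha, f."""
    if not np.array_equal(gen.q_grid, sing.q_grid):
        raise ValueError("spectra do not share a q grid")
    return pd.DataFrame(
        {
            "q": gen.q_grid,
            "D_q": gen.d_q,
            "R2": gen.r_squared,
            "tau": sing.tau,
            "alpha": sing.alpha,
            "f": sing.f_alpha,
        }
    )
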