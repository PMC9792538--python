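"""Reduction of the two spectra plus the mask area to a 10-feature vector.

The ten features summarize brain-structure change across dementia stages:
D1 and D2 (information and correlation dimensions), alpha0 (the Hoelder
exponent at the spectrum apex, q = 0), the spectrum endpoints alpha_min /
alpha_max with their f values, the spectrum width W = alpha_max - alpha_min,
the symmetrical shift |alpha0 - (alpha_min + alpha_max)/2|, and the apparent
section area A. A broad, right-shifted spectrum with reduced D1/D2 and
shrinking A is the signature of advancing atrophy.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .multifractal import GeneralizedSpectrum, SingularitySpectrum

__all__ = ["FEATURE_NAMES", "FeatureVector", "extract_features", "features_to_frame"]

# Fixed serialization order for feature tables.
FEATURE_NAMES = [
    "D1",
    "D2",
    "alpha0",
    "alpha_min",
    "f_alpha_min",
    "alpha_max",
    "f_alpha_max",
    "width",
    "shift",
    "area",
]


@dataclass(frozen=True)
class FeatureVector:
    D1: float
    D2: float
    alpha0: float
    alpha_min: float
    f_alpha_min: float
    alpha_max: float
    f_alpha_max: float
    width: float
    shift: float
    area: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"feature {f.name} is not finite: {v!r}")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES])

    @classmethod
    def from_array(cls, values: np.ndarray) -> "FeatureVector":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(FEATURE_NAMES),):
            raise ValueError(f"expected {len(FEATURE_NAMES)} features, got {values.shape}")
        return cls(**dict(zip(FEATURE_NAMES, values)))


def _extreme_index(alpha: np.ndarray, q: np.ndarray, kind: str) -> int:
    # Ties between q points achieving the extremum go to the larger |q|.
    target = alpha.min() if kind == "min" else alpha.max()
    candidates = np.flatnonzero(alpha == target)
    return int(candidates[np.argmax(np.abs(q[candidates]))])


def extract_features(
    gen: GeneralizedSpectrum, sing: SingularitySpectrum, area: float
) -> FeatureVector:
    """Build the 10-feature vector from a fitted spectrum pair and area."""
    if not np.array_equal(gen.q_grid, sing.q_grid):
        raise ValueError("generalized and singularity spectra use different q grids")
    if not (np.isfinite(area) and area > 0):
        raise ValueError(f"area must be positive and finite, got {area!r}")
    if not (np.isfinite(sing.alpha).all() and np.isfinite(sing.f_alpha).all()):
        raise ValueError("singularity spectrum contains non-finite values")
    q = sing.q_grid
    i0 = np.flatnonzero(q == 0.0)
    if i0.size == 0:
        raise ValueError("q grid must contain q = 0")
    alpha0 = float(sing.alpha[i0[0]])
    imin = _extreme_index(sing.alpha, q, "min")
    imax = _extreme_index(sing.alpha, q, "max")
    alpha_min = float(sing.alpha[imin])
    alpha_max = float(sing.alpha[imax])
    return FeatureVector(
        D1=gen.d1,
        D2=gen.d2,
        alpha0=alpha0,
        alpha_min=alpha_min,
        f_alpha_min=float(sing.f_alpha[imin]),
        alpha_max=alpha_max,
        f_alpha_max=float(sing.f_alpha[imax]),
        width=alpha_max - alpha_min,
        shift=abs(alpha0 - 0.5 * (alpha_min + alpha_max)),
        area=float(area),
    )


def features_to_frame(
    rows: list[tuple[str, FeatureVector]] | list[tuple[str, FeatureVector, str]],
) -> pd.DataFrame:
    """Feature table: image_id, the 10 features in fixed order, optional stage."""
    records = []
    for row in rows:
        image_id, fv = row[0], row[1]
        rec = {"image_id": image_id, **dict(zip(FEATURE_NAMES, fv.to_array()))}
        if len(row) > 2:
            rec["stage"] = row[2]
        records.append(rec)
    return pd.DataFrame.from_records(records)
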