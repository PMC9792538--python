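"""Feature-significance statistics: one-way ANOVA, normality moments, and
variance homogeneity across disease stages.

These are the screening statistics used to show that each extracted feature
separates the stage groups (ANOVA F and p), that per-group distributions
are consistent with normality (skewness and excess kurtosis both inside
the +/-2 band), and that group variances are homogeneous (a max/min
variance F ratio against a critical value).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import FEATURE_NAMES

__all__ = [
    "validate_groups",
    "one_way_anova",
    "moments",
    "variance_homogeneity",
    "levene_homogeneity",
    "HomogeneityResult",
    "feature_significance_table",
]


def validate_groups(groups) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(gs):
        if g.ndim != 1 or g.size < 3:
            raise ValueError(f"group {i} must be 1D with n >= 3")
        if not np.isfinite(g).all():
            raise ValueError(f"group {i} contains non-finite values")
    return gs


def one_way_anova(groups) -> tuple[float, float]:
    """Classical between/within mean-square F with its F-distribution p."""
    gs = validate_groups(groups)
    pooled = np.concatenate(gs)
    if np.ptp(pooled) == 0:
        warnings.warn("all values identical: ANOVA F undefined", stacklevel=2)
        return float("nan"), float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = sps.f_oneway(*gs)
    return float(f), float(p)


def moments(values) -> tuple[float, float]:
    """Fisher skewness g1 and excess kurtosis g2 (normal -> 0, 0).

    Defined from the third and fourth standardized central moments, so the
    conventional +/-2 normality screening band applies directly.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise ValueError("need a 1D sample with n >= 4")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance sample: moments undefined")
    return float(sps.skew(x)), float(sps.kurtosis(x, fisher=True))


@dataclass(frozen=True)
class HomogeneityResult:
    ratio: float
    p_value: float
    homogeneous: bool | None  # None when no critical value was supplied


def variance_homogeneity(groups, critical: float | None = None) -> HomogeneityResult:
    """Hartley-style max/min variance ratio with an approximate F p-value.

    The p-value uses the plain F(n_max - 1, n_min - 1) upper tail as an
    approximation (it ignores the selection of extremes over k groups).
    When ``critical`` is given, ``homogeneous`` is the verdict ratio < critical.
    """
    gs = validate_groups(groups)
    variances = np.array([g.var(ddof=1) for g in gs])
    if variances.min() == 0:
        warnings.warn("a group has zero variance: ratio undefined", stacklevel=2)
        return HomogeneityResult(float("nan"), float("nan"), None)
    i_max = int(variances.argmax())
    i_min = int(variances.argmin())
    ratio = float(variances[i_max] / variances[i_min])
    p = float(sps.f.sf(ratio, gs[i_max].size - 1, gs[i_min].size - 1))
    verdict = None if critical is None else bool(ratio < critical)
    return HomogeneityResult(ratio=ratio, p_value=p, homogeneous=verdict)


def levene_homogeneity(groups) -> tuple[float, float]:
    """Levene's test (median-centered), the robust alternative."""
    gs = validate_groups(groups)
    stat, p = sps.levene(*gs, center="median")
    return float(stat), float(p)


def feature_significance_table(
    df: pd.DataFrame,
    label_col: str = "stage",
    critical: float | None = None,
) -> pd.DataFrame:
    """Per-feature stage statistics mirroring a stage-comparison table.

    One row per feature: per-stage mean and SD, ANOVA F and p, pooled
    skewness and excess kurtosis, and the homogeneity ratio with its p.
    """
    missing = [c for c in FEATURE_NAMES + [label_col] if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    stages = list(dict.fromkeys(df[label_col]))
    rows = []
    for feat in FEATURE_NAMES:
        groups = [df.loc[df[label_col] == s, feat].to_numpy(float) for s in stages]
        f, p = one_way_anova(groups)
        g1, g2 = moments(np.concatenate(groups))
        hom = variance_homogeneity(groups, critical=critical)
        rec: dict[str, object] = {"feature": feat}
        for s, g in zip(stages, groups):
            rec[f"mean_{s}"] = g.mean()
            rec[f"sd_{s}"] = g.std(ddof=1)
        rec.update(
            F=f,
            p_value=p,
            skewness=g1,
            kurtosis=g2,
            homogeneity_F=hom.ratio,
            homogeneity_p=hom.p_value,
        )
        rows.append(rec)
    return pd.DataFrame(rows)
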