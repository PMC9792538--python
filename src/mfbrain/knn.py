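"""From-scratch K-Nearest-Neighbor stage classifier.

The classifier stores z-score-standardized training feature vectors and
assigns a query the majority label of its k nearest (Euclidean) training
points. Standardization is fitted on the training split only; without it,
distances would be dominated by the apparent-area feature, whose scale is
two orders of magnitude above the spectrum-shape features.

Determinism rules: distance ties are broken by training-row order; vote
ties by the class of the nearest neighbor among the tied classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .features import FEATURE_NAMES

__all__ = [
    "LabeledDataset",
    "KnnModel",
    "fit",
    "predict",
    "predict_batch",
    "evaluate_split",
    "EvaluationResult",
    "save_model",
    "load_model",
]

KAGGLE_STAGES = ["no_dementia", "very_mild", "mild", "moderate"]
ADNI_STAGES = ["CN", "MCI", "AD"]
STAGE_SCHEMES = {"kaggle": KAGGLE_STAGES, "adni": ADNI_STAGES}

_MODEL_VERSION = "mfbrain-knn-1"


@dataclass(frozen=True)
class LabeledDataset:
    """Feature matrix (n rows, 10 columns in fixed order) with stage labels."""

    features: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.features, dtype=float)
        y = np.asarray(self.labels)
        if x.ndim != 2 or x.shape[1] != len(FEATURE_NAMES):
            raise ValueError(f"features must be (n, {len(FEATURE_NAMES)}), got {x.shape}")
        if y.shape != (x.shape[0],):
            raise ValueError("labels must align with feature rows")
        if x.shape[0] == 0:
            raise ValueError("dataset is empty")
        if not np.isfinite(x).all():
            raise ValueError("features contain non-finite values")
        object.__setattr__(self, "features", x)
        object.__setattr__(self, "labels", y.astype(str))

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def classes(self) -> list[str]:
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(lab, None)
        return list(seen)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label_col: str = "stage") -> "LabeledDataset":
        missing = [c for c in FEATURE_NAMES + [label_col] if c not in df.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")
        return cls(df[FEATURE_NAMES].to_numpy(float), df[label_col].to_numpy(str))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=FEATURE_NAMES)
        df["stage"] = self.labels
        return df


@dataclass(frozen=True)
class KnnModel:
    k: int
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    x_train: np.ndarray  # standardized
    y_train: np.ndarray
    classes: tuple[str, ...]


def fit(data: LabeledDataset, k: int = 5) -> KnnModel:
    """Store the standardized training set; KNN needs no iterative training."""
    if not (isinstance(k, (int, np.integer)) and k >= 1):
        raise ValueError(f"k must be a positive integer, got {k!r}")
    if k > data.n:
        raise ValueError(f"k = {k} exceeds the {data.n} training rows")
    mean = data.features.mean(axis=0)
    sd = data.features.std(axis=0, ddof=0)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        names = [FEATURE_NAMES[i] for i in flat]
        raise ValueError(f"zero-variance feature(s) in training data: {names}")
    x = (data.features - mean) / sd
    return KnnModel(
        k=int(k),
        feature_mean=mean,
        feature_sd=sd,
        x_train=x,
        y_train=data.labels.copy(),
        classes=tuple(sorted(set(data.labels))),
    )


def _vote(model: KnnModel, z: np.ndarray) -> tuple[str, dict[str, float]]:
    d = np.sqrt(((model.x_train - z) ** 2).sum(axis=1))
    # Stable sort keeps training-row order among exactly tied distances.
    order = np.argsort(d, kind="stable")[: model.k]
    neighbor_labels = model.y_train[order]
    counts: dict[str, int] = {}
    for lab in neighbor_labels:
        counts[lab] = counts.get(lab, 0) + 1
    top = max(counts.values())
    tied = {lab for lab, c in counts.items() if c == top}
    if len(tied) == 1:
        label = next(iter(tied))
    else:
        # Nearest neighbor whose class is among the tied classes decides.
        label = next(lab for lab in neighbor_labels if lab in tied)
    votes = {c: counts.get(c, 0) / model.k for c in model.classes}
    return label, votes


def predict(model: KnnModel, x: np.ndarray) -> tuple[str, dict[str, float]]:
    """Classify one raw feature vector; returns (label, vote fractions)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.x_train.shape[1],):
        raise ValueError(f"expected {model.x_train.shape[1]} features, got {x.shape}")
    if not np.isfinite(x).all():
        raise ValueError("feature vector contains non-finite values")
    z = (x - model.feature_mean) / model.feature_sd
    return _vote(model, z)


def predict_batch(model: KnnModel, x: np.ndarray) -> tuple[np.ndarray, pd.DataFrame]:
    """Classify rows of a raw feature matrix; vote fractions per class."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    labels = []
    votes = []
    for row in x:
        lab, v = predict(model, row)
        labels.append(lab)
        votes.append(v)
    return np.array(labels), pd.DataFrame(votes, columns=list(model.classes))


@dataclass(frozen=True)
class EvaluationResult:
    """Per-run and averaged split-evaluation metrics."""

    per_run: list[dict]
    mean_accuracy: float
    mean_sensitivity: dict[str, float]
    mean_specificity: dict[str, float]
    mean_precision: dict[str, float]


def evaluate_split(
    data: LabeledDataset,
    n_train_per_class: int,
    n_test_per_class: int,
    k: int = 5,
    n_runs: int = 7,
    seed: int = 0,
) -> EvaluationResult:
    """Repeated seeded per-class splits: fit on train, score on test, average.

    Each run draws, per class, a random permutation and takes the first
    ``n_train_per_class`` rows for training and the next ``n_test_per_class``
    for testing (no replacement). Reported metrics are per-run and averaged
    over runs.
    """
    rng = np.random.default_rng(seed)
    classes = data.classes
    by_class = {c: np.flatnonzero(data.labels == c) for c in classes}
    need = n_train_per_class + n_test_per_class
    for c, idx in by_class.items():
        if idx.size < need:
            raise ValueError(f"class {c!r} has {idx.size} rows, needs {need}")

    runs = []
    for _ in range(n_runs):
        train_idx, test_idx = [], []
        for c in classes:
            perm = rng.permutation(by_class[c])
            train_idx.append(perm[:n_train_per_class])
            test_idx.append(perm[n_train_per_class:need])
        tr = np.concatenate(train_idx)
        te = np.concatenate(test_idx)
        model = fit(LabeledDataset(data.features[tr], data.labels[tr]), k=k)
        pred, _votes = predict_batch(model, data.features[te])
        y_true = data.labels[te]
        _matrix, per_class = _metrics.confusion_matrix(y_true, pred, classes=classes)
        correct = {c: int(per_class[c].tp) for c in classes}
        tested = {c: int((y_true == c).sum()) for c in classes}
        reports = {c: _metrics.binary_metrics(per_class[c]) for c in classes}
        runs.append(
            {
                "accuracy": _metrics.overall_accuracy(
                    [correct[c] for c in classes], [tested[c] for c in classes]
                ),
                "sensitivity": {c: reports[c].sensitivity for c in classes},
                "specificity": {c: reports[c].specificity for c in classes},
                "precision": {c: reports[c].precision for c in classes},
            }
        )

    def _mean(metric: str) -> dict[str, float]:
        out = {}
        for c in classes:
            vals = [r[metric][c] for r in runs if r[metric][c] is not None]
            out[c] = float(np.mean(vals)) if vals else float("nan")
        return out

    return EvaluationResult(
        per_run=runs,
        mean_accuracy=float(np.mean([r["accuracy"] for r in runs])),
        mean_sensitivity=_mean("sensitivity"),
        mean_specificity=_mean("specificity"),
        mean_precision=_mean("precision"),
    )


def save_model(model: KnnModel, path: str | Path) -> None:
    """Persist the model as a delimited-text bundle with a version tag."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# {_MODEL_VERSION}\n")
        fh.write(f"k\t{model.k}\n")
        fh.write("classes\t" + "\t".join(model.classes) + "\n")
        fh.write("mean\t" + "\t".join(repr(float(v)) for v in model.feature_mean) + "\n")
        fh.write("sd\t" + "\t".join(repr(float(v)) for v in model.feature_sd) + "\n")
        for row, lab in zip(model.x_train, model.y_train):
            fh.write(str(lab) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def load_model(path: str | Path) -> KnnModel:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0] != f"# {_MODEL_VERSION}":
        raise ValueError(f"{path}: not a {_MODEL_VERSION} bundle")
    header: dict[str, list[str]] = {}
    rows, labels = [], []
    for line in lines[1:]:
        parts = line.split("\t")
        if parts[0] in ("k", "classes", "mean", "sd"):
            header[parts[0]] = parts[1:]
        else:
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    return KnnModel(
        k=int(header["k"][0]),
        feature_mean=np.array([float(v) for v in header["mean"]]),
        feature_sd=np.array([float(v) for v in header["sd"]]),
        x_train=np.array(rows),
        y_train=np.array(labels),
        classes=tuple(header["classes"]),
    )
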