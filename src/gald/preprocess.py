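"""Tabular I/O and preprocessing: deduplication and Min-Max scaling.

The detector consumes plain numeric CSV (header row, comma separated, one
object per row). An optional binary label column (1 = anomaly) is carried
alongside the feature matrix but is used only for evaluation — never during
fitting or scoring. Preprocessing follows the order: exact-duplicate removal
first, then per-feature Min-Max normalization to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "Dataset",
    "NormalizationParams",
    "read_table",
    "write_table",
    "write_scores",
    "deduplicate",
    "minmax_normalize",
]

DEFAULT_LABEL_COLUMN = "label"


@dataclass
class Dataset:
    """Numeric table of objects with optional binary anomaly labels.

    Attributes
    ----------
    X : ndarray of shape (n, d)
        Feature matrix, one row per object.
    y : ndarray of shape (n,) or None
        Binary labels, 1 = anomaly. Evaluation-only.
    feature_names : list of str
        Column names for X.
    """

    X: np.ndarray
    y: Optional[np.ndarray] = None
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional (objects x features)")
        if self.X.shape[0] < 1 or self.X.shape[1] < 1:
            raise ValueError("dataset needs at least one row and one column")
        if not np.isfinite(self.X).all():
            raise ValueError("X contains non-finite values")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=int)
            if self.y.shape != (self.X.shape[0],):
                raise ValueError("label vector length must match number of rows")
            if not np.isin(self.y, (0, 1)).all():
                raise ValueError("labels must be binary (0 = normal, 1 = anomaly)")
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(self.X.shape[1])]
        elif len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length must match number of columns")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]


@dataclass
class NormalizationParams:
    """Per-feature minimum and maximum recorded at fit time.

    Applying the stored parameters at score time guarantees unseen rows are
    scaled identically to the training data. Constant features (min == max)
    map to 0.
    """

    x_min: np.ndarray
    x_max: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.x_min = np.asarray(self.x_min, dtype=float)
        self.x_max = np.asarray(self.x_max, dtype=float)
        if self.x_min.shape != self.x_max.shape:
            raise ValueError("x_min and x_max must have the same shape")
        if np.any(self.x_min > self.x_max):
            raise ValueError("x_min must not exceed x_max")
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(self.x_min.size)]

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        span = self.x_max - self.x_min
        out = np.zeros_like(X)
        ok = span > 0
        out[:, ok] = (X[:, ok] - self.x_min[ok]) / span[ok]
        return out

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        span = self.x_max - self.x_min
        return X * span + self.x_min

    def to_file(self, path: str | Path) -> None:
        """Write one `name min max` line per feature (flat text)."""
        lines = [
            f"{name}\t{float(lo)!r}\t{float(hi)!r}"
            for name, lo, hi in zip(self.feature_names, self.x_min, self.x_max)
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "NormalizationParams":
        names, lows, highs = [], [], []
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            name, lo, hi = line.split("\t")
            names.append(name)
            lows.append(float(lo))
            highs.append(float(hi))
        return cls(np.array(lows), np.array(highs), names)


def read_table(path: str | Path, label_column: Optional[str] = DEFAULT_LABEL_COLUMN) -> Dataset:
    """Load a CSV into a :class:`Dataset`.

    Parameters
    ----------
    path : path to a comma-separated file with a header row.
    label_column : name of the binary label column to split off, or None to
        treat every column as a feature. A named column that is absent from
        the file is ignored (unlabeled data is the common case).

    Raises
    ------
    FileNotFoundError, ValueError
        Missing file; a non-numeric or missing cell; label values outside {0, 1}.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if df.shape[0] < 1:
        raise ValueError(f"{path}: no data rows")
    y = None
    if label_column is not None and label_column in df.columns:
        y_raw = pd.to_numeric(df[label_column], errors="coerce")
        if y_raw.isna().any() or not y_raw.isin((0, 1)).all():
            raise ValueError(f"{path}: label column {label_column!r} must be binary 0/1")
        y = y_raw.to_numpy(dtype=int)
        df = df.drop(columns=[label_column])
    feature_names = [str(c) for c in df.columns]
    X = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.isnan(X).any():
        bad = df.columns[np.isnan(X).any(axis=0)].tolist()
        raise ValueError(f"{path}: non-numeric or missing values in columns {bad}")
    if not np.isfinite(X).all():
        raise ValueError(f"{path}: non-finite values present")
    return Dataset(X=X, y=y, feature_names=feature_names)


def write_table(data: Dataset, path: str | Path, label_column: str = DEFAULT_LABEL_COLUMN) -> None:
    """Write a Dataset back to CSV (labels appended as `label_column` if present)."""
    df = pd.DataFrame(data.X, columns=data.feature_names)
    if data.y is not None:
        df[label_column] = data.y
    df.to_csv(path, index=False)


def write_scores(
    path: str | Path,
    anomaly_factors: np.ndarray,
    predicted: Optional[np.ndarray] = None,
) -> None:
    """Write per-object scores as CSV (row_index, anomaly_factor, predicted_label)."""
    af = np.asarray(anomaly_factors, dtype=float)
    df = pd.DataFrame({"row_index": np.arange(af.size), "anomaly_factor": af})
    if predicted is not None:
        df["predicted_label"] = np.asarray(predicted, dtype=int)
    df.to_csv(path, index=False)


def deduplicate(data: Dataset) -> Dataset:
    """Collapse exact duplicate rows to their first occurrence, preserving order.

    Rows are duplicates only if identical across every feature and (when
    present) the label.
    """
    if data.y is not None:
        key = np.column_stack([data.X, data.y.astype(float)])
    else:
        key = data.X
    _, first = np.unique(key, axis=0, return_index=True)
    keep = np.sort(first)
    return Dataset(
        X=data.X[keep],
        y=None if data.y is None else data.y[keep],
        feature_names=list(data.feature_names),
    )


def minmax_normalize(data: Dataset) -> tuple[Dataset, NormalizationParams]:
    """Rescale each feature to [0, 1] by its minimum and maximum.

    x' = (x - x_min) / (x_max - x_min), computed per feature over the full
    dataset. Constant features map to 0. Returns the scaled dataset and the
    parameters needed to apply the identical scaling to new rows.
    """
    params = NormalizationParams(
        x_min=data.X.min(axis=0),
        x_max=data.X.max(axis=0),
        feature_names=list(data.feature_names),
    )
    scaled = Dataset(
        X=params.transform(data.X),
        y=None if data.y is None else data.y.copy(),
        feature_names=list(data.feature_names),
    )
    return scaled, params
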