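"""Evaluation of scored runs against ground-truth labels.

Five quantities: AUC of the raw anomaly-factor ranking (Mann-Whitney
convention, ties get half credit), and from thresholded predictions the
accuracy, detection rate (recall on anomalies), false-alarm rate
(false-positive rate on normals) — all as percentages — plus wall-clock
time of the scored run. Counts and percentages are kept together so every
report is internally consistent by construction.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_auc_score

from gald.scoring import threshold_scores

__all__ = ["EvalReport", "auc", "confusion_metrics", "evaluate_run"]


@dataclass
class EvalReport:
    auc: float
    acc: float  # percent
    dr: float  # percent
    far: float  # percent
    tp: int
    fp: int
    tn: int
    fn: int
    threshold_rule: str = "contamination-quantile"
    elapsed_seconds: float = 0.0

    def __post_init__(self) -> None:
        n = self.tp + self.fp + self.tn + self.fn
        if n > 0:
            assert abs(self.acc - 100.0 * (self.tp + self.tn) / n) < 1e-9
        if self.tp + self.fn > 0:
            assert abs(self.dr - 100.0 * self.tp / (self.tp + self.fn)) < 1e-9
        if self.fp + self.tn > 0:
            assert abs(self.far - 100.0 * self.fp / (self.fp + self.tn)) < 1e-9

    def to_dict(self) -> dict:
        return asdict(self)

    def to_file(self, path: str | Path) -> None:
        """Flat key-value text, one metric per line."""
        lines = [f"{k}\t{v}" for k, v in self.to_dict().items()]
        Path(path).write_text("\n".join(lines) + "\n")

    def __str__(self) -> str:
        return (
            f"AUC={self.auc:.4f}  ACC={self.acc:.2f}%  DR={self.dr:.2f}%  "
            f"FAR={self.far:.2f}%  (tp={self.tp} fp={self.fp} tn={self.tn} fn={self.fn}, "
            f"{self.elapsed_seconds:.3f}s)"
        )


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    return labels


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve of the score ranking.

    Equals P(score_anomaly > score_normal) + 0.5 * P(tie) over all
    anomaly/normal pairs; requires both classes present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(labels)
    if labels.min() == labels.max():
        raise ValueError("AUC needs at least one normal and one anomaly label")
    return float(roc_auc_score(labels, scores))


def confusion_metrics(pred: np.ndarray, labels: np.ndarray) -> dict:
    """Accuracy, detection rate and false-alarm rate (percent) with raw counts."""
    pred = _check_labels(pred)
    labels = _check_labels(labels)
    if pred.shape != labels.shape:
        raise ValueError("prediction/label length mismatch")
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    n = labels.size
    return {
        "acc": 100.0 * (tp + tn) / n,
        "dr": 100.0 * tp / (tp + fn) if tp + fn else 0.0,
        "far": 100.0 * fp / (fp + tn) if fp + tn else 0.0,
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
    }


def evaluate_run(
    anomaly_factors: np.ndarray,
    labels: np.ndarray,
    contamination: float,
    elapsed_seconds: float | None = None,
) -> EvalReport:
    """Full report: AUC on raw scores + thresholded confusion metrics."""
    t0 = time.perf_counter()
    a = auc(anomaly_factors, labels)
    pred = threshold_scores(anomaly_factors, contamination)
    cm = confusion_metrics(pred, labels)
    elapsed = elapsed_seconds if elapsed_seconds is not None else time.perf_counter() - t0
    return EvalReport(auc=a, elapsed_seconds=elapsed, **cm)


def append_results_csv(
    path: str | Path,
    dataset: str,
    method: str,
    report: EvalReport,
    seed: int,
) -> None:
    """Append one run to a batch results CSV, creating the header if new."""
    path = Path(path)
    header = "dataset,method,auc,acc,dr,far,seconds,seed\n"
    line = (
        f"{dataset},{method},{report.auc:.4f},{report.acc:.2f},{report.dr:.2f},"
        f"{report.far:.2f},{report.elapsed_seconds:.4f},{seed}\n"
    )
    if not path.exists():
        path.write_text(header + line)
    else:
        with path.open("a") as fh:
            fh.write(line)
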