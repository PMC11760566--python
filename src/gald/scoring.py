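"""Anomaly factor and the end-to-end fit/score path.

The anomaly factor of object x_i is the mean ratio of its synthetic
neighbors' densities to its own:

    AF_i = ( sum_{FD_j in N_k(x_i)} LSD(FD_j) / LSD(x_i) ) / |N_k(x_i)|

An object whose density matches the fake-normal population scores near 1;
an object in a sparser region than the fake-normals scores above 1 and is
ranked more anomalous. Fitting never reads labels: the pipeline is
deduplicate -> Min-Max normalize -> adversarial training -> draw the
synthetic set FD -> precompute leave-one-out synthetic densities. Scoring is
transductive by default (score the rows the model was fitted on) but unseen
rows of the same dimensionality are scored with the fit-time scaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from gald.density import lsd_all, lsd_synthetic, neighborhood
from gald.gan import GANConfig, TrainedGAN, sample_synthetic, spawn_seeds, train_gan
from gald.preprocess import Dataset, NormalizationParams, deduplicate, minmax_normalize

__all__ = ["GALDModel", "anomaly_factor", "fit", "score", "threshold_scores"]

DEFAULT_K = 10


@dataclass
class GALDModel:
    """Everything needed to score objects: GAN, scaling, FD and its densities."""

    gan: TrainedGAN
    norm: NormalizationParams
    fd: np.ndarray
    lsd_fd: np.ndarray
    k: int

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.gan.save(directory / "gan.npz")
        self.norm.to_file(directory / "normalization.tsv")
        np.savez(directory / "synthetic.npz", fd=self.fd, lsd_fd=self.lsd_fd, k=self.k)

    @classmethod
    def load(cls, directory: str | Path) -> "GALDModel":
        directory = Path(directory)
        z = np.load(directory / "synthetic.npz")
        return cls(
            gan=TrainedGAN.load(directory / "gan.npz"),
            norm=NormalizationParams.from_file(directory / "normalization.tsv"),
            fd=z["fd"],
            lsd_fd=z["lsd_fd"],
            k=int(z["k"]),
        )


def anomaly_factor(x_lsd: float, neighbor_lsds: np.ndarray) -> float:
    """Mean neighbor-to-own density ratio for a single object."""
    neighbor_lsds = np.atleast_1d(np.asarray(neighbor_lsds, dtype=float))
    if neighbor_lsds.size == 0:
        raise ValueError("anomaly factor requires a non-empty neighborhood")
    if x_lsd <= 0:
        raise ValueError("own density must be positive")
    return float(neighbor_lsds.mean() / x_lsd)


def fit(X_raw: Dataset, config: GANConfig | None = None, k: int = DEFAULT_K) -> GALDModel:
    """Fit the detector on unlabeled data.

    Labels on X_raw, if any, are ignored entirely. The synthetic-set size
    defaults to the deduplicated row count; the draw seed and the training
    seed are fanned out from config.seed so the whole fit is reproducible.
    """
    if config is None:
        config = GANConfig()
    data = deduplicate(Dataset(X=X_raw.X, y=None, feature_names=list(X_raw.feature_names)))
    n = data.n
    if n < max(10, k + 1):
        raise ValueError(f"need at least max(10, k+1) distinct rows, got {n}")
    normed, params = minmax_normalize(data)
    s = config.n_synthetic if config.n_synthetic is not None else n
    if k >= s:
        raise ValueError(f"k={k} must be smaller than the synthetic-set size {s}")
    train_seed, fd_seed = spawn_seeds(config.seed, 2)
    train_cfg = GANConfig(**{**config.__dict__, "seed": train_seed})
    gan = train_gan(normed.X, train_cfg)
    fd = sample_synthetic(gan, s, seed=fd_seed)
    return GALDModel(gan=gan, norm=params, fd=fd, lsd_fd=lsd_synthetic(fd, k), k=k)


def score(model: GALDModel, X: Dataset | np.ndarray) -> np.ndarray:
    """Anomaly factor of each row of X under a fitted model.

    Rows are scaled with the fit-time normalization, their synthetic
    neighborhoods and densities computed against the stored FD, and Eq-style
    mean density ratios returned aligned with the input rows.
    """
    Xm = X.X if isinstance(X, Dataset) else np.asarray(X, dtype=float)
    if Xm.ndim != 2 or Xm.shape[1] != model.fd.shape[1]:
        raise ValueError(
            f"expected {model.fd.shape[1]} features, got {Xm.shape[1] if Xm.ndim == 2 else 'non-2D'}"
        )
    Xn = model.norm.transform(Xm)
    own = lsd_all(Xn, model.fd, model.k)
    out = np.empty(Xn.shape[0])
    for i in range(Xn.shape[0]):
        nb = neighborhood(Xn[i], model.fd, model.k)
        out[i] = anomaly_factor(own[i], model.lsd_fd[nb.neighbor_ids])
    return out


def threshold_scores(af: np.ndarray, contamination: float) -> np.ndarray:
    """Flag the ceil(contamination * n) largest anomaly factors.

    Ties are broken toward the lower row index so the flag count is exact.
    """
    af = np.asarray(af, dtype=float)
    if af.size == 0:
        raise ValueError("empty score vector")
    if not 0 < contamination < 1:
        raise ValueError("contamination must be in (0, 1)")
    n_flag = int(np.ceil(contamination * af.size))
    order = np.argsort(-af, kind="stable")  # stable: equal scores keep index order
    pred = np.zeros(af.size, dtype=int)
    pred[order[:n_flag]] = 1
    return pred
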