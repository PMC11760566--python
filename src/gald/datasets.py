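"""Seeded synthetic benchmarks emulating imbalanced anomaly-detection tables.

Real benchmark suites for unsupervised outlier detection (medical,
industrial-fault and materials tables) share a common shape: a few percent
up to ~30% anomalies, 2-50 features, normal objects concentrated in one or
more dense regions, and anomalies that are either far from the normal mass
or embedded just outside its core. The generators here reproduce exactly
those regimes so the whole pipeline is testable without any download:
Gaussian normal clusters with unit standard deviation, "far" anomalies
rejected-sampled at a minimum distance from every cluster center, and
"embedded" anomalies placed in a cluster's 1-2 sigma shell. Defaults mirror
a bearing-fault-style regime (~7% anomalies).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from gald.preprocess import Dataset, deduplicate, minmax_normalize

__all__ = ["FixtureSpec", "make_blobs_with_outliers", "make_imbalanced_two_mode"]

logger = logging.getLogger(__name__)

_MAX_REJECT = 10_000


@dataclass
class FixtureSpec:
    """Parameters of one synthetic benchmark draw.

    separation is the anomaly offset in units of the normal clusters'
    standard deviation (sigma = 1 before rescaling); embedded_fraction is the
    share of anomalies placed inside the 1-2 sigma shell of a normal cluster
    rather than far away.
    """

    n_normal: int = 800
    n_anomaly: int = 60
    d: int = 2
    n_clusters: int = 1
    separation: float = 6.0
    embedded_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_normal < 1 or self.d < 1 or self.n_clusters < 1:
            raise ValueError("n_normal, d and n_clusters must be positive")
        if self.n_anomaly < 0 or self.n_anomaly > self.n_normal:
            raise ValueError("need 0 <= n_anomaly <= n_normal (anomalies are the minority)")
        if not 0.0 <= self.embedded_fraction <= 1.0:
            raise ValueError("embedded_fraction must be in [0, 1]")
        if self.separation <= 0:
            raise ValueError("separation must be positive")


def _cluster_centers(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.n_clusters == 1:
        return np.zeros((1, spec.d))
    # centers spread far enough apart that clusters stay distinct
    spacing = max(8.0, spec.separation)
    centers = np.zeros((spec.n_clusters, spec.d))
    for i in range(1, spec.n_clusters):
        direction = rng.standard_normal(spec.d)
        direction /= np.linalg.norm(direction)
        centers[i] = centers[i - 1] + spacing * direction
    return centers


def make_blobs_with_outliers(spec: FixtureSpec) -> Dataset:
    """Gaussian normal clusters plus far and/or embedded anomalies.

    Normal objects: unit-covariance Gaussian around each cluster center
    (clusters filled round-robin). Far anomalies: uniform draws over an
    enclosing box, accepted only at >= separation sigma from every center.
    Embedded anomalies: on a random direction at radius 1-2 sigma from a
    cluster center — inside the fringe of the normal region, the regime
    where pure distance-to-center rules fail. Output is Min-Max normalized
    with labels 1 = anomaly; deterministic in spec.seed.
    """
    rng = np.random.default_rng(spec.seed)
    centers = _cluster_centers(spec, rng)

    assign = np.arange(spec.n_normal) % spec.n_clusters
    normals = centers[assign] + rng.standard_normal((spec.n_normal, spec.d))

    n_embedded = int(round(spec.embedded_fraction * spec.n_anomaly))
    n_far = spec.n_anomaly - n_embedded

    rows = [normals]
    if n_far:
        margin = spec.separation + 4.0
        lo = centers.min(axis=0) - margin
        hi = centers.max(axis=0) + margin
        far = np.empty((n_far, spec.d))
        filled = 0
        attempts = 0
        while filled < n_far:
            attempts += 1
            if attempts > _MAX_REJECT:
                raise ValueError(
                    "could not place far anomalies: separation too large for the sampling box"
                )
            cand = rng.uniform(lo, hi, size=(n_far - filled, spec.d))
            ok = (cdist(cand, centers) >= spec.separation).all(axis=1)
            take = cand[ok]
            far[filled : filled + take.shape[0]] = take
            filled += take.shape[0]
        rows.append(far)
    if n_embedded:
        which = rng.integers(0, spec.n_clusters, size=n_embedded)
        direction = rng.standard_normal((n_embedded, spec.d))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        radius = rng.uniform(1.0, 2.0, size=(n_embedded, 1))
        rows.append(centers[which] + radius * direction)

    X = np.vstack(rows)
    y = np.concatenate([np.zeros(spec.n_normal, dtype=int), np.ones(spec.n_anomaly, dtype=int)])
    perm = rng.permutation(X.shape[0])
    data = Dataset(X=X[perm], y=y[perm], feature_names=[f"f{j}" for j in range(spec.d)])
    data = deduplicate(data)  # defensive; continuous draws collide with probability 0
    normed, _ = minmax_normalize(data)
    return normed


def make_imbalanced_two_mode(spec: FixtureSpec) -> Dataset:
    """One dominant normal mode plus a compact minority mode of anomalies.

    Emulates the two-latent-distribution setting in which adversarial
    training should devote the generator to the majority mode: normals form
    a single unit-sigma Gaussian at the origin, anomalies their own
    unit-sigma Gaussian at separation sigma along a random direction. A
    split that is not actually imbalanced (>= 40% anomalies) is allowed but
    logged as violating the method's premise.
    """
    rng = np.random.default_rng(spec.seed)
    frac = spec.n_anomaly / (spec.n_normal + spec.n_anomaly) if spec.n_anomaly else 0.0
    if frac >= 0.4:
        logger.warning(
            "anomaly fraction %.2f is not a minority regime; the generator may not "
            "prefer either mode",
            frac,
        )
    direction = rng.standard_normal(spec.d)
    direction /= np.linalg.norm(direction)
    normals = rng.standard_normal((spec.n_normal, spec.d))
    rows = [normals]
    if spec.n_anomaly:
        anomalies = spec.separation * direction + rng.standard_normal((spec.n_anomaly, spec.d))
        rows.append(anomalies)
    X = np.vstack(rows)
    y = np.concatenate([np.zeros(spec.n_normal, dtype=int), np.ones(spec.n_anomaly, dtype=int)])
    perm = rng.permutation(X.shape[0])
    data = Dataset(X=X[perm], y=y[perm], feature_names=[f"f{j}" for j in range(spec.d)])
    data = deduplicate(data)
    normed, _ = minmax_normalize(data)
    return normed
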