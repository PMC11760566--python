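"""Adversarial training of the fake-normal generator.

A standard minimax GAN: the generator G maps Gaussian latent vectors to data
space, the discriminator D maps data-space points to a probability of being
real. On a class-imbalanced table the adversarial loss is dominated by the
majority (normal) objects, so G converges toward the normal-object
distribution — its samples act as "fake normals" for density scoring.

The discriminator ascends

    V_D = sum_i log D(x_i) + sum_j log(1 - D(G(z_j)))

and the generator descends

    V_G = sum_j log(1 - D(G(z_j)))

in alternating single steps per iteration. Both networks are fully connected
multilayer perceptrons (default 3 ReLU hidden layers, sigmoid outputs)
implemented directly in numpy with manual backpropagation and Adam updates;
every random draw (initialization, minibatch selection, latent noise) is
derived from a single seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "GANConfig",
    "TrainedGAN",
    "discriminator_objective",
    "generator_objective",
    "train_gan",
    "sample_synthetic",
    "spawn_seeds",
]

# probabilities clamped away from {0, 1} before logs
_P_EPS = 1e-7


def spawn_seeds(seed: int, count: int) -> list[int]:
    """Deterministically fan a single seed out to `count` independent sub-seeds.

    Sub-seeds are below 2**31 so they remain valid for any downstream RNG.
    """
    state = np.random.SeedSequence(seed).generate_state(count, dtype=np.uint32)
    return [int(s % (2**31 - 1)) for s in state]


@dataclass
class GANConfig:
    """Hyperparameters of the adversarial fit.

    latent_dim defaults to the data dimension d when left as None; the
    learning rate and depth follow the reference settings (3 hidden layers,
    lr 1e-4). n_synthetic (size of the fake-normal sample, None -> n) keeps
    the synthetic population the same size as the data so density scales are
    comparable.
    """

    latent_dim: Optional[int] = None
    hidden_layers: int = 3
    hidden_width: Optional[int] = None
    learning_rate: float = 1e-4
    epochs: int = 1500
    batch_size: int = 64
    n_synthetic: Optional[int] = None
    seed: int = 0
    optimizer: str = "adam"  # "adam" or "sgd"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative")
        if self.batch_size < 1:
            raise ValueError("batch_size must be at least 1")
        if self.hidden_layers < 1:
            raise ValueError("hidden_layers must be at least 1")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")


def _default_width(d: int) -> int:
    # smallest conventional width for the stated depth at tabular scale
    return max(16, min(128, 4 * d))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class _MLP:
    """Minimal fully connected net: ReLU hidden layers, sigmoid output."""

    def __init__(self, sizes: list[int], rng: np.random.Generator):
        self.sizes = list(sizes)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        n_layers = len(sizes) - 1
        for i, (fan_in, fan_out) in enumerate(zip(sizes[:-1], sizes[1:])):
            # He init for the ReLU stack; small init on the sigmoid output layer
            # (DCGAN convention) so the generator starts near the center of the
            # normalized cube and the discriminator starts uninformative
            scale = 0.02 if i == n_layers - 1 else np.sqrt(2.0 / fan_in)
            self.W.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))
        # Adam state
        self._m = [np.zeros_like(w) for w in self.W] + [np.zeros_like(b) for b in self.b]
        self._v = [np.zeros_like(w) for w in self.W] + [np.zeros_like(b) for b in self.b]
        self._t = 0

    def forward(self, x: np.ndarray, keep_cache: bool = False):
        """Return sigmoid output of shape (batch, sizes[-1]); optionally a cache."""
        a = np.asarray(x, dtype=float)
        cache = [a]
        n_layers = len(self.W)
        for i, (w, b) in enumerate(zip(self.W, self.b)):
            z = a @ w + b
            a = _sigmoid(z) if i == n_layers - 1 else np.maximum(z, 0.0)
            if keep_cache:
                cache.append(a)
        return (a, cache) if keep_cache else a

    def backward(self, cache: list[np.ndarray], delta_out: np.ndarray):
        """Backpropagate dL/d(pre-sigmoid output) through the net.

        Returns (weight grads, bias grads, dL/dinput). `delta_out` must be the
        gradient with respect to the output layer's pre-activation.
        """
        gW = [np.zeros_like(w) for w in self.W]
        gb = [np.zeros_like(b) for b in self.b]
        delta = delta_out
        for i in range(len(self.W) - 1, -1, -1):
            gW[i] = cache[i].T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.W[i].T) * (cache[i] > 0)
        d_input = delta @ self.W[0].T
        return gW, gb, d_input

    def step(self, gW, gb, lr: float, optimizer: str = "adam") -> None:
        """Descend the supplied gradients (pass negated grads to ascend)."""
        grads = gW + gb
        params = self.W + self.b
        if optimizer == "sgd":
            for p, g in zip(params, grads):
                p -= lr * g
            return
        self._t += 1
        b1, b2, eps = 0.5, 0.999, 1e-8
        for i, (p, g) in enumerate(zip(params, grads)):
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g * g
            m_hat = self._m[i] / (1 - b1**self._t)
            v_hat = self._v[i] / (1 - b2**self._t)
            p -= lr * m_hat / (np.sqrt(v_hat) + eps)


@dataclass
class TrainedGAN:
    """Generator/discriminator parameter states plus training history."""

    generator: _MLP
    discriminator: _MLP
    loss_history: list[tuple[float, float]]  # (discriminator objective, generator objective)
    config: GANConfig
    d: int

    def save(self, path: str | Path) -> None:
        """Persist parameters + config to a single .npz archive."""
        arrays = {}
        for tag, net in (("g", self.generator), ("d", self.discriminator)):
            for i, (w, b) in enumerate(zip(net.W, net.b)):
                arrays[f"{tag}_W{i}"] = w
                arrays[f"{tag}_b{i}"] = b
        arrays["g_sizes"] = np.array(self.generator.sizes)
        arrays["d_sizes"] = np.array(self.discriminator.sizes)
        arrays["loss_history"] = np.array(self.loss_history, dtype=float).reshape(-1, 2)
        cfg = {k: v for k, v in asdict(self.config).items()}
        arrays["config_json"] = np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedGAN":
        z = np.load(path)
        cfg = GANConfig(**json.loads(bytes(z["config_json"]).decode()))
        rng = np.random.default_rng(0)
        nets = {}
        for tag in ("g", "d"):
            net = _MLP(list(z[f"{tag}_sizes"]), rng)
            for i in range(len(net.W)):
                net.W[i] = z[f"{tag}_W{i}"]
                net.b[i] = z[f"{tag}_b{i}"]
            nets[tag] = net
        history = [tuple(row) for row in z["loss_history"]]
        return cls(
            generator=nets["g"],
            discriminator=nets["d"],
            loss_history=history,
            config=cfg,
            d=nets["g"].sizes[-1],
        )


def _clamp(p: np.ndarray) -> np.ndarray:
    return np.clip(np.asarray(p, dtype=float), _P_EPS, 1.0 - _P_EPS)


def discriminator_objective(d_real: np.ndarray, d_fake: np.ndarray) -> float:
    """V_D = sum log(d_real) + sum log(1 - d_fake); the discriminator ascends this.

    Supremum 0 is approached when the discriminator is perfect (d_real -> 1,
    d_fake -> 0). Probabilities are clamped away from {0, 1} before the logs.
    """
    d_real = np.atleast_1d(np.asarray(d_real, dtype=float))
    d_fake = np.atleast_1d(np.asarray(d_fake, dtype=float))
    if d_real.size == 0 or d_fake.size == 0:
        raise ValueError("objective requires non-empty probability vectors")
    return float(np.log(_clamp(d_real)).sum() + np.log1p(-_clamp(d_fake)).sum())


def generator_objective(d_fake: np.ndarray) -> float:
    """V_G = sum log(1 - d_fake); the generator descends this (fooling D drives it down)."""
    d_fake = np.atleast_1d(np.asarray(d_fake, dtype=float))
    if d_fake.size == 0:
        raise ValueError("objective requires a non-empty probability vector")
    return float(np.log1p(-_clamp(d_fake)).sum())


def _build_nets(d: int, config: GANConfig, rng: np.random.Generator) -> tuple[_MLP, _MLP]:
    latent = config.latent_dim if config.latent_dim is not None else d
    width = config.hidden_width if config.hidden_width is not None else _default_width(d)
    g_sizes = [latent] + [width] * config.hidden_layers + [d]
    d_sizes = [d] + [width] * config.hidden_layers + [1]
    return _MLP(g_sizes, rng), _MLP(d_sizes, rng)


def train_gan(X: np.ndarray, config: GANConfig) -> TrainedGAN:
    """Alternating adversarial fit of generator and discriminator on X.

    Per iteration: one discriminator ascent step on a real minibatch of size m
    plus m generated samples, then one generator descent step on m fresh
    latent draws. X is expected Min-Max normalized to [0, 1] (the generator's
    sigmoid output lives there). Fully reproducible from config.seed.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be a 2-D array with at least 2 rows")
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")
    n, d = X.shape
    m = min(config.batch_size, n)
    rng = np.random.default_rng(config.seed)
    gen, disc = _build_nets(d, config, rng)
    latent = gen.sizes[0]

    history: list[tuple[float, float]] = []
    for epoch in range(config.epochs):
        # ---- discriminator ascent on real batch + fakes
        idx = rng.choice(n, size=m, replace=False)
        real = X[idx]
        z = rng.standard_normal((m, latent))
        fake, _ = gen.forward(z, keep_cache=True)

        p_real, cache_r = disc.forward(real, keep_cache=True)
        p_fake, cache_f = disc.forward(fake, keep_cache=True)
        d_obj = discriminator_objective(p_real.ravel(), p_fake.ravel())
        # ascend (1/m)[log D(x) + log(1-D(G(z)))]; d/ds log p = 1-p, d/ds log(1-p) = -p
        delta_r = -(1.0 - p_real) / m  # negated: step() descends
        delta_f = p_fake / m
        gWr, gbr, _ = disc.backward(cache_r, delta_r)
        gWf, gbf, _ = disc.backward(cache_f, delta_f)
        gW = [a + b for a, b in zip(gWr, gWf)]
        gb = [a + b for a, b in zip(gbr, gbf)]
        disc.step(gW, gb, config.learning_rate, config.optimizer)

        # ---- generator descent on fresh noise
        z = rng.standard_normal((m, latent))
        fake, cache_g = gen.forward(z, keep_cache=True)
        p_fake, cache_f = disc.forward(fake, keep_cache=True)
        g_obj = generator_objective(p_fake.ravel())
        # minimize (1/m) log(1 - D(G(z))): d/ds log(1-p) = -p
        delta_d = -p_fake / m
        _, _, d_fake_grad = disc.backward(cache_f, delta_d)
        # through generator's sigmoid output
        delta_g = d_fake_grad * fake * (1.0 - fake)
        gWg, gbg, _ = gen.backward(cache_g, delta_g)
        gen.step(gWg, gbg, config.learning_rate, config.optimizer)

        if not (np.isfinite(d_obj) and np.isfinite(g_obj)):
            raise FloatingPointError(f"non-finite adversarial loss at epoch {epoch}")
        history.append((d_obj, g_obj))

    return TrainedGAN(generator=gen, discriminator=disc, loss_history=history, config=config, d=d)


def sample_synthetic(gan: TrainedGAN, count: int, seed: int) -> np.ndarray:
    """Draw `count` fake-normal objects: z ~ N(0, I) pushed through the generator.

    Returns an array of shape (count, d) with entries in [0, 1] (sigmoid
    output); reproducible from `seed`.
    """
    if count < 1:
        raise ValueError("count must be at least 1")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((count, gan.generator.sizes[0]))
    return gan.generator.forward(z)
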