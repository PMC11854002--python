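"""Denoising diffusion probabilistic model over molecule latents.

The forward process is the fixed Gaussian Markov chain
``q(x_t | x_{t-1}) = N(sqrt(1 - beta_t) x_{t-1}, beta_t I)`` with a linear
beta schedule; marginalising gives the closed form
``x_t = sqrt(alpha_bar_t) x_0 + sqrt(1 - alpha_bar_t) eps``.  A residual MLP
with feature-wise linear modulation (FiLM) timestep conditioning is trained
to predict the injected noise, minimising
``L = E || eps - eps_theta(x_t, t) ||^2`` with t uniform on {1..T}.  Ancestral
sampling then reverses the chain from pure Gaussian noise, using the Ho et
al. posterior-mean parameterisation with variance beta_t.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import _nn

__all__ = [
    "NoiseSchedule", "linear_schedule", "forward_noise",
    "DenoiserConfig", "Denoiser", "noise_prediction_loss",
    "sample_training_batch", "train_denoiser", "sample_unguided",
]


@dataclass(frozen=True)
class NoiseSchedule:
    """Per-timestep beta/alpha/alpha_bar tables, index 0 holding t=1."""

    T: int
    beta: np.ndarray
    alpha: np.ndarray
    alpha_bar: np.ndarray

    def __post_init__(self):
        if self.T < 1 or len(self.beta) != self.T:
            raise ValueError("schedule length mismatch")
        if not (np.all(self.beta > 0) and np.all(self.beta < 1)):
            raise ValueError("beta must lie in (0, 1)")
        if np.any(np.diff(self.beta) < -1e-15):
            raise ValueError("beta must be nondecreasing")


def linear_schedule(T: int, beta_start: float = 1e-4,
                    beta_end: float = 0.02) -> NoiseSchedule:
    """Linear beta schedule from beta_start (t=1) to beta_end (t=T)."""
    if T < 1:
        raise ValueError("T must be >= 1")
    if not (0.0 < beta_start <= beta_end < 1.0):
        raise ValueError("require 0 < beta_start <= beta_end < 1")
    beta = np.linspace(beta_start, beta_end, T)
    alpha = 1.0 - beta
    return NoiseSchedule(T=T, beta=beta, alpha=alpha,
                         alpha_bar=np.cumprod(alpha))


def forward_noise(x0: np.ndarray, t: int, eps: np.ndarray,
                  schedule: NoiseSchedule) -> np.ndarray:
    """Closed-form forward noising: sqrt(ab_t) x0 + sqrt(1 - ab_t) eps."""
    if not 1 <= t <= schedule.T:
        raise ValueError(f"timestep {t} outside 1..{schedule.T}")
    x0 = np.asarray(x0, dtype=np.float64)
    eps = np.asarray(eps, dtype=np.float64)
    if x0.shape != eps.shape:
        raise ValueError("x0 and eps shapes differ")
    ab = schedule.alpha_bar[t - 1]
    return np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * eps


def noise_prediction_loss(eps: np.ndarray, eps_pred: np.ndarray) -> float:
    """Mean over examples of the squared L2 norm of the prediction error."""
    eps = np.atleast_2d(eps)
    eps_pred = np.atleast_2d(eps_pred)
    return float(((eps - eps_pred) ** 2).sum(axis=1).mean())


@dataclass(frozen=True)
class TrainingBatch:
    x0: np.ndarray
    t: np.ndarray
    eps: np.ndarray
    x_t: np.ndarray


def sample_training_batch(latents: np.ndarray, schedule: NoiseSchedule,
                          rng: np.random.Generator,
                          size: int | None = None) -> TrainingBatch:
    """Draw (x0, t, eps, x_t) with t uniform on {1..T} and eps standard normal."""
    latents = np.atleast_2d(latents)
    idx = (rng.integers(0, len(latents), size=size)
           if size is not None else np.arange(len(latents)))
    x0 = latents[idx]
    t = rng.integers(1, schedule.T + 1, size=len(x0))
    eps = rng.standard_normal(x0.shape)
    ab = schedule.alpha_bar[t - 1][:, None]
    x_t = np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * eps
    return TrainingBatch(x0=x0, t=t, eps=eps, x_t=x_t)


@dataclass(frozen=True)
class DenoiserConfig:
    latent_dim: int = 32
    hidden_dim: int = 128
    n_res_blocks: int = 3
    timestep_embed_dim: int = 64
    epochs: int = 200
    batch_size: int = 128
    learning_rate: float = 1e-3
    lr_decay: float = 0.1    # final learning rate as a fraction of the initial
    seed: int = 0

    def __post_init__(self):
        if self.n_res_blocks < 1:
            raise ValueError("n_res_blocks must be >= 1")


class _ResBlock(_nn.Module):
    """Fully connected residual block with FiLM timestep conditioning."""

    def __init__(self, dim: int, embed_dim: int, rng: np.random.Generator):
        self.fc1 = _nn.Linear(dim, dim, rng)
        self.fc2 = _nn.Linear(dim, dim, rng)
        self.film = _nn.Linear(embed_dim, 2 * dim, rng)
        self.dim = dim

    def __call__(self, h: _nn.Tensor, temb: _nn.Tensor) -> _nn.Tensor:
        film = self.film(temb)
        n = film.shape[0]
        scale = film.reshape(n, 2, self.dim)
        # split scale/shift without a slicing primitive: mask products
        mask_s = np.zeros((2, 1)); mask_s[0, 0] = 1.0
        mask_b = np.zeros((2, 1)); mask_b[1, 0] = 1.0
        s = (scale * mask_s).sum(axis=1)
        b = (scale * mask_b).sum(axis=1)
        inner = _nn.relu(self.fc1(h) * (1.0 + s) + b)
        return h + self.fc2(inner)


class Denoiser(_nn.Module):
    """Noise predictor eps_theta(x_t, t): linear in, FiLM residual blocks,
    layer norm, linear out."""

    def __init__(self, config: DenoiserConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d, h = config.latent_dim, config.hidden_dim
        self.inp = _nn.Linear(d, h, rng)
        self.blocks = [_ResBlock(h, config.timestep_embed_dim, rng)
                       for _ in range(config.n_res_blocks)]
        self.norm = _nn.LayerNorm(h)
        self.out = _nn.Linear(h, d, rng)
        self.train_losses: list[float] = []

    def forward_tensor(self, x: _nn.Tensor, t: np.ndarray) -> _nn.Tensor:
        temb = _nn.Tensor(_nn.sinusoidal_embedding(t, self.config.timestep_embed_dim))
        h = self.inp(x)
        for block in self.blocks:
            h = block(h, temb)
        return self.out(self.norm(h))

    def __call__(self, x: np.ndarray, t: int | np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        t = np.broadcast_to(np.asarray(t), (len(x),))
        return self.forward_tensor(_nn.Tensor(x), t).data.copy()

    def save(self, path: str | Path, schedule: NoiseSchedule) -> None:
        arrays = {f"p{i}": a for i, a in enumerate(self.state_arrays())}
        np.savez(path, _meta=json.dumps({"config": asdict(self.config)}),
                 _beta=schedule.beta, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> tuple["Denoiser", NoiseSchedule]:
        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["_meta"]))
            beta = f["_beta"]
            arrays = [f[f"p{i}"] for i in range(len(f.files) - 2)]
        model = cls(DenoiserConfig(**meta["config"]))
        model.load_state_arrays(arrays)
        alpha = 1.0 - beta
        schedule = NoiseSchedule(T=len(beta), beta=beta, alpha=alpha,
                                 alpha_bar=np.cumprod(alpha))
        return model, schedule


def train_denoiser(latents: np.ndarray, schedule: NoiseSchedule,
                   config: DenoiserConfig, verbose: bool = False) -> Denoiser:
    """Minimise the noise-prediction loss over the latent dataset."""
    latents = np.atleast_2d(np.asarray(latents, dtype=np.float64))
    if len(latents) < 2:
        raise ValueError("need at least 2 latent vectors")
    if latents.shape[1] != config.latent_dim:
        raise ValueError("latent dimension mismatch")
    model = Denoiser(config)
    rng = np.random.default_rng(config.seed + 1)
    opt = _nn.Adam(model.parameters(), lr=config.learning_rate)
    n = len(latents)
    for epoch in range(config.epochs):
        # linear learning-rate decay stabilises the late training epochs
        frac = epoch / max(config.epochs - 1, 1)
        opt.lr = config.learning_rate * (1.0 - (1.0 - config.lr_decay) * frac)
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = sample_training_batch(latents[idx], schedule, rng)
            pred = model.forward_tensor(_nn.Tensor(batch.x_t), batch.t)
            err = pred - _nn.Tensor(batch.eps)
            loss = (err * err).sum(axis=1).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * len(idx)
        model.train_losses.append(total / n)
        if verbose:
            print(f"epoch {epoch + 1}/{config.epochs}  loss {total / n:.4f}")
    return model


def ancestral_step(x: np.ndarray, t: int, eps_hat: np.ndarray,
                   schedule: NoiseSchedule, noise: np.ndarray | None) -> np.ndarray:
    """One reverse step x_t -> x_{t-1} given predicted noise.

    Posterior mean in the Ho et al. parameterisation with variance beta_t;
    ``noise`` must be None at the final step (t=1).
    """
    b = schedule.beta[t - 1]
    a = schedule.alpha[t - 1]
    ab = schedule.alpha_bar[t - 1]
    mean = (x - b / np.sqrt(1.0 - ab) * eps_hat) / np.sqrt(a)
    if noise is None:
        return mean
    return mean + np.sqrt(b) * noise


def sample_unguided(n: int, schedule: NoiseSchedule, denoiser: Denoiser,
                    seed: int = 0) -> np.ndarray:
    """Ancestral DDPM sampling of n latent vectors from Gaussian noise."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, denoiser.config.latent_dim))
    for t in range(schedule.T, 0, -1):
        eps_hat = denoiser(x, t)
        noise = rng.standard_normal(x.shape) if t > 1 else None
        x = ancestral_step(x, t, eps_hat, schedule, noise)
    return x
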