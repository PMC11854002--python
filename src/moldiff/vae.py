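"""Variational autoencoder over one-hot token matrices.

The VAE supplies the continuous latent space the diffusion model is trained
on.  Encoder and decoder are MLPs over the flattened ``max_len x |V|`` one-hot
matrix; the decoder ends in a per-position softmax, so its output rows are
probability vectors — the differentiable relaxation consumed by the property
predictors during guidance.  Hard argmax decoding happens only when final
molecules are emitted.

Training maximises the evidence lower bound: token cross-entropy
reconstruction plus a KL term against the standard-normal prior, with a
linear warm-up of the KL weight.  ``encode_batch`` returns posterior means,
so the latent dataset the diffusion model sees is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import _nn
from .codec import MoleculeRecord, Vocabulary, decode_indices, to_onehot

__all__ = ["VAEConfig", "VAE", "train_vae"]


@dataclass(frozen=True)
class VAEConfig:
    latent_dim: int = 32
    hidden_dims: tuple[int, ...] = (256,)
    kl_weight: float = 0.1
    kl_warmup_fraction: float = 0.2   # fraction of epochs to ramp KL from 0
    epochs: int = 60
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.kl_weight < 0:
            raise ValueError("kl_weight must be nonnegative")


class VAE(_nn.Module):
    def __init__(self, vocab: Vocabulary, config: VAEConfig):
        self.vocab = vocab
        self.config = config
        self.input_dim = vocab.max_len * len(vocab)
        rng = np.random.default_rng(config.seed)
        dims = [self.input_dim, *config.hidden_dims]
        self.encoder_body = _nn.MLP(dims, rng) if len(dims) > 1 else None
        enc_out = dims[-1]
        self.mu_head = _nn.Linear(enc_out, config.latent_dim, rng)
        self.logvar_head = _nn.Linear(enc_out, config.latent_dim, rng)
        self.decoder = _nn.MLP([config.latent_dim, *reversed(config.hidden_dims),
                                self.input_dim], rng)
        self.train_losses: list[float] = []
        self.reconstruction_accuracy: float | None = None

    # -- core passes -------------------------------------------------------
    def _encode_tensor(self, x: _nn.Tensor) -> tuple[_nn.Tensor, _nn.Tensor]:
        h = x
        if self.encoder_body is not None:
            h = self.encoder_body(h)
            h = _nn.relu(h)
        return self.mu_head(h), self.logvar_head(h)

    def decode_tensor(self, z: _nn.Tensor) -> _nn.Tensor:
        """Differentiable decode: (n, latent_dim) -> (n, max_len, |V|) probabilities."""
        logits = self.decoder(z)
        n = logits.shape[0]
        logits = logits.reshape(n, self.vocab.max_len, len(self.vocab))
        return _nn.softmax(logits, axis=-1)

    # -- user-facing numpy API ----------------------------------------------
    def encode_batch(self, records: list[MoleculeRecord]) -> np.ndarray:
        """Posterior-mean latents, one row per record (deterministic)."""
        X = np.stack([to_onehot(r, self.vocab).ravel() for r in records])
        mu, _ = self._encode_tensor(_nn.Tensor(X))
        return mu.data.copy()

    def decode_batch(self, latents: np.ndarray) -> np.ndarray:
        """Relaxed decodings: (n, max_len, |V|) with rows summing to 1."""
        z = np.atleast_2d(np.asarray(latents, dtype=np.float64))
        if z.shape[1] != self.config.latent_dim:
            raise ValueError(f"latent dimension {z.shape[1]} != {self.config.latent_dim}")
        return self.decode_tensor(_nn.Tensor(z)).data.copy()

    def decode_smiles(self, latents: np.ndarray) -> list[str]:
        """Hard (argmax) decode of latents to canonical SMILES."""
        probs = self.decode_batch(latents)
        return [decode_indices(p.argmax(axis=1), self.vocab) for p in probs]

    def sample_prior(self, n: int, seed: int = 0) -> np.ndarray:
        """n i.i.d. standard-normal latent vectors."""
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = np.random.default_rng(seed)
        return rng.standard_normal((n, self.config.latent_dim))

    # -- persistence ---------------------------------------------------------
    def save(self, path: str | Path) -> None:
        arrays = {f"p{i}": a for i, a in enumerate(self.state_arrays())}
        np.savez(path, _meta=json.dumps({
            "vocab": {"tokens": list(self.vocab.tokens), "max_len": self.vocab.max_len},
            "config": asdict(self.config)}), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "VAE":
        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["_meta"]))
            arrays = [f[f"p{i}"] for i in range(len(f.files) - 1)]
        cfg = meta["config"]
        cfg["hidden_dims"] = tuple(cfg["hidden_dims"])
        vocab = Vocabulary(tokens=tuple(meta["vocab"]["tokens"]),
                           max_len=int(meta["vocab"]["max_len"]))
        model = cls(vocab, VAEConfig(**cfg))
        model.load_state_arrays(arrays)
        return model


def train_vae(records: list[MoleculeRecord], vocab: Vocabulary,
              config: VAEConfig = VAEConfig(), verbose: bool = False) -> VAE:
    """Fit the VAE by stochastic gradient ascent on the ELBO.

    Per-epoch training loss is recorded on ``model.train_losses`` and the
    final training-set sequence reconstruction accuracy (fraction of
    molecules whose full argmax token sequence is reproduced) on
    ``model.reconstruction_accuracy``.
    """
    if not records:
        raise ValueError("empty training set")
    for r in records:
        if len(r.tokens) != vocab.max_len:
            raise ValueError("record/vocabulary mismatch")

    model = VAE(vocab, config)
    rng = np.random.default_rng(config.seed + 1)
    X = np.stack([to_onehot(r, vocab).ravel() for r in records])
    n = len(X)
    opt = _nn.Adam(model.parameters(), lr=config.learning_rate)
    warmup = max(1, int(round(config.kl_warmup_fraction * config.epochs)))

    for epoch in range(config.epochs):
        beta = config.kl_weight * min(1.0, (epoch + 1) / warmup)
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = _nn.Tensor(X[idx])
            mu, logvar = model._encode_tensor(xb)
            eps = rng.standard_normal(mu.shape)
            z = mu + (logvar * 0.5).exp() * _nn.Tensor(eps)
            logits = model.decoder(z)
            logp = _nn.log_softmax(
                logits.reshape(len(idx), vocab.max_len, len(vocab)), axis=-1)
            recon = -(logp * xb.reshape(len(idx), vocab.max_len, len(vocab))
                      ).sum(axis=(1, 2)).mean()
            kl = (-0.5) * (1.0 + logvar - mu * mu - logvar.exp()).sum(axis=1).mean()
            loss = recon + beta * kl
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * len(idx)
        model.train_losses.append(total / n)
        if verbose:
            print(f"epoch {epoch + 1}/{config.epochs}  loss {total / n:.4f}")

    # training-set sequence reconstruction accuracy from posterior means
    mu = model.encode_batch(records)
    probs = model.decode_batch(mu)
    hits = sum(int(np.array_equal(p.argmax(axis=1), np.asarray(r.tokens)))
               for p, r in zip(probs, records))
    model.reconstruction_accuracy = hits / n
    return model
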