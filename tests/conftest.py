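"""Shared fixtures: the synthetic library and a fully trained model bundle.

Heavy artifacts (the 500-molecule library, trained VAE, denoiser and property
predictors) are built once per session; individual tests treat them as
read-only.  All seeds are fixed so the whole suite is deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

import moldiff as md
from moldiff.ddpm import DenoiserConfig, train_denoiser
from moldiff.experiments import ModelBundle
from moldiff.properties import PredictorConfig, train_predictor

# study conditions of the desk-scale fixture pipeline
LIBRARY_N = 500
LIBRARY_SEED = 7
LATENT_DIM = 32
T_FIXTURE = 100
BETA_FIXTURE = (1e-3, 0.2)   # scaled so alpha_bar_T ~ 0 at T=100


@pytest.fixture(scope="session")
def library() -> list[str]:
    return md.generate_library(md.FixtureSpec(n_molecules=LIBRARY_N, seed=LIBRARY_SEED))


@pytest.fixture(scope="session")
def vocab(library):
    return md.build_vocabulary(library)


@pytest.fixture(scope="session")
def records(library, vocab):
    return [md.encode(s, vocab) for s in library]


@pytest.fixture(scope="session")
def schedule():
    return md.linear_schedule(T_FIXTURE, *BETA_FIXTURE)


@pytest.fixture(scope="session")
def bundle(library, vocab, records, schedule) -> ModelBundle:
    """Fixture-trained pipeline: VAE, latent denoiser, logP/size predictors."""
    vae = md.train_vae(records, vocab, md.VAEConfig(
        latent_dim=LATENT_DIM, hidden_dims=(256,), epochs=80,
        batch_size=64, seed=0))
    latents = vae.encode_batch(records)
    denoiser = train_denoiser(latents, schedule, DenoiserConfig(
        latent_dim=LATENT_DIM, hidden_dim=128, epochs=400, batch_size=128, seed=0))
    predictors = {
        name: train_predictor(records, vocab, name,
                              PredictorConfig(epochs=80, seed=0))
        for name in ("logP", "n_heavy_atoms")
    }
    return ModelBundle(vae=vae, denoiser=denoiser, schedule=schedule,
                       predictors=predictors)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
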