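"""Guidance: gradient algebra, closed-form linear oracle, reduction to
unguided sampling, and the statistical response of generated properties."""

import numpy as np
import pytest

import moldiff as md
from moldiff.ddpm import Denoiser, DenoiserConfig, linear_schedule, sample_unguided
from moldiff.guidance import (GuidanceError, GuidanceSpec, guidance_gradient,
                              guided_step, sample_guided, sample_guided_latents)
from moldiff.properties import LatentLinearPredictor


@pytest.fixture(scope="module")
def toy_denoiser():
    return Denoiser(DenoiserConfig(latent_dim=4, hidden_dim=16, epochs=1, seed=0))


@pytest.fixture(scope="module")
def toy_schedule():
    return linear_schedule(30, 1e-3, 0.2)


class TestGradient:
    def test_empty_spec_zero_vector(self, rng):
        x = rng.standard_normal((3, 4))
        g = guidance_gradient(x, GuidanceSpec(), vae=None)
        assert np.array_equal(g, np.zeros_like(x))

    def test_constant_predictor_zero_gradient(self, rng):
        x = rng.standard_normal((3, 4))
        const = LatentLinearPredictor(np.zeros(4))
        g = guidance_gradient(x, GuidanceSpec(terms=((const, 2.0),)), vae=None)
        assert np.array_equal(g, np.zeros_like(x))

    def test_opposed_terms_cancel_exactly(self, rng):
        x = rng.standard_normal((3, 4))
        p = LatentLinearPredictor(rng.standard_normal(4))
        spec = GuidanceSpec(terms=((p, 1.5), (p, -1.5)))
        assert np.array_equal(guidance_gradient(x, spec, vae=None), np.zeros_like(x))

    def test_additivity_over_terms(self, rng):
        x = rng.standard_normal((2, 4))
        p1 = LatentLinearPredictor(rng.standard_normal(4))
        p2 = LatentLinearPredictor(rng.standard_normal(4))
        g1 = guidance_gradient(x, GuidanceSpec(terms=((p1, 0.7),)), vae=None)
        g2 = guidance_gradient(x, GuidanceSpec(terms=((p2, -1.3),)), vae=None)
        g12 = guidance_gradient(x, GuidanceSpec(terms=((p1, 0.7), (p2, -1.3))), vae=None)
        assert np.array_equal(g12, g1 + g2)

    def test_linear_predictor_gradient_is_sw(self, rng):
        w = np.array([1.0, -2.0, 0.5, 3.0])
        x = rng.standard_normal((5, 4))
        g = guidance_gradient(x, GuidanceSpec(terms=((LatentLinearPredictor(w), 2.0),)),
                              vae=None)
        assert np.allclose(g, np.broadcast_to(2.0 * w, g.shape))

    def test_nonfinite_gradient_names_term(self, rng):
        bad = LatentLinearPredictor(np.array([np.inf, 0, 0, 0]), name="bad_term")
        with pytest.raises(GuidanceError, match="bad_term"):
            guidance_gradient(rng.standard_normal((2, 4)),
                              GuidanceSpec(terms=((bad, 1.0),)), vae=None)

    def test_clipping_bounds_norm(self, rng):
        w = np.full(4, 1e6)
        spec = GuidanceSpec(terms=((LatentLinearPredictor(w), 1.0),), clip_norm=10.0)
        g = guidance_gradient(rng.standard_normal((3, 4)), spec, vae=None)
        assert np.all(np.linalg.norm(g, axis=1) <= 10.0 + 1e-9)


class TestGuidedStep:
    def test_closed_form_shift_for_linear_predictor(self, toy_denoiser, toy_schedule, rng):
        # With y(z) = w.z and strength s, modifying the predicted noise by
        # -sqrt(1-ab_t) s w shifts the posterior mean by (beta_t/sqrt(alpha_t)) s w.
        w = np.array([0.5, -1.0, 2.0, 0.0])
        x = rng.standard_normal((6, 4))
        t = 12
        base = guided_step(x, t, GuidanceSpec(), toy_denoiser, toy_schedule,
                           None, np.random.default_rng(3))
        for s in (0.7, 1.4):
            spec = GuidanceSpec(terms=((LatentLinearPredictor(w), s),))
            out = guided_step(x, t, spec, toy_denoiser, toy_schedule,
                              None, np.random.default_rng(3))
            expected = (toy_schedule.beta[t - 1]
                        / np.sqrt(toy_schedule.alpha[t - 1])) * s * w
            assert np.allclose(out - base, np.broadcast_to(expected, x.shape),
                               atol=1e-12)

    def test_shift_doubles_with_strength(self, toy_denoiser, toy_schedule, rng):
        w = rng.standard_normal(4)
        x = rng.standard_normal((4, 4))
        base = guided_step(x, 9, GuidanceSpec(), toy_denoiser, toy_schedule,
                           None, np.random.default_rng(0))
        shifts = []
        for s in (0.5, 1.0):
            spec = GuidanceSpec(terms=((LatentLinearPredictor(w), s),))
            out = guided_step(x, 9, spec, toy_denoiser, toy_schedule,
                              None, np.random.default_rng(0))
            shifts.append(out - base)
        assert np.allclose(shifts[1], 2.0 * shifts[0], atol=1e-12)

    def test_zero_strengths_identical_trajectory(self, toy_denoiser, toy_schedule):
        p = LatentLinearPredictor(np.ones(4))
        spec = GuidanceSpec(terms=((p, 0.0),))
        a = sample_guided_latents(5, spec, toy_schedule, toy_denoiser, None, seed=4)
        b = sample_unguided(5, toy_schedule, toy_denoiser, seed=4)
        assert np.array_equal(a, b)

    def test_latent_mode_moves_along_gradient(self, toy_denoiser, toy_schedule, rng):
        w = rng.standard_normal(4)
        x = rng.standard_normal((3, 4))
        spec = GuidanceSpec(terms=((LatentLinearPredictor(w), 1.0),),
                            mode="latent", latent_eta=0.1)
        base = guided_step(x, 7, GuidanceSpec(), toy_denoiser, toy_schedule,
                           None, np.random.default_rng(1))
        out = guided_step(x, 7, spec, toy_denoiser, toy_schedule,
                          None, np.random.default_rng(1))
        assert not np.array_equal(out, base)

    def test_invalid_timestep(self, toy_denoiser, toy_schedule, rng):
        with pytest.raises(ValueError, match="timestep"):
            guided_step(rng.standard_normal((2, 4)), 0, GuidanceSpec(),
                        toy_denoiser, toy_schedule, None, np.random.default_rng(0))

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            GuidanceSpec(mode="bogus")
        with pytest.raises(ValueError):
            GuidanceSpec(terms=((LatentLinearPredictor(np.ones(2)), np.nan),))


class TestSampleGuided:
    def test_empty_spec_equals_unguided_decode(self, bundle):
        smiles = sample_guided(20, GuidanceSpec(), bundle.schedule,
                               bundle.denoiser, bundle.vae, seed=11)
        latents = sample_unguided(20, bundle.schedule, bundle.denoiser, seed=11)
        assert smiles == bundle.vae.decode_smiles(latents)

    def test_invalid_n(self, bundle):
        with pytest.raises(ValueError):
            sample_guided(0, GuidanceSpec(), bundle.schedule,
                          bundle.denoiser, bundle.vae, seed=1)

    def test_logp_guidance_raises_mean(self, bundle):
        # strongest tested strength pushes mean computed logP above unguided
        pred = bundle.predictors["logP"]
        unguided = sample_guided(100, GuidanceSpec(), bundle.schedule,
                                 bundle.denoiser, bundle.vae, seed=21)
        guided = sample_guided(100, GuidanceSpec(terms=((pred, 5.0),)),
                               bundle.schedule, bundle.denoiser, bundle.vae, seed=21)
        m0 = np.mean([md.compute_properties(s)["logP"] for s in unguided if s])
        m1 = np.mean([md.compute_properties(s)["logP"] for s in guided if s])
        assert m1 > m0
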