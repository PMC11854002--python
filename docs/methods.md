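# Methods

`moldiff` generates small drug-like molecules with a latent denoising
diffusion model and steers the generation toward target molecular properties
with gradient-based predictor guidance.  This note records the model, its
assumptions, the parameters that matter, and the design decisions taken
where more than one reasonable choice existed.

## Molecular representation

Molecules are handled as canonical SMILES externally and as fixed-length
token sequences internally.  The token grammar (`moldiff.codec`) is a
SELFIES-style robust derivation scheme built for this package: atom tokens
(`[C]`, `[=O]`, …) carry the element and the order of the bond to the
current attachment point, `[Branch]`/`[Pop]` manage a branch stack, and
`[Ring{k}]` closes a ring to the atom created `k` steps earlier.  The
decoder clips every requested bond to the valences still available and skips
unsatisfiable tokens, so **every** token sequence — including uniformly
random ones — derives a chemically valid molecule.  This
robustness-by-construction is what allows a generative model to emit relaxed
probability matrices and still always produce parseable chemistry; it is
fuzz-tested with random sequences in the suite.

Scope of the grammar: neutral organic molecules over C, N, O, S, F, Cl
without stereochemistry, with sulfur restricted to the divalent state.
Aromatic systems are kekulised on encode and re-perceived on decode, so
round-trips compare equal as canonical SMILES.  The alphabet and the maximum
sequence length are derived from the training library at vocabulary-build
time (token order lexicographic for reproducibility, one reserved `[nop]`
padding token, right padding); generation cannot produce sequences longer
than the longest training tokenisation, a documented limitation.  A sequence
that derives no atoms (e.g. all padding) decodes to the documented
empty-molecule sentinel `""` rather than raising.

## Synthetic library

The fixture generator assembles a deterministic drug-like library from
curated aromatic/aliphatic scaffolds and substituents plus enumerated small
alkanes/alcohols/amines, deduplicated as canonical SMILES.  Defaults: 500
molecules, seed 7, 1–25 heavy atoms.  The construction guarantees the
features downstream experiments need — every molecule valid, neutral and
token-encodable; ring counts spanning {0, 1, 2}; computed logP spanning
roughly −1.7 to 5.5 with interquartile range ≈ 1.4 — so property guidance
has signal at desk scale.  What it does **not** emulate: the size (hundreds
of thousands of compounds), charge states, stereochemistry, or the exact
property marginals of a real screening library such as ZINC.  Passing tests
therefore demonstrate the mechanics and statistical behaviour of the method,
not chemical coverage at production scale.

## VAE

Encoder and decoder are MLPs over the flattened `max_len × |V|` one-hot
matrix (default: one hidden layer of 256 units, latent dimension 32 at
fixture scale; a production run would use a much larger latent size).  The
decoder ends in a per-position softmax, giving probability rows — the
differentiable relaxation consumed by predictors during guidance; hard
argmax decoding happens only at final molecule emission.  Training maximises
the ELBO (token cross-entropy + KL to the standard-normal prior) with Adam;
the KL weight defaults to 0.1 with a linear warm-up over the first 20% of
epochs, a standard remedy against early posterior collapse.  The latent
dataset handed to the diffusion model uses **posterior means**, not sampled
posteriors, so the diffusion model learns a stable, deterministic embedding
of the library.

## Diffusion model

The forward process is the fixed Gaussian chain
`q(x_t | x_{t-1}) = N(√(1−β_t) x_{t−1}, β_t I)` with a linear β schedule,
giving the closed form `x_t = √ᾱ_t x_0 + √(1−ᾱ_t) ε` with `α_t = 1−β_t`,
`ᾱ_t = Π α_i`.  The denoiser predicts the injected noise ε (a linear layer,
three fully connected residual blocks with feature-wise linear modulation
(FiLM) conditioning on a sinusoidal timestep embedding, a layer norm, and a
final linear layer) and is trained on
`L = E‖ε − ε_θ(x_t, t)‖²` with `t` uniform on {1..T}.  Ancestral sampling
uses the posterior mean parameterisation with variance `σ_t² = β_t` (the
simpler of the two standard choices) and adds no noise at the final step.

Schedule defaults are T = 1000 with β from 1e-4 to 0.02.  Fixture-scale
runs use T = 100, and the β endpoints must then be scaled up (we use 1e-3
to 0.2) so that `ᾱ_T ≈ 0`: with the T = 1000 endpoints at T = 100 the chain
retains `√ᾱ_T ≈ 0.6` of the signal, the terminal distribution is far from
the standard-normal prior used to start sampling, and all generated moments
shrink accordingly.  The denoiser trainer decays the learning rate linearly
to 10% of its initial value; with a constant rate the late-training weights
oscillate enough to visibly perturb the generated moments at small model
sizes.

Two independent oracles validate this machinery: (i) `ᾱ_t` tables are
checked against brute-force running products to 1e-12; (ii) for data
`x₀ ~ N(μ, I)` the optimal noise predictor has the closed form
`ε*(x,t) = √(1−ᾱ_t)(x − √ᾱ_t μ)`, and ancestral sampling with it recovers
`N(μ, ≈I)` — this checks the sampler with no trained component in the loop.
The trained counterpart (10⁴ two-dimensional Gaussian latents, hidden width
96, 300 epochs, ≈3 min CPU) recovers the mean within 0.1 per coordinate and
the variance within a few percent.

## Property predictors and guidance

Ground-truth calculators are RDKit descriptors; synthetic accessibility uses
the Ertl–Schuffenhauer scorer shipped with RDKit; penalised logP is
`p_logP = logP − SA − n_largerings` with a "large ring" having more than 6
atoms.  Note two deliberately distinct ring definitions: the >6-atom count
inside p-logP versus the "very small or large cycle" descriptor (≤4 or ≥7
atoms) reported alongside the other 14 properties.

Surrogate predictors are MLPs (two hidden layers, 128/64) over the flattened
one-hot matrix.  Labels are z-scored for training and un-scaled at
prediction, so guidance gradients have comparable magnitude across
properties with very different ranges; the held-out (10%, seeded split)
Pearson r is reported after training.  At fixture scale the logP surrogate
reaches r ≈ 0.97 and the heavy-atom surrogate r ≈ 0.999.

Guidance maximises the signed-strength objective
`J(x_t) = Σ_k s_k ŷ_k(decode(x_t))` by modifying the predicted noise,

    ε̃ = ε̂ − √(1−ᾱ_t) · ∇_{x_t} J,

the classifier-guidance form; positive strengths push a property up.  Design
choices here, each of which had a plausible alternative:

* **Update rule.**  Gradients could equally be applied directly to the
  latent (`x_t ← x_t + η ∇J`); both forms are implemented (`mode="noise"`
  default, `mode="latent"` optional) since the noise-modification form has
  the cleaner closed-form algebra: for a linear latent predictor
  `ŷ(z) = w·z` the one-step shift is exactly `(β_t/√α_t)·s·w`, which the
  tests verify and which doubles with the strength.
* **Objective.**  A signed linear objective rather than squared error to a
  target value, matching increase/decrease semantics; predictors consume the
  decoder's relaxed probability rows (no straight-through estimator).
* **Stabilisation.**  Per-sample gradient clipping at norm 100 by default.
* **Multi-property combination.**  Plain sum of scaled gradients, no
  normalisation; term gradients are computed separately so additivity is
  exact and a non-finite gradient can be attributed to the offending term.

With an empty specification or all strengths zero the guided sampler is
bit-identical to the unguided one under the same seed (the fresh-noise
stream is drawn in the same order), which the tests assert exactly.

Guidance strengths are implementation-specific: their scale depends on the
predictor's z-scored output and the latent geometry, so absolute strength
values do not transfer between differently trained models.  The fixture
sweeps use ±5, chosen once from a development run of the fixture pipeline as
a strength that produces a clear shift without destabilising generation.

## Metrics and experiments

Identity is canonical-SMILES equality.  Novelty is the multiset fraction of
generated molecules absent from the training set; uniqueness the fraction of
distinct canonical SMILES; internal diversity `1 − mean pairwise Tanimoto`
over 2048-bit Morgan fingerprints of radius 2 (power 1; singleton sets score
0 by convention).  Distribution overlap with a reference set is quantified
by the per-property two-sample Kolmogorov–Smirnov distance, since graphical
overlap is not testable.

Sweeps run all strengths under one shared seed, so conditions are paired and
the zero-strength row is exactly unguided generation.  Desk-scale defaults
are 200 molecules per condition and 3–7 strengths; paper-scale values
(10,000 per condition) are reachable through configuration.  Multi-property
scenarios are projected with a joint 2-component PCA on 166-bit MACCS
fingerprints; component signs follow a fixed convention (largest-magnitude
loading positive) so coordinates are deterministic.  The reusable
drug-likeness filter keeps molecules with QED ≥ 0.6 whose rings all have
4–6 atoms.

At fixture scale the four logP/size quadrant scenarios reproduce the
expected pattern: three quadrants land on the intended side of the unguided
means, while the low-logP/high-atom-count quadrant is the hardest — large
organic molecules are predominantly lipophilic, so this combination fights
chemistry itself, and no numerical assertion is placed on it.

## Numerical and degenerate-input conventions

All randomness flows through explicitly seeded `numpy.random.Generator`
instances; no global state, no wall-clock-derived defaults, and training is
bit-reproducible given (data, config, seed).  Gradients from the internal
autodiff engine are verified against central finite differences.  Decoder
probability rows must sum to 1 within 1e-6; `ᾱ` tables match brute-force
products within 1e-12; schedule bounds require `0 < β_1 ≤ β_T < 1`.  T = 1
schedules, single-molecule metric sets, constant predictor labels (warning,
constant predictor), empty guidance specifications, and all-padding
decodings are all defined, tested cases rather than errors.

## Known limitations

* Sequence length and alphabet are frozen at vocabulary-build time;
  generation cannot exceed the longest training tokenisation.
* The codec covers neutral, stereochemistry-free molecules over six
  elements; charged or exotic-valence species are rejected on ingestion.
* Fixture-scale models (latent 32, T = 100, 500 molecules) demonstrate the
  mechanism; absolute metric values at this scale are not comparable to
  production-scale training, and guidance-strength values are not
  transferable between models.
* Docking-based objectives are supported only through the external label
  table path (smiles,value CSV); no docking engine is run.
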