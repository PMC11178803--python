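# Methods

## Model

`rxndkl` fits exact Gaussian-process regressions to reaction yields. The
observation model is y = f(x) + ε with ε ~ N(0, σ²) and a zero-mean GP
prior over f on *standardized* targets (yields are transformed to zero
mean/unit variance using constants computed on the training fold only, and
every prediction is transformed back, so callers always see percent yield).
The base covariance is Matérn-5/2 with one shared lengthscale (no ARD) and
a signal-variance (outputscale) factor:

    k(r) = outputscale · (1 + √5 r/ℓ + 5r²/(3ℓ²)) · exp(−√5 r/ℓ),

with r the Euclidean distance either between raw feature vectors
(`GaussianProcess`) or between neural embeddings (`DeepKernelGP`).

The deep kernel is k(g_φ(x_i), g_φ(x_j) | θ). Two extractor families:

* **FFNN** (vector inputs — fingerprints or descriptors): two fully
  connected layers, input → 256 → 64, ReLU, dropout 0.1 after each layer in
  training mode only.
* **MPNN** (molecular graphs): node states of width 64 initialized by a
  linear+tanh projection of atom features; T = 3 message rounds in which an
  edge network (bond features → 32 → 64×64 matrix) maps each neighbour
  state to a message, messages are summed and a GRU updates the node state;
  readout by M = 3 set2set processing steps (an LSTM-driven attention over
  node states), giving a 128-wide order-invariant graph vector; per-role
  graph vectors are summed (so the reaction embedding is invariant to
  reactant order) and passed through a 128→64 FFNN head with dropout 0.1.
  Weights are shared across the four roles.

All architecture sizes are configuration keys (`FFNNConfig`, `MPNNConfig`);
the defaults above were chosen once as standard sizes for this model family
and are not tuned per dataset.

## Training

The full Gaussian log marginal likelihood (with the ½ factors and the
n·log 2π constant, so values are comparable across training-set sizes) is
the single objective for every parameter:

* `GaussianProcess.fit` optimizes {ℓ, outputscale, σ²} with L-BFGS-B under
  a softplus positivity reparameterization; analytic gradients come from
  the closed form dℒ/dK = ½(ααᵀ − K⁻¹), α = K⁻¹y. Initial values ℓ = 1,
  outputscale = 1, σ² = 0.1 on the standardized scale. If the optimizer
  ends below the start point the initial state is returned instead.
* `DeepKernelGP.fit` optimizes {θ, φ, σ²} jointly with full-batch Adam
  (default 400 epochs, learning rate 0.001), backpropagating the same
  closed-form dℒ/dK through the kernel into every network weight via the
  in-package reverse-mode autodiff engine (`rxndkl.autodiff`). Full-batch
  training keeps the loss identical to exact-GP inference; there is no
  minibatching. Dropout is active only inside the training forward pass —
  whenever embeddings feed the GP for prediction, NLPD or acquisition the
  extractor runs in evaluation mode and is deterministic.

The `GNNRegressor` baseline shares the identical MPNN trunk (asserted in
tests) with a linear head and mean-squared-error loss; it produces point
predictions without variance.

## Numerical choices

* **Factorization**: Cholesky on K + σ²I, first with no jitter; on failure
  a jitter ladder 1e-8 → 1e-4 (×10 per step) is climbed, and exhaustion is
  a hard error reporting a condition estimate. Predictive variances are
  floored at 1e-12.
* **Differentiable kernel**: squared distances are clipped at zero and the
  square root is taken of r² + 1e-12 so the Gram diagonal stays
  differentiable; the relative error against the exact kernel is < 1e-11
  (the non-differentiable exact form is used for all prediction paths).
* **Positivity**: softplus reparameterization for ℓ, outputscale, σ².
* **NLPD** is the *mean* of −log N(tᵢ; μᵢ, σᵢ²) over test points, so values
  are comparable across test sizes; the summed form is available via
  `reduce="sum"`.
* **Split sizes**: floor(n·f_train) and floor(n·f_val), remainder to test;
  fixed and documented because any rounding rule is defensible.
* **Acquisition ties** break toward the lowest candidate index; the BO
  incumbent is the best *observed* acquired yield, the natural choice for a
  noiseless lookup benchmark. EI is computed on the original yield scale;
  since standardization is affine and EI's argmax is invariant under a
  common monotone rescaling of μ, σ and the incumbent, the selected
  candidate is identical either way.
* **Re-standardization**: the BO surrogate re-fits its standardizer on the
  acquired yields at every refit (each refit is from scratch; no warm
  start).

## Synthetic data

`synth_reaction_grid` emulates the structure of a combinatorial
cross-coupling screen: a full Cartesian grid over per-role component sets
(default 15 aryl halides × 4 ligands × 3 bases × 23 additives = 4140
reactions, optionally subsampled to mimic incomplete screens), with

    yield = clip(50 + Σ_role effect + I[aryl, additive] + ε, 0, 100),

main effects uniform on ±15/±10/±8/±15 yield points per role, interactions
I ~ N(0, strength²) sampled per (aryl halide, additive) pair — echoing the
chemistry, where additives poison specific substrates — and ε ~ N(0, 5²)
observation noise by default. Component SMILES are fixed packaged toy
vocabularies (substituted halogenated aromatics, phosphines, amines,
heteroaromatics) chosen to parse under any standard SMILES reader.

What the generator does **not** emulate: real yield mechanisms, the heavy
zero-inflation of experimental HTE yield distributions, correlated plate
effects, or realistic chemical similarity between components. Passing tests
therefore demonstrate that the machinery is correct and that representation
learning helps when component-pair interactions dominate — not that any
particular accuracy will transfer to a given experimental dataset.

`gp_draw_dataset` draws exactly from N(0, K + σ²I) for parameter-recovery
and oracle tests.

## Benchmark conditions used by tests and the acceptance script

* GP-vs-DKL comparison: 8×4×3×8 grid (768 reactions), interaction strength
  20, noise sd 5, Morgan features at 256 bits/component, 70:10:20 splits.
  The test suite runs 10 seeded splits; the acceptance script reports the
  mean over 3 for a faster single pass.
* BO benchmark: a 500-candidate pool (8×4×4×8 grid subsampled), 5%
  random initialization, 20 iterations; 50 trials for EI and random, 20 for
  the greedy-mean ablation, with a GP surrogate at 128 bits/component.
* Oracle equivalence: 100 random instances, n ≤ 20, d ≤ 8, tolerance 1e-8
  against explicit inverse/determinant formulas.

## Design decisions that were genuinely open

* The marginal likelihood is implemented as the complete Gaussian log
  density even where a proportional form (dropping ½ and the 2π constant)
  would suffice for optimization — comparability across n matters for the
  reported traces.
* NLPD as a mean rather than a sum (flagged: both conventions exist; the
  sum is one flag away).
* The DRFP-style reaction fingerprint enumerates canonical circular
  fragment SMILES up to the radius on each side of the reaction, takes the
  symmetric difference as *sets*, and hashes each survivor with the first 8
  bytes of SHA-1 — a fixed, platform-independent scheme. It mirrors the
  differential-fingerprint idea in spirit; bit-exact equality with other
  implementations is not promised and tests rely on structural properties
  (identity reactions hash to zero, reactant order irrelevant).
* Atom features: element one-hot over a configurable vocabulary (default
  C/N/O/F/P/S/Cl/Br/I + "other"), degree, formal charge, hybridization,
  aromaticity, attached-H count, chirality tag; bond features: type
  one-hot, conjugation, ring membership, stereo. Atoms are renumbered by
  canonical rank so equivalent SMILES writings give identical graphs.
* Leave-component-out splits hold out all reactions containing named
  component values for a role (a generic splitter; no attempt to reproduce
  any specific published split definition).
* R² is computed per run and then averaged across runs (pooling is the
  alternative convention).

## Known limitations

* Exact GP only: O(n³) factorizations cap practical training sizes at a
  few thousand reactions on one CPU; no sparse or approximate variants.
* One shared lengthscale (no ARD), single-output regression only.
* The autodiff engine implements exactly the operations this package needs;
  it is not a general-purpose framework.
* DKL training is seeded and bit-reproducible on one machine but, like any
  BLAS-dependent pipeline, not necessarily across platforms.
* The uncertainty-quality Spearman correlation on synthetic grids is weak —
  homoscedastic synthetic noise gives little error-rank signal — so it is
  reported, not asserted against.
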