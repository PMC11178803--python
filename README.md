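# rxndkl

Deep kernel learning for reaction-yield prediction with calibrated
uncertainty, and Bayesian optimization over discrete reaction candidate
pools.

## The problem

High-throughput experimentation screens combinatorial grids of reaction
conditions — for a Pd-catalysed C–N cross-coupling, every combination of
aryl halide, ligand, base and additive — and measures a percent yield for
each. Two modelling questions follow:

1. **Prediction with uncertainty.** Given a subset of measured reactions,
   predict the yield of the rest, with an honest error bar per prediction.
2. **Optimization.** Given a small budget of experiments, find the
   highest-yielding reaction in the pool with as few measurements as
   possible.

Standard Gaussian processes (GPs) give calibrated uncertainty but cannot
learn a representation from raw molecular inputs; neural networks learn
representations but not calibrated uncertainty. Deep kernel learning (DKL)
composes the two: a neural network g_φ maps each reaction representation
into an embedding space where a Matérn-5/2 base kernel k(·,·|θ) operates,

    k_DKL(x_i, x_j | θ, φ) = k(g_φ(x_i), g_φ(x_j) | θ),

and *all* parameters {θ, φ, σ²} are trained jointly by maximizing the exact
GP log marginal likelihood

    ℒ = −½ yᵀ(K_θ,φ + σ²I)⁻¹ y − ½ log|K_θ,φ + σ²I| − (n/2) log 2π.

Prediction uses the closed-form GP posterior on the embeddings (mean =
predicted yield, variance = its uncertainty), which in turn drives
expected-improvement (EI) Bayesian optimization:

    EI(x) = σ(x)·[z Φ(z) + φ(z)],   z = (μ(x) − f⁺)/σ(x),

with f⁺ the best yield observed so far.

Reaction representations supported: concatenated per-component Morgan
fingerprints (512 bits × 4 roles = 2048), a differential reaction
fingerprint (hashed symmetric difference of reactant/product circular
substructures, 2048 bits), concatenated per-component descriptor tables,
and molecular graphs processed by a message-passing network (edge-network
messages, GRU updates, set2set readout) with weights shared across roles.

Everything — including the reverse-mode autodiff engine the extractors are
trained with — is implemented in numpy/scipy inside this package; rdkit
handles the chemistry, scikit-learn/umap-learn the cluster analysis.

## Worked example

```python
import numpy as np
from rxndkl import (GridSpec, synth_reaction_grid, morgan_reaction_fp,
                    GaussianProcess, DeepKernelGP, DKLConfig,
                    SplitSpec, make_splits, regression_metrics)

# a synthetic 768-reaction grid with aryl-halide x additive interactions
rxns = synth_reaction_grid(GridSpec(counts=(8, 4, 3, 8),
                                    interaction_strength=20.0, noise_sd=5.0, seed=0))
X = morgan_reaction_fp(rxns, bits_per_component=256).values
y = np.array([r.yield_ for r in rxns])
train, _, test = make_splits(rxns, SplitSpec(seed=0))      # 70:10:20

gp = GaussianProcess(X[train], y[train]).fit()
print(regression_metrics(gp.predict(X[test]), y[test]))
# {'rmse': 7.21, 'mae': 5.77, 'r2': 0.90, 'nlpd': 3.38, 'spearman_rho': 0.27}

dkl = DeepKernelGP(X[train], y[train], extractor="ffnn",
                   config=DKLConfig(seed=0)).fit()          # 400 epochs, Adam lr 1e-3
print(regression_metrics(dkl.predict(X[test]), y[test]))
# {'rmse': 6.69, 'mae': 5.37, 'r2': 0.91, 'nlpd': 3.32, 'spearman_rho': 0.10}
```

The deep kernel cuts test RMSE from 7.21 to 6.69 yield points on this grid:
the learned embedding captures the aryl-halide × additive interaction
structure that a fixed kernel on raw fingerprints cannot. The NLPD
(negative log predictive density, mean per test point) measures uncertainty
quality; `spearman_rho` is the rank correlation between |error| and the
predictive standard deviation.

For optimization:

```python
from rxndkl import BOConfig, CandidatePool, run_bo, aggregate_traces
from rxndkl.bo import gp_surrogate

traces = [run_bo(CandidatePool(features=X, yields=y), gp_surrogate,
                 policy="ei", config=BOConfig(seed=s)) for s in range(50)]
print(aggregate_traces(traces).tail(1))
#     iteration  mean_incumbent  se_incumbent   (EI finds ~96% yield in 20 queries)
```

A command-line interface mirrors the library:

```bash
rxndkl synth --counts 8,4,3,8 --out grid.csv
rxndkl evaluate grid.csv --method dkl-ffnn --runs 10 --out metrics.csv
rxndkl bo grid.csv --policy ei --trials 50 --out-dir bo_out/
```

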