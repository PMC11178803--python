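"""Bayesian optimization over a discrete pool of candidate reactions.

The loop mirrors yield optimization on a lookup benchmark: a seeded random
5% of the pool initializes the surrogate, the remaining 95% is the held-out
candidate set, and for a fixed number of iterations (default 20) the
surrogate is refit on the acquired reactions, the acquisition function is
scored on the held-out set, the argmax candidate (lowest index on ties) is
revealed and moved to the acquired set.  Policies: expected improvement
(EI), greedy predictive mean, and uniform random selection.  Benchmarks are
aggregated over many independently initialized trials as the pointwise mean
incumbent-best curve with its standard error.

EI under a Gaussian posterior is EI = σ·(z·Φ(z) + φ(z)) with
z = (μ − f⁺)/σ, where f⁺ is the incumbent (best observed acquired yield);
at σ = 0 it degenerates to max(μ − f⁺, 0), so EI is zero whenever no
improvement is possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .gp import GaussianProcess, PredictiveDistribution

__all__ = [
    "BOConfig",
    "CandidatePool",
    "BOTrace",
    "expected_improvement",
    "run_bo",
    "aggregate_traces",
    "gp_surrogate",
]


@dataclass(frozen=True)
class BOConfig:
    """Loop settings: 5% random initialization, 20 iterations by default."""

    init_fraction: float = 0.05
    n_iterations: int = 20
    seed: int = 0


@dataclass
class CandidatePool:
    """Discrete benchmark pool with oracle yields revealed on acquisition."""

    features: np.ndarray
    yields: np.ndarray
    ids: list = None
    acquired: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.intp))

    def __post_init__(self):
        self.features = np.atleast_2d(np.asarray(self.features, dtype=np.float64))
        self.yields = np.asarray(self.yields, dtype=np.float64).ravel()
        if self.features.shape[0] != self.yields.size:
            raise ValueError("features rows and yields length mismatch")
        if self.ids is None:
            self.ids = list(range(self.yields.size))

    @property
    def n(self) -> int:
        return self.yields.size

    @property
    def heldout(self) -> np.ndarray:
        mask = np.ones(self.n, dtype=bool)
        mask[self.acquired] = False
        return np.flatnonzero(mask)


@dataclass
class BOTrace:
    """Per-iteration record of one BO trial.

    Row 0 summarizes initialization (no candidate chosen); the incumbent
    column is the best observed acquired yield and is non-decreasing.
    """

    chosen: list
    revealed: list
    incumbent: list
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(len(self.incumbent)),
                "candidate_id": self.chosen,
                "yield": self.revealed,
                "incumbent": self.incumbent,
            }
        ).assign(seed=self.seed)


def expected_improvement(pred: PredictiveDistribution, incumbent: float) -> np.ndarray:
    """Closed-form EI of each candidate over the incumbent best."""
    if np.any(pred.variance < 0):
        raise ValueError("negative predictive variance")
    mu = pred.mean
    sd = pred.sd
    ei = np.maximum(mu - incumbent, 0.0)  # σ = 0 limit
    pos = sd > 0
    z = (mu[pos] - incumbent) / sd[pos]
    ei_pos = sd[pos] * (z * norm.cdf(z) + norm.pdf(z))
    out = ei.copy()
    out[pos] = np.maximum(ei_pos, 0.0)
    return out


def gp_surrogate(X, y, seed):
    """Default surrogate: exact Matérn-5/2 GP, targets re-standardized each refit."""
    return GaussianProcess(X, y).fit()


def run_bo(
    pool: CandidatePool,
    surrogate_factory=gp_surrogate,
    policy: str = "ei",
    config: BOConfig = BOConfig(),
) -> BOTrace:
    """One seeded BO trial on a discrete pool; returns the full trace.

    The surrogate is refit from scratch on the acquired set at every
    iteration (the acquired yields are re-standardized each refit inside the
    model).  Acquisition argmax ties break toward the lowest candidate
    index.  ``policy="random"`` needs no surrogate and is plain sampling
    without replacement.
    """
    if policy not in ("ei", "greedy", "random"):
        raise ValueError(f"unknown policy {policy!r}")
    rng = np.random.default_rng(config.seed)
    n_init = max(2, int(round(pool.n * config.init_fraction)))
    if pool.n < n_init + config.n_iterations:
        raise ValueError("pool too small for init size + iterations")
    acquired = list(rng.choice(pool.n, size=n_init, replace=False))
    incumbent = float(pool.yields[acquired].max())
    trace = BOTrace(chosen=[None], revealed=[None], incumbent=[incumbent], seed=config.seed)
    for _ in range(config.n_iterations):
        heldout = np.setdiff1d(np.arange(pool.n), np.asarray(acquired, dtype=np.intp))
        if policy == "random":
            pick = int(rng.choice(heldout))
        else:
            fitted = surrogate_factory(pool.features[acquired], pool.yields[acquired], config.seed)
            pred = fitted.predict(pool.features[heldout])
            scores = pred.mean if policy == "greedy" else expected_improvement(pred, incumbent)
            pick = int(heldout[int(np.argmax(scores))])  # argmax -> lowest index on ties
        acquired.append(pick)
        y_new = float(pool.yields[pick])
        incumbent = max(incumbent, y_new)
        trace.chosen.append(pool.ids[pick])
        trace.revealed.append(y_new)
        trace.incumbent.append(incumbent)
    pool.acquired = np.asarray(acquired, dtype=np.intp)
    return trace


def aggregate_traces(traces: list[BOTrace]) -> pd.DataFrame:
    """Pointwise mean ± standard error of the incumbent curves across trials."""
    lengths = {len(t.incumbent) for t in traces}
    if len(lengths) != 1:
        raise ValueError(f"ragged traces: lengths {sorted(lengths)}")
    curves = np.array([t.incumbent for t in traces], dtype=np.float64)
    mean = curves.mean(axis=0)
    se = curves.std(axis=0, ddof=1) / np.sqrt(curves.shape[0]) if curves.shape[0] > 1 else np.zeros_like(mean)
    return pd.DataFrame(
        {"iteration": np.arange(curves.shape[1]), "mean_incumbent": mean, "se_incumbent": se}
    )
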