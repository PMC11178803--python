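"""Experimental protocol: splits, metrics, learning curves, cluster analysis.

Implements the repeated-evaluation procedure used for benchmarking yield
models: seeded 70:10:20 random train/validation/test splits (or
leave-component-out splits where every reaction containing a held-out
component value goes to the test set), target standardization fit on the
training fold only, RMSE / MAE / R² / NLPD / error–uncertainty Spearman ρ
per run, and mean ± standard error aggregation over runs and over a ladder
of training fractions.  A k-means summary of embedding space (after a
pluggable 2-D reduction) reports per-cluster sizes, median yields and
component composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.cluster import KMeans

from ._standardize import Standardizer, standardizer
from .gp import PredictiveDistribution, nlpd

__all__ = [
    "SplitSpec",
    "make_splits",
    "standardizer",
    "Standardizer",
    "regression_metrics",
    "repeated_evaluation",
    "cluster_summary",
    "DEFAULT_FRACTION_LADDER",
]

#: train-fraction ladder for learning curves (train share of the data)
DEFAULT_FRACTION_LADDER = (0.8, 0.7, 0.5, 0.3, 0.2, 0.1, 0.05)


@dataclass(frozen=True)
class SplitSpec:
    """Random or leave-component-out split specification.

    Random mode: sizes are floor(n·f_train), floor(n·f_val), remainder to
    test.  Leave-out mode: every reaction whose ``component_role`` value is
    in ``held_out`` goes to test; train/val are drawn from the rest using
    the train:val ratio.
    """

    mode: str = "random"
    fractions: tuple = (0.7, 0.1, 0.2)
    seed: int = 0
    component_role: str | None = None
    held_out: tuple = ()

    def __post_init__(self):
        if self.mode not in ("random", "leave_component_out"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        f = np.asarray(self.fractions, dtype=float)
        if f.size != 3 or np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9 or f[0] <= 0 or f[2] < 0:
            raise ValueError(f"fractions must be non-negative and sum to 1, got {self.fractions}")
        if self.mode == "leave_component_out" and (self.component_role is None or not self.held_out):
            raise ValueError("leave_component_out mode needs component_role and held_out values")


def make_splits(reactions, spec: SplitSpec):
    """Deterministic (train, val, test) index arrays for a reaction list."""
    n = len(reactions)
    rng = np.random.default_rng(spec.seed)
    if spec.mode == "random":
        if n < 10:
            raise ValueError("random splitting requires n >= 10")
        perm = rng.permutation(n)
        n_train = int(np.floor(n * spec.fractions[0]))
        n_val = int(np.floor(n * spec.fractions[1]))
        train, val, test = perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :]
    else:
        held = set(spec.held_out)
        values = [r.components.get(spec.component_role) for r in reactions]
        if not held.issubset(values):
            missing = held - set(values)
            raise ValueError(f"held-out values not present in table: {sorted(missing)}")
        test = np.array([i for i, v in enumerate(values) if v in held], dtype=np.intp)
        rest = np.array([i for i, v in enumerate(values) if v not in held], dtype=np.intp)
        rest = rest[rng.permutation(rest.size)]
        f_train, f_val = spec.fractions[0], spec.fractions[1]
        n_train = int(np.floor(rest.size * f_train / (f_train + f_val)))
        train, val = rest[:n_train], rest[n_train:]
    if train.size == 0 or test.size == 0:
        raise ValueError("split produced an empty train or test set")
    return np.sort(train), np.sort(val), np.sort(test)


def save_split_indices(prefix, train, val, test) -> None:
    """Write the three index sets as plain-text files (one index per line)."""
    for name, idx in (("train", train), ("val", val), ("test", test)):
        np.savetxt(f"{prefix}.{name}.idx", np.asarray(idx, dtype=np.intp), fmt="%d")


def load_split_indices(prefix):
    """Read back index files written by :func:`save_split_indices`."""
    return tuple(
        np.loadtxt(f"{prefix}.{name}.idx", dtype=np.intp).reshape(-1)
        for name in ("train", "val", "test")
    )


def regression_metrics(pred: PredictiveDistribution, targets) -> dict:
    """Per-run metric row: RMSE, MAE, R², NLPD and error–uncertainty ρ.

    R² = 1 − SSE/SST with SST about the target mean; ρ is the Spearman rank
    correlation between |error| and predictive standard deviation (average
    ranks for ties).
    """
    t = np.asarray(targets, dtype=np.float64).ravel()
    if t.size != len(pred):
        raise ValueError("length mismatch between predictions and targets")
    err = pred.mean - t
    sst = np.sum((t - t.mean()) ** 2)
    if sst == 0:
        raise ValueError("R^2 undefined for zero-variance targets")
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    r2 = float(1.0 - np.sum(err**2) / sst)
    abs_err = np.abs(err)
    if np.allclose(abs_err, abs_err[0]) or np.allclose(pred.sd, pred.sd[0]):
        rho = 0.0
    else:
        rho = float(spearmanr(abs_err, pred.sd).statistic)
    return {
        "rmse": rmse,
        "mae": mae,
        "r2": r2,
        "nlpd": nlpd(pred, t),
        "spearman_rho": rho,
    }


def _aggregate(df: pd.DataFrame, by) -> pd.DataFrame:
    """Mean ± standard error of each metric over runs."""
    g = df.groupby(by, sort=False)
    mean = g.mean(numeric_only=True)
    se = g.sem(numeric_only=True, ddof=1).fillna(0.0)
    out = mean.join(se, lsuffix="_mean", rsuffix="_se")
    return out.reset_index()


def repeated_evaluation(
    model_factory,
    X,
    y,
    n_runs: int = 10,
    fractions=None,
    val_fraction: float = 0.1,
    base_seed: int = 0,
    reactions=None,
):
    """Run the split → fit → predict → metrics protocol over seeds and fractions.

    ``model_factory(X_train, y_train, seed)`` must return a fitted object
    with ``predict(X_test) -> PredictiveDistribution`` (model classes in this
    package standardize on their own training targets, matching the
    protocol).  ``fractions`` is the ladder of train shares (default: the
    single 0.7 entry of the 70:10:20 split); the remainder after the
    validation share goes to test.  Run seeds are ``base_seed + run_index``.

    Returns ``(per_run_df, aggregate_df)``; failed runs are recorded with
    NaN metrics and skipped in the aggregate.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    X = np.atleast_2d(np.asarray(X, dtype=np.float64)) if not isinstance(X, list) else X
    y = np.asarray(y, dtype=np.float64).ravel()
    items = reactions if reactions is not None else [None] * y.size
    fractions = (0.7,) if fractions is None else tuple(fractions)
    rows = []
    for frac in fractions:
        test_frac = max(1.0 - frac - val_fraction, 0.0)
        for run in range(n_runs):
            seed = base_seed + run
            spec = SplitSpec(mode="random", fractions=(frac, val_fraction, test_frac), seed=seed)
            tr, va, te = make_splits(items, spec)
            row = {"train_fraction": frac, "run": run, "seed": seed,
                   "n_train": tr.size, "n_test": te.size}
            try:
                Xtr = [X[i] for i in tr] if isinstance(X, list) else X[tr]
                Xte = [X[i] for i in te] if isinstance(X, list) else X[te]
                fitted = model_factory(Xtr, y[tr], seed)
                row.update(regression_metrics(fitted.predict(Xte), y[te]))
            except Exception as e:  # noqa: BLE001 - recorded, not fatal
                row.update({"rmse": np.nan, "mae": np.nan, "r2": np.nan,
                            "nlpd": np.nan, "spearman_rho": np.nan, "error": str(e)})
            rows.append(row)
    per_run = pd.DataFrame(rows)
    ok = per_run.dropna(subset=["rmse"])
    agg = _aggregate(
        ok[["train_fraction", "rmse", "mae", "r2", "nlpd", "spearman_rho"]], "train_fraction"
    )
    return per_run, agg


def _pca_2d(embeddings: np.ndarray) -> np.ndarray:
    centered = embeddings - embeddings.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return centered @ vt[:2].T


def cluster_summary(embeddings, yields, k: int = 4, reducer=None, components=None, seed: int = 0):
    """k-means summary of a 2-D reduction of embedding space.

    ``reducer`` maps an (n, d) matrix to (n, 2); by default UMAP is used if
    installed, otherwise a PCA projection (the reduction algorithm is
    injected, not part of the method).  Returns ``(summary_df, labels)``
    where the summary has one row per cluster with its size, median yield
    and — when ``components`` (list of role→value dicts) is given — the
    distinct per-role component values present.
    """
    Z = np.atleast_2d(np.asarray(embeddings, dtype=np.float64))
    yld = np.asarray(yields, dtype=np.float64).ravel()
    if Z.shape[0] != yld.size:
        raise ValueError("embeddings rows and yields length mismatch")
    if not (1 <= k <= Z.shape[0]):
        raise ValueError(f"k={k} out of range for n={Z.shape[0]}")
    if reducer is None:
        try:
            import umap  # noqa: PLC0415 - optional heavy import

            reducer = umap.UMAP(n_components=2, random_state=seed).fit_transform
        except ImportError:
            reducer = _pca_2d
    coords = np.asarray(reducer(Z), dtype=np.float64)
    if coords.shape != (Z.shape[0], 2):
        raise ValueError("reducer must return an (n, 2) array")
    labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(coords)
    rows = []
    for c in range(k):
        mask = labels == c
        row = {"cluster": c, "size": int(mask.sum()), "median_yield": float(np.median(yld[mask]))}
        if components is not None:
            roles = components[0].keys()
            for role in roles:
                row[role] = sorted({components[i][role] for i in np.flatnonzero(mask)})
        rows.append(row)
    return pd.DataFrame(rows), labels
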