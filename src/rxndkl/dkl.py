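"""Deep kernel learning: neural extractor + exact GP, trained end to end.

The deep kernel is k_DKL(x_i, x_j | θ, φ) = k(g_φ(x_i), g_φ(x_j) | θ): a
neural network g_φ maps each reaction representation into an embedding space
where a Matérn-5/2 base kernel with hyperparameters θ operates.  All
parameters {θ, φ, σ²} are learned jointly by maximizing the full-batch GP
log marginal likelihood with Adam (defaults: 400 epochs, learning rate
0.001).  Prediction runs the extractor in evaluation mode (dropout off) and
the closed-form GP posterior on the embeddings; means and variances are
returned on the original yield scale.

:class:`DeepKernelGP` follows the Model/Results convention: construct from
features (or molecular graphs) and yields, call :meth:`~DeepKernelGP.fit`,
get a :class:`DKLResults` with predictions, the marginal-likelihood trace
and a summary table.  :class:`GNNRegressor` is the uncertainty-free baseline
sharing the identical MPNN trunk with a linear regression head.
"""

from __future__ import annotations

import io
import json

import numpy as np

from . import autodiff as ad
from ._standardize import Standardizer
from .featurize import DEFAULT_ROLES, GraphFeatureConfig, morgan_reaction_fp, reactions_to_graphs
from .gp import _JITTERS, GPState, KernelParams, PredictiveDistribution, matern52_gram_ad, posterior_predict
from .nn import Adam, BatchedGraphs, FFNNConfig, FFNNExtractor, MPNNConfig, MPNNExtractor, batch_reactions

__all__ = [
    "DKLConfig",
    "IdentityExtractor",
    "DeepKernelGP",
    "DKLResults",
    "GNNRegressor",
    "GNNResults",
    "train_dkl",
    "dkl_predict",
]


class DKLConfig:
    """Training configuration for the joint extractor+GP optimization."""

    def __init__(self, epochs: int = 400, lr: float = 1e-3, seed: int = 0,
                 init_kernel: KernelParams | None = None):
        self.epochs = int(epochs)
        self.lr = float(lr)
        self.seed = int(seed)
        self.init_kernel = init_kernel or KernelParams(1.0, 1.0, 0.1)


class IdentityExtractor:
    """Pass-through extractor: the deep kernel collapses to the base GP."""

    def __init__(self):
        self.params = {}

    def parameters(self):
        return []

    def zero_grad(self):
        pass

    def extract(self, X, rng=None) -> ad.Tensor:
        return X if isinstance(X, ad.Tensor) else ad.Tensor(np.atleast_2d(np.asarray(X, float)))

    def state_dict(self):
        return {}

    def load_state_dict(self, state):
        pass


def _raw_kernel_tensor(init: KernelParams) -> ad.Tensor:
    vals = np.array([init.lengthscale, init.outputscale, init.noise])
    raw = vals + np.log1p(-np.exp(-np.maximum(vals, 1e-12)))
    return ad.Tensor(raw, requires_grad=True, name="raw_kernel")


def _lml_with_jitter(Kn: ad.Tensor, y: np.ndarray) -> ad.Tensor:
    n = Kn.shape[0]
    for jit in _JITTERS:
        try:
            return ad.gaussian_lml(Kn + jit * np.eye(n) if jit else Kn, y)
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("Gram factorization failed after jitter ladder")


class DeepKernelGP:
    """Deep kernel GP regression model.

    Parameters
    ----------
    X : array-like (n, d) or list of role→MolecularGraph dicts
        Training representations.  Vectors go with ``extractor="ffnn"`` (or
        ``"identity"``), graph maps with ``extractor="mpnn"``.
    y : array-like (n,)
        Percent yields; standardized internally (constants kept on the model).
    extractor : {"ffnn", "mpnn", "identity"}
    config : DKLConfig
    ffnn_config, mpnn_config
        Architecture overrides; sensible defaults are derived from the data.
    """

    def __init__(self, X, y, extractor: str = "ffnn", config: DKLConfig | None = None,
                 ffnn_config: FFNNConfig | None = None, mpnn_config: MPNNConfig | None = None,
                 roles=DEFAULT_ROLES, standardize: bool = True):
        y = np.asarray(y, dtype=np.float64).ravel()
        if y.size < 10 and extractor != "identity":
            raise ValueError("deep kernel training requires at least 10 reactions")
        self.kind = extractor
        self.roles = tuple(roles)
        self.config = config or DKLConfig()
        self.scaler = Standardizer.fit(y) if standardize else Standardizer(0.0, 1.0)
        self.y = y
        self.y_std = self.scaler.transform(y)
        rng = np.random.default_rng(self.config.seed)
        if extractor in ("ffnn", "identity"):
            self.train_X = np.atleast_2d(np.asarray(X, dtype=np.float64))
            if self.train_X.shape[0] != y.size:
                raise ValueError("X rows and y length must match")
            if extractor == "ffnn":
                self.ffnn_config = ffnn_config or FFNNConfig(input_width=self.train_X.shape[1])
                if self.ffnn_config.input_width != self.train_X.shape[1]:
                    raise ValueError("ffnn_config input width does not match data")
                self.extractor = FFNNExtractor(self.ffnn_config, rng)
            else:
                self.extractor = IdentityExtractor()
            self._train_input = self.train_X
        elif extractor == "mpnn":
            self.graph_maps = list(X)
            if len(self.graph_maps) != y.size:
                raise ValueError("graph list and y length must match")
            g0 = self.graph_maps[0][self.roles[0]]
            self.mpnn_config = mpnn_config or MPNNConfig(
                node_width=g0.node_features.shape[1], edge_width=g0.edge_features.shape[1]
            )
            self.extractor = MPNNExtractor(self.mpnn_config, rng)
            self._train_input = batch_reactions(self.graph_maps, self.roles)
        else:
            raise ValueError(f"unknown extractor {extractor!r}")

    # ------------------------------------------------------------ constructors
    @classmethod
    def from_reactions(cls, reactions, featurizer: str = "morgan", roles=DEFAULT_ROLES,
                       radius: int = 2, bits_per_component: int = 512, fp_mode: str = "concat",
                       graph_config: GraphFeatureConfig = GraphFeatureConfig(), **kwargs):
        """Build the model straight from :class:`~rxndkl.featurize.Reaction` records."""
        y = [r.yield_ for r in reactions]
        if featurizer == "morgan":
            fm = morgan_reaction_fp(reactions, radius=radius,
                                    bits_per_component=bits_per_component, mode=fp_mode, roles=roles)
            model = cls(fm.values, y, extractor="ffnn", roles=roles, **kwargs)
            model.featurizer_tag = fm.featurizer_tag
        elif featurizer == "graph":
            graphs = reactions_to_graphs(reactions, roles=roles, config=graph_config)
            model = cls(graphs, y, extractor="mpnn", roles=roles, **kwargs)
            model.featurizer_tag = "graph"
        else:
            raise ValueError(f"unknown featurizer {featurizer!r}")
        return model

    # ------------------------------------------------------------------- fit
    def fit(self, epochs: int | None = None, lr: float | None = None,
            seed: int | None = None, callback=None) -> "DKLResults":
        """Jointly optimize {θ, φ, σ²} on the full-batch log marginal likelihood.

        Deterministic for a fixed seed (weight init and dropout masks both
        derive from it).  Raises with the offending epoch if the loss goes
        non-finite.
        """
        cfg = self.config
        epochs = cfg.epochs if epochs is None else int(epochs)
        lr = cfg.lr if lr is None else float(lr)
        seed = cfg.seed if seed is None else int(seed)
        raw_kernel = _raw_kernel_tensor(cfg.init_kernel)
        opt = Adam(self.extractor.parameters() + [raw_kernel], lr=lr)
        dropout_rng = np.random.default_rng((seed, 0x5eed))
        trace = np.empty(epochs)
        for epoch in range(epochs):
            opt.zero_grad()
            raw_kernel.zero_grad()
            Z = self.extractor.extract(self._train_input, rng=dropout_rng)
            pos = ad.softplus(raw_kernel)
            K = matern52_gram_ad(Z, pos[0], pos[1])
            Kn = K + ad.mul(ad.Tensor(np.eye(Z.shape[0])), ad.reshape(pos[2], (1, 1)))
            lml = _lml_with_jitter(Kn, self.y_std)
            if not np.isfinite(lml.value):
                raise RuntimeError(f"non-finite marginal likelihood at epoch {epoch}")
            trace[epoch] = float(lml.value)
            # seed with -1 so accumulated grads are those of the loss (-LML)
            lml.backward(np.asarray(-1.0))
            opt.step()
            if callback is not None:
                callback(epoch, float(lml.value))
        sp = np.logaddexp(0.0, raw_kernel.value)
        params = KernelParams(lengthscale=float(sp[0]), outputscale=float(sp[1]), noise=float(sp[2]))
        return DKLResults(self, params, trace)


class DKLResults:
    """Fitted deep kernel GP: embeddings, posterior prediction, diagnostics."""

    def __init__(self, model: DeepKernelGP, params: KernelParams, lml_trace: np.ndarray):
        self.model = model
        self.params = params
        self.lml_trace = np.asarray(lml_trace, dtype=np.float64)
        self.llf = float(self.lml_trace[-1]) if self.lml_trace.size else np.nan
        Z_train = self.embed_train()
        self.state = GPState(Z_train, model.y_std, params)

    # ----------------------------------------------------------- embeddings
    def embed_train(self) -> np.ndarray:
        return self.model.extractor.extract(self.model._train_input, rng=None).value

    def embed(self, X) -> np.ndarray:
        """Evaluation-mode embeddings of new inputs (latent space of Fig.-5 style analysis)."""
        return self.model.extractor.extract(self._prepare(X), rng=None).value

    def _prepare(self, X):
        if self.model.kind == "mpnn":
            if isinstance(X, BatchedGraphs):
                return X
            return batch_reactions(list(X), self.model.roles)
        return np.atleast_2d(np.asarray(X, dtype=np.float64))

    # ----------------------------------------------------------- prediction
    def predict(self, X) -> PredictiveDistribution:
        """GP posterior on embeddings, de-standardized to percent yield."""
        pred = posterior_predict(self.state, self.embed(X))
        return PredictiveDistribution(
            mean=self.model.scaler.inverse(pred.mean),
            variance=self.model.scaler.inverse_variance(pred.variance),
            scale_tag="original",
        )

    def summary(self) -> str:
        buf = io.StringIO()
        m = self.model
        buf.write("Deep Kernel GP Regression\n")
        buf.write("=" * 50 + "\n")
        buf.write(f"{'Extractor:':<28}{m.kind}\n")
        buf.write(f"{'No. observations:':<28}{m.y.size}\n")
        n_weights = sum(p.value.size for p in m.extractor.parameters())
        buf.write(f"{'Extractor parameters:':<28}{n_weights}\n")
        buf.write(f"{'Epochs / final LML:':<28}{self.lml_trace.size} / {self.llf:.4f}\n")
        buf.write(f"{'Lengthscale:':<28}{self.params.lengthscale:.4f}\n")
        buf.write(f"{'Outputscale:':<28}{self.params.outputscale:.4f}\n")
        buf.write(f"{'Noise variance:':<28}{self.params.noise:.4f}\n")
        return buf.getvalue()

    # -------------------------------------------------------------- persist
    def save(self, path: str) -> None:
        """Versioned checkpoint: architecture, weights, kernel, standardizer."""
        meta = {
            "version": 1,
            "kind": self.model.kind,
            "roles": list(self.model.roles),
            "kernel": [self.params.lengthscale, self.params.outputscale, self.params.noise],
            "scaler": [self.model.scaler.mean, self.model.scaler.sd],
            "featurizer_tag": getattr(self.model, "featurizer_tag", None),
        }
        arrays = {f"w_{k}": v for k, v in self.model.extractor.state_dict().items()}
        np.savez(path, meta=json.dumps(meta), lml_trace=self.lml_trace, **arrays)


def train_dkl(X, y, extractor: str = "ffnn", config: DKLConfig | None = None, **kwargs) -> DKLResults:
    """Functional wrapper: build a :class:`DeepKernelGP` and fit it."""
    return DeepKernelGP(X, y, extractor=extractor, config=config, **kwargs).fit()


def dkl_predict(results: DKLResults, X) -> PredictiveDistribution:
    """Posterior predictive distribution on the original yield scale."""
    return results.predict(X)


class GNNRegressor:
    """Stand-alone GNN baseline: identical MPNN trunk, linear head, MSE loss.

    Produces point predictions only — no predictive variance — which is the
    comparison case for the uncertainty-carrying deep kernel model.
    """

    def __init__(self, graph_maps, y, config: DKLConfig | None = None,
                 mpnn_config: MPNNConfig | None = None, roles=DEFAULT_ROLES):
        self.roles = tuple(roles)
        self.config = config or DKLConfig()
        y = np.asarray(y, dtype=np.float64).ravel()
        self.scaler = Standardizer.fit(y)
        self.y_std = self.scaler.transform(y)
        g0 = graph_maps[0][self.roles[0]]
        self.mpnn_config = mpnn_config or MPNNConfig(
            node_width=g0.node_features.shape[1], edge_width=g0.edge_features.shape[1]
        )
        rng = np.random.default_rng(self.config.seed)
        self.trunk = MPNNExtractor(self.mpnn_config, rng)
        self.head_W = ad.Tensor(np.zeros((self.mpnn_config.embedding, 1)), requires_grad=True)
        self.head_b = ad.Tensor(np.zeros(1), requires_grad=True)
        self._batch = batch_reactions(list(graph_maps), self.roles)

    def fit(self, epochs: int | None = None, lr: float | None = None) -> "GNNResults":
        epochs = self.config.epochs if epochs is None else int(epochs)
        lr = self.config.lr if lr is None else float(lr)
        params = self.trunk.parameters() + [self.head_W, self.head_b]
        opt = Adam(params, lr=lr)
        dropout_rng = np.random.default_rng((self.config.seed, 0x6e6e))
        losses = np.empty(epochs)
        n = self.y_std.size
        for epoch in range(epochs):
            opt.zero_grad()
            emb = self.trunk.extract(self._batch, rng=dropout_rng)
            pred = ad.reshape(emb @ self.head_W + self.head_b, (-1,))
            err = pred - ad.Tensor(self.y_std)
            loss = ad.mul(ad.tsum(ad.mul(err, err)), 1.0 / n)
            if not np.isfinite(loss.value):
                raise RuntimeError(f"non-finite loss at epoch {epoch}")
            losses[epoch] = float(loss.value)
            loss.backward()
            opt.step()
        return GNNResults(self, losses)


class GNNResults:
    """Fitted GNN baseline; `predict` returns point estimates (no variance)."""

    def __init__(self, model: GNNRegressor, loss_trace: np.ndarray):
        self.model = model
        self.loss_trace = loss_trace

    def predict(self, graph_maps) -> np.ndarray:
        batch = graph_maps if isinstance(graph_maps, BatchedGraphs) else batch_reactions(
            list(graph_maps), self.model.roles
        )
        emb = self.model.trunk.extract(batch, rng=None)
        pred = (emb @ self.model.head_W + self.model.head_b).value.ravel()
        return self.model.scaler.inverse(pred)
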