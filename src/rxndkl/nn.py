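"""Neural feature extractors for the deep kernel.

Two extractor families map reactions to the embedding space the GP kernel
operates on:

* :class:`FFNNExtractor` — two fully connected layers (ReLU, dropout 0.1 in
  training mode) on a fixed-width vector representation (fingerprints or
  descriptors);
* :class:`MPNNExtractor` — a message-passing network on molecular graphs: an
  edge network conditions each message on bond features, a gated recurrent
  unit updates node states over T rounds, a set2set model pools node states
  into an order-invariant graph vector, per-role graph vectors are summed
  into a reaction vector (invariant to reactant order) and passed through
  the same two-layer FFNN head.

Everything is expressed with the in-package autodiff tensors so the GP
marginal likelihood can backpropagate into every weight.  Weights are stored
as plain arrays in named dicts; initialization is Glorot-uniform from a
caller-provided seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .featurize import MolecularGraph, GraphFeatureConfig

__all__ = [
    "FFNNConfig",
    "MPNNConfig",
    "FFNNExtractor",
    "MPNNExtractor",
    "BatchedGraphs",
    "Adam",
]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


@dataclass(frozen=True)
class FFNNConfig:
    """Two-layer feed-forward extractor: input → hidden → embedding."""

    input_width: int
    hidden: int = 256
    embedding: int = 64
    dropout: float = 0.1


@dataclass(frozen=True)
class MPNNConfig:
    """Message-passing extractor sizes.

    ``hidden`` is the node-state width; ``message_steps`` (T) the number of
    message-passing rounds; ``set2set_steps`` (M) the number of set2set
    processing steps.  The reaction-level FFNN head takes the summed 2·hidden
    set2set vector to ``embedding``.
    """

    node_width: int
    edge_width: int
    hidden: int = 64
    message_steps: int = 3
    set2set_steps: int = 3
    edge_hidden: int = 32
    head_hidden: int = 128
    embedding: int = 64
    dropout: float = 0.1


class _Module:
    """Named-parameter container with flat access for the optimizer."""

    def __init__(self):
        self.params: dict[str, ad.Tensor] = {}

    def _add(self, name: str, value: np.ndarray) -> ad.Tensor:
        t = ad.Tensor(value, requires_grad=True, name=name)
        self.params[name] = t
        return t

    def parameters(self) -> list[ad.Tensor]:
        return list(self.params.values())

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()

    def state_dict(self) -> dict:
        return {k: v.value.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        for k, t in self.params.items():
            t.value = np.asarray(state[k], dtype=np.float64).reshape(t.value.shape)


class FFNNExtractor(_Module):
    """g_φ: two affine layers with ReLU; dropout active only in train mode."""

    def __init__(self, config: FFNNConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        c = config
        self._add("W1", _glorot(rng, c.input_width, c.hidden))
        self._add("b1", np.zeros(c.hidden))
        self._add("W2", _glorot(rng, c.hidden, c.embedding))
        self._add("b2", np.zeros(c.embedding))

    def extract(self, X, rng: np.random.Generator | None = None) -> ad.Tensor:
        """Embed an (n, input_width) matrix; pass ``rng`` to enable dropout."""
        x = X if isinstance(X, ad.Tensor) else ad.Tensor(np.atleast_2d(np.asarray(X, float)))
        if x.shape[1] != self.config.input_width:
            raise ValueError(f"input width {x.shape[1]} != configured {self.config.input_width}")
        h = ad.relu(x @ self.params["W1"] + self.params["b1"])
        h = ad.dropout(h, self.config.dropout, rng)
        out = h @ self.params["W2"] + self.params["b2"]
        return ad.dropout(out, self.config.dropout, rng)


@dataclass
class BatchedGraphs:
    """Disjoint union of molecular graphs for vectorized message passing.

    Each undirected bond is expanded into two directed arcs so messages flow
    both ways.  ``graph_ids`` assigns every node to its source graph;
    ``reaction_ids`` (optional) assigns every graph to a reaction.
    """

    node_features: np.ndarray
    arc_src: np.ndarray
    arc_dst: np.ndarray
    arc_features: np.ndarray
    graph_ids: np.ndarray
    n_graphs: int
    reaction_ids: np.ndarray | None = None
    n_reactions: int = 0

    @classmethod
    def from_graphs(cls, graphs: list[MolecularGraph], reaction_ids=None, n_reactions: int = 0):
        nodes, srcs, dsts, afeats, gids = [], [], [], [], []
        offset = 0
        for gi, g in enumerate(graphs):
            nodes.append(g.node_features)
            gids.append(np.full(g.n_atoms, gi))
            if g.edges.size:
                u, v = g.edges[:, 0] + offset, g.edges[:, 1] + offset
                srcs.extend((u, v))
                dsts.extend((v, u))
                afeats.extend((g.edge_features, g.edge_features))
            offset += g.n_atoms
        ew = graphs[0].edge_features.shape[1] if graphs else 0
        return cls(
            node_features=np.concatenate(nodes, axis=0),
            arc_src=np.concatenate(srcs) if srcs else np.zeros(0, dtype=np.intp),
            arc_dst=np.concatenate(dsts) if dsts else np.zeros(0, dtype=np.intp),
            arc_features=np.concatenate(afeats, axis=0) if afeats else np.zeros((0, ew)),
            graph_ids=np.concatenate(gids),
            n_graphs=len(graphs),
            reaction_ids=None if reaction_ids is None else np.asarray(reaction_ids, dtype=np.intp),
            n_reactions=n_reactions,
        )


class MPNNExtractor(_Module):
    """Graph extractor: edge-network messages, GRU updates, set2set readout.

    Weights are shared across all reaction roles; the reaction embedding is
    the role-wise sum of graph vectors followed by the FFNN head, which makes
    it invariant to both node order and role order by construction.
    """

    def __init__(self, config: MPNNConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        c = config
        h = c.hidden
        self._add("W_in", _glorot(rng, c.node_width, h))
        self._add("b_in", np.zeros(h))
        # edge network: bond features -> h*h message transform
        self._add("We1", _glorot(rng, c.edge_width, c.edge_hidden))
        self._add("be1", np.zeros(c.edge_hidden))
        self._add("We2", _glorot(rng, c.edge_hidden, h * h))
        self._add("be2", np.zeros(h * h))
        # GRU update gates
        for gate in ("z", "r", "n"):
            self._add(f"W{gate}", _glorot(rng, h, h))
            self._add(f"U{gate}", _glorot(rng, h, h))
            self._add(f"bg{gate}", np.zeros(h))
        # set2set LSTM: input 2h, hidden h
        self._add("Wl", _glorot(rng, 2 * h, 4 * h))
        self._add("Ul", _glorot(rng, h, 4 * h))
        self._add("bl", np.zeros(4 * h))
        # reaction-level FFNN head on the summed 2h set2set vector
        self._add("Wh1", _glorot(rng, 2 * h, c.head_hidden))
        self._add("bh1", np.zeros(c.head_hidden))
        self._add("Wh2", _glorot(rng, c.head_hidden, c.embedding))
        self._add("bh2", np.zeros(c.embedding))

    # ------------------------------------------------------------- internals
    def _message_passing(self, batch: BatchedGraphs) -> ad.Tensor:
        p = self.params
        h_dim = self.config.hidden
        h = ad.tanh(ad.Tensor(batch.node_features) @ p["W_in"] + p["b_in"])
        if batch.arc_src.size == 0 or self.config.message_steps == 0:
            return h
        e_hidden = ad.relu(ad.Tensor(batch.arc_features) @ p["We1"] + p["be1"])
        A = ad.reshape(e_hidden @ p["We2"] + p["be2"], (-1, h_dim, h_dim))
        n_nodes = batch.node_features.shape[0]
        for _ in range(self.config.message_steps):
            h_src = ad.gather(h, batch.arc_src)
            msg = ad.tsum(ad.mul(A, ad.reshape(h_src, (-1, 1, h_dim))), axis=2)
            m = ad.segment_sum(msg, batch.arc_dst, n_nodes)
            z = ad.sigmoid(m @ p["Wz"] + h @ p["Uz"] + p["bgz"])
            r = ad.sigmoid(m @ p["Wr"] + h @ p["Ur"] + p["bgr"])
            n_t = ad.tanh(m @ p["Wn"] + ad.mul(r, h @ p["Un"]) + p["bgn"])
            h = ad.add(ad.mul(1.0 - z, n_t), ad.mul(z, h))
        return h

    def _set2set(self, h: ad.Tensor, batch: BatchedGraphs) -> ad.Tensor:
        p = self.params
        hd = self.config.hidden
        ng = batch.n_graphs
        q = ad.Tensor(np.zeros((ng, hd)))
        c = ad.Tensor(np.zeros((ng, hd)))
        q_star = ad.Tensor(np.zeros((ng, 2 * hd)))
        for _ in range(self.config.set2set_steps):
            gates = q_star @ p["Wl"] + q @ p["Ul"] + p["bl"]
            gi = ad.sigmoid(ad.gather(gates.T, slice(0, hd)).T)
            gf = ad.sigmoid(ad.gather(gates.T, slice(hd, 2 * hd)).T)
            gg = ad.tanh(ad.gather(gates.T, slice(2 * hd, 3 * hd)).T)
            go = ad.sigmoid(ad.gather(gates.T, slice(3 * hd, 4 * hd)).T)
            c = ad.add(ad.mul(gf, c), ad.mul(gi, gg))
            q = ad.mul(go, ad.tanh(c))
            energy = ad.tsum(ad.mul(h, ad.gather(q, batch.graph_ids)), axis=1)
            a = ad.segment_softmax(energy, batch.graph_ids, ng)
            r = ad.segment_sum(ad.mul(h, ad.reshape(a, (-1, 1))), batch.graph_ids, ng)
            q_star = ad.concat([q, r], axis=1)
        return q_star

    def extract(self, batch: BatchedGraphs, rng: np.random.Generator | None = None) -> ad.Tensor:
        """Reaction embeddings for a batch whose graphs carry reaction ids."""
        if batch.reaction_ids is None:
            raise ValueError("batch must carry reaction_ids for reaction embedding")
        p = self.params
        h = self._message_passing(batch)
        graph_vecs = self._set2set(h, batch)
        rxn = ad.segment_sum(graph_vecs, batch.reaction_ids, batch.n_reactions)
        hid = ad.relu(rxn @ p["Wh1"] + p["bh1"])
        hid = ad.dropout(hid, self.config.dropout, rng)
        out = hid @ p["Wh2"] + p["bh2"]
        return ad.dropout(out, self.config.dropout, rng)

    def graph_vectors(self, batch: BatchedGraphs) -> ad.Tensor:
        """Per-graph set2set vectors (no head), for diagnostics."""
        return self._set2set(self._message_passing(batch), batch)


def batch_reactions(graph_maps: list[dict], roles) -> BatchedGraphs:
    """Flatten per-reaction role→graph maps into one disjoint batch."""
    graphs, rxn_ids = [], []
    for i, gm in enumerate(graph_maps):
        for role in roles:
            graphs.append(gm[role])
            rxn_ids.append(i)
    return BatchedGraphs.from_graphs(graphs, reaction_ids=rxn_ids, n_reactions=len(graph_maps))


class Adam:
    """Adam optimizer over a list of tensors (full-batch use)."""

    def __init__(self, params: list[ad.Tensor], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.value = p.value - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
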