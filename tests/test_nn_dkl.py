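"""Extractors and deep kernel training: shapes, invariances, equivalences."""

import copy

import numpy as np
import pytest

import rxndkl.autodiff as ad
from rxndkl.dkl import DeepKernelGP, DKLConfig, GNNRegressor, IdentityExtractor, dkl_predict
from rxndkl.featurize import MolecularGraph, mol_to_graph, reactions_to_graphs
from rxndkl.gp import GPState, KernelParams, fit_gp, log_marginal_likelihood, posterior_predict
from rxndkl.nn import BatchedGraphs, FFNNConfig, FFNNExtractor, MPNNConfig, MPNNExtractor, batch_reactions
from rxndkl.synthetic import GridSpec, synth_reaction_grid

ROLES = ("aryl_halide", "ligand", "base", "additive")


@pytest.fixture(scope="module")
def tiny_graph_maps():
    rxns = synth_reaction_grid(GridSpec(counts=(3, 2, 2, 3), noise_sd=0.0, seed=3))[:12]
    return reactions_to_graphs(rxns), np.array([r.yield_ for r in rxns])


def _small_mpnn(graph_maps, seed=0, **over):
    g0 = graph_maps[0][ROLES[0]]
    cfg = MPNNConfig(
        node_width=g0.node_features.shape[1],
        edge_width=g0.edge_features.shape[1],
        hidden=8,
        edge_hidden=6,
        head_hidden=16,
        embedding=4,
        **over,
    )
    return MPNNExtractor(cfg, np.random.default_rng(seed)), cfg


class TestFFNN:
    def test_eval_mode_deterministic(self):
        ext = FFNNExtractor(FFNNConfig(input_width=10, hidden=8, embedding=4), np.random.default_rng(0))
        x = np.random.default_rng(1).standard_normal((3, 10))
        np.testing.assert_array_equal(ext.extract(x).value, ext.extract(x).value)

    def test_train_mode_applies_dropout(self):
        ext = FFNNExtractor(FFNNConfig(input_width=10, hidden=64, embedding=32), np.random.default_rng(0))
        x = np.ones((4, 10))
        a = ext.extract(x, rng=np.random.default_rng(0)).value
        b = ext.extract(x, rng=np.random.default_rng(99)).value
        assert not np.array_equal(a, b)

    def test_zero_weights_zero_embedding(self):
        ext = FFNNExtractor(FFNNConfig(input_width=5, hidden=3, embedding=2), np.random.default_rng(0))
        ext.load_state_dict({k: np.zeros_like(v) for k, v in ext.state_dict().items()})
        out = ext.extract(np.random.standard_normal((6, 5))).value
        np.testing.assert_array_equal(out, 0.0)

    def test_output_width_and_input_validation(self):
        ext = FFNNExtractor(FFNNConfig(input_width=7, embedding=9), np.random.default_rng(0))
        assert ext.extract(np.zeros((2, 7))).shape == (2, 9)
        with pytest.raises(ValueError):
            ext.extract(np.zeros((2, 8)))


class TestMPNN:
    def test_role_order_invariance(self, tiny_graph_maps):
        graph_maps, _ = tiny_graph_maps
        ext, _ = _small_mpnn(graph_maps)
        a = ext.extract(batch_reactions(graph_maps, ROLES)).value
        b = ext.extract(batch_reactions(graph_maps, ROLES[::-1])).value
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_node_order_invariance(self, tiny_graph_maps):
        graph_maps, _ = tiny_graph_maps
        ext, _ = _small_mpnn(graph_maps)
        base = ext.extract(batch_reactions(graph_maps, ROLES)).value
        rng = np.random.default_rng(0)
        permuted = copy.deepcopy(graph_maps)
        for gm in permuted:
            role = ROLES[rng.integers(4)]
            g = gm[role]
            perm = rng.permutation(g.n_atoms)
            gm[role] = MolecularGraph(
                node_features=g.node_features[np.argsort(perm)],
                edges=perm[g.edges],
                edge_features=g.edge_features,
            )
        out = ext.extract(batch_reactions(permuted, ROLES)).value
        np.testing.assert_allclose(base, out, atol=1e-6)

    def test_zero_message_steps_single_node(self):
        g = {r: mol_to_graph("C") for r in ROLES}
        ext, cfg = _small_mpnn([g], message_steps=0)
        out = ext.extract(batch_reactions([g], ROLES)).value
        assert out.shape == (1, cfg.embedding) and np.isfinite(out).all()

    def test_deterministic_for_seed(self, tiny_graph_maps):
        graph_maps, _ = tiny_graph_maps
        a = _small_mpnn(graph_maps, seed=5)[0].extract(batch_reactions(graph_maps, ROLES)).value
        b = _small_mpnn(graph_maps, seed=5)[0].extract(batch_reactions(graph_maps, ROLES)).value
        np.testing.assert_array_equal(a, b)


class TestDKL:
    def test_identity_extractor_equals_gp_posterior(self):
        """With the extractor frozen to identity, prediction must reproduce the
        closed-form GP posterior exactly (equivalence oracle)."""
        rng = np.random.default_rng(0)
        X = rng.standard_normal((20, 3))
        y = 50 + 10 * rng.standard_normal(20)
        model = DeepKernelGP(X, y, extractor="identity", config=DKLConfig(epochs=5, lr=0.01))
        res = model.fit()
        direct = posterior_predict(GPState(X, model.y_std, res.params), X[:7])
        via_dkl = dkl_predict(res, X[:7])
        np.testing.assert_allclose(via_dkl.mean, model.scaler.inverse(direct.mean), atol=1e-10)
        np.testing.assert_allclose(
            via_dkl.variance, model.scaler.inverse_variance(direct.variance), atol=1e-10
        )

    def test_identity_training_approaches_lbfgs_optimum(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 3, (25, 2))
        y = 50 + 20 * np.sin(X[:, 0]) + 2.0 * rng.standard_normal(25)
        model = DeepKernelGP(X, y, extractor="identity", config=DKLConfig(epochs=600, lr=0.05))
        res = model.fit()
        lbfgs = fit_gp(X, model.y_std)
        assert res.llf >= log_marginal_likelihood(lbfgs) - 0.5

    def test_training_improves_lml(self, small_grid_features):
        X, y = small_grid_features
        res = DeepKernelGP(X[:40], y[:40], config=DKLConfig(epochs=30, seed=0)).fit()
        assert res.lml_trace[-1] > res.lml_trace[0]

    def test_duplicated_queries_identical(self, small_grid_features):
        X, y = small_grid_features
        res = DeepKernelGP(X[:30], y[:30], config=DKLConfig(epochs=10, seed=0)).fit()
        pred = res.predict(np.vstack([X[30:32], X[30:32]]))
        np.testing.assert_array_equal(pred.mean[:2], pred.mean[2:])
        np.testing.assert_array_equal(pred.variance[:2], pred.variance[2:])
        assert np.all(pred.variance > 0)

    def test_seeded_training_reproducible(self, small_grid_features):
        X, y = small_grid_features
        r1 = DeepKernelGP(X[:30], y[:30], config=DKLConfig(epochs=15, seed=3)).fit()
        r2 = DeepKernelGP(X[:30], y[:30], config=DKLConfig(epochs=15, seed=3)).fit()
        np.testing.assert_array_equal(r1.lml_trace, r2.lml_trace)
        np.testing.assert_array_equal(r1.embed_train(), r2.embed_train())

    def test_deep_kernel_gram_psd_for_random_weights(self, small_grid_features):
        X, _ = small_grid_features
        from rxndkl.gp import matern52_gram

        for seed in range(5):
            ext = FFNNExtractor(FFNNConfig(input_width=X.shape[1], hidden=16, embedding=8),
                                np.random.default_rng(seed))
            Z = ext.extract(X[:25]).value
            K = matern52_gram(Z, Z, KernelParams(1.0, 1.0, 0.0))
            assert np.linalg.eigvalsh(K + 1e-8 * np.eye(25)).min() >= 0

    def test_default_config_echoes_protocol(self):
        cfg = DKLConfig()
        assert cfg.epochs == 400 and cfg.lr == pytest.approx(1e-3)

    def test_too_few_reactions_rejected(self):
        with pytest.raises(ValueError):
            DeepKernelGP(np.zeros((5, 3)), 50 + np.arange(5.0))

    def test_mpnn_dkl_end_to_end(self, tiny_graph_maps):
        graph_maps, y = tiny_graph_maps
        g0 = graph_maps[0][ROLES[0]]
        cfg = MPNNConfig(node_width=g0.node_features.shape[1], edge_width=g0.edge_features.shape[1],
                         hidden=6, edge_hidden=4, head_hidden=8, embedding=3)
        res = DeepKernelGP(graph_maps, y, extractor="mpnn", mpnn_config=cfg,
                           config=DKLConfig(epochs=8, seed=0)).fit()
        pred = res.predict(graph_maps[:3])
        assert pred.mean.shape == (3,) and np.all(pred.variance > 0)
        assert res.lml_trace[-1] > res.lml_trace[0]


class TestGNNBaseline:
    def test_trunk_identical_to_dkl_component(self, tiny_graph_maps):
        graph_maps, y = tiny_graph_maps
        gnn = GNNRegressor(graph_maps, y, config=DKLConfig(epochs=1))
        dkl = DeepKernelGP(graph_maps, y, extractor="mpnn", config=DKLConfig(epochs=1))
        assert gnn.mpnn_config == dkl.mpnn_config
        assert {k: v.shape for k, v in gnn.trunk.params.items()} == {
            k: v.shape for k, v in dkl.extractor.params.items()
        }

    def test_fits_separable_toy(self, tiny_graph_maps):
        graph_maps, y = tiny_graph_maps
        g0 = graph_maps[0][ROLES[0]]
        cfg = MPNNConfig(node_width=g0.node_features.shape[1], edge_width=g0.edge_features.shape[1],
                         hidden=6, edge_hidden=4, head_hidden=8, embedding=4)
        res = GNNRegressor(graph_maps, y, mpnn_config=cfg,
                           config=DKLConfig(epochs=150, lr=0.02)).fit()
        assert res.loss_trace[-1] < 0.25 * res.loss_trace[0]

    def test_point_predictions_only(self, tiny_graph_maps):
        graph_maps, y = tiny_graph_maps
        res = GNNRegressor(graph_maps, y, config=DKLConfig(epochs=2)).fit()
        out = res.predict(graph_maps[:4])
        assert isinstance(out, np.ndarray) and out.shape == (4,)
        assert not hasattr(out, "variance")
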