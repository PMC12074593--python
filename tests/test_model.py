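"""SAGE layer, MLP head, focal loss and the full classifier.

Layer math is checked against an independent per-node loop oracle, the loss
against direct formula evaluation, and the backward pass against central
finite differences.
"""

import numpy as np
import pytest
from sklearn.base import clone

from graphbind.errors import DegenerateInputError, ShapeError
from graphbind.model import (
    FocalLossConfig,
    GraphSAGEClassifier,
    MlpParams,
    SageLayerParams,
    _loss_and_grads,
    focal_loss,
    init_params,
    mlp_forward,
    model_forward,
    sage_forward,
)

from conftest import make_graph


def sage_loop_oracle(H, edges, W, b, aggregate="sum"):
    """Per-node arithmetic, no matrix ops over the graph."""
    n, d = H.shape
    nbrs = {i: [] for i in range(n)}
    for i, j in edges:
        nbrs[int(i)].append(int(j))
        nbrs[int(j)].append(int(i))
    out = np.zeros((n, W.shape[0]))
    for i in range(n):
        agg = np.zeros(d)
        for j in nbrs[i]:
            agg += H[j]
        if aggregate == "mean" and nbrs[i]:
            agg /= len(nbrs[i])
        z = W @ np.concatenate([H[i], agg]) + b
        out[i] = np.maximum(z, 0.0)
    return out


def tiny_mlp(d=2, h1=3, h2=2, seed=0):
    rng = np.random.default_rng(seed)
    return MlpParams(w1=rng.normal(size=(h1, d)), b1=rng.normal(size=h1),
                     w2=rng.normal(size=(h2, h1)), b2=rng.normal(size=h2),
                     w_out=rng.normal(size=(2, h2)), b_out=rng.normal(size=2))


class TestSageForward:
    def test_isolated_node_identity_on_concat(self):
        H = np.array([[1.5, 2.0]])
        params = SageLayerParams(W=np.eye(4), b=np.zeros(4))
        out = sage_forward(H, np.empty((0, 2)), params)
        np.testing.assert_allclose(out, [[1.5, 2.0, 0.0, 0.0]])

    def test_neighbor_sum(self):
        # node 0 has neighbors carrying (1,0) and (0,1): its aggregate is (1,1)
        H = np.array([[5.0, 5.0], [1.0, 0.0], [0.0, 1.0]])
        params = SageLayerParams(W=np.eye(4), b=np.zeros(4))
        out = sage_forward(H, np.array([[0, 1], [0, 2]]), params)
        np.testing.assert_allclose(out[0], [5.0, 5.0, 1.0, 1.0])

    def test_path_graph_matches_hand_computation(self):
        H = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0], [2.0, 0.0]])
        edges = np.array([[0, 1], [1, 2], [2, 3]])
        W = np.array([[0.5, -0.25, 0.1, 0.2],
                      [-0.3, 0.4, 0.05, -0.1]])
        b = np.array([0.01, -0.02])
        got = sage_forward(H, edges, SageLayerParams(W=W, b=b))
        np.testing.assert_allclose(got, sage_loop_oracle(H, edges, W, b), atol=1e-12)

    @pytest.mark.parametrize("aggregate", ["sum", "mean"])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_loop_oracle_random_graphs(self, aggregate, seed):
        rng = np.random.default_rng(seed)
        g = make_graph(n=int(rng.integers(2, 20)), d=3, seed=seed)
        params = SageLayerParams(W=rng.normal(size=(4, 6)), b=rng.normal(size=4))
        got = sage_forward(g.node_features, g.edges, params, aggregate)
        want = sage_loop_oracle(g.node_features, g.edges, params.W, params.b, aggregate)
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_permutation_equivariant(self):
        rng = np.random.default_rng(3)
        g = make_graph(n=12, d=3, seed=3)
        params = SageLayerParams(W=rng.normal(size=(5, 6)), b=rng.normal(size=5))
        perm = rng.permutation(12)
        inv = np.argsort(perm)
        out = sage_forward(g.node_features, g.edges, params)
        out_p = sage_forward(g.node_features[perm], inv[g.edges], params)
        np.testing.assert_allclose(out_p, out[perm], atol=1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ShapeError):
            sage_forward(np.zeros((3, 2)), np.empty((0, 2)),
                         SageLayerParams(W=np.eye(6), b=np.zeros(6)))


class TestMlpForward:
    def test_rows_are_distributions(self):
        out = mlp_forward(np.random.default_rng(0).normal(size=(7, 2)), tiny_mlp())
        assert out.shape == (7, 2)
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(out > 0)

    def test_zero_logits_give_uniform(self):
        params = MlpParams(w1=np.zeros((3, 2)), b1=np.zeros(3),
                           w2=np.zeros((2, 3)), b2=np.zeros(2),
                           w_out=np.zeros((2, 2)), b_out=np.zeros(2))
        np.testing.assert_allclose(mlp_forward(np.array([[3.0, -1.0]]), params),
                                   [[0.5, 0.5]])

    def test_matches_direct_arithmetic(self):
        params = tiny_mlp(seed=4)
        x = np.array([0.7, -1.2])

        def lrelu(v):
            return np.where(v > 0, v, 0.01 * v)

        a1 = lrelu(params.w1 @ x + params.b1)
        a2 = lrelu(params.w2 @ a1 + params.b2)
        z = params.w_out @ a2 + params.b_out
        want = np.exp(z) / np.exp(z).sum()
        np.testing.assert_allclose(mlp_forward(x[None, :], params)[0], want, atol=1e-12)


class TestFocalLoss:
    def test_reduces_to_cross_entropy_at_gamma_zero(self):
        cfg = FocalLossConfig(alpha=1.0, gamma=0.0)
        for p in np.linspace(0.01, 0.99, 25):
            assert focal_loss(p, 1, cfg) == pytest.approx(-np.log(p), abs=1e-12)
            assert focal_loss(p, 0, cfg) == pytest.approx(-np.log(1 - p), abs=1e-12)

    def test_zero_at_certain_correct_prediction(self):
        assert focal_loss(1.0, 1, FocalLossConfig()) == 0.0
        assert focal_loss(0.0, 0, FocalLossConfig()) == 0.0

    def test_hand_computed_point(self):
        # alpha=0.25, gamma=2, p_t=0.5: 0.25 * 0.25 * ln 2 = 0.0433216...
        got = focal_loss(0.5, 1, FocalLossConfig(alpha=0.25, gamma=2.0))
        assert got == pytest.approx(0.25 * 0.5 ** 2 * np.log(2), abs=1e-9)
        assert got == pytest.approx(0.04332, abs=1e-5)

    def test_strictly_decreasing_in_pt_and_nonnegative(self):
        cfg = FocalLossConfig(alpha=0.5, gamma=2.0)
        ps = np.linspace(0.01, 0.99, 50)
        losses = [focal_loss(p, 1, cfg) for p in ps]
        assert all(l >= 0 for l in losses)
        assert all(b < a for a, b in zip(losses, losses[1:]))

    def test_batch_mean_and_validation(self):
        cfg = FocalLossConfig(alpha=1.0, gamma=0.0)
        got = focal_loss(np.array([0.8, 0.6]), np.array([1, 0]), cfg)
        assert got == pytest.approx((-np.log(0.8) - np.log(0.4)) / 2)
        with pytest.raises(ValueError):
            focal_loss(1.2, 1, cfg)
        with pytest.raises(ShapeError):
            focal_loss(np.array([0.5, 0.5]), np.array([1]), cfg)


class TestModelForward:
    def test_single_node_graph_one_row(self):
        g = make_graph(n=1, d=3, seed=0)
        params = init_params(3, (4,), (4, 3), 2, np.random.default_rng(0))
        out = model_forward(g, params)
        assert out.shape == (1, 2)
        np.testing.assert_allclose(out.sum(), 1.0)

    def test_rows_sum_to_one(self, random_graph):
        params = init_params(4, (5, 4), (6, 3), 2, np.random.default_rng(1))
        out = model_forward(random_graph, params)
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(out > 0)

    def test_zero_features_zero_biases_uniform(self):
        g = make_graph(n=6, d=3, seed=2)
        g.node_features = np.zeros_like(g.node_features)
        params = init_params(3, (4,), (4, 3), 2, np.random.default_rng(0))
        for arr in params.arrays():
            if arr.ndim == 1:
                arr[...] = 0.0
        np.testing.assert_allclose(model_forward(g, params), 0.5)

    def test_permutation_equivariance_full_model(self):
        g = make_graph(n=10, d=3, seed=5)
        params = init_params(3, (4, 4), (5, 3), 2, np.random.default_rng(2))
        rng = np.random.default_rng(7)
        perm = rng.permutation(10)
        inv = np.argsort(perm)
        gp = make_graph(n=10, d=3, seed=5)
        gp.node_features = g.node_features[perm]
        gp.edges = np.sort(inv[g.edges], axis=1)
        gp.labels = g.labels[perm]
        out = model_forward(g, params)
        np.testing.assert_allclose(model_forward(gp, params), out[perm], atol=1e-12)


class TestGradients:
    @pytest.mark.parametrize("aggregate", ["sum", "mean"])
    @pytest.mark.parametrize("gamma", [0.0, 2.0])
    def test_analytic_gradient_matches_finite_differences(self, aggregate, gamma):
        g = make_graph(n=8, d=3, pos_frac=0.4, seed=9)
        params = init_params(3, (4,), (4, 3), 2, np.random.default_rng(3))
        # move biases off zero so no pre-activation sits exactly on a
        # ReLU/LeakyReLU kink, where finite differences are ill-defined
        rng = np.random.default_rng(8)
        for arr in params.arrays():
            if arr.ndim == 1:
                arr[...] = 0.1 * rng.standard_normal(arr.shape)
        train_idx = np.arange(8)
        cfg = FocalLossConfig(alpha=0.5, gamma=gamma)
        _, grads = _loss_and_grads(g, params, train_idx, cfg, aggregate, 0.01)
        eps = 1e-6
        for arr, grad in zip(params.arrays(), grads):
            flat = arr.ravel()
            for k in np.random.default_rng(0).choice(flat.size,
                                                     size=min(5, flat.size),
                                                     replace=False):
                orig = flat[k]
                flat[k] = orig + eps
                lp, _ = _loss_and_grads(g, params, train_idx, cfg, aggregate, 0.01)
                flat[k] = orig - eps
                lm, _ = _loss_and_grads(g, params, train_idx, cfg, aggregate, 0.01)
                flat[k] = orig
                num = (lp - lm) / (2 * eps)
                assert grad.ravel()[k] == pytest.approx(num, rel=1e-4, abs=1e-7)


class TestClassifier:
    def fitted(self, seed=0, epochs=40):
        g = make_graph(n=60, d=4, pos_frac=0.3, seed=seed)
        clf = GraphSAGEClassifier(sage_hidden=(8,), mlp_hidden=(8, 4),
                                  epochs=epochs, seed=seed, learning_rate=5e-3)
        return clf.fit(g), g

    def test_deterministic_given_seed(self):
        a, _ = self.fitted(seed=1)
        b, _ = self.fitted(seed=1)
        np.testing.assert_array_equal(a.loss_history_, b.loss_history_)

    def test_loss_decreases_on_learnable_signal(self):
        clf, _ = self.fitted(seed=2)
        assert clf.loss_history_[-1] < clf.loss_history_[0]

    def test_predict_threshold_ge_rule(self):
        clf, g = self.fitted(seed=3)
        prob = clf.predict_proba(g)[:, 1]
        pred = clf.predict(g)
        np.testing.assert_array_equal(pred, (prob >= 0.5).astype(int))

    def test_single_class_training_raises(self):
        g = make_graph(n=20, seed=0)
        g.labels[:] = 0
        with pytest.raises(DegenerateInputError):
            GraphSAGEClassifier(epochs=2).fit(g)

    def test_save_load_round_trip(self, tmp_path):
        clf, g = self.fitted(seed=4, epochs=10)
        clf.save(tmp_path / "ckpt")
        back = GraphSAGEClassifier.load(tmp_path / "ckpt")
        np.testing.assert_allclose(back.predict_proba(g), clf.predict_proba(g),
                                   atol=1e-12)
        assert back.get_params() == clf.get_params()

    def test_sklearn_estimator_protocol(self):
        clf = GraphSAGEClassifier(epochs=5, gamma=1.5)
        assert clone(clf).get_params() == clf.get_params()
        clf.set_params(gamma=0.5)
        assert clf.get_params()["gamma"] == 0.5
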