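"""Graph construction, normalization, forward/backward, and training."""

import numpy as np
import pytest

from adgcn_omics import gcn


# ---------------------------------------------------------------- similarity

def test_cosine_similarity_identities():
    X = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [-1.0, 0.0]])
    S = gcn.composite_similarity(X)
    assert S[0, 1] == pytest.approx(1.0)
    assert S[0, 2] == pytest.approx(0.0)
    assert S[0, 3] == pytest.approx(-1.0)
    assert np.allclose(np.diag(S), 1.0)


def test_zero_norm_row_gets_zero_similarity():
    X = np.array([[1.0, 0.0], [0.0, 0.0], [0.0, 1.0]])
    S = gcn.composite_similarity(X)
    assert S[1, 0] == 0.0 and S[1, 2] == 0.0 and S[1, 1] == 1.0


def test_threshold_is_strict():
    S = np.array([[1.0, 0.5, 0.6], [0.5, 1.0, 0.2], [0.6, 0.2, 1.0]])
    edges = gcn.threshold_edges(S, 0.5)
    assert edges == {(0, 2)}          # exactly 0.5 excluded


def test_threshold_complete_and_empty():
    n = 4
    assert len(gcn.threshold_edges(np.ones((n, n)))) == n * (n - 1) // 2
    assert gcn.threshold_edges(np.zeros((n, n))) == set()


# ---------------------------------------------------------------- knn

def test_knn_expand_hand_example():
    # 1-D points 0, 1, 10 with k=1: 0->1, 1->0, 10->1
    X = np.array([[0.0], [1.0], [10.0]])
    edges = gcn.knn_expand(X, k=1, existing_edges=set())
    assert edges == {(0, 1), (1, 2)}


def test_knn_expand_union_and_complete():
    X = np.random.default_rng(0).normal(size=(5, 3))
    full = {(i, j) for i in range(5) for j in range(i + 1, 5)}
    assert gcn.knn_expand(X, k=4, existing_edges=set()) == full
    assert gcn.knn_expand(X, k=2, existing_edges=full) == full


# ---------------------------------------------------------------- weights

def test_cognitive_weights_identities():
    base = np.arange(12, dtype=float)
    cog = np.vstack([base, base * 2 + 5, -base, np.full(12, 3.0)])
    edges = [(0, 1), (0, 2), (0, 3)]
    w = gcn.cognitive_edge_weights(cog, edges)
    assert w[(0, 1)] == pytest.approx(1.0)           # affine rescaling
    assert w[(0, 2)] == gcn.WEIGHT_FLOOR             # anticorrelated floor
    assert w[(0, 3)] == gcn.WEIGHT_FLOOR             # zero variance


def test_build_graph_strategies():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(20, 6))
    cog = rng.normal(size=(20, 12))
    g2 = gcn.build_graph(X, cog, "SIM_KNN_UNWEIGHTED", k=3)
    assert all(w == 1.0 for w in g2.weights.values())
    g1 = gcn.build_graph(X, cog, "SIM_ONLY_W", k=3)
    g3 = gcn.build_graph(X, cog, "SIM_KNN_W", k=3)
    assert set(g1.edges) <= set(g3.edges)
    with pytest.raises(ValueError):
        gcn.build_graph(X, cog, "bogus")


# ---------------------------------------------------------------- adjacency

def test_normalized_adjacency_hand_values():
    g = gcn.GraphSpec(1, [], {}, "SIM_KNN_W", 0.5, 1)
    assert np.allclose(gcn.normalize_adjacency(g), [[1.0]])
    g2 = gcn.GraphSpec(2, [(0, 1)], {(0, 1): 1.0}, "SIM_KNN_W", 0.5, 1)
    assert np.allclose(gcn.normalize_adjacency(g2), 0.5)


def test_normalized_adjacency_spectrum():
    rng = np.random.default_rng(2)
    for _ in range(5):
        n = 15
        edges = [(i, j) for i in range(n) for j in range(i + 1, n)
                 if rng.random() < 0.3]
        weights = {e: float(rng.uniform(0.1, 1.0)) for e in edges}
        g = gcn.GraphSpec(n, edges, weights, "SIM_KNN_W", 0.5, 1)
        evals = np.linalg.eigvalsh(gcn.normalize_adjacency(g))
        assert evals.max() <= 1 + 1e-9
        assert evals.min() >= -1 - 1e-9


def test_neighbor_mean_operator_isolated_row():
    g = gcn.GraphSpec(3, [(0, 1)], {(0, 1): 2.0}, "SIM_KNN_W", 0.5, 1)
    M = gcn.neighbor_mean_operator(g)
    assert np.allclose(M[2], 0.0)
    assert np.allclose(M[0], [0.0, 1.0, 0.0])


# ---------------------------------------------------------------- forward

def make_graph(n, rng, p=0.3):
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)
             if rng.random() < p]
    weights = {e: float(rng.uniform(0.2, 1.0)) for e in edges}
    return gcn.GraphSpec(n, edges, weights, "SIM_KNN_W", 0.5, 5)


def test_forward_zero_weights_give_bias():
    rng = np.random.default_rng(3)
    g = make_graph(8, rng)
    X = rng.normal(size=(8, 4))
    params = gcn.AdgcnParams.init(4, seed=0)
    for name, arr in params.weight_items():
        if name.endswith("gamma"):
            continue
        arr[...] = 0.0
    A = gcn.normalize_adjacency(g)
    scores, _ = gcn.forward(A, g, X, params, mode="eval")
    assert np.allclose(scores, params.b_out)


def test_forward_permutation_equivariance():
    rng = np.random.default_rng(4)
    n = 12
    g = make_graph(n, rng)
    X = rng.normal(size=(n, 5))
    params = gcn.AdgcnParams.init(5, seed=1)
    A = gcn.normalize_adjacency(g)
    s1, _ = gcn.forward(A, g, X, params, mode="eval")
    perm = rng.permutation(n)
    remap = {int(p): i for i, p in enumerate(perm)}

    def pe(e):
        a, b = remap[e[0]], remap[e[1]]
        return (a, b) if a < b else (b, a)

    g2 = gcn.GraphSpec(n, [pe(e) for e in g.edges],
                       {pe(e): w for e, w in g.weights.items()},
                       g.strategy, g.sim_threshold, g.k)
    A2 = gcn.normalize_adjacency(g2)
    s2, _ = gcn.forward(A2, g2, X[perm], params, mode="eval")
    assert np.allclose(s2, s1[perm], atol=1e-10)


def test_forward_single_node_graph():
    g = gcn.GraphSpec(1, [], {}, "SIM_KNN_W", 0.5, 1)
    X = np.array([[1.0, -2.0, 0.5]])
    params = gcn.AdgcnParams.init(3, seed=2)
    scores, caches = gcn.forward(gcn.normalize_adjacency(g), g, X, params,
                                 mode="eval")
    assert scores.shape == (1, 2)
    assert np.allclose(caches["MH1"], 0.0)  # no neighbors -> zero vector


# ---------------------------------------------------------------- gradients

def test_backprop_matches_finite_differences():
    """Analytic gradients of the masked cross-entropy agree with central
    finite differences for every trainable tensor."""
    rng = np.random.default_rng(5)
    n = 10
    g = make_graph(n, rng)
    X = rng.normal(size=(n, 4))
    y = rng.integers(0, 2, n)
    mask = np.zeros(n, bool)
    mask[:6] = True
    A = gcn.normalize_adjacency(g)
    params = gcn.AdgcnParams.init(4, seed=3)

    import copy

    def loss_of(p):
        pc = copy.deepcopy(p)       # _bn_forward mutates running stats
        scores, _ = gcn.forward(A, g, X, pc, mode="train")
        z = scores - scores.max(axis=1, keepdims=True)
        logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
        return -logp[mask, y[mask]].mean()

    base = copy.deepcopy(params)
    _, grads = gcn._loss_and_grads(A, g, X, y, mask, copy.deepcopy(params))
    eps = 1e-6
    for name, arr in base.weight_items():
        G = grads[name]
        it = np.nditer(arr, flags=["multi_index"])
        checked = 0
        while not it.finished and checked < 4:
            idx = it.multi_index
            p_plus = copy.deepcopy(base)
            dict(p_plus.weight_items())[name][idx] += eps
            p_minus = copy.deepcopy(base)
            dict(p_minus.weight_items())[name][idx] -= eps
            fd = (loss_of(p_plus) - loss_of(p_minus)) / (2 * eps)
            assert G[idx] == pytest.approx(fd, rel=1e-3, abs=1e-6), name
            checked += 1
            it.iternext()


# ---------------------------------------------------------------- training

def test_training_fits_separable_data():
    rng = np.random.default_rng(6)
    n = 60
    y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
    X = rng.normal(size=(n, 5))
    X[:, 0] += 3.0 * y
    g = gcn.build_graph(X, rng.normal(size=(n, 12)), "SIM_KNN_UNWEIGHTED",
                        k=5)
    mask = np.ones(n, bool)
    params, history = gcn.train(
        g, gcn.zscore_columns(X), y, mask,
        gcn.TrainConfig(epochs=200, seed=0, early_stop_patience=200))
    _, yhat = gcn.predict(g, gcn.zscore_columns(X), params)
    assert (yhat == y).mean() == 1.0


def test_training_loss_descends():
    drops = []
    for seed in range(5):
        rng = np.random.default_rng(seed)
        n = 40
        X = rng.normal(size=(n, 6))
        y = rng.integers(0, 2, n)
        g = make_graph(n, rng)
        params, hist = gcn.train(
            g, X, y, np.ones(n, bool),
            gcn.TrainConfig(epochs=50, seed=seed, early_stop_patience=50))
        drops.append(hist[min(49, len(hist) - 1)] - hist[0])
    assert np.median(drops) <= 0


def test_training_is_deterministic():
    rng = np.random.default_rng(7)
    n = 30
    X = rng.normal(size=(n, 4))
    y = rng.integers(0, 2, n)
    g = make_graph(n, rng)
    cfg = gcn.TrainConfig(epochs=40, seed=5)
    _, h1 = gcn.train(g, X, y, np.ones(n, bool), cfg)
    _, h2 = gcn.train(g, X, y, np.ones(n, bool), cfg)
    assert h1 == h2


def test_training_mask_validation():
    g = make_graph(10, np.random.default_rng(8))
    X = np.zeros((10, 3))
    with pytest.raises(ValueError, match="empty"):
        gcn.train(g, X, np.zeros(10, int), np.zeros(10, bool),
                  gcn.TrainConfig())
    with pytest.raises(ValueError, match="both classes"):
        gcn.train(g, X, np.zeros(10, int), np.ones(10, bool),
                  gcn.TrainConfig())


def test_strict_weight_mode_runs_and_differs_only_in_weights():
    rng = np.random.default_rng(9)
    n = 60
    y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
    X = rng.normal(size=(n, 5))
    X[:, 0] += 1.0 * y
    cog = (y[:, None] - 0.5) * np.array([1, -1] * 6) + rng.normal(size=(n, 12))
    cfg = gcn.TrainConfig(epochs=60, seed=0)
    rep = gcn.cross_validate(X, cog, y, "SIM_KNN_W", config=cfg, seed=0,
                             k=5, strict_weights=True)
    assert rep.config_snapshot["strict_weights"] is True
    assert -1 <= rep.aggregate["mcc"] <= 1
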