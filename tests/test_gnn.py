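"""Forward semantics, symmetries, gradients and training behavior."""

import math

import numpy as np
import pytest

from petridyn import (
    GeneratorConfig,
    ModelConfig,
    build_io_subgraph,
    forward,
    generate_ppn,
    generate_structural_task,
    init_params,
    load_checkpoint,
    loss,
    predict,
    save_checkpoint,
    train,
)
from petridyn.gnn import (
    VARIANTS,
    GraphBatch,
    _BN_EPS,
    _backward_batch,
    _forward_batch,
    class_balanced_weights,
)
from petridyn.graphprep import IOSubgraph


def dense_forward(params, cfg, sub):
    """Brute-force reference: explicit loops over nodes, labels, neighbors.

    Implements the layer equations directly on dicts, with inference-mode
    batch normalization, independent of the vectorized implementation.
    """
    t, run = params.tensors, params.running
    if cfg.variant == "connectivity":
        feats = {v: np.ones(1) for v in range(sub.n_nodes)}
    elif cfg.variant == "source_dest":
        feats = {v: sub.features[v, :2].copy() for v in range(sub.n_nodes)}
    else:
        feats = {v: sub.features[v].copy() for v in range(sub.n_nodes)}
    h = feats
    pooled = []
    for layer in range(cfg.layers):
        new = {}
        for v in range(sub.n_nodes):
            z = t[f"W{layer}"] @ h[v]
            if cfg.variant == "edge_aware":
                for a in cfg.labels:
                    agg = sum(
                        (h[u] for (u, w, lab) in sub.edges if w == v and lab == a),
                        np.zeros_like(h[v]),
                    )
                    z = z + t[f"E:{a}:{layer}"] @ agg
            elif cfg.variant != "baseline":
                agg = sum((h[u] for (u, w, _) in sub.edges if w == v), np.zeros_like(h[v]))
                z = z + t[f"U{layer}"] @ agg
            r = np.maximum(z, 0.0)
            r_hat = (r - run[f"mean{layer}"]) / np.sqrt(run[f"var{layer}"] + _BN_EPS)
            new[v] = t[f"gamma{layer}"] * r_hat + t[f"beta{layer}"]
        h = new
        pooled.append(sum(h.values()) / sub.n_nodes)
    h_g = np.concatenate(pooled)
    return 1.0 / (1.0 + math.exp(-(t["w_out"] @ h_g + t["b_out"][0])))


def random_small_subgraphs(n, max_nodes=10, seed=0):
    """Featurized I/O subgraphs with <= max_nodes nodes from random PPNs."""
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        ppn = generate_ppn(
            GeneratorConfig(n_places=(3, 5), n_transitions=(2, 4)),
            seed=int(rng.integers(2**31 - 1)),
        )
        places = sorted(ppn.places)
        i, o = rng.choice(len(places), size=2, replace=False)
        sub = build_io_subgraph(ppn, places[i], places[o])
        if sub is not None and sub.n_nodes <= max_nodes:
            out.append(sub)
    return out


def randomize_running_stats(params, cfg, rng):
    # exercise batch normalization with non-trivial inference statistics
    for layer in range(cfg.layers):
        params.running[f"mean{layer}"] = rng.normal(size=cfg.d) * 0.3
        params.running[f"var{layer}"] = rng.uniform(0.5, 2.0, size=cfg.d)


class TestForward:
    def test_zero_weights_predict_one_half(self):
        cfg = ModelConfig(variant="edge_aware", d=4, layers=2)
        params = init_params(cfg)
        for k in params.tensors:
            params.tensors[k] = np.zeros_like(params.tensors[k])
        sub = random_small_subgraphs(1, seed=5)[0]
        assert forward(params, cfg, sub).probability == pytest.approx(0.5)

    @pytest.mark.parametrize("variant", VARIANTS)
    def test_matches_dense_oracle_on_random_graphs(self, variant):
        rng = np.random.default_rng(17)
        subs = random_small_subgraphs(50 if variant == "edge_aware" else 10, seed=23)
        cfg = ModelConfig(variant=variant, d=5, layers=3, seed=3)
        params = init_params(cfg)
        randomize_running_stats(params, cfg, rng)
        for sub in subs:
            got = forward(params, cfg, sub).probability
            want = dense_forward(params, cfg, sub)
            assert got == pytest.approx(want, abs=1e-6)

    @pytest.mark.parametrize("variant", VARIANTS)
    def test_prediction_invariant_under_node_permutation(self, variant):
        rng = np.random.default_rng(11)
        cfg = ModelConfig(variant=variant, d=6, layers=3, seed=1)
        params = init_params(cfg)
        randomize_running_stats(params, cfg, rng)
        for sub in random_small_subgraphs(8, seed=31):
            perm = rng.permutation(sub.n_nodes)
            p0 = forward(params, cfg, sub).probability
            p1 = forward(params, cfg, sub.permuted(perm)).probability
            assert p0 == pytest.approx(p1, abs=1e-6)

    def test_baseline_invariant_under_edge_rewiring(self):
        rng = np.random.default_rng(7)
        cfg = ModelConfig(variant="baseline", d=6, layers=3, seed=2)
        params = init_params(cfg)
        for sub in random_small_subgraphs(6, seed=41):
            p0 = forward(params, cfg, sub).probability
            # rewire every edge to random endpoints, same node multiset
            new_edges = [
                (int(rng.integers(sub.n_nodes)), int(rng.integers(sub.n_nodes)), a)
                for _, _, a in sub.edges
            ]
            rewired = IOSubgraph(
                nodes=list(sub.nodes),
                is_place=sub.is_place.copy(),
                edges=new_edges,
                input_index=sub.input_index,
                output_index=sub.output_index,
                features=sub.features.copy(),
            )
            assert forward(params, cfg, rewired).probability == pytest.approx(p0, abs=1e-9)

    def test_edge_aware_with_tied_matrices_collapses_to_shared_u(self):
        cfg_e = ModelConfig(variant="edge_aware", d=5, layers=3, seed=4)
        cfg_u = ModelConfig(variant="node_type", d=5, layers=3, seed=4)
        pe, pu = init_params(cfg_e), init_params(cfg_u)
        for layer in range(cfg_e.layers):
            for a in cfg_e.labels:  # tie all edge matrices to the shared U
                pe.tensors[f"E:{a}:{layer}"] = pu.tensors[f"U{layer}"].copy()
            for name in (f"W{layer}", f"gamma{layer}", f"beta{layer}"):
                pe.tensors[name] = pu.tensors[name].copy()
        pe.tensors["w_out"] = pu.tensors["w_out"].copy()
        pe.tensors["b_out"] = pu.tensors["b_out"].copy()
        for sub in random_small_subgraphs(10, seed=51):
            assert forward(pe, cfg_e, sub).probability == pytest.approx(
                forward(pu, cfg_u, sub).probability, abs=1e-6
            )

    def test_receptive_field_is_l_hop_local(self):
        """A node's final embedding ignores nodes more than L directed hops away."""
        import networkx as nx

        cfg = ModelConfig(variant="edge_aware", d=4, layers=2, seed=6)
        params = init_params(cfg)
        sub = generate_structural_task(40, seed=13)[0].subgraph
        g = nx.DiGraph((u, v) for u, v, _ in sub.edges)
        base = forward(params, cfg, sub).node_embeddings[-1]
        dist = dict(nx.all_pairs_shortest_path_length(g))
        u = 0
        perturbed = sub.permuted(np.arange(sub.n_nodes))  # deep copy
        perturbed.features[u] = perturbed.features[u] + 2.0
        new = forward(params, cfg, perturbed).node_embeddings[-1]
        for v in range(sub.n_nodes):
            hops = dist.get(u, {}).get(v, np.inf)
            if hops > cfg.layers and v != u:
                np.testing.assert_allclose(new[v], base[v], atol=1e-10)

    def test_feature_width_mismatch_raises(self):
        cfg = ModelConfig(variant="edge_aware", d=4, layers=1)
        sub = random_small_subgraphs(1, seed=2)[0]
        sub.features = None
        with pytest.raises(ValueError):
            forward(init_params(cfg), cfg, sub)


class TestLoss:
    def test_perfect_predictions_drive_loss_to_zero(self):
        y = np.array([1.0, 0.0, 1.0])
        assert loss(np.array([1 - 1e-9, 1e-9, 1 - 1e-9]), y) < 1e-6

    def test_half_confidence_on_positive_is_ln2(self):
        assert loss(np.array([0.5]), np.array([1.0])) == pytest.approx(math.log(2), abs=1e-12)

    def test_hand_computed_batch(self):
        got = loss(np.array([0.9, 0.2]), np.array([1.0, 0.0]))
        want = -0.5 * (math.log(0.9) + math.log(0.8))
        assert got == pytest.approx(want, abs=1e-12)


class TestGradients:
    @pytest.mark.parametrize("variant", ["baseline", "node_type", "edge_aware"])
    def test_analytic_gradient_matches_numeric(self, variant):
        """Central-difference check on a random sample of weights."""
        cfg = ModelConfig(variant=variant, d=3, layers=2, seed=0)
        params = init_params(cfg)
        subs = random_small_subgraphs(4, seed=9)
        y = np.array([1.0, 0.0, 1.0, 0.0])
        batch = GraphBatch(subs, cfg)

        def run():
            backup = {k: v.copy() for k, v in params.running.items()}
            out = _forward_batch(params, cfg, batch, training=True, keep_cache=True)
            params.running.update(backup)
            return out

        prob, h_g, cache, _ = run()
        grads = _backward_batch(params, cfg, batch, y, prob, h_g, cache)
        rng = np.random.default_rng(1)
        for name, arr in params.tensors.items():
            flat = arr.reshape(-1)
            for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                eps, orig = 1e-6, flat[i]
                flat[i] = orig + eps
                l1 = loss(run()[0], y)
                flat[i] = orig - eps
                l2 = loss(run()[0], y)
                flat[i] = orig
                numeric = (l1 - l2) / (2 * eps)
                assert grads[name].reshape(-1)[i] == pytest.approx(numeric, abs=1e-4, rel=1e-3)


class TestTraining:
    def test_weighted_sampler_balances_classes_in_expectation(self):
        # class ratio 9:1; with inverse-frequency weights the expected
        # minority fraction per draw is 1/2
        y = np.array([1] * 90 + [0] * 10)
        w = class_balanced_weights(y)
        rng = np.random.default_rng(0)
        draws = rng.choice(len(y), size=20000, replace=True, p=w)
        frac_minority = np.mean(y[draws] == 0)
        assert frac_minority == pytest.approx(0.5, abs=0.05)

    def test_single_class_data_refused(self):
        ex = generate_structural_task(20, seed=0)
        ones = [e for e in ex if e.y == 1][:6]
        cfg = ModelConfig(d=4, layers=1, epochs=1)
        with pytest.raises(ValueError, match="single class"):
            train(cfg, ones)

    def test_same_seed_gives_identical_history(self):
        ex = generate_structural_task(60, seed=3)
        cfg = ModelConfig(variant="edge_aware", d=4, layers=2, epochs=3, seed=5, batch_size=16)
        _, h1 = train(cfg, ex[:40], ex[40:])
        _, h2 = train(cfg, ex[:40], ex[40:])
        assert h1 == h2

    def test_training_reduces_loss_on_separable_task(self):
        ex = generate_structural_task(300, seed=8)
        cfg = ModelConfig(variant="edge_aware", d=8, layers=3, epochs=5, seed=0)
        _, history = train(cfg, ex)
        assert history[-1]["train_loss"] < history[0]["train_loss"]

    def test_checkpoint_round_trip_preserves_predictions(self, tmp_path):
        ex = generate_structural_task(30, seed=2)
        cfg = ModelConfig(variant="edge_aware", d=4, layers=2, epochs=2, seed=1)
        params, _ = train(cfg, ex)
        path = tmp_path / "model.json"
        save_checkpoint(params, cfg, path)
        loaded, cfg2 = load_checkpoint(path)
        subs = [e.subgraph for e in ex[:5]]
        np.testing.assert_allclose(predict(params, cfg, subs), predict(loaded, cfg2, subs), atol=1e-12)
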