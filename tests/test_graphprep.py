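"""Graph augmentation, I/O-subgraph extraction, featurization, assembly."""

import numpy as np
import pytest

from petridyn import (
    GeneratorConfig,
    PropertyLabel,
    assemble_dataset,
    augment,
    build_io_subgraph,
    dataset_stats,
    extract_io_subgraph,
    featurize,
    generate_ppn,
    load_dataset,
    save_dataset,
)
from petridyn.graphprep import label_set

from conftest import make_ppn, reachable_matrix, simple_path_nodes


class TestAugment:
    def test_single_reaction_gains_back_arc(self, passthrough):
        g = augment(passthrough)
        assert g.number_of_edges() == 3
        labels = sorted((u, v, d["label"]) for u, v, d in g.edges(data=True))
        assert ("r", "A", "reactant") in labels  # the augmentation arc

    def test_reaction_without_reactants_gains_nothing(self):
        ppn = make_ppn(
            ["P", "B"], ["r"],
            [("P", "r", "promoter"), ("r", "B", "product")],
        )
        g = augment(ppn)
        assert g.number_of_edges() == 2

    def test_reversible_pair_counts(self):
        # r: A->B and r_rev: B->A: 4 original arcs + 2 back-arcs
        ppn = make_ppn(
            ["A", "B"], ["r", "r_rev"],
            [
                ("A", "r", "reactant"), ("r", "B", "product"),
                ("B", "r_rev", "reactant"), ("r_rev", "A", "product"),
            ],
        )
        assert augment(ppn).number_of_edges() == 6

    def test_three_label_scheme_collapses_product(self, passthrough):
        g = augment(passthrough, scheme="three")
        assert {d["label"] for _, _, d in g.edges(data=True)} <= set(label_set("three"))


class TestExtraction:
    def test_full_chain_is_kept(self, chain3):
        sub = extract_io_subgraph(augment(chain3), "A", "C")
        assert sub.n_nodes == 5
        assert set(sub.nodes) == {"A", "r1", "B", "r2", "C"}

    def test_dangling_product_excluded(self, chain3):
        chain3.places.add("D")
        chain3.initial_marking["D"] = 0.0
        from petridyn import Arc

        chain3.arcs.add(Arc("r1", "D", "product", 1))
        sub = extract_io_subgraph(augment(chain3), "A", "C")
        assert "D" not in sub.nodes

    def test_unreachable_output_returns_absent(self, chain3):
        # C is downstream of A; reversed query has no directed path
        assert extract_io_subgraph(augment(chain3), "C", "A") is None

    def test_same_input_output_rejected(self, chain3):
        with pytest.raises(ValueError):
            extract_io_subgraph(augment(chain3), "A", "A")

    def test_extraction_is_idempotent(self, chain3):
        import networkx as nx

        sub = extract_io_subgraph(augment(chain3), "A", "C")
        g = nx.MultiDiGraph()
        for i, n in enumerate(sub.nodes):
            g.add_node(n, is_place=bool(sub.is_place[i]))
        for u, v, a in sub.edges:
            g.add_edge(sub.nodes[u], sub.nodes[v], label=a)
        again = extract_io_subgraph(g, sub.input, sub.output)
        assert again.nodes == sub.nodes
        assert sorted(again.edges) == sorted(sub.edges)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_transitive_closure_oracle_on_random_nets(self, seed):
        """Reach/co-reach via boolean matrix closure, on cyclic augmented graphs."""
        ppn = generate_ppn(GeneratorConfig(n_places=(3, 6), n_transitions=(2, 5)), seed=seed)
        g = augment(ppn)
        nodes = sorted(g.nodes)
        idx = {n: i for i, n in enumerate(nodes)}
        edges = [(idx[u], idx[v]) for u, v in g.edges()]
        reach = reachable_matrix(len(nodes), edges)
        places = sorted(ppn.places)
        src, dst = places[0], places[-1]
        expected = {
            nodes[j]
            for j in range(len(nodes))
            if reach[idx[src], j] and reach[j, idx[dst]]
        }
        sub = extract_io_subgraph(g, src, dst)
        got = set(sub.nodes) if sub else set()
        if not reach[idx[src], idx[dst]]:
            assert sub is None
        else:
            assert got == expected

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_simple_path_enumeration_on_dags(self, seed):
        """On acyclic graphs the node set equals the union of all simple paths."""
        import networkx as nx

        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        g = nx.MultiDiGraph()
        for i in range(n):
            g.add_node(f"v{i}", is_place=bool(i % 2))
        edges = []
        for u in range(n):
            for v in range(u + 1, n):  # forward edges only: guaranteed acyclic
                if rng.random() < 0.25:
                    g.add_edge(f"v{u}", f"v{v}", label="reactant")
                    edges.append((u, v))
        sub = extract_io_subgraph(g, "v0", f"v{n - 1}")
        expected = simple_path_nodes(n, edges, 0, n - 1)
        if not expected:
            assert sub is None
        else:
            assert set(sub.nodes) == {f"v{i}" for i in sorted(expected)}


class TestFeaturize:
    def test_indicator_vectors(self, chain3):
        sub = featurize(extract_io_subgraph(augment(chain3), "A", "C"))
        feats = {sub.nodes[i]: sub.features[i].tolist() for i in range(sub.n_nodes)}
        assert feats["A"] == [1.0, 0.0, 1.0]
        assert feats["C"] == [0.0, 1.0, 1.0]
        assert feats["B"] == [0.0, 0.0, 1.0]
        assert feats["r1"] == [0.0, 0.0, 0.0]

    def test_row_sums_places_one_or_two_transitions_zero(self, chain3):
        sub = featurize(extract_io_subgraph(augment(chain3), "A", "C"))
        sums = sub.features.sum(axis=1)
        assert set(sums[sub.is_place]) <= {1.0, 2.0}
        assert (sums[~sub.is_place] == 0).all()

    def test_inhibitor_edge_label_preserved(self):
        ppn = make_ppn(
            ["A", "B", "I"], ["r", "r2"],
            [("A", "r", "reactant"), ("r", "B", "product"), ("I", "r", "inhibitor"),
             ("A", "r2", "reactant"), ("r2", "I", "product")],
            marking={"A": 1.0},
        )
        sub = build_io_subgraph(ppn, "A", "B")
        labels = {a for _, _, a in sub.edges}
        assert "inhibitor" in labels


class TestAssembly:
    def triples(self, chain3):
        lab = PropertyLabel("robustness", 0.7, True)
        return [(chain3, "A", "C", lab), (chain3, "C", "A", lab)]

    def test_unreachable_triple_dropped_with_reason(self, chain3):
        examples, drops = assemble_dataset(self.triples(chain3))
        assert len(examples) == 1
        assert drops == [("ppn1", "C", "A", "no path")]

    def test_oversized_subgraph_dropped(self, chain3):
        examples, drops = assemble_dataset(self.triples(chain3)[:1], max_nodes=3)
        assert not examples
        assert "max_nodes" in drops[0][3]

    def test_stats_row_matches_labels(self, chain3):
        lab_pos = PropertyLabel("robustness", 0.9, True)
        lab_neg = PropertyLabel("robustness", 0.1, False)
        triples = [(chain3, "A", "C", lab_pos)] * 3 + [(chain3, "A", "B", lab_neg)] * 2
        examples, drops = assemble_dataset(triples)
        assert not drops
        stats = dataset_stats(examples, "robustness")
        assert stats["No. of graphs"][0] == 5
        assert stats["Positive (%)"][0].startswith("3")

    def test_dataset_round_trip_on_disk(self, tmp_path, chain3):
        examples, _ = assemble_dataset(self.triples(chain3))
        save_dataset(examples, tmp_path / "data")
        loaded = load_dataset(tmp_path / "data")
        assert len(loaded) == len(examples)
        a, b = examples[0].subgraph, loaded[0].subgraph
        assert a.nodes == b.nodes
        assert sorted(a.edges) == sorted(b.edges)
        np.testing.assert_array_equal(a.features, b.features)
        assert examples[0].y == loaded[0].y
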