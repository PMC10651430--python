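"""Shared fixtures: tiny hand-built nets and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from petridyn import PPN, Arc, KineticLaw


def make_ppn(places, transitions, arcs, marking=None, rates=None) -> PPN:
    """Compact PPN builder for tests.

    ``arcs`` are (source, target, role[, weight]) tuples; ``rates`` maps
    transitions to rate constants (default 1.0).
    """
    rates = rates or {}
    return PPN(
        places=set(places),
        transitions=set(transitions),
        arcs={Arc(*a) if len(a) == 4 else Arc(a[0], a[1], a[2], 1) for a in arcs},
        kinetics={t: KineticLaw(rate_constant=rates.get(t, 1.0)) for t in transitions},
        initial_marking=dict(marking or {}),
    )


@pytest.fixture
def ab_equilibrium() -> PPN:
    """A <-> B with equal rate constants; equilibrium splits mass evenly."""
    return make_ppn(
        ["A", "B"],
        ["f", "b"],
        [("A", "f", "reactant"), ("f", "B", "product"), ("B", "b", "reactant"), ("b", "A", "product")],
        marking={"A": 2.0, "B": 0.0},
    )


@pytest.fixture
def passthrough() -> PPN:
    """Irreversible A -> B: all of A's initial mass ends up in B."""
    return make_ppn(
        ["A", "B"],
        ["r"],
        [("A", "r", "reactant"), ("r", "B", "product")],
        marking={"A": 1.0, "B": 0.0},
    )


@pytest.fixture
def chain3() -> PPN:
    """A -> B -> C conversion chain."""
    return make_ppn(
        ["A", "B", "C"],
        ["r1", "r2"],
        [
            ("A", "r1", "reactant"),
            ("r1", "B", "product"),
            ("B", "r2", "reactant"),
            ("r2", "C", "product"),
        ],
        marking={"A": 1.0, "B": 0.0, "C": 0.0},
    )


@pytest.fixture
def disconnected_io() -> PPN:
    """Input A and output D live in separate reaction components."""
    return make_ppn(
        ["A", "B", "C", "D"],
        ["r1", "r2"],
        [
            ("A", "r1", "reactant"),
            ("r1", "B", "product"),
            ("C", "r2", "reactant"),
            ("r2", "D", "product"),
        ],
        marking={"A": 1.0, "B": 0.0, "C": 1.0, "D": 0.0},
    )


# ---------------------------------------------------------------------------
# Independent oracles


def reachable_matrix(n: int, edges) -> np.ndarray:
    """Boolean transitive closure by repeated matrix multiplication."""
    adj = np.zeros((n, n), dtype=bool)
    for u, v in edges:
        adj[u, v] = True
    reach = np.eye(n, dtype=bool) | adj
    for _ in range(n):
        new = reach | (reach @ reach)
        if (new == reach).all():
            break
        reach = new
    return reach


def simple_path_nodes(n: int, edges, src: int, dst: int) -> set[int]:
    """Union of nodes on all simple src->dst paths (exhaustive DFS)."""
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    for u, v in edges:
        adj[u].append(v)
    found: set[int] = set()

    def dfs(node: int, path: list[int]) -> None:
        if node == dst:
            found.update(path)
            return
        for nxt in adj[node]:
            if nxt not in path:
                path.append(nxt)
                dfs(nxt, path)
                path.pop()

    dfs(src, [src])
    return found
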