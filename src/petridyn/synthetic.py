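"""Random PPNs, structural toy tasks, and desk-scale dynamics datasets.

Everything every other module needs for testing is generated here, from
seeds, with no downloads:

* :func:`generate_ppn` draws random validated mass-action nets with
  reactant/product/promoter/inhibitor arcs, log-uniform rate constants
  and uniform initial markings.
* :func:`generate_structural_task` emits I/O subgraphs whose binary
  label is a purely structural predicate — "every directed path from the
  input to the output traverses at least one inhibitor arc" — computed
  by exhaustive path enumeration.  The generator is built so that the
  model-variant ladder is exercised: node counts are label-independent
  (a structure-agnostic model stays near chance), the *topology* carries
  partial information through a latent regime that couples the density
  of promoter "skip" arcs with the presence of an inhibitor (a
  connectivity-only model picks this up), and the *edge labels* determine
  the label exactly (only an edge-aware model can resolve it fully).
* :func:`generate_dynamics_task` is the end-to-end miniature of a
  simulation-labeled dataset build: small random nets, random
  input/output pairs, labels from the properties module itself.

All randomness flows through seeded ``numpy`` generators; no global
state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .core import PPN, Arc, KineticLaw, validate
from .graphprep import IOSubgraph, LabeledExample, featurize
from .properties import (
    MorrisConfig,
    PropertyLabel,
    RobustnessConfig,
    SimSettings,
    assess_property,
)

__all__ = [
    "GeneratorConfig",
    "StructuralTaskConfig",
    "generate_ppn",
    "generate_structural_task",
    "generate_dynamics_task",
    "structural_label",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Shape of the random mass-action nets.

    Ranges are inclusive.  ``extra_arc_prob`` controls arc density beyond
    the one-reactant-one-product minimum; modifier probabilities are per
    transition; rate constants are log-uniform over ``k_range``; initial
    concentrations uniform over ``marking_range``.
    """

    n_places: tuple[int, int] = (5, 10)
    n_transitions: tuple[int, int] = (4, 10)
    extra_arc_prob: float = 0.3
    promoter_prob: float = 0.15
    inhibitor_prob: float = 0.15
    k_range: tuple[float, float] = (0.1, 10.0)
    marking_range: tuple[float, float] = (0.1, 2.0)
    weight2_prob: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.n_places, self.n_transitions):
            if not 1 <= lo <= hi:
                raise ValueError("degenerate size range")
        for p in (self.extra_arc_prob, self.promoter_prob, self.inhibitor_prob, self.weight2_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


def generate_ppn(cfg: GeneratorConfig | None = None, seed: int | None = None) -> PPN:
    """A random, validated, weakly connected mass-action PPN.

    Deterministic given the seed (``seed`` overrides ``cfg.seed``).
    Every transition gets at least one reactant and one product;
    disconnected components are stitched together with extra reactant
    arcs rather than resampled, so generation always terminates.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n_p = int(rng.integers(cfg.n_places[0], cfg.n_places[1] + 1))
    n_t = int(rng.integers(cfg.n_transitions[0], cfg.n_transitions[1] + 1))
    places = [f"s{i}" for i in range(n_p)]
    transitions = [f"r{j}" for j in range(n_t)]

    ppn = PPN(places=set(places), transitions=set(transitions))
    log_lo, log_hi = np.log(cfg.k_range[0]), np.log(cfg.k_range[1])
    for p in places:
        ppn.initial_marking[p] = float(rng.uniform(*cfg.marking_range))

    def weight() -> int:
        return 2 if rng.random() < cfg.weight2_prob else 1

    for t in transitions:
        ppn.kinetics[t] = KineticLaw(rate_constant=float(np.exp(rng.uniform(log_lo, log_hi))))
        n_react = 1 + (rng.random() < cfg.extra_arc_prob and n_p > 2)
        react = rng.choice(n_p, size=min(n_react, n_p - 1), replace=False)
        rest = [i for i in range(n_p) if i not in set(react.tolist())]
        n_prod = 1 + (rng.random() < cfg.extra_arc_prob and len(rest) > 1)
        prod = rng.choice(len(rest), size=min(n_prod, len(rest)), replace=False)
        for i in react:
            ppn.arcs.add(Arc(places[i], t, "reactant", weight()))
        for i in prod:
            ppn.arcs.add(Arc(t, places[rest[i]], "product", weight()))
        used = {places[i] for i in react} | {places[rest[i]] for i in prod}
        free = [p for p in places if p not in used]
        if free and rng.random() < cfg.promoter_prob:
            ppn.arcs.add(Arc(free[int(rng.integers(len(free)))], t, "promoter", 1))
            free = [p for p in free if Arc(p, t, "promoter", 1) not in ppn.arcs]
        if free and rng.random() < cfg.inhibitor_prob:
            ppn.arcs.add(Arc(free[int(rng.integers(len(free)))], t, "inhibitor", 1))

    # stitch weakly connected components together (place -> transition arcs)
    g = nx.Graph()
    g.add_nodes_from(places)
    g.add_nodes_from(transitions)
    for a in ppn.arcs:
        g.add_edge(a.source, a.target)
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), sorted(c)[0]))
    main = comps[0]
    for comp in comps[1:]:
        t_candidates = sorted(c for c in comp if c in ppn.transitions)
        p_candidates = sorted(c for c in main if c in ppn.places)
        if t_candidates and p_candidates:
            p = p_candidates[int(rng.integers(len(p_candidates)))]
            ppn.arcs.add(Arc(p, t_candidates[0], "reactant", 1))
        else:  # component is a lone place: feed it from a main transition
            p = sorted(c for c in comp if c in ppn.places)[0]
            t = sorted(c for c in main if c in ppn.transitions)[0]
            ppn.arcs.add(Arc(t, p, "product", 1))
        main = main | comp

    assert not validate(ppn), validate(ppn)
    return ppn


# ---------------------------------------------------------------------------
# Structural toy task


@dataclass(frozen=True)
class StructuralTaskConfig:
    """Knobs of the structural toy task.

    Graphs are reaction chains of ``m`` in ``m_range`` steps with
    promoter skip arcs and at most one inhibitor-labeled chain arc.  A
    latent regime z ~ Bernoulli(1/2) sets (inhibitor probability, skip
    probability) to ``regime1`` or ``regime0``; the coupling makes the
    skip pattern (visible topology) informative about the label while
    node counts stay label-independent.  ``balance_tol`` bounds the
    class imbalance of the emitted dataset.
    """

    m_range: tuple[int, int] = (3, 5)
    regime1: tuple[float, float] = (0.9, 0.15)  # (p_inhibitor, p_skip)
    regime0: tuple[float, float] = (0.2, 0.5)
    balance_tol: float = 0.1


def _structural_graph(m: int, inh_pos: int | None, skips: list[int]) -> IOSubgraph:
    """Chain P0 -> T1 -> P1 ... -> Pm with back-arcs and skip arcs.

    Chain arc P_{i-1} -> T_i is the inhibitor when i == inh_pos, else a
    reactant arc.  Every transition has a reactant-labeled back-arc to
    its upstream place; skip j adds a promoter arc P_{j-1} -> T_{j+1}
    (bypassing T_j and P_j).  Node counts and back-arc topology are
    independent of the inhibitor's presence and position.
    """
    nodes = []
    for i in range(m):
        nodes.append(f"P{i}")
        nodes.append(f"T{i + 1}")
    nodes.append(f"P{m}")
    idx = {n: i for i, n in enumerate(nodes)}
    is_place = np.array([n.startswith("P") for n in nodes])
    edges: list[tuple[int, int, str]] = []
    for i in range(1, m + 1):
        role = "inhibitor" if i == inh_pos else "reactant"
        edges.append((idx[f"P{i - 1}"], idx[f"T{i}"], role))
        edges.append((idx[f"T{i}"], idx[f"P{i}"], "product"))
        edges.append((idx[f"T{i}"], idx[f"P{i - 1}"], "reactant"))  # back-arc
    for j in skips:
        edges.append((idx[f"P{j - 1}"], idx[f"T{j + 1}"], "promoter"))
    sub = IOSubgraph(
        nodes=nodes,
        is_place=is_place,
        edges=sorted(edges),
        input_index=idx["P0"],
        output_index=idx[f"P{m}"],
        provenance=f"structural-m{m}",
    )
    return featurize(sub)


def structural_label(sub: IOSubgraph) -> int:
    """1 iff every directed input->output path traverses an inhibitor arc."""
    g = nx.MultiDiGraph()
    g.add_nodes_from(range(sub.n_nodes))
    for u, v, a in sub.edges:
        g.add_edge(u, v, label=a)
    paths = nx.all_simple_edge_paths(g, sub.input_index, sub.output_index)
    found = False
    for path in paths:
        found = True
        if not any(g.edges[e]["label"] == "inhibitor" for e in path):
            return 0
    return 1 if found else 0


def generate_structural_task(
    n: int,
    cfg: StructuralTaskConfig | None = None,
    seed: int = 0,
) -> list[LabeledExample]:
    """``n`` labeled structural examples, classes balanced within 10%.

    Balancing is by per-class rejection: draws whose class quota is
    already filled are discarded.  The returned list is shuffled so that
    any contiguous slice mixes both classes.  Deterministic given
    ``seed``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    cfg = cfg or StructuralTaskConfig()
    rng = np.random.default_rng(seed)
    quota = {1: (n + 1) // 2, 0: n - (n + 1) // 2}
    counts = {0: 0, 1: 0}
    out: list[LabeledExample] = []
    while len(out) < n:
        m = int(rng.integers(cfg.m_range[0], cfg.m_range[1] + 1))
        p_inh, p_skip = cfg.regime1 if rng.random() < 0.5 else cfg.regime0
        inh_pos = int(rng.integers(1, m + 1)) if rng.random() < p_inh else None
        skips = [j for j in range(1, m) if rng.random() < p_skip]
        sub = _structural_graph(m, inh_pos, skips)
        y = structural_label(sub)
        if counts[y] >= quota[y]:
            continue
        counts[y] += 1
        out.append(LabeledExample(sub, y, property="structural"))
    rng.shuffle(out)
    return out


# ---------------------------------------------------------------------------
# Dynamics task (end-to-end miniature)


def generate_dynamics_task(
    n: int,
    cfg: GeneratorConfig | None = None,
    property: str = "robustness",
    robustness_cfg: RobustnessConfig | None = None,
    morris_cfg: MorrisConfig | None = None,
    sim: SimSettings | None = None,
    seed: int = 0,
    pairs_per_net: int = 3,
) -> list[tuple[PPN, str, str, PropertyLabel]]:
    """``n`` simulation-labeled (PPN, input, output, label) triples.

    Labels are produced by the properties module on small random nets —
    the same procedure that would label a real model collection, at desk
    scale.  Only (input, output) pairs connected by a directed path in
    the augmented graph are queried (unreachable pairs would be discarded
    at subgraph extraction anyway).  Triples whose simulations fail are
    dropped and not counted toward ``n``; labels are bit-reproducible for
    a fixed seed.
    """
    from .graphprep import augment, extract_io_subgraph

    cfg = cfg or GeneratorConfig(n_places=(4, 7), n_transitions=(3, 7))
    rng = np.random.default_rng(seed)
    out: list[tuple[PPN, str, str, PropertyLabel]] = []
    while len(out) < n:
        ppn = generate_ppn(cfg, seed=int(rng.integers(2**31 - 1)))
        graph = augment(ppn)
        places = sorted(ppn.places)
        tried: set[tuple[str, str]] = set()
        for _ in range(pairs_per_net):
            if len(out) >= n:
                break
            i, o = rng.choice(len(places), size=2, replace=False)
            pair = (places[i], places[o])
            if pair in tried:
                continue
            tried.add(pair)
            if extract_io_subgraph(graph, pair[0], pair[1]) is None:
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # stiff-solver chatter in batch mode
                    label = assess_property(
                        ppn, pair[0], pair[1], property,
                        robustness_cfg=robustness_cfg, morris_cfg=morris_cfg, sim=sim,
                    )
            except Exception:
                continue  # non-converged or degenerate: dropped
            out.append((ppn, pair[0], pair[1], label))
    return out
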