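"""Arc knock-out analysis of trained models.

Each edge of an I/O subgraph is deleted in turn (node set unchanged) and
the model's prediction recomputed; the drop in confidence
``y_g - y_{g\\e}`` is read as the arc's contribution to the prediction.
Edges whose removal would break the subgraph's defining property —
a directed input-to-output path must survive, and every node must stay
both reachable from the input and co-reachable to the output — are not
removed and are reported with the violated condition.

A knocked-out arc can additionally be cross-checked against the ground
truth: the corresponding arc is deleted from the *PPN* (a removed
reactant arc means the species is no longer consumed; a removed product
arc means it is no longer produced), the rate system is rebuilt, and the
dynamical property re-assessed by simulation.  Arcs that exist only in
the augmented graph (reaction-to-reactant back-arcs) map to no PPN
change and are flagged instead of silently validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .core import PPN, Arc
from .gnn import ModelConfig, ModelParams, predict
from .graphprep import IOSubgraph
from .properties import MorrisConfig, PropertyLabel, RobustnessConfig, SimSettings, assess_property

__all__ = [
    "KnockoutEntry",
    "KnockoutReport",
    "KnockoutValidation",
    "removable_edges",
    "knockout_scan",
    "knockout_validate",
    "knockout_to_dot",
]

Edge = tuple[int, int, str]


@dataclass
class KnockoutEntry:
    edge: Edge
    edge_names: tuple[str, str, str]
    removable: bool
    reason: str = ""  # violated condition for non-removable edges
    probability: float | None = None  # y_{g\e}
    contribution: float | None = None  # y_g - y_{g\e}
    simulated: PropertyLabel | None = None


@dataclass
class KnockoutReport:
    base_probability: float
    entries: list[KnockoutEntry] = field(default_factory=list)

    @property
    def removable(self) -> list[KnockoutEntry]:
        return [e for e in self.entries if e.removable]

    @property
    def non_removable(self) -> list[KnockoutEntry]:
        return [e for e in self.entries if not e.removable]


@dataclass
class KnockoutValidation:
    arc_in_ppn: bool
    pruned_transitions: list[str] = field(default_factory=list)
    label: PropertyLabel | None = None


def removable_edges(sub: IOSubgraph) -> tuple[list[Edge], list[tuple[Edge, str]]]:
    """Partition the subgraph's edges into removable and non-removable.

    An edge is removable iff after deleting it (one parallel copy only)
    (i) a directed input->output path still exists and (ii) no node ends
    up disconnected from the input-output flow entirely, i.e. both
    unreachable from the input *and* unable to reach the output.  (A node
    that keeps one of the two stays attached to the flow; demanding both
    would forbid removing any arc that feeds a side branch, including
    arcs on one of two parallel input-output routes.)
    """
    g = nx.DiGraph()
    g.add_nodes_from(range(sub.n_nodes))
    multiplicity: dict[tuple[int, int], int] = {}
    for u, v, _ in sub.edges:
        multiplicity[(u, v)] = multiplicity.get((u, v), 0) + 1
        g.add_edge(u, v)
    i, o = sub.input_index, sub.output_index

    removable: list[Edge] = []
    blocked: list[tuple[Edge, str]] = []
    for edge in sub.edges:
        u, v, _ = edge
        if multiplicity[(u, v)] > 1:  # a parallel arc keeps connectivity intact
            removable.append(edge)
            continue
        g.remove_edge(u, v)
        try:
            if not nx.has_path(g, i, o):
                blocked.append((edge, "breaks the input-output path"))
                continue
            fwd = nx.descendants(g, i) | {i}
            bwd = nx.ancestors(g, o) | {o}
            lost = sorted(set(range(sub.n_nodes)) - (fwd | bwd))
            if lost:
                names = ", ".join(sub.nodes[x] for x in lost)
                blocked.append((edge, f"node(s) {names} disconnect from the input-output flow"))
                continue
            removable.append(edge)
        finally:
            g.add_edge(u, v)
    return removable, blocked


def knockout_scan(params: ModelParams, cfg: ModelConfig, sub: IOSubgraph) -> KnockoutReport:
    """One inference pass per removable edge on the edge-deleted subgraph.

    Deterministic; the node set is never re-extracted, so each
    contribution isolates the effect of its single edge.
    """
    base = float(predict(params, cfg, [sub])[0])
    rem, blocked = removable_edges(sub)
    report = KnockoutReport(base_probability=base)
    knocked = [sub.without_edge(e) for e in rem]
    probs = predict(params, cfg, knocked) if knocked else []
    blocked_map = dict(blocked)
    for edge in sub.edges:
        names = (sub.nodes[edge[0]], sub.nodes[edge[1]], edge[2])
        if edge in blocked_map:
            report.entries.append(KnockoutEntry(edge, names, removable=False, reason=blocked_map[edge]))
        else:
            p = float(probs[rem.index(edge)])
            report.entries.append(
                KnockoutEntry(edge, names, removable=True, probability=p, contribution=base - p)
            )
    return report


def knockout_validate(
    ppn: PPN,
    input: str,
    output: str,
    edge: tuple[str, str, str],
    property: str = "robustness",
    robustness_cfg: RobustnessConfig | None = None,
    morris_cfg: MorrisConfig | None = None,
    sim: SimSettings | None = None,
) -> KnockoutValidation:
    """Re-simulate the property on the PPN with one arc deleted.

    ``edge`` is (source, target, role) in PPN node identifiers.  An edge
    with no counterpart arc in the PPN (an augmentation back-arc) yields
    ``arc_in_ppn=False`` and no simulation.  A transition stripped of its
    last arc is pruned and reported.
    """
    arc = Arc(edge[0], edge[1], edge[2], 1)
    match = [a for a in ppn.arcs if (a.source, a.target, a.role) == (arc.source, arc.target, arc.role)]
    if not match:
        return KnockoutValidation(arc_in_ppn=False)
    knocked = ppn.without_arc(match[0], prune_empty=True)
    pruned = sorted(ppn.transitions - knocked.transitions)
    label = assess_property(
        knocked, input, output, property,
        robustness_cfg=robustness_cfg, morris_cfg=morris_cfg, sim=sim,
    )
    return KnockoutValidation(arc_in_ppn=True, pruned_transitions=pruned, label=label)


def knockout_to_dot(report: KnockoutReport, sub: IOSubgraph) -> str:
    """GraphViz DOT rendering of a knock-out report.

    Red arcs increased the prediction when removed, blue decreased it,
    black arcs are non-removable.  Edge labels carry the knocked-out
    prediction.
    """
    lines = ["digraph knockout {"]
    for i, name in enumerate(sub.nodes):
        shape = "ellipse" if sub.is_place[i] else "box"
        color = "green" if i == sub.input_index else ("yellow" if i == sub.output_index else "white")
        lines.append(f'  n{i} [label="{name}", shape={shape}, style=filled, fillcolor="{color}"];')
    for entry in report.entries:
        u, v, a = entry.edge
        if not entry.removable:
            lines.append(f'  n{u} -> n{v} [color=black, label="{a}"];')
        else:
            delta = entry.probability - report.base_probability
            color = "red" if delta > 0 else ("blue" if delta < 0 else "gray")
            lines.append(f'  n{u} -> n{v} [color={color}, label="{a}\\n{entry.probability:.2f}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"
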