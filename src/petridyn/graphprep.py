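"""From (PPN, input, output) triples to labeled learning subgraphs.

Four-step preprocessing:

1. *Augment* the PPN's directed graph with one arc from every reaction
   back to each of its reactants, making the reaction's (negative)
   influence on its reactants explicit to a directed traversal.
2. *Extract* the subgraph of nodes lying on a directed path from the
   input species I to the output species O, computed as the forward
   reachable set of I intersected with the backward reachable set of O.
   When O is unreachable from I the triple yields no subgraph and the
   dataset entry is discarded.
3. *Featurize* nodes with a 3-vector of indicators
   (Source = "is I", Dest = "is O", NodeType = "is a place").
4. *Label* edges from a discrete label set.  The default scheme keeps
   four labels {reactant, product, promoter, inhibitor}, with
   augmentation arcs labeled "reactant" (they represent consumption);
   the ``"three"`` scheme collapses product into reactant, honoring the
   minimal {reactant, promoter, inhibitor} set.

Stoichiometric weights are dropped at featurization; the model consumes
labels only.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .core import PPN
from .properties import PropertyLabel

__all__ = [
    "EDGE_LABELS",
    "label_set",
    "IOSubgraph",
    "LabeledExample",
    "augment",
    "extract_io_subgraph",
    "featurize",
    "build_io_subgraph",
    "assemble_dataset",
    "dataset_stats",
    "save_dataset",
    "load_dataset",
]

EDGE_LABELS = ("reactant", "product", "promoter", "inhibitor")
#: Label given to the reaction->reactant arcs added by augmentation.
AUGMENT_LABEL = "reactant"


def label_set(scheme: str = "four") -> tuple[str, ...]:
    """The ordered edge-label alphabet for a labeling scheme."""
    if scheme == "four":
        return EDGE_LABELS
    if scheme == "three":
        return ("reactant", "promoter", "inhibitor")
    raise ValueError(f"unknown label scheme {scheme!r}")


@dataclass
class IOSubgraph:
    """A directed, edge-labeled, node-featured subgraph for one (I, O) pair.

    ``edges`` hold indices into ``nodes``; ``features`` is the (n, 3)
    Source/Dest/NodeType indicator matrix.  Every node lies on at least
    one directed path from the input node to the output node (in the
    reach/co-reach sense over the augmented graph).
    """

    nodes: list[str]
    is_place: np.ndarray  # (n,) bool
    edges: list[tuple[int, int, str]]
    input_index: int
    output_index: int
    features: np.ndarray | None = None
    provenance: str = ""

    @property
    def input(self) -> str:
        return self.nodes[self.input_index]

    @property
    def output(self) -> str:
        return self.nodes[self.output_index]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edges_by_name(self) -> list[tuple[str, str, str]]:
        return [(self.nodes[u], self.nodes[v], a) for u, v, a in self.edges]

    def permuted(self, perm: np.ndarray) -> "IOSubgraph":
        """Relabel nodes by ``perm`` (new position of each old index)."""
        perm = np.asarray(perm)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        order = list(inv)  # order[new] = old
        return IOSubgraph(
            nodes=[self.nodes[o] for o in order],
            is_place=self.is_place[order],
            edges=sorted((int(perm[u]), int(perm[v]), a) for u, v, a in self.edges),
            input_index=int(perm[self.input_index]),
            output_index=int(perm[self.output_index]),
            features=None if self.features is None else self.features[order],
            provenance=self.provenance,
        )

    def without_edge(self, edge: tuple[int, int, str]) -> "IOSubgraph":
        """Copy with one edge removed; the node set is kept unchanged."""
        if edge not in self.edges:
            raise KeyError(f"edge {edge} not in subgraph")
        edges = list(self.edges)
        edges.remove(edge)
        return IOSubgraph(
            nodes=list(self.nodes),
            is_place=self.is_place.copy(),
            edges=edges,
            input_index=self.input_index,
            output_index=self.output_index,
            features=None if self.features is None else self.features.copy(),
            provenance=self.provenance,
        )


@dataclass
class LabeledExample:
    subgraph: IOSubgraph
    y: int
    property: str = ""
    label_info: PropertyLabel | None = None


def augment(ppn: PPN, scheme: str = "four") -> nx.MultiDiGraph:
    """The PPN's directed labeled graph plus reaction->reactant back-arcs."""
    labels = label_set(scheme)
    g = nx.MultiDiGraph()
    for p in sorted(ppn.places):
        g.add_node(p, is_place=True)
    for t in sorted(ppn.transitions):
        g.add_node(t, is_place=False)
    for a in sorted(ppn.arcs):
        lab = a.role
        if scheme == "three" and lab == "product":
            lab = "reactant"
        assert lab in labels
        g.add_edge(a.source, a.target, label=lab)
        if a.role == "reactant":
            g.add_edge(a.target, a.source, label=AUGMENT_LABEL)
    return g


def extract_io_subgraph(graph: nx.MultiDiGraph, input: str, output: str) -> IOSubgraph | None:
    """Nodes reachable from ``input`` and co-reachable to ``output``,
    with the induced edges; ``None`` when no path exists."""
    if input == output:
        raise ValueError("input and output species must differ")
    if input not in graph or output not in graph:
        raise KeyError("input and output must be nodes of the graph")
    forward = nx.descendants(graph, input) | {input}
    if output not in forward:
        return None
    backward = nx.ancestors(graph, output) | {output}
    keep = sorted(forward & backward)
    index = {n: i for i, n in enumerate(keep)}
    edges = sorted(
        (index[u], index[v], data["label"])
        for u, v, data in graph.edges(data=True)
        if u in index and v in index
    )
    is_place = np.array([graph.nodes[n]["is_place"] for n in keep], dtype=bool)
    return IOSubgraph(
        nodes=keep,
        is_place=is_place,
        edges=edges,
        input_index=index[input],
        output_index=index[output],
    )


def featurize(sub: IOSubgraph) -> IOSubgraph:
    """Fill the (Source, Dest, NodeType) indicator features in place.

    The input place maps to [1, 0, 1], the output place to [0, 1, 1],
    other places to [0, 0, 1] and transitions to [0, 0, 0].
    """
    n = sub.n_nodes
    feats = np.zeros((n, 3))
    feats[sub.input_index, 0] = 1.0
    feats[sub.output_index, 1] = 1.0
    feats[:, 2] = sub.is_place.astype(float)
    if not (sub.is_place[sub.input_index] and sub.is_place[sub.output_index]):
        raise ValueError("input and output must be place nodes")
    sub.features = feats
    return sub


def build_io_subgraph(ppn: PPN, input: str, output: str, scheme: str = "four", provenance: str = "") -> IOSubgraph | None:
    """augment -> extract -> featurize for one triple; None when no path."""
    sub = extract_io_subgraph(augment(ppn, scheme), input, output)
    if sub is None:
        return None
    sub.provenance = provenance
    return featurize(sub)


def assemble_dataset(
    triples: list[tuple[PPN, str, str, PropertyLabel]],
    max_nodes: int = 200,
    scheme: str = "four",
    provenance_ids: list[str] | None = None,
) -> tuple[list[LabeledExample], list[tuple[str, str, str, str]]]:
    """Build labeled examples from assessed triples.

    Triples whose output is unreachable from the input, or whose subgraph
    exceeds ``max_nodes`` nodes, are dropped; every drop is reported in
    the returned log as (ppn id, input, output, reason).
    """
    examples: list[LabeledExample] = []
    drops: list[tuple[str, str, str, str]] = []
    for i, (ppn, inp, out, lab) in enumerate(triples):
        pid = provenance_ids[i] if provenance_ids else f"ppn{i}"
        sub = build_io_subgraph(ppn, inp, out, scheme, provenance=pid)
        if sub is None:
            drops.append((pid, inp, out, "no path"))
            continue
        if sub.n_nodes > max_nodes:
            drops.append((pid, inp, out, f"{sub.n_nodes} nodes > max_nodes={max_nodes}"))
            continue
        examples.append(LabeledExample(sub, int(lab.binary), lab.property, lab))
    return examples, drops


def save_dataset(examples: list[LabeledExample], directory) -> None:
    """Write a dataset as an index table plus per-example edge lists.

    Layout: ``index.tsv`` with one row per example (provenance id,
    input, output, property, label, sizes) and ``examples/ex<i>.txt``
    holding the node table (id, place flag, source flag, dest flag) and
    the labeled edge list.
    """
    from pathlib import Path

    directory = Path(directory)
    (directory / "examples").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, e in enumerate(examples):
        s = e.subgraph
        rows.append(
            {
                "example": f"ex{i:05d}",
                "ppn": s.provenance,
                "input": s.input,
                "output": s.output,
                "property": e.property,
                "label": e.y,
                "n_nodes": s.n_nodes,
                "n_edges": s.n_edges,
            }
        )
        lines = ["[nodes]"]
        for j, name in enumerate(s.nodes):
            lines.append(
                f"{name} {int(s.is_place[j])} {int(j == s.input_index)} {int(j == s.output_index)}"
            )
        lines.append("[edges]")
        for u, v, a in s.edges:
            lines.append(f"{u} {v} {a}")
        (directory / "examples" / f"ex{i:05d}.txt").write_text("\n".join(lines) + "\n")
    pd.DataFrame(rows).to_csv(directory / "index.tsv", sep="\t", index=False)


def load_dataset(directory) -> list[LabeledExample]:
    """Read a dataset written by :func:`save_dataset`."""
    from pathlib import Path

    directory = Path(directory)
    index = pd.read_csv(directory / "index.tsv", sep="\t", keep_default_na=False)
    out: list[LabeledExample] = []
    for _, row in index.iterrows():
        text = (directory / "examples" / f"{row['example']}.txt").read_text()
        nodes: list[str] = []
        place_flags: list[bool] = []
        in_idx = out_idx = -1
        edges: list[tuple[int, int, str]] = []
        section = ""
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("["):
                section = line.strip("[]")
                continue
            parts = line.split()
            if section == "nodes":
                name, is_p, is_i, is_o = parts
                if int(is_i):
                    in_idx = len(nodes)
                if int(is_o):
                    out_idx = len(nodes)
                nodes.append(name)
                place_flags.append(bool(int(is_p)))
            elif section == "edges":
                edges.append((int(parts[0]), int(parts[1]), parts[2]))
        sub = IOSubgraph(
            nodes=nodes,
            is_place=np.array(place_flags),
            edges=edges,
            input_index=in_idx,
            output_index=out_idx,
            provenance=str(row["ppn"]),
        )
        featurize(sub)
        out.append(LabeledExample(sub, int(row["label"]), str(row["property"])))
    return out


def dataset_stats(examples: list[LabeledExample], property: str = "") -> pd.DataFrame:
    """One summary row per dataset: counts, class balance, graph sizes."""
    n = len(examples)
    pos = sum(e.y for e in examples)
    nodes = np.array([e.subgraph.n_nodes for e in examples]) if n else np.array([0])
    edges = np.array([e.subgraph.n_edges for e in examples]) if n else np.array([0])
    prop = property or (examples[0].property if examples else "")
    return pd.DataFrame(
        [
            {
                "Property": prop,
                "No. of graphs": n,
                "Positive (%)": f"{pos} ({0 if n == 0 else round(100 * pos / n)}%)",
                "Negative (%)": f"{n - pos} ({0 if n == 0 else round(100 * (n - pos) / n)}%)",
                "Avg. No. of nodes": f"{nodes.mean():.0f} ± {nodes.std():.0f}",
                "Avg. No. of edges": f"{edges.mean():.0f} ± {edges.std():.0f}",
            }
        ]
    )
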