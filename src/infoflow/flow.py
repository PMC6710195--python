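"""Information-flow matrices: maximum flow over transfer-entropy capacity graphs.

The sparse TE matrix is read as the adjacency matrix of a directed, weighted
graph in which the capacity of edge (i, j) is the (nonnegative) TE from node i
to node j.  Functional connectivity between two nodes is then the maximum
flow from one to the other, which accounts for indirect routes as well as the
direct edge.  Three variants are produced:

* ``full_unrestricted`` — node x node max flow over the whole graph;
* ``full_restricted``   — node x node max flow where, for a source in group X
  and sink in group Y, only edges with tail in X and head in Y are eligible
  (within-group edges when X == Y);
* ``reduced``           — group x group sums of the restricted full matrix,
  with within-group flow sums on the diagonal.

With the reference 20-group hemisphere x lobe scheme the reduced matrix has
400 cells, 20 of them within-group.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .panel import GroupScheme
from .te import TEMatrix

__all__ = [
    "InformationFlowMatrix",
    "capacity_graph",
    "max_flow_value",
    "restricted_edge_set",
    "compute_full_if_matrix",
    "reduce_if_matrix",
    "flatten_features",
]

VARIANTS = ("full_unrestricted", "full_restricted", "reduced")


@dataclass
class InformationFlowMatrix:
    """Directed flow matrix, node x node (full) or group x group (reduced)."""

    values: np.ndarray
    labels: list[str]
    variant: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("values must be square and match labels")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if np.any(self.values < 0):
            raise ValueError("flow values must be nonnegative")
        if self.variant != "reduced" and np.any(np.diag(self.values) != 0):
            raise ValueError("full flow matrices have zero diagonal")
        self.labels = [str(l) for l in self.labels]


def capacity_graph(te_sparse: TEMatrix) -> nx.DiGraph:
    """Directed capacity graph of a sparse TE matrix.

    Zero-capacity edges are dropped (identical flow values, smaller graph);
    all nodes are present even when isolated.
    """
    if not te_sparse.sparse:
        raise ValueError("capacity graph requires a sparse (clipped) TE matrix")
    g = nx.DiGraph()
    g.add_nodes_from(te_sparse.node_ids)
    vals = te_sparse.values
    ii, jj = np.nonzero(vals > 0)
    g.add_edges_from(
        (te_sparse.node_ids[i], te_sparse.node_ids[j], {"capacity": float(vals[i, j])})
        for i, j in zip(ii, jj)
    )
    return g


def max_flow_value(graph: nx.DiGraph, source: str, sink: str) -> float:
    """Maximum-flow value from ``source`` to ``sink``.

    The value is unique (min-cut capacity) even though optimal flow
    assignments need not be.
    """
    if source == sink:
        raise ValueError("source and sink must differ")
    for node in (source, sink):
        if node not in graph:
            raise KeyError(f"node {node!r} not in graph")
    if graph.out_degree(source) == 0 or graph.in_degree(sink) == 0:
        return 0.0
    return float(nx.maximum_flow_value(graph, source, sink, capacity="capacity"))


def restricted_edge_set(
    te_sparse: TEMatrix, scheme: GroupScheme, source: str, sink: str
) -> nx.DiGraph:
    """Capacity graph restricted to edges from group(source) to group(sink).

    Only edges whose tail lies in the source's group and whose head lies in
    the sink's group are kept; if both nodes share a group this keeps all
    edges inside that group.
    """
    scheme.check_covers(te_sparse.node_ids)
    for node in (source, sink):
        if node not in te_sparse.node_ids:
            raise KeyError(f"node {node!r} not in TE matrix")
    gs, gt = scheme.group_of(source), scheme.group_of(sink)
    return _group_pair_subgraph(te_sparse, scheme, gs, gt)


def _group_pair_subgraph(
    te_sparse: TEMatrix, scheme: GroupScheme, group_tail: str, group_head: str
) -> nx.DiGraph:
    idx = {n: i for i, n in enumerate(te_sparse.node_ids)}
    tails = [n for n in te_sparse.node_ids if scheme.group_of(n) == group_tail]
    heads = [n for n in te_sparse.node_ids if scheme.group_of(n) == group_head]
    g = nx.DiGraph()
    g.add_nodes_from(tails)
    g.add_nodes_from(heads)
    vals = te_sparse.values
    for t in tails:
        it = idx[t]
        for h in heads:
            if t == h:
                continue
            cap = vals[it, idx[h]]
            if cap > 0:
                g.add_edge(t, h, capacity=float(cap))
    return g


def compute_full_if_matrix(
    te_sparse: TEMatrix,
    scheme: GroupScheme | None = None,
    restricted: bool = False,
) -> InformationFlowMatrix:
    """Node x node information-flow matrix (restricted or not).

    Entry (i, j), i != j, is the max-flow value from node i to node j over
    either the whole capacity graph or the group-restricted edge set; the
    diagonal is zero.  Pair computations are independent of each other.
    """
    if not te_sparse.sparse:
        raise ValueError("information flow requires a sparse TE matrix")
    if restricted and scheme is None:
        raise ValueError("restricted flow requires a group scheme")
    nodes = te_sparse.node_ids
    n = len(nodes)
    values = np.zeros((n, n))
    if not restricted:
        g = capacity_graph(te_sparse)
        for i, src in enumerate(nodes):
            if g.out_degree(src) == 0:
                continue
            for j, dst in enumerate(nodes):
                if i != j:
                    values[i, j] = max_flow_value(g, src, dst)
        return InformationFlowMatrix(values, list(nodes), "full_unrestricted")

    scheme.check_covers(nodes)
    groups = [scheme.group_of(nd) for nd in nodes]
    # one subgraph per ordered group pair; reused for every node pair in it
    for gx in scheme.group_ids:
        for gy in scheme.group_ids:
            sub = _group_pair_subgraph(te_sparse, scheme, gx, gy)
            srcs = [i for i in range(n) if groups[i] == gx]
            dsts = [j for j in range(n) if groups[j] == gy]
            for i in srcs:
                for j in dsts:
                    if i != j:
                        values[i, j] = max_flow_value(sub, nodes[i], nodes[j])
    return InformationFlowMatrix(values, list(nodes), "full_restricted")


def reduce_if_matrix(
    if_full: InformationFlowMatrix, scheme: GroupScheme
) -> InformationFlowMatrix:
    """Group x group reduction: sum full flows over ordered node pairs.

    Cell (x, y) sums the restricted full-matrix flows over node pairs
    (i in x, j in y), i != j; the diagonal therefore holds within-group flow
    sums.  Directed: (x, y) generally differs from (y, x).
    """
    if if_full.variant != "full_restricted":
        raise ValueError(
            "reduction is defined on the anatomically restricted full matrix, "
            f"got variant {if_full.variant!r}"
        )
    scheme.check_covers(if_full.labels)
    gidx = np.array([scheme.group_index(nd) for nd in if_full.labels])
    g = scheme.n_groups
    values = np.zeros((g, g))
    np.add.at(values, (gidx[:, None], gidx[None, :]), if_full.values)
    return InformationFlowMatrix(values, list(scheme.group_ids), "reduced")


def flatten_features(if_matrix: InformationFlowMatrix) -> tuple[np.ndarray, list[str]]:
    """Row-major flattening (diagonal included) with stable cell labels.

    The reference 20-group scheme yields 400 features labeled ``"x->y"``.
    """
    labels = [f"{x}->{y}" for x in if_matrix.labels for y in if_matrix.labels]
    return if_matrix.values.ravel(order="C").copy(), labels


def brute_force_min_cut(graph: nx.DiGraph, source: str, sink: str) -> float:
    """Minimum s-t cut capacity by exhaustive enumeration (small graphs only).

    Exponential-time reference used to validate max-flow values via the
    max-flow = min-cut theorem; practical for graphs of <= ~12 nodes.
    """
    others = [n for n in graph.nodes if n not in (source, sink)]
    if len(others) > 20:
        raise ValueError("brute-force cut enumeration is for small graphs")
    best = np.inf
    for bits in range(2 ** len(others)):
        side = {source}
        for b, n in enumerate(others):
            if bits >> b & 1:
                side.add(n)
        cut = sum(
            d["capacity"]
            for u, v, d in graph.edges(data=True)
            if u in side and v not in side
        )
        best = min(best, cut)
    return float(best)
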