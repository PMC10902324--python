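"""Domain types and modularity computations for multilayer gene networks.

A multilayer network is a stack of undirected, weighted gene graphs
(layers) over the union of their node sets.  A single partition of that
node universe is scored by summing, over layers, the Newman-Girvan
modularity with a resolution parameter ``gamma`` multiplying the
configuration-null term:

    Q_l(P; gamma) = sum_c [ w_c / W_l - gamma * (d_c / (2 W_l))**2 ]

where ``w_c`` is the intra-community edge weight (self-loops counted once),
``d_c`` the total weighted degree of the community's nodes (self-loops
count twice) and ``W_l`` the layer's total edge weight.  Larger ``gamma``
penalizes large communities, yielding finer partitions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Mapping, Optional, Sequence, Set, Tuple

logger = logging.getLogger("multicom")

GeneId = str

Edge = Tuple[GeneId, GeneId]  # canonical: lexicographically sorted pair


def _check_gene_id(g: GeneId) -> GeneId:
    if not isinstance(g, str) or not g or any(ch.isspace() for ch in g):
        raise ValueError(f"invalid gene id: {g!r} (non-empty, no whitespace)")
    return g


def edge_key(a: GeneId, b: GeneId) -> Edge:
    """Canonical unordered representation of an edge."""
    return (a, b) if a <= b else (b, a)


@dataclass
class Layer:
    """One undirected weighted gene graph.

    ``edges`` maps canonical unordered pairs to positive weights.
    Self-loops are forbidden in user-supplied layers; internal condensed
    layers produced by Louvain aggregation may carry them
    (``allow_self_loops=True``).
    """

    name: str
    nodes: Set[GeneId] = field(default_factory=set)
    edges: Dict[Edge, float] = field(default_factory=dict)
    allow_self_loops: bool = False

    def __post_init__(self) -> None:
        for g in self.nodes:
            _check_gene_id(g)
        canon: Dict[Edge, float] = {}
        for (a, b), w in self.edges.items():
            if w <= 0:
                raise ValueError(f"layer {self.name!r}: non-positive weight on {(a, b)}")
            if a == b and not self.allow_self_loops:
                raise ValueError(f"layer {self.name!r}: self-loop on {a!r}")
            k = edge_key(a, b)
            canon[k] = canon.get(k, 0.0) + w
        self.edges = canon
        missing = {g for e in self.edges for g in e} - self.nodes
        if missing:
            self.nodes |= missing

    @classmethod
    def from_edges(
        cls,
        name: str,
        edges: Iterable[Tuple[GeneId, GeneId]] | Mapping[Edge, float],
        nodes: Optional[Iterable[GeneId]] = None,
        allow_self_loops: bool = False,
    ) -> "Layer":
        if isinstance(edges, Mapping):
            e = dict(edges)
        else:
            e = {}
            for a, b in edges:
                k = edge_key(a, b)
                e[k] = e.get(k, 0.0) + 1.0
        return cls(name=name, nodes=set(nodes or ()), edges=e, allow_self_loops=allow_self_loops)

    @property
    def total_weight(self) -> float:
        """Total edge weight W_l (each undirected edge once, self-loops once)."""
        return sum(self.edges.values())

    def degrees(self) -> Dict[GeneId, float]:
        """Weighted degree per node; a self-loop contributes twice its weight."""
        d = {g: 0.0 for g in self.nodes}
        for (a, b), w in self.edges.items():
            if a == b:
                d[a] += 2.0 * w
            else:
                d[a] += w
                d[b] += w
        return d

    def adjacency(self) -> Dict[GeneId, Dict[GeneId, float]]:
        """Neighbor map excluding self-loops (used by local moving)."""
        adj: Dict[GeneId, Dict[GeneId, float]] = {g: {} for g in self.nodes}
        for (a, b), w in self.edges.items():
            if a == b:
                continue
            adj[a][b] = adj[a].get(b, 0.0) + w
            adj[b][a] = adj[b].get(a, 0.0) + w
        return adj


@dataclass
class MultilayerNetwork:
    """An ordered stack of layers clustered with one common partition.

    A node absent from a layer is treated as isolated (degree 0) there.
    """

    layers: Sequence[Layer]

    def __post_init__(self) -> None:
        if len(self.layers) < 1:
            raise ValueError("a multilayer network needs at least one layer")
        names = [l.name for l in self.layers]
        if len(set(names)) != len(names):
            raise ValueError(f"layer names must be unique, got {names}")

    @property
    def node_universe(self) -> Set[GeneId]:
        u: Set[GeneId] = set()
        for l in self.layers:
            u |= l.nodes
        return u

    @property
    def n_layers(self) -> int:
        return len(self.layers)


@dataclass
class Partition:
    """A total assignment of the node universe to integer community labels."""

    assignment: Dict[GeneId, int]

    def __post_init__(self) -> None:
        for c in self.assignment.values():
            if c < 0:
                raise ValueError("community labels must be non-negative")

    @property
    def nodes(self) -> Set[GeneId]:
        return set(self.assignment)

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def communities(self) -> Dict[int, Set[GeneId]]:
        out: Dict[int, Set[GeneId]] = {}
        for g, c in self.assignment.items():
            out.setdefault(c, set()).add(g)
        return out

    def canonicalized(self) -> "Partition":
        """Relabel communities 0..k-1 by first appearance in sorted node order."""
        relabel: Dict[int, int] = {}
        out: Dict[GeneId, int] = {}
        for g in sorted(self.assignment):
            c = self.assignment[g]
            if c not in relabel:
                relabel[c] = len(relabel)
            out[g] = relabel[c]
        return Partition(out)

    def restricted(self, nodes: Set[GeneId]) -> "Partition":
        return Partition({g: c for g, c in self.assignment.items() if g in nodes})

    def same_community(self, a: GeneId, b: GeneId) -> bool:
        return self.assignment[a] == self.assignment[b]


# ---------------------------------------------------------------------------
# Layer construction
# ---------------------------------------------------------------------------

def project_shared_membership(groups: Mapping[str, Set[GeneId]], name: str = "projection") -> Layer:
    """Bipartite projection of a named gene-set collection onto genes.

    Two distinct genes are connected (weight 1) iff they co-occur in at
    least one group; e.g. shared-pathway or shared-metabolite layers built
    from any GMT catalog.
    """
    if not groups:
        raise ValueError("no groups")
    nodes: Set[GeneId] = set()
    edges: Dict[Edge, float] = {}
    for members in groups.values():
        ms = sorted(members)
        nodes.update(ms)
        for i, a in enumerate(ms):
            for b in ms[i + 1:]:
                edges[edge_key(a, b)] = 1.0
    return Layer(name=name, nodes=nodes, edges=edges)


# ---------------------------------------------------------------------------
# Modularity
# ---------------------------------------------------------------------------

def layer_modularity(layer: Layer, partition: Partition, gamma: float) -> float:
    """Resolution-parametrized Newman-Girvan modularity of one layer."""
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    W = layer.total_weight
    if W <= 0:
        raise ValueError(f"empty layer {layer.name!r} (total weight 0)")
    missing = layer.nodes - partition.nodes
    if missing:
        raise ValueError(f"partition does not cover layer nodes: {sorted(missing)[:5]}")
    asg = partition.assignment
    w_c: Dict[int, float] = {}
    d_c: Dict[int, float] = {}
    for (a, b), w in layer.edges.items():
        ca, cb = asg[a], asg[b]
        if a == b:
            w_c[ca] = w_c.get(ca, 0.0) + w
            d_c[ca] = d_c.get(ca, 0.0) + 2.0 * w
        else:
            if ca == cb:
                w_c[ca] = w_c.get(ca, 0.0) + w
            d_c[ca] = d_c.get(ca, 0.0) + w
            d_c[cb] = d_c.get(cb, 0.0) + w
    q = 0.0
    for c, d in d_c.items():
        q += w_c.get(c, 0.0) / W - gamma * (d / (2.0 * W)) ** 2
    return q


def multilayer_modularity(net: MultilayerNetwork, partition: Partition, gamma: float) -> float:
    """Sum of per-layer modularities under the common partition.

    Zero-weight layers are skipped with a warning and contribute 0; the
    call errors only when every layer is empty.
    """
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    total = 0.0
    any_nonempty = False
    for layer in net.layers:
        if layer.total_weight <= 0:
            logger.warning("layer %r has zero total weight; contributes 0 to Q", layer.name)
            continue
        any_nonempty = True
        total += layer_modularity(layer, partition, gamma)
    if not any_nonempty:
        raise ValueError("all layers empty")
    return total


# ---------------------------------------------------------------------------
# Overlap and similarity measures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapReport:
    shared_edges: int
    edge_jaccard: float
    node_jaccard: float


def layer_edge_overlap(a: Layer, b: Layer) -> OverlapReport:
    """Edge- and node-level Jaccard overlap between two layers (symmetric)."""
    if not a.edges or not b.edges:
        raise ValueError("both layers must be nonempty")
    ea, eb = set(a.edges), set(b.edges)
    shared = ea & eb
    union = ea | eb
    nu = a.nodes | b.nodes
    ni = a.nodes & b.nodes
    return OverlapReport(
        shared_edges=len(shared),
        edge_jaccard=len(shared) / len(union),
        node_jaccard=len(ni) / len(nu) if nu else 0.0,
    )


def community_similarity(
    comm_a: Set[GeneId], comm_b: Set[GeneId], genes_of_interest: Set[GeneId]
) -> float:
    """Shared genes of interest divided by the sum of the community sizes.

    This size-sum denominator is deliberate (range [0, 0.5]); for the
    conventional index see :func:`gene_set_jaccard`.
    """
    if not comm_a and not comm_b:
        raise ValueError("both communities empty")
    shared = comm_a & comm_b & genes_of_interest
    return len(shared) / (len(comm_a) + len(comm_b))


def gene_set_jaccard(a: Set[GeneId], b: Set[GeneId]) -> float:
    """Standard Jaccard index |a & b| / |a | b|."""
    u = a | b
    if not u:
        raise ValueError("both sets empty")
    return len(a & b) / len(u)
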