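"""Generalized Louvain maximization of multilayer modularity.

All layers are clustered with a single common partition; the objective is
the sum over layers of resolution-parametrized modularities (see
:mod:`multicom.core`).  The algorithm is the classic two-phase Louvain:
seeded local moving from singletons, then condensation of communities into
super-nodes, repeated until no improving move exists.  Runs are
deterministic given (network, gamma, seed): the only randomness is the
seeded node visiting order.

An exhaustive enumerator over all set partitions is provided as an oracle
for small instances.
"""

from __future__ import annotations

import logging
import random
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .core import (
    GeneId,
    Layer,
    MultilayerNetwork,
    Partition,
    edge_key,
    multilayer_modularity,
)

logger = logging.getLogger("multicom")

# Moves must improve Q by more than this to count (floating-point livelock guard).
MIN_GAIN = 1e-12


# ---------------------------------------------------------------------------
# Aggregation (phase 2 condensation)
# ---------------------------------------------------------------------------

def aggregate(net: MultilayerNetwork, partition: Partition) -> MultilayerNetwork:
    """Condense communities into super-nodes, layer by layer.

    Inter-community weights are summed into single edges; intra-community
    weight becomes a self-loop of the same total, so every layer's total
    weight — and the modularity of the induced partition — is conserved.
    Super-nodes are named by the community label as a string.
    """
    universe = net.node_universe
    missing = universe - partition.nodes
    if missing:
        raise ValueError(f"partition does not cover the node universe: {sorted(missing)[:5]}")
    asg = partition.assignment
    labels = {asg[g] for g in universe}
    new_layers: List[Layer] = []
    for layer in net.layers:
        edges: Dict[Tuple[str, str], float] = {}
        for (a, b), w in layer.edges.items():
            ca, cb = str(asg[a]), str(asg[b])
            k = edge_key(ca, cb)
            edges[k] = edges.get(k, 0.0) + w
        new_layers.append(
            Layer(
                name=layer.name,
                nodes={str(c) for c in labels},
                edges=edges,
                allow_self_loops=True,
            )
        )
    return MultilayerNetwork(layers=new_layers)


# ---------------------------------------------------------------------------
# Local moving on one level
# ---------------------------------------------------------------------------

class _LayerState:
    """Per-layer bookkeeping for incremental modularity gains."""

    __slots__ = ("W", "adj", "deg", "sigma_deg")

    def __init__(self, layer: Layer, universe: Sequence[GeneId], node_comm: Dict[GeneId, int]):
        self.W = layer.total_weight
        self.adj = layer.adjacency()
        deg = layer.degrees()
        self.deg = {g: deg.get(g, 0.0) for g in universe}
        self.sigma_deg: Dict[int, float] = {}
        for g in universe:
            c = node_comm[g]
            self.sigma_deg[c] = self.sigma_deg.get(c, 0.0) + self.deg[g]


def _local_moving(
    net: MultilayerNetwork, gamma: float, rng: random.Random
) -> Tuple[Dict[GeneId, int], bool]:
    """One Louvain level: move nodes between communities until stable.

    Returns the node->community map and whether any move was made.
    """
    universe = sorted(net.node_universe)
    node_comm: Dict[GeneId, int] = {g: i for i, g in enumerate(universe)}
    next_label = len(universe)
    # zero-weight layers contribute nothing to Q and are skipped
    states = [
        _LayerState(l, universe, node_comm) for l in net.layers if l.total_weight > 0
    ]
    if not states:
        raise ValueError("all layers empty")

    comm_sizes: Dict[int, int] = {c: 1 for c in node_comm.values()}
    any_move = False
    while True:
        order = list(universe)
        rng.shuffle(order)
        moved_this_pass = False
        for v in order:
            cur = node_comm[v]
            # candidate communities: adjacent in any layer, plus a fresh singleton
            k_v: List[Dict[int, float]] = []
            cands: Set[int] = set()
            for st in states:
                kl: Dict[int, float] = {}
                for u, w in st.adj.get(v, {}).items():
                    cu = node_comm[u]
                    kl[cu] = kl.get(cu, 0.0) + w
                k_v.append(kl)
                cands.update(kl)
            cands.discard(cur)
            fresh: Optional[int] = None
            if comm_sizes[cur] > 1:
                fresh = next_label
                cands.add(fresh)
            if not cands:
                continue

            # gain of removing v from its current community, per layer
            base = 0.0
            for st, kl in zip(states, k_v):
                d_v = st.deg[v]
                sd_cur = st.sigma_deg[cur] - d_v
                base += -kl.get(cur, 0.0) / st.W + gamma * d_v * sd_cur / (2.0 * st.W * st.W)

            best_gain = MIN_GAIN
            best_c: Optional[int] = None
            for c in sorted(cands):
                gain = base
                if c != fresh:
                    for st, kl in zip(states, k_v):
                        d_v = st.deg[v]
                        sd_c = st.sigma_deg.get(c, 0.0)
                        gain += kl.get(c, 0.0) / st.W - gamma * d_v * sd_c / (2.0 * st.W * st.W)
                if gain > best_gain:  # ties keep the smallest label (sorted scan)
                    best_gain = gain
                    best_c = c
            if best_c is None:
                continue

            if best_c == fresh:
                next_label += 1
            for st in states:
                d_v = st.deg[v]
                st.sigma_deg[cur] -= d_v
                st.sigma_deg[best_c] = st.sigma_deg.get(best_c, 0.0) + d_v
            comm_sizes[cur] -= 1
            if comm_sizes[cur] == 0:
                del comm_sizes[cur]
            comm_sizes[best_c] = comm_sizes.get(best_c, 0) + 1
            node_comm[v] = best_c
            moved_this_pass = True
            any_move = True
        if not moved_this_pass:
            break
    return node_comm, any_move


# ---------------------------------------------------------------------------
# Public entry points
# ---------------------------------------------------------------------------

def louvain_multilayer(
    net: MultilayerNetwork,
    gamma: float,
    seed: int,
    n_restarts: int = 1,
    trace: Optional[List[float]] = None,
) -> Partition:
    """Seeded generalized Louvain on a multilayer network.

    Starts from singletons; each accepted local move strictly increases
    the summed modularity; local moving and condensation alternate until a
    level produces no move.  With ``n_restarts > 1`` the best of k seeded
    runs (seed, seed+1, ...) is returned.  ``trace``, if given, collects
    the Q value after each level.
    """
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    if not any(l.total_weight > 0 for l in net.layers):
        raise ValueError("all layers empty")
    if n_restarts > 1:
        best: Optional[Partition] = None
        best_q = float("-inf")
        for r in range(n_restarts):
            p = louvain_multilayer(net, gamma, seed + r)
            q = multilayer_modularity(net, p, gamma)
            if q > best_q + MIN_GAIN:
                best_q, best = q, p
        assert best is not None
        return best

    rng = random.Random(seed)
    universe = sorted(net.node_universe)
    # original node -> community label; at level > 0 the level-net node
    # carrying gene g is named str(orig_label[g])
    orig_label: Dict[GeneId, int] = {g: i for i, g in enumerate(universe)}
    level_net = net
    first_level = True

    while True:
        node_comm, moved = _local_moving(level_net, gamma, rng)
        canon = Partition(dict(node_comm)).canonicalized()
        n_comms = canon.n_communities
        if not moved or n_comms == len(node_comm):
            break
        if first_level:
            orig_label = {g: canon.assignment[g] for g in universe}
            first_level = False
        else:
            orig_label = {g: canon.assignment[str(c)] for g, c in orig_label.items()}
        if trace is not None:
            trace.append(multilayer_modularity(net, Partition(dict(orig_label)), gamma))
        if n_comms == 1:
            break
        level_net = aggregate(level_net, canon)

    result = Partition(dict(orig_label)).canonicalized()
    if trace is not None and not trace:
        trace.append(multilayer_modularity(net, result, gamma))
    return result


def louvain_monolayer(layer: Layer, gamma: float, seed: int, n_restarts: int = 1) -> Partition:
    """Louvain on a single layer (multilayer special case with L=1)."""
    return louvain_multilayer(MultilayerNetwork([layer]), gamma, seed, n_restarts=n_restarts)


# ---------------------------------------------------------------------------
# Exhaustive oracle
# ---------------------------------------------------------------------------

def _restricted_growth_strings(n: int):
    """All set partitions of range(n) as restricted growth strings, in
    lexicographic order (the canonical labeling over sorted nodes)."""
    a = [0] * n
    b = [0] * n  # b[i] = max(a[:i+1]); b[0] = 0
    while True:
        yield list(a)
        # increment from the right
        i = n - 1
        while i > 0 and a[i] == b[i - 1] + 1:
            i -= 1
        if i == 0:
            return
        a[i] += 1
        b[i] = max(b[i - 1], a[i])
        for j in range(i + 1, n):
            a[j] = 0
            b[j] = b[i]


def exhaustive_best_partition(
    net: MultilayerNetwork, gamma: float, max_nodes: int = 10
) -> Tuple[Partition, float]:
    """Enumerate every set partition of the node universe and return one of
    maximal Q (lexicographically smallest canonical labeling on ties)."""
    universe = sorted(net.node_universe)
    n = len(universe)
    if n > max_nodes:
        raise ValueError(f"{n} nodes exceeds the exhaustive bound of {max_nodes}")
    best_q = float("-inf")
    best: Optional[Partition] = None
    for rgs in _restricted_growth_strings(n):
        p = Partition({g: c for g, c in zip(universe, rgs)})
        q = multilayer_modularity(net, p, gamma)
        if q > best_q + 1e-12:  # strict: first (lexicographically smallest) wins ties
            best_q, best = q, p
    assert best is not None
    return best, best_q
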