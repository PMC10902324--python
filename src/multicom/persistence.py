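"""Resolution sweep and persistence-module extraction.

A sweep runs multilayer Louvain at each value of a resolution grid
(default: 8 evenly spaced values covering (0, 4]).  For a designated set
of genes of interest, co-membership counts record at how many grid values
each gene pair shared a community.  A *module* is a connected component
(size >= 2) of the co-membership graph thresholded at n shared values; at
n = len(grid) its genes co-cluster over the entire resolution range.  The
*persistent core* of a fully persistent module is the intersection, over
grid values, of the full network community containing it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx

from .core import GeneId, MultilayerNetwork, Partition
from .detect import louvain_multilayer

logger = logging.getLogger("multicom")

DEFAULT_GRID: Tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)

Pair = Tuple[GeneId, GeneId]


def _pair(a: GeneId, b: GeneId) -> Pair:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class ResolutionGrid:
    """Strictly increasing positive resolution values (default 8 over (0,4])."""

    values: Tuple[float, ...] = DEFAULT_GRID

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError("empty resolution grid")
        if any(v <= 0 for v in self.values):
            raise ValueError("resolution values must be positive")
        if any(b <= a for a, b in zip(self.values, self.values[1:])):
            raise ValueError("resolution values must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class SweepResult:
    """Partitions, seeds and Q values from one resolution sweep."""

    grid: ResolutionGrid
    partitions: List[Partition]
    seeds: List[int]
    q_values: List[float]

    def __post_init__(self) -> None:
        if not (len(self.partitions) == len(self.grid) == len(self.seeds) == len(self.q_values)):
            raise ValueError("sweep components must have one entry per grid value")

    @property
    def node_universe(self) -> Set[GeneId]:
        return self.partitions[0].nodes


@dataclass
class CoMembership:
    """Per-pair counts of shared community membership across the sweep."""

    counts: Dict[Pair, int]
    n_grid: int
    retained: Set[GeneId]
    dropped: Set[GeneId]

    def count(self, a: GeneId, b: GeneId) -> int:
        return self.counts.get(_pair(a, b), 0)


@dataclass
class Module:
    """A group (>= 2) of genes of interest co-clustered at >= n grid values."""

    genes: FrozenSet[GeneId]
    threshold: int
    anchored: bool = False

    @property
    def size(self) -> int:
        return len(self.genes)


def sweep(
    net: MultilayerNetwork,
    grid: ResolutionGrid | Sequence[float] = DEFAULT_GRID,
    seed: int = 0,
    n_restarts: int = 1,
) -> SweepResult:
    """Run multilayer Louvain at every grid value.

    Per-value seeds are derived as ``seed + index`` so each value can be
    re-run in isolation; the result feeds every downstream statistic.
    """
    from .core import multilayer_modularity

    if not isinstance(grid, ResolutionGrid):
        grid = ResolutionGrid(tuple(grid))
    partitions, seeds, qs = [], [], []
    for i, gamma in enumerate(grid.values):
        s = seed + i
        try:
            p = louvain_multilayer(net, gamma, s, n_restarts=n_restarts)
        except Exception as exc:
            raise RuntimeError(f"community detection failed at gamma={gamma}: {exc}") from exc
        partitions.append(p)
        seeds.append(s)
        qs.append(multilayer_modularity(net, p, gamma))
        logger.info("sweep gamma=%g seed=%d Q=%.6f communities=%d", gamma, s, qs[-1], p.n_communities)
    return SweepResult(grid=grid, partitions=partitions, seeds=seeds, q_values=qs)


def co_membership_counts(sweep_result: SweepResult, genes_of_interest: Set[GeneId]) -> CoMembership:
    """Count, per unordered gene pair, the grid values at which both genes
    share a community.  Genes absent from the network are dropped with a
    warning (they cannot co-cluster)."""
    universe = sweep_result.node_universe
    retained = sorted(genes_of_interest & universe)
    dropped = set(genes_of_interest) - universe
    if dropped:
        logger.warning("dropping %d genes of interest not present in the network", len(dropped))
    if not retained:
        raise ValueError("no genes of interest present in the network")
    counts: Dict[Pair, int] = {}
    for p in sweep_result.partitions:
        asg = p.assignment
        by_comm: Dict[int, List[GeneId]] = {}
        for g in retained:
            by_comm.setdefault(asg[g], []).append(g)
        for members in by_comm.values():
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    k = _pair(a, b)
                    counts[k] = counts.get(k, 0) + 1
    return CoMembership(
        counts=counts, n_grid=len(sweep_result.grid), retained=set(retained), dropped=dropped
    )


def extract_modules(
    comember: CoMembership, n: int, anchor_genes: Optional[Set[GeneId]] = None
) -> List[Module]:
    """Connected components (size >= 2) of the co-membership graph
    thresholded at count >= n, sorted by decreasing size then smallest
    member.  ``anchor_genes`` marks modules containing a known causal gene."""
    if not (1 <= n <= comember.n_grid):
        raise ValueError(f"threshold n={n} outside [1, {comember.n_grid}]")
    g = nx.Graph()
    for (a, b), c in comember.counts.items():
        if c >= n:
            g.add_edge(a, b)
    anchors = anchor_genes or set()
    modules = [
        Module(genes=frozenset(comp), threshold=n, anchored=bool(comp & anchors))
        for comp in nx.connected_components(g)
        if len(comp) >= 2
    ]
    modules.sort(key=lambda m: (-m.size, min(m.genes)))
    return modules


def largest_module_with(modules: Sequence[Module], anchor_genes: Set[GeneId]) -> Optional[Module]:
    """Largest module intersecting the anchor set (ties: smallest member)."""
    hits = [m for m in modules if m.genes & anchor_genes]
    if not hits:
        return None
    return min(hits, key=lambda m: (-m.size, min(m.genes)))


def persistent_core(sweep_result: SweepResult, module: Module) -> Set[GeneId]:
    """All network nodes that stay in the module's community at every grid
    value: the intersection over the grid of the full community containing
    the module's genes.  Requires the module to be fully persistent
    (one community per grid value)."""
    core: Optional[Set[GeneId]] = None
    for gamma, p in zip(sweep_result.grid.values, sweep_result.partitions):
        labels = {p.assignment[g] for g in module.genes}
        if len(labels) != 1:
            raise ValueError(
                f"module genes split across {len(labels)} communities at gamma={gamma}; "
                "the persistent core is defined only for fully persistent modules — "
                "export per-gamma communities instead"
            )
        label = labels.pop()
        community = {g for g, c in p.assignment.items() if c == label}
        core = community if core is None else core & community
    assert core is not None
    return core


# ---------------------------------------------------------------------------
# Group-specific gene sets ("CMS-linked" construction)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupGeneSets:
    """Severity-group unions and private sets of patient variant genes.

    The linked gene set (causal genes plus both groups' variant genes) is
    the universe over which persistence modules are defined; the private
    sets anchor the group-specific analyses.
    """

    severe_union: FrozenSet[GeneId]
    not_severe_union: FrozenSet[GeneId]
    severe_private: FrozenSet[GeneId]
    not_severe_private: FrozenSet[GeneId]
    linked: FrozenSet[GeneId]
    per_class_counts: Mapping[str, Mapping[str, int]]


def build_group_gene_sets(
    causal: Set[GeneId],
    per_patient_sets: Mapping[str, Mapping[str, Set[GeneId]]],
    severity_labels: Mapping[str, str],
) -> GroupGeneSets:
    """Union and group-private variant gene sets per severity class.

    ``per_patient_sets`` maps patient id -> {"compound_het": set, "cnv": set};
    ``severity_labels`` maps patient id -> "severe" | "not_severe".
    """
    unions: Dict[str, Dict[str, Set[GeneId]]] = {
        "severe": {"compound_het": set(), "cnv": set()},
        "not_severe": {"compound_het": set(), "cnv": set()},
    }
    for pid, classes in per_patient_sets.items():
        sev = severity_labels.get(pid)
        if sev not in ("severe", "not_severe"):
            raise ValueError(f"patient {pid!r} has no valid severity label (got {sev!r})")
        for cls in ("compound_het", "cnv"):
            unions[sev][cls] |= set(classes.get(cls, set()))
    severe_union = unions["severe"]["compound_het"] | unions["severe"]["cnv"]
    not_union = unions["not_severe"]["compound_het"] | unions["not_severe"]["cnv"]
    counts = {
        sev: {
            "compound_het": len(unions[sev]["compound_het"]),
            "cnv": len(unions[sev]["cnv"]),
            "combined": len(unions[sev]["compound_het"] | unions[sev]["cnv"]),
        }
        for sev in unions
    }
    return GroupGeneSets(
        severe_union=frozenset(severe_union),
        not_severe_union=frozenset(not_union),
        severe_private=frozenset(severe_union - not_union),
        not_severe_private=frozenset(not_union - severe_union),
        linked=frozenset(set(causal) | severe_union | not_union),
        per_class_counts=counts,
    )
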