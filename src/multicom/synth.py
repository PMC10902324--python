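"""Synthetic inputs with the statistical structure the analysis assumes.

The generator plants a single community partition shared by all layers —
an independent-edge stochastic block model per layer, with per-layer node
coverage masks emulating layers built from heterogeneous sources — and on
top of it a patient cohort whose severe group carries community-coherent
private variant genes, plus a disease->genes catalog with a tunable
fraction of community-coherent sets.  Everything is seeded and
deterministic.

Default study conditions: 3 communities of 30 genes, 3 layers at full
coverage with intra/inter edge probabilities 0.3 / 0.01; a 20-patient
cohort (8 severe / 12 not-severe) with 10 background genes per patient
and 5 community-coherent signal genes per severe patient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .core import GeneId, Layer, MultilayerNetwork, Partition, edge_key
from .stats import Cohort, GeneSetCatalog, Patient


@dataclass(frozen=True)
class PlantedTruth:
    """Ground-truth partition and the generator parameters behind it."""

    partition: Partition
    sizes: Tuple[int, ...]
    p_in: float
    p_out: float
    n_layers: int
    coverage: Tuple[float, ...]
    seed: int

    def community(self, label: int) -> Set[GeneId]:
        return {g for g, c in self.partition.assignment.items() if c == label}


def _gene_ids(n: int) -> List[GeneId]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


def simulate_multilayer(
    sizes: Sequence[int] = (30, 30, 30),
    L: int = 3,
    p_in: float = 0.3,
    p_out: float = 0.01,
    coverage: Optional[Sequence[float]] = None,
    seed: int = 0,
) -> Tuple[MultilayerNetwork, PlantedTruth]:
    """Planted-partition multilayer network: one shared block structure,
    independent edges per layer, optional per-layer node coverage.

    Each layer keeps every node with probability ``coverage[l]`` (at least
    2 nodes per community are always retained, so the planted structure
    stays visible in every layer).
    """
    if coverage is None:
        coverage = [1.0] * L
    if len(coverage) != L:
        raise ValueError(f"need one coverage value per layer ({L}), got {len(coverage)}")
    if not all(0 < c <= 1 for c in coverage):
        raise ValueError("coverage values must lie in (0, 1]")
    if p_in <= p_out:
        raise ValueError("unidentifiable planted structure: require p_in > p_out")
    if p_out < 0 or p_in > 1:
        raise ValueError("edge probabilities must lie in [0, 1]")
    n = sum(sizes)
    genes = _gene_ids(n)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    truth = Partition({g: int(c) for g, c in zip(genes, labels)})
    rng = np.random.default_rng(seed)
    layers: List[Layer] = []
    for l in range(L):
        keep = rng.random(n) < coverage[l]
        # force >= 2 retained nodes per community
        for c in range(len(sizes)):
            members = np.flatnonzero(labels == c)
            kept = members[keep[members]]
            if kept.size < 2:
                extra = rng.choice(members, size=2 - kept.size, replace=False)
                keep[extra] = True
        nodes_idx = np.flatnonzero(keep)
        edges: Dict[Tuple[GeneId, GeneId], float] = {}
        for a_pos, i in enumerate(nodes_idx):
            for j in nodes_idx[a_pos + 1:]:
                p = p_in if labels[i] == labels[j] else p_out
                if rng.random() < p:
                    edges[edge_key(genes[i], genes[j])] = 1.0
        layers.append(
            Layer(name=f"layer{l}", nodes={genes[i] for i in nodes_idx}, edges=edges)
        )
    net = MultilayerNetwork(layers)
    return net, PlantedTruth(
        partition=truth,
        sizes=tuple(int(s) for s in sizes),
        p_in=p_in,
        p_out=p_out,
        n_layers=L,
        coverage=tuple(float(c) for c in coverage),
        seed=seed,
    )


def simulate_cohort(
    truth: PlantedTruth,
    n_severe: int = 8,
    n_not: int = 12,
    signal_community: Optional[int] = 0,
    k_signal: int = 5,
    k_background: int = 10,
    n_causal: int = 3,
    seed: int = 0,
) -> Tuple[Cohort, Set[GeneId]]:
    """Patient cohort with group-private variant genes.

    Every patient draws ``k_background`` genes uniformly from the node
    universe; each severe patient additionally draws ``k_signal`` genes
    from the planted ``signal_community``.  The causal genes are a
    held-out subset of the signal community (excluded from the severe
    signal draws), so a causal-anchored severe module exists by
    construction; with ``signal_community=None`` the cohort is a null
    (exchangeable) cohort and the causal genes are random.
    """
    if n_severe < 1 or n_not < 1:
        raise ValueError("both severity classes need at least one patient")
    rng = np.random.default_rng(seed)
    universe = sorted(truth.partition.nodes)
    if signal_community is not None:
        comm = sorted(truth.community(signal_community))
        if k_signal + n_causal > len(comm):
            raise ValueError(
                f"k_signal + n_causal = {k_signal + n_causal} exceeds the "
                f"signal community size {len(comm)}"
            )
        causal = set(rng.choice(comm, size=n_causal, replace=False).tolist())
        signal_pool = sorted(set(comm) - causal)
    else:
        causal = set(rng.choice(universe, size=n_causal, replace=False).tolist())
        signal_pool = []
    fine_cycle = ["mild"] * (n_not - min(2, n_not)) + ["intermediate"] * min(2, n_not)
    patients: List[Patient] = []
    for i in range(n_severe + n_not):
        severe = i < n_severe
        genes: Set[GeneId] = set()
        if k_background > 0:
            genes |= set(rng.choice(universe, size=k_background, replace=False).tolist())
        if severe and signal_pool and k_signal > 0:
            genes |= set(rng.choice(signal_pool, size=k_signal, replace=False).tolist())
        glist = sorted(genes)
        half = len(glist) // 2
        patients.append(
            Patient(
                id=f"P{i + 1:02d}",
                severity="severe" if severe else "not_severe",
                compound_het_genes=set(glist[:half]),
                cnv_genes=set(glist[half:]),
                fine_label="severe" if severe else fine_cycle[(i - n_severe) % len(fine_cycle)],
                treatment=bool(rng.random() < 0.65),
            )
        )
    return Cohort(patients), causal


def simulate_catalog(
    truth: PlantedTruth,
    n_sets: int = 100,
    size_range: Tuple[int, int] = (2, 10),
    coherent_fraction: float = 1.0,
    seed: int = 0,
) -> GeneSetCatalog:
    """Disease->genes catalog with a tunable fraction of sets drawn wholly
    from one planted community (coherent) vs uniformly from the universe
    (the validation null mechanism)."""
    lo, hi = size_range
    if lo < 2:
        raise ValueError("minimum set size must be >= 2")
    if not (0 <= coherent_fraction <= 1):
        raise ValueError("coherent_fraction must lie in [0, 1]")
    min_comm = min(truth.sizes)
    if hi > min_comm:
        raise ValueError(
            f"size_range max {hi} exceeds the smallest community ({min_comm} genes)"
        )
    rng = np.random.default_rng(seed)
    universe = sorted(truth.partition.nodes)
    communities = [sorted(truth.community(c)) for c in range(len(truth.sizes))]
    sets: Dict[str, Set[GeneId]] = {}
    n_coherent = int(round(coherent_fraction * n_sets))
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        if i < n_coherent:
            pool = communities[int(rng.integers(len(communities)))]
        else:
            pool = universe
        sets[f"D{i + 1:04d}"] = set(rng.choice(pool, size=size, replace=False).tolist())
    return GeneSetCatalog(sets)


def adjusted_rand_index(p1: Partition, p2: Partition) -> float:
    """Chance-corrected agreement between two partitions of the same
    nodes; 1 iff identical up to relabeling."""
    if p1.nodes != p2.nodes:
        raise ValueError("partitions must cover the same node set")
    nodes = sorted(p1.nodes)
    a = [p1.assignment[g] for g in nodes]
    b = [p2.assignment[g] for g in nodes]
    return float(adjusted_rand_score(a, b))
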