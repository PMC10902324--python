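"""Randomization-based significance procedures for the module analysis.

Three null models are implemented:

* catalog validation — each gene set of a disease->genes catalog is
  replaced by a size-matched uniform draw from the network's nodes
  ("balanced" randomization); observed per-set co-membership statistics
  are compared with the pooled null by a one-sided rank-sum test;
* severity-label shuffling — severity labels are permuted among patients
  (class sizes preserved), the group gene sets rebuilt, and the size of
  the largest causal-anchored module recorded, yielding a null
  distribution of module sizes;
* minimum significant module size — add-one permutation p-values
  p(k) = (1 + #{null >= k}) / (1 + R) for each candidate size k, adjusted
  by Benjamini-Hochberg, give the smallest module size not expected at
  random.

Classical tests (Fisher exact, Wilcoxon rank-sum, BH adjustment) are
delegated to scipy/statsmodels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import GeneId, Partition
from .persistence import Module, SweepResult, build_group_gene_sets

logger = logging.getLogger("multicom")

SEVERITIES = ("severe", "not_severe")
FINE_LABELS = ("mild", "intermediate", "severe")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCatalog:
    """Named gene sets (disease -> associated genes)."""

    sets: Dict[str, Set[GeneId]]

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def sizes(self) -> Dict[str, int]:
        return {name: len(g) for name, g in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class Patient:
    id: str
    severity: str
    compound_het_genes: Set[GeneId] = field(default_factory=set)
    cnv_genes: Set[GeneId] = field(default_factory=set)
    fine_label: Optional[str] = None
    treatment: Optional[bool] = None
    clinical_vars: Dict[str, Optional[bool]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.severity not in SEVERITIES:
            raise ValueError(
                f"patient {self.id!r}: severity {self.severity!r} not in {SEVERITIES}"
            )
        if self.fine_label is not None:
            if self.fine_label not in FINE_LABELS:
                raise ValueError(
                    f"patient {self.id!r}: fine label {self.fine_label!r} not in {FINE_LABELS}"
                )
            implied = "severe" if self.fine_label == "severe" else "not_severe"
            if implied != self.severity:
                raise ValueError(
                    f"patient {self.id!r}: fine label {self.fine_label!r} inconsistent "
                    f"with severity {self.severity!r}"
                )

    @property
    def variant_genes(self) -> Set[GeneId]:
        return self.compound_het_genes | self.cnv_genes


@dataclass
class Cohort:
    patients: List[Patient]

    def __post_init__(self) -> None:
        ids = [p.id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate patient ids")

    @property
    def n_severe(self) -> int:
        return sum(p.severity == "severe" for p in self.patients)

    @property
    def n_not_severe(self) -> int:
        return sum(p.severity == "not_severe" for p in self.patients)

    def severity_labels(self) -> Dict[str, str]:
        return {p.id: p.severity for p in self.patients}

    def per_patient_sets(self) -> Dict[str, Dict[str, Set[GeneId]]]:
        return {
            p.id: {"compound_het": set(p.compound_het_genes), "cnv": set(p.cnv_genes)}
            for p in self.patients
        }


# ---------------------------------------------------------------------------
# Catalog preprocessing and co-membership statistic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CatalogFilterReport:
    n_initial: int
    n_dropped_singleton: int
    n_dropped_oversized: int
    size_cutoff: float
    n_genes_dropped_off_network: int
    n_dropped_below_pair: int
    n_retained: int
    mean_genes_per_set: float


def preprocess_catalog(
    catalog: GeneSetCatalog,
    network_nodes: Set[GeneId],
    iqr_mult: float = 1.5,
) -> Tuple[GeneSetCatalog, CatalogFilterReport]:
    """Size- and coverage-filter a gene-set catalog before validation.

    In order: (1) drop size-1 sets; (2) drop sets larger than
    Q3 + iqr_mult * IQR of the remaining size distribution (linear-
    interpolation quantiles); (3) intersect each set with the network's
    nodes; (4) drop sets reduced below 2 genes.
    """
    if not catalog.sets:
        raise ValueError("empty catalog")
    n0 = len(catalog)
    kept = {n: set(g) for n, g in catalog.sets.items() if len(g) >= 2}
    n_singleton = n0 - len(kept)
    sizes = np.array([len(g) for g in kept.values()], dtype=float)
    if sizes.size == 0:
        raise ValueError("catalog empty after removing single-gene sets")
    q1, q3 = np.percentile(sizes, [25, 75])
    cutoff = q3 + iqr_mult * (q3 - q1)
    kept2 = {n: g for n, g in kept.items() if len(g) <= cutoff}
    n_oversized = len(kept) - len(kept2)
    dropped_genes = 0
    kept3: Dict[str, Set[GeneId]] = {}
    for n, g in kept2.items():
        on_net = g & network_nodes
        dropped_genes += len(g) - len(on_net)
        kept3[n] = on_net
    final = {n: g for n, g in kept3.items() if len(g) >= 2}
    n_below = len(kept3) - len(final)
    if not final:
        raise ValueError("catalog empty after filtering")
    mean_size = float(np.mean([len(g) for g in final.values()]))
    report = CatalogFilterReport(
        n_initial=n0,
        n_dropped_singleton=n_singleton,
        n_dropped_oversized=n_oversized,
        size_cutoff=float(cutoff),
        n_genes_dropped_off_network=dropped_genes,
        n_dropped_below_pair=n_below,
        n_retained=len(final),
        mean_genes_per_set=mean_size,
    )
    return GeneSetCatalog(final), report


def set_comembership_stat(partition: Partition, genes: Set[GeneId]) -> int:
    """Number of unordered pairs of (retained) genes sharing a community."""
    retained = [g for g in genes if g in partition.assignment]
    if len(retained) < 2:
        raise ValueError("fewer than 2 genes present in the partition")
    counts: Dict[int, int] = {}
    for g in retained:
        c = partition.assignment[g]
        counts[c] = counts.get(c, 0) + 1
    return sum(m * (m - 1) // 2 for m in counts.values())


# ---------------------------------------------------------------------------
# Catalog validation with balanced randomizations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CatalogValidationRow:
    gamma: float
    observed: Tuple[int, ...]           # per-set statistic, catalog order
    null_mean: float
    rank_sum_p: float                   # size-stratified one-sided rank-sum p
    pooled_rank_sum_p: float            # unstratified p against the pooled null
    stratum_p: Mapping[int, float]      # set size -> add-one empirical p of stratum mean


def _stratified_rank_sum_p(
    observed: np.ndarray, null: np.ndarray, sizes: np.ndarray
) -> float:
    """One-sided (observed greater) rank-sum p, stratified by set size.

    The balanced null matches the observed catalog's size composition
    exactly, which under-disperses the pooled rank-sum statistic; within a
    size stratum observed and null values are exchangeable, so per-stratum
    Mann-Whitney z-scores combined by sqrt(n)-weighted Stouffer give a
    calibrated p with an analytic tail.
    """
    zs: List[float] = []
    ws: List[float] = []
    for s in np.unique(sizes):
        mask = sizes == s
        obs_s = observed[mask]
        null_s = null[:, mask].ravel()
        pooled = np.concatenate([obs_s, null_s])
        if np.all(pooled == pooled[0]):
            z = 0.0  # degenerate stratum carries no evidence
        else:
            res = sps.mannwhitneyu(
                obs_s, null_s, alternative="greater",
                method="asymptotic", use_continuity=False,
            )
            p_s = float(np.clip(res.pvalue, 1e-300, 1 - 1e-16))
            z = float(sps.norm.isf(p_s))
        zs.append(z)
        ws.append(math.sqrt(obs_s.size))
    z_comb = float(np.dot(ws, zs) / math.sqrt(np.dot(ws, ws)))
    return float(sps.norm.sf(z_comb))


def catalog_validation(
    sweep_result: SweepResult,
    catalog: GeneSetCatalog,
    R: int = 1000,
    seed: int = 0,
) -> List[CatalogValidationRow]:
    """Compare per-set co-membership statistics against balanced
    randomizations at every resolution value.

    Each randomization replaces every set by a uniform same-size draw
    (without replacement) from the node universe; the pooled null feeds a
    one-sided rank-sum test (observed greater), and per set-size strata an
    add-one empirical p of the stratum mean.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    universe = sorted(sweep_result.node_universe)
    idx = {g: i for i, g in enumerate(universe)}
    names = sorted(catalog.sets)
    set_idx = [np.array([idx[g] for g in catalog.sets[n] if g in idx]) for n in names]
    for n, arr in zip(names, set_idx):
        if arr.size < 2:
            raise ValueError(
                f"set {n!r} has fewer than 2 genes on the network; preprocess the catalog first"
            )
    sizes = np.array([a.size for a in set_idx])
    rng = np.random.default_rng(seed)
    # one fixed family of R randomized catalogs, reused at every gamma
    null_sets = [
        [rng.choice(len(universe), size=s, replace=False) for s in sizes] for _ in range(R)
    ]

    def stat(labels: np.ndarray, members: np.ndarray) -> int:
        _, c = np.unique(labels[members], return_counts=True)
        return int(np.sum(c * (c - 1) // 2))

    rows: List[CatalogValidationRow] = []
    for gamma, part in zip(sweep_result.grid.values, sweep_result.partitions):
        labels = np.array([part.assignment[g] for g in universe])
        observed = np.array([stat(labels, m) for m in set_idx])
        null = np.array([[stat(labels, m) for m in draw] for draw in null_sets])  # R x n_sets
        p = _stratified_rank_sum_p(observed, null, sizes)
        pooled_p = rank_sum_test(null.ravel().tolist(), observed.tolist(), alternative="greater")
        stratum_p: Dict[int, float] = {}
        for s in sorted(set(sizes.tolist())):
            mask = sizes == s
            obs_mean = float(observed[mask].mean())
            null_means = null[:, mask].mean(axis=1)
            stratum_p[int(s)] = float((1 + np.sum(null_means >= obs_mean)) / (1 + R))
        rows.append(
            CatalogValidationRow(
                gamma=gamma,
                observed=tuple(int(v) for v in observed),
                null_mean=float(null.mean()),
                rank_sum_p=p,
                pooled_rank_sum_p=pooled_p,
                stratum_p=stratum_p,
            )
        )
    return rows


# ---------------------------------------------------------------------------
# Severity-label shuffling null
# ---------------------------------------------------------------------------

def _label_vectors(
    sweep_result: SweepResult, genes: Set[GeneId]
) -> Dict[GeneId, Tuple[int, ...]]:
    """Community label of each gene at each grid value (network genes only)."""
    universe = sweep_result.node_universe
    out: Dict[GeneId, Tuple[int, ...]] = {}
    for g in genes & universe:
        out[g] = tuple(p.assignment[g] for p in sweep_result.partitions)
    return out


def _largest_anchored_size(
    goi: Set[GeneId],
    causal: Set[GeneId],
    n: int,
    label_vec: Dict[GeneId, Tuple[int, ...]],
) -> int:
    """Size of the largest causal-anchored module at threshold n (0 if none).

    Union-find over the co-membership graph restricted to ``goi``;
    equivalent to extract_modules + largest_module_with on the same input.
    """
    members = sorted(g for g in goi if g in label_vec)
    if len(members) < 2:
        return 0
    parent = {g: g for g in members}

    def find(x: GeneId) -> GeneId:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(members):
        va = label_vec[a]
        for b in members[i + 1:]:
            vb = label_vec[b]
            if sum(x == y for x, y in zip(va, vb)) >= n:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
    comp: Dict[GeneId, List[GeneId]] = {}
    for g in members:
        comp.setdefault(find(g), []).append(g)
    best = 0
    for mem in comp.values():
        if len(mem) >= 2 and any(g in causal for g in mem) and len(mem) > best:
            best = len(mem)
    return best


def observed_group_module_sizes(
    sweep_result: SweepResult,
    cohort: Cohort,
    causal: Set[GeneId],
    n: int,
) -> Dict[str, int]:
    """Observed largest causal-anchored module size per severity group.

    The genes of interest of a group are the causal genes plus the
    group-private variant genes.
    """
    gs = build_group_gene_sets(causal, cohort.per_patient_sets(), cohort.severity_labels())
    relevant = set(causal) | set(gs.severe_union) | set(gs.not_severe_union)
    lv = _label_vectors(sweep_result, relevant)
    return {
        "severe": _largest_anchored_size(set(causal) | set(gs.severe_private), causal, n, lv),
        "not_severe": _largest_anchored_size(
            set(causal) | set(gs.not_severe_private), causal, n, lv
        ),
    }


def label_shuffle_null(
    sweep_result: SweepResult,
    cohort: Cohort,
    causal: Set[GeneId],
    n: int,
    R: int = 1000,
    seed: int = 0,
) -> Dict[str, np.ndarray]:
    """Null distribution of largest anchored-module size under severity
    label shuffling (class sizes preserved).

    The sweep's partitions do not depend on the labels, so they are
    computed once and reused for every shuffle; only the group gene sets,
    co-membership tallies and module extraction are redone.
    """
    if cohort.n_severe == 0 or cohort.n_not_severe == 0:
        raise ValueError("both severity classes must be nonempty")
    pids = [p.id for p in cohort.patients]
    true_labels = [p.severity for p in cohort.patients]
    per_patient = cohort.per_patient_sets()
    all_genes = set(causal)
    for classes in per_patient.values():
        all_genes |= classes["compound_het"] | classes["cnv"]
    lv = _label_vectors(sweep_result, all_genes)
    rng = np.random.default_rng(seed)
    null = {"severe": np.zeros(R, dtype=int), "not_severe": np.zeros(R, dtype=int)}
    for r in range(R):
        perm = rng.permutation(len(pids))
        labels = {pids[i]: true_labels[j] for i, j in enumerate(perm)}
        gs = build_group_gene_sets(causal, per_patient, labels)
        null["severe"][r] = _largest_anchored_size(
            set(causal) | set(gs.severe_private), causal, n, lv
        )
        null["not_severe"][r] = _largest_anchored_size(
            set(causal) | set(gs.not_severe_private), causal, n, lv
        )
    return null


@dataclass(frozen=True)
class ModuleSizeSignificance:
    k_min: Optional[int]
    p_by_k: Mapping[int, float]
    p_adjusted_by_k: Mapping[int, float]


def min_significant_module_size(
    null_sizes: Sequence[int],
    observed: Module,
    alpha: float = 0.05,
) -> ModuleSizeSignificance:
    """Smallest module size not expected under the label-shuffling null.

    For each candidate size k in 2..|observed|, the add-one permutation
    p-value p(k) = (1 + #{null >= k}) / (1 + R) is BH-adjusted across the
    candidate sizes; k_min is the smallest k with adjusted p <= alpha.
    """
    null = np.asarray(null_sizes)
    if null.size == 0:
        raise ValueError("empty null distribution")
    if observed.size < 2:
        raise ValueError("observed module must have at least 2 genes")
    ks = list(range(2, observed.size + 1))
    R = null.size
    pvals = [(1 + int(np.sum(null >= k))) / (1 + R) for k in ks]
    padj = bh_adjust(pvals)
    k_min = next((k for k, pa in zip(ks, padj) if pa <= alpha), None)
    return ModuleSizeSignificance(
        k_min=k_min,
        p_by_k=dict(zip(ks, pvals)),
        p_adjusted_by_k=dict(zip(ks, padj)),
    )


# ---------------------------------------------------------------------------
# Classical tests
# ---------------------------------------------------------------------------

def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-tailed Fisher exact p for a 2x2 contingency table.

    Degenerate tables (a zero row or column margin) return p = 1 with a
    warning so that scans over sparse variables complete.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("table entries must be integers")
        t = np.round(t).astype(int)
    if (t < 0).any():
        raise ValueError("table entries must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        logger.warning("degenerate 2x2 table (zero margin): p defined as 1")
        return 1.0
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], alternative: str = "two_sided"
) -> float:
    """Wilcoxon rank-sum p-value; ``greater`` tests whether y exceeds x.

    Exact enumeration for total sample size <= 20 (full permutation
    enumeration when ties are present), normal approximation with tie and
    continuity corrections otherwise.
    """
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    alt = {"greater": "greater", "less": "less", "two_sided": "two-sided"}.get(alternative)
    if alt is None:
        raise ValueError(f"unknown alternative {alternative!r}")
    xs, ys = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    pooled = np.concatenate([xs, ys])
    if np.all(pooled == pooled[0]):
        return 1.0  # no evidence either way
    total = xs.size + ys.size
    has_ties = np.unique(pooled).size < total
    if total <= 20 and not has_ties:
        method = "exact"
    elif total <= 20 and min(xs.size, ys.size) >= 2:
        method = sps.PermutationMethod(n_resamples=math.inf)
    else:
        method = "asymptotic"
    return float(sps.mannwhitneyu(ys, xs, alternative=alt, method=method).pvalue)


def bh_adjust(pvals: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up adjustment (order-preserving)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return [float(v) for v in multipletests(p, method="fdr_bh")[1]]


# ---------------------------------------------------------------------------
# Clinical/treatment association scan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssociationRow:
    variable: str
    table: Tuple[Tuple[int, int], Tuple[int, int]]  # severity x variable
    n_excluded: int
    p: float
    p_adjusted: float


def clinical_association_scan(cohort: Cohort, variables: Sequence[str]) -> List[AssociationRow]:
    """Two-tailed Fisher exact association of severity with binary
    clinical/treatment variables, BH-adjusted across the scanned set.

    The variable name ``treatment`` reads the patient treatment flag; any
    other name reads the patient's clinical variables.  Patients missing a
    variable are excluded for that variable (logged).
    """
    if not variables:
        raise ValueError("no variables to scan")
    partial: List[Tuple[str, Tuple[Tuple[int, int], Tuple[int, int]], int, float]] = []
    for var in variables:
        counts = {("severe", True): 0, ("severe", False): 0,
                  ("not_severe", True): 0, ("not_severe", False): 0}
        excluded = 0
        for pat in cohort.patients:
            val = pat.treatment if var == "treatment" else pat.clinical_vars.get(var)
            if val is None:
                excluded += 1
                continue
            counts[(pat.severity, bool(val))] += 1
        if excluded:
            logger.info("variable %r: excluded %d patients with missing values", var, excluded)
        table = (
            (counts[("severe", True)], counts[("severe", False)]),
            (counts[("not_severe", True)], counts[("not_severe", False)]),
        )
        partial.append((var, table, excluded, fisher_exact_2x2(table)))
    padj = bh_adjust([row[3] for row in partial])
    return [
        AssociationRow(variable=v, table=t, n_excluded=e, p=p, p_adjusted=pa)
        for (v, t, e, p), pa in zip(partial, padj)
    ]
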