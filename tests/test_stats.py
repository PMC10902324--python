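import itertools
import math

import numpy as np
import pytest
from scipy.stats import hypergeom

import multicom as mc
from multicom.persistence import ResolutionGrid
from multicom.stats import Patient, _largest_anchored_size, _label_vectors


def _sweep_from_partitions(parts):
    grid = ResolutionGrid(tuple(0.5 * (i + 1) for i in range(len(parts))))
    return mc.SweepResult(grid=grid, partitions=parts, seeds=list(range(len(parts))),
                          q_values=[0.0] * len(parts))


# ---------------------------------------------------------------------------
# Cohort type
# ---------------------------------------------------------------------------

def test_patient_fine_label_consistency():
    with pytest.raises(ValueError, match="inconsistent"):
        Patient(id="p", severity="severe", fine_label="mild")
    with pytest.raises(ValueError, match="severity"):
        Patient(id="p", severity="Severe")
    with pytest.raises(ValueError, match="duplicate"):
        mc.Cohort([Patient(id="p", severity="severe"), Patient(id="p", severity="severe")])


# ---------------------------------------------------------------------------
# Catalog preprocessing
# ---------------------------------------------------------------------------

def test_preprocess_catalog_worked_example():
    """Sizes [1,2,2,3,3,3,4,30]: the singleton goes first, then the 30-gene
    set falls above Q3 + 1.5 IQR = 5.0 of the remaining size distribution."""
    genes = [f"g{i}" for i in range(60)]
    sizes = [1, 2, 2, 3, 3, 3, 4, 30]
    sets, k = {}, 0
    for i, s in enumerate(sizes):
        sets[f"S{i}"] = set(genes[k:k + s])
        k += s
    catalog = mc.GeneSetCatalog(sets)
    filtered, rep = mc.preprocess_catalog(catalog, set(genes))
    assert rep.n_dropped_singleton == 1
    assert rep.size_cutoff == pytest.approx(5.0)
    assert rep.n_dropped_oversized == 1
    assert rep.n_retained == 6
    assert "S7" not in filtered.sets and "S0" not in filtered.sets


def test_preprocess_catalog_network_intersection():
    catalog = mc.GeneSetCatalog({"A": {"a", "b"}, "B": {"c", "offnet"}})
    filtered, rep = mc.preprocess_catalog(catalog, {"a", "b", "c"})
    assert rep.n_genes_dropped_off_network == 1
    assert rep.n_dropped_below_pair == 1          # B reduced to {c}
    assert set(filtered.sets) == {"A"}
    with pytest.raises(ValueError, match="empty"):
        mc.preprocess_catalog(mc.GeneSetCatalog({"A": {"x", "y"}}), {"a"})


def test_set_comembership_stat():
    p = mc.Partition({"a": 0, "b": 0, "c": 1, "d": 2, "e": 0})
    assert mc.set_comembership_stat(p, {"a", "b", "c"}) == 1
    assert mc.set_comembership_stat(p, {"a", "b", "e"}) == 3      # C(3,2)
    assert mc.set_comembership_stat(p, {"a", "c", "d"}) == 0
    with pytest.raises(ValueError):
        mc.set_comembership_stat(p, {"a", "ghost"})


# ---------------------------------------------------------------------------
# Catalog validation
# ---------------------------------------------------------------------------

def test_catalog_validation_degenerate_universe_observed_equals_null():
    # every set is the whole (tiny) universe, so observed and every
    # randomization coincide exactly
    p = mc.Partition({"a": 0, "b": 0, "c": 0})
    sw = _sweep_from_partitions([p])
    catalog = mc.GeneSetCatalog({"S1": {"a", "b", "c"}})
    rows = mc.catalog_validation(sw, catalog, R=1, seed=0)
    assert rows[0].observed == (3,)
    assert rows[0].null_mean == pytest.approx(3.0)
    assert rows[0].stratum_p[3] == pytest.approx(1.0)
    with pytest.raises(ValueError, match="R"):
        mc.catalog_validation(sw, catalog, R=0, seed=0)


def test_catalog_validation_planted_coherence(planted, planted_sweep):
    _, truth = planted
    catalog = mc.simulate_catalog(truth, n_sets=40, coherent_fraction=1.0, seed=11)
    filtered, _ = mc.preprocess_catalog(catalog, planted_sweep.node_universe)
    rows = mc.catalog_validation(planted_sweep, filtered, R=100, seed=12)
    assert all(r.rank_sum_p < 0.01 for r in rows)
    assert all(np.mean(r.observed) > r.null_mean for r in rows)


# ---------------------------------------------------------------------------
# Label-shuffle null
# ---------------------------------------------------------------------------

def _uniform_cohort(genes):
    pats = [Patient(id=f"p{i}", severity="severe" if i < 3 else "not_severe",
                    compound_het_genes=set(genes)) for i in range(8)]
    return mc.Cohort(pats)


def test_label_shuffle_identical_lists_constant_null():
    p = mc.Partition({g: 0 for g in "abcd"})
    sw = _sweep_from_partitions([p] * 4)
    cohort = _uniform_cohort({"a", "b"})
    null = mc.label_shuffle_null(sw, cohort, causal={"a"}, n=4, R=20, seed=0)
    # identical lists => private sets always empty => module is the causal
    # baseline only, constant across shuffles
    assert len(set(null["severe"].tolist())) == 1
    assert len(set(null["not_severe"].tolist())) == 1


def test_label_shuffle_determinism(planted, planted_sweep):
    _, truth = planted
    cohort, causal = mc.simulate_cohort(truth, seed=21)
    n1 = mc.label_shuffle_null(planted_sweep, cohort, causal, n=4, R=30, seed=9)
    n2 = mc.label_shuffle_null(planted_sweep, cohort, causal, n=4, R=30, seed=9)
    assert (n1["severe"] == n2["severe"]).all()
    assert (n1["not_severe"] == n2["not_severe"]).all()
    with pytest.raises(ValueError, match="class"):
        mc.label_shuffle_null(
            planted_sweep,
            mc.Cohort([Patient(id="p", severity="severe")]), causal, n=4, R=2, seed=0)


def test_planted_severe_signal_beats_shuffle_null(planted, planted_sweep):
    """With background-free variant lists, every severe patient's genes lie
    in the signal community, so the observed severe anchored module
    dominates every label-shuffle size."""
    _, truth = planted
    cohort, causal = mc.simulate_cohort(truth, signal_community=0,
                                        k_background=0, seed=33)
    obs = mc.observed_group_module_sizes(planted_sweep, cohort, causal, n=4)
    null = mc.label_shuffle_null(planted_sweep, cohort, causal, n=4, R=200, seed=34)
    assert obs["severe"] > int(null["severe"].max())


def test_planted_signal_with_background_noise_is_significant(planted, planted_sweep):
    """Under the default noisy generator the observed severe module is in
    the upper tail of the shuffle null (add-one p), though a rare shuffle
    can match it."""
    _, truth = planted
    import numpy as np
    ps = []
    for seed in (33, 91, 154):
        cohort, causal = mc.simulate_cohort(truth, signal_community=0, seed=seed)
        obs = mc.observed_group_module_sizes(planted_sweep, cohort, causal, n=4)
        null = mc.label_shuffle_null(planted_sweep, cohort, causal, n=4, R=200,
                                     seed=seed + 1)
        ps.append((1 + int((null["severe"] >= obs["severe"]).sum())) / 201)
    assert min(ps) <= 0.05


def test_fast_anchored_size_matches_module_extraction(planted, planted_sweep):
    _, truth = planted
    cohort, causal = mc.simulate_cohort(truth, seed=55)
    gs = mc.build_group_gene_sets(causal, cohort.per_patient_sets(),
                                  cohort.severity_labels())
    goi = set(causal) | set(gs.severe_private)
    lv = _label_vectors(planted_sweep, goi)
    for n in (2, 4, 8):
        fast = _largest_anchored_size(goi, set(causal), n, lv)
        com = mc.co_membership_counts(planted_sweep, goi)
        mods = mc.extract_modules(com, n, anchor_genes=set(causal))
        top = mc.largest_module_with(mods, set(causal))
        assert fast == (top.size if top else 0)


# ---------------------------------------------------------------------------
# Minimum significant module size
# ---------------------------------------------------------------------------

def test_min_significant_size_forced_by_add_one_estimator():
    null = [1, 2, 3, 4, 5] * 200                      # R = 1000, all <= 5
    observed = mc.Module(frozenset(f"g{i}" for i in range(15)), 8)
    res = mc.min_significant_module_size(null, observed)
    assert res.p_by_k[6] == pytest.approx(1 / 1001)
    assert all(res.p_by_k[k] == pytest.approx(1 / 1001) for k in range(6, 16))
    assert res.k_min == 6


def test_min_significant_size_none_when_null_dominates():
    null = [2] * 100
    observed = mc.Module(frozenset({"a", "b"}), 8)
    res = mc.min_significant_module_size(null, observed)
    assert res.p_by_k[2] == pytest.approx(1.0)
    assert res.k_min is None


def test_add_one_p_direct_count():
    res = mc.min_significant_module_size([2, 2, 3], mc.Module(frozenset("abc"), 8))
    assert res.p_by_k[3] == pytest.approx((1 + 1) / 4)


def test_add_one_p_bounds_and_monotonicity():
    rng = np.random.default_rng(0)
    null = rng.integers(0, 10, size=200).tolist()
    obs = mc.Module(frozenset(f"g{i}" for i in range(12)), 8)
    res = mc.min_significant_module_size(null, obs)
    ps = [res.p_by_k[k] for k in range(2, 13)]
    assert all(1 / 201 <= p <= 1 for p in ps)
    assert all(b <= a for a, b in zip(ps, ps[1:]))    # non-increasing in k
    with pytest.raises(ValueError, match="null"):
        mc.min_significant_module_size([], obs)


# ---------------------------------------------------------------------------
# Fisher exact
# ---------------------------------------------------------------------------

def _fisher_enumeration(table):
    """Independent oracle: sum hypergeometric probabilities of all tables
    with the observed margins whose probability <= the observed one."""
    (a, b), (c, d) = table
    r1, n1, N = a + b, a + c, a + b + c + d
    p_obs = hypergeom.pmf(a, N, r1, n1)
    total = 0.0
    for x in range(max(0, r1 + n1 - N), min(r1, n1) + 1):
        p = hypergeom.pmf(x, N, r1, n1)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(1.0, total)


def test_fisher_severity_treatment_table():
    """8 severe (4 treated) vs 12 not-severe (9 treated)."""
    assert mc.fisher_exact_2x2([[4, 4], [9, 3]]) == pytest.approx(0.356, abs=5e-4)


def test_fisher_small_tables():
    assert mc.fisher_exact_2x2([[1, 0], [0, 1]]) == pytest.approx(1.0)
    assert mc.fisher_exact_2x2([[5, 0], [0, 5]]) == pytest.approx(2 / 252)


def test_fisher_matches_enumeration_oracle():
    rng = np.random.default_rng(3)
    for _ in range(200):
        N = int(rng.integers(4, 41))
        a = rng.multinomial(N, [0.25] * 4).reshape(2, 2)
        if (a.sum(axis=0) == 0).any() or (a.sum(axis=1) == 0).any():
            continue
        assert mc.fisher_exact_2x2(a.tolist()) == pytest.approx(
            _fisher_enumeration(a.tolist()), rel=1e-9, abs=1e-12
        )


def test_fisher_degenerate_and_invalid():
    with pytest.raises(ValueError):
        mc.fisher_exact_2x2([[-1, 1], [1, 1]])
    with pytest.raises(ValueError):
        mc.fisher_exact_2x2([[1, 2, 3], [4, 5, 6]])
    assert mc.fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0


# ---------------------------------------------------------------------------
# Rank-sum
# ---------------------------------------------------------------------------

def _ranksum_enumeration(x, y, alternative):
    """Exact oracle: enumerate all assignments of the pooled values."""
    pooled = sorted(x + y)
    n = len(x)
    obs = sum(pooled.index(v) + 1 for v in sorted(y))  # no ties assumed

    def rank_sum(idx):
        return sum(i + 1 for i in idx)

    stats = [rank_sum(c) for c in itertools.combinations(range(len(pooled)), len(y))]
    if alternative == "greater":
        return sum(s >= obs for s in stats) / len(stats)
    if alternative == "less":
        return sum(s <= obs for s in stats) / len(stats)
    return sum(
        abs(s - len(y) * (len(pooled) + 1) / 2) >= abs(obs - len(y) * (len(pooled) + 1) / 2)
        for s in stats
    ) / len(stats)


def test_rank_sum_extreme_separation():
    assert mc.rank_sum_test([1, 2, 3], [4, 5, 6], "greater") == pytest.approx(0.05)


def test_rank_sum_identical_samples_two_sided():
    assert mc.rank_sum_test([1, 2, 3], [1, 2, 3], "two_sided") == pytest.approx(1.0)


def test_rank_sum_swap_symmetry():
    x, y = [1.0, 3.0, 7.0], [2.0, 8.0, 9.0, 11.0]
    assert mc.rank_sum_test(x, y, "greater") == pytest.approx(
        mc.rank_sum_test(y, x, "less")
    )


def test_rank_sum_matches_enumeration_for_small_samples():
    rng = np.random.default_rng(8)
    for _ in range(20):
        nx, ny = int(rng.integers(2, 6)), int(rng.integers(2, 6))
        vals = rng.choice(100, size=nx + ny, replace=False).astype(float)
        x, y = vals[:nx].tolist(), vals[nx:].tolist()
        for alt in ("greater", "less", "two_sided"):
            assert mc.rank_sum_test(x, y, alt) == pytest.approx(
                _ranksum_enumeration(x, y, alt), abs=1e-12
            )
    with pytest.raises(ValueError):
        mc.rank_sum_test([], [1.0], "greater")


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

def test_bh_adjust_fixture():
    assert mc.bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
    assert mc.bh_adjust([0.2]) == [0.2]
    assert mc.bh_adjust([1.0, 1.0]) == [1.0, 1.0]


def test_bh_adjust_properties():
    rng = np.random.default_rng(1)
    p = rng.random(20)
    adj = mc.bh_adjust(p.tolist())
    assert all(a >= r for a, r in zip(adj, p))
    perm = rng.permutation(20)
    adj_perm = mc.bh_adjust(p[perm].tolist())
    assert adj_perm == pytest.approx(np.asarray(adj)[perm].tolist())
    with pytest.raises(ValueError):
        mc.bh_adjust([1.2])


# ---------------------------------------------------------------------------
# Clinical association scan
# ---------------------------------------------------------------------------

def _printed_cohort():
    """8 severe patients (4 treated) and 12 not-severe (9 treated)."""
    pats = []
    for i in range(8):
        pats.append(Patient(id=f"s{i}", severity="severe", treatment=i < 4))
    for i in range(12):
        pats.append(Patient(id=f"m{i}", severity="not_severe", treatment=i < 9))
    return mc.Cohort(pats)


def test_treatment_association_on_printed_cohort():
    rows = mc.clinical_association_scan(_printed_cohort(), ["treatment"])
    assert rows[0].table == ((4, 4), (9, 3))
    assert rows[0].p == pytest.approx(0.356, abs=5e-4)
    assert rows[0].p_adjusted == rows[0].p      # single scanned variable


def test_perfectly_aligned_variable():
    pats = [Patient(id=f"a{i}", severity="severe", clinical_vars={"v": True})
            for i in range(4)]
    pats += [Patient(id=f"b{i}", severity="not_severe", clinical_vars={"v": False})
             for i in range(4)]
    rows = mc.clinical_association_scan(mc.Cohort(pats), ["v"])
    assert rows[0].p == pytest.approx(2 / 70)


def test_constant_variable_degenerate_margin():
    pats = [Patient(id=f"p{i}", severity="severe" if i < 2 else "not_severe",
                    clinical_vars={"v": True}) for i in range(5)]
    rows = mc.clinical_association_scan(mc.Cohort(pats), ["v"])
    assert rows[0].p == 1.0


def test_missing_values_excluded():
    pats = [Patient(id=f"p{i}", severity="severe" if i < 3 else "not_severe",
                    clinical_vars={"v": None if i == 0 else i % 2 == 0})
            for i in range(8)]
    rows = mc.clinical_association_scan(mc.Cohort(pats), ["v"])
    assert rows[0].n_excluded == 1
    assert sum(rows[0].table[0]) + sum(rows[0].table[1]) == 7
    with pytest.raises(ValueError, match="variables"):
        mc.clinical_association_scan(mc.Cohort(pats), [])
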