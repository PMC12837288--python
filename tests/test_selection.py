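"""Objectives, stratified allocation and the swap-search optimizer."""

import itertools

import numpy as np
import pandas as pd
import pytest

from germcore.metrics import DistanceMatrix
from germcore.selection import (
    INTENSITIES,
    OBJECTIVES,
    OptimizerConfig,
    SelectionContext,
    SelectionStrategy,
    allocate_stratified,
    objective_an,
    objective_en,
    objective_he,
    objective_sh,
    objective_weighted,
    optimize_subset,
    run_strategy_grid,
    select_core,
)
from conftest import make_matrix


def _dm(values, ids=None):
    v = np.array(values, float)
    ids = ids or [f"a{i}" for i in range(len(v))]
    return DistanceMatrix(metric="MR", accession_ids=ids, values=v)


# ----------------------------------------------------------------------
# Objective hand values

def test_objective_en_hand_values():
    d = _dm([[0, 0.2, 0.4], [0.2, 0, 0.6], [0.4, 0.6, 0]])
    assert objective_en(d.accession_ids, d) == pytest.approx((0.2 + 0.2 + 0.4) / 3)
    const = _dm(0.3 * (1 - np.eye(4)))
    assert objective_en(const.accession_ids, const) == pytest.approx(0.3)
    with pytest.raises(ValueError):
        objective_en(["a0"], d)


def test_objective_en_duplicate_pulls_value_down():
    """A zero-distance (clone) pair strictly lowers the nearest-entry mean."""
    base = 0.5 * (1 - np.eye(4))
    with_dup = base.copy()
    with_dup[2, 3] = with_dup[3, 2] = 0.0
    v_clean = objective_en([f"a{i}" for i in range(4)], _dm(base))
    v_dup = objective_en([f"a{i}" for i in range(4)], _dm(with_dup))
    assert v_dup < v_clean


def test_objective_an_hand_values():
    ids = ["a0", "a1", "a2", "a3"]
    v = np.zeros((4, 4))
    v[0, 1] = v[1, 0] = 0.2
    v[0, 2] = v[2, 0] = 0.4
    v[0, 3] = v[3, 0] = 0.6
    v[1, 2] = v[2, 1] = 0.5
    v[1, 3] = v[3, 1] = 0.5
    v[2, 3] = v[3, 2] = 0.5
    d = _dm(v, ids)
    assert objective_an(["a0"], ids, d) == pytest.approx((0 + 0.2 + 0.4 + 0.6) / 4)
    assert objective_an(ids, ids, d) == 0.0


def test_objective_an_monotone_in_core_growth():
    rng = np.random.default_rng(0)
    x = rng.random((8, 2))
    v = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
    ids = [f"a{i}" for i in range(8)]
    d = _dm(v / v.max(), ids)
    prev = objective_an(ids[:1], ids, d)
    for k in range(2, 8):
        cur = objective_an(ids[:k], ids, d)
        assert cur <= prev + 1e-12
        prev = cur


def test_objective_he_exhaustive_recomputation():
    rng = np.random.default_rng(1)
    g = make_matrix(rng.integers(0, 3, size=(4, 12)).tolist())
    for k in (2, 3):
        for combo in itertools.combinations(g.accession_ids, k):
            sub = g.subset_accessions(list(combo))
            p = sub.dosage.mean(axis=0) / 2.0
            expected = float(np.mean(2 * p * (1 - p)))
            assert objective_he(list(combo), g) == pytest.approx(expected, abs=1e-12)


def test_objective_sh_hand_value():
    # 3 loci with alt freqs 0.5, 0.9, 1.0 in the core
    g = make_matrix([[1, 2, 2], [1, 2, 2], [0, 1, 2], [2, 2, 2]])
    core = ["acc1", "acc2", "acc3", "acc4"]
    p = g.dosage.mean(axis=0) / 2.0
    q = np.concatenate([p, 1 - p]) / 3.0
    q = q[q > 0]
    expected = -np.sum(q * np.log(q))
    assert objective_sh(core, g) == pytest.approx(expected, abs=1e-12)


def test_objective_sh_uniform_and_rare_allele_sensitivity():
    # all loci at p=0.5 -> ln(2L)
    g = make_matrix([[0] * 5, [2] * 5])
    assert objective_sh(g.accession_ids, g) == pytest.approx(np.log(10), abs=1e-12)
    # losing the only rare allele strictly decreases the value
    g = make_matrix([[0, 0, 0], [1, 0, 0], [0, 0, 0]])
    with_rare = objective_sh(g.accession_ids, g)
    without = objective_sh(["acc1", "acc3"], g)
    assert with_rare > without


def test_objective_weighted_degenerate_weights_rank_like_en():
    rng = np.random.default_rng(2)
    g = make_matrix(rng.integers(0, 3, size=(8, 30)).tolist())
    ctx = SelectionContext(g)
    cores = [list(c) for c in itertools.combinations(g.accession_ids, 3)]
    d = DistanceMatrix("MR", ctx.ids, ctx.distance("MR"))
    en_vals = [objective_en(c, d) for c in cores]
    w_vals = [objective_weighted(c, [("EN_MR", 1.0)], ctx, seed=5) for c in cores]
    assert np.argmax(en_vals) == np.argmax(w_vals)
    order_en = np.argsort(en_vals)
    order_w = np.argsort(w_vals)
    assert list(order_en) == list(order_w)


# ----------------------------------------------------------------------
# Stratified allocation

def test_allocation_proportional_exact():
    quota = allocate_stratified({"A": 65, "B": 10, "D": 345}, 0.20)
    assert quota == {"A": 13, "B": 2, "D": 69}
    assert sum(quota.values()) == 84


def test_allocation_tie_breaks_to_first_group():
    assert allocate_stratified({"x": 10, "y": 10}, 0.25) == {"x": 3, "y": 2}


def test_allocation_excluded_group_absent():
    quota = allocate_stratified({"A": 50, "hybrid": 7}, 0.10, exclusions=["hybrid"])
    assert "hybrid" not in quota
    assert sum(quota.values()) == 5


def test_allocation_minimum_one_per_group():
    quota = allocate_stratified({"big": 96, "small": 4}, 0.10)
    assert quota["small"] >= 1
    assert sum(quota.values()) == 10


def test_allocation_infeasible_minimum_errors():
    with pytest.raises(ValueError):
        allocate_stratified({"a": 5, "b": 5, "c": 5}, 0.10)


# ----------------------------------------------------------------------
# Optimizer

def _brute_force_best(ctx, objective, k, seed):
    score = ctx.score_fn(objective, k, seed)
    best = -np.inf
    for combo in itertools.combinations(range(ctx.n), k):
        best = max(best, score(np.array(combo)))
    return best


@pytest.mark.parametrize("objective", ["EN_MR", "HE", "AN_CE"])
def test_optimizer_matches_enumeration_small(objective):
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        g = make_matrix(rng.integers(0, 3, size=(8, 25)).tolist())
        ctx = SelectionContext(g)
        _, val = optimize_subset(ctx, objective, 3, seed)
        best = _brute_force_best(ctx, objective, 3, seed)
        assert val <= best + 1e-9  # never better than the true optimum
        hits += abs(val - best) < 1e-9
    assert hits >= 18


def test_optimizer_saturation_core_equals_collection():
    rng = np.random.default_rng(3)
    g = make_matrix(rng.integers(0, 3, size=(6, 20)).tolist())
    ctx = SelectionContext(g)
    ids, score = optimize_subset(ctx, "AN_MR", 6, seed=0)
    assert sorted(ids) == sorted(g.accession_ids)
    assert ctx.raw_value("AN_MR", score) == 0.0


def test_incremental_evaluator_matches_from_scratch():
    """HE/SH swap updates agree with full recomputation at every step."""
    rng = np.random.default_rng(4)
    dosage = rng.integers(-1, 3, size=(15, 40))
    g = make_matrix([[None if v < 0 else int(v) for v in row] for row in dosage])
    ctx = SelectionContext(g)
    for kind in ("HE", "SH"):
        ev = ctx._component(kind)
        core = np.array([0, 3, 7, 9])
        ev.reset(core)
        scratch = ctx.score_fn(kind, 4, seed=0)
        for pos, new in [(0, 5), (2, 12), (3, 1)]:
            inc = ev.try_swap(pos, new)
            cand = core.copy()
            cand[pos] = new
            assert inc == pytest.approx(scratch(cand), abs=1e-9)
            ev.accept()
            core = cand


def test_optimizer_beats_random_subsets(small_panel):
    g, _, _ = small_panel
    ctx = SelectionContext(g)
    k = 12
    _, opt_val = optimize_subset(ctx, "EN_MR", k, seed=5)
    score = ctx.score_fn("EN_MR", k, seed=5)
    rng = np.random.default_rng(5)
    wins = sum(
        opt_val >= score(rng.choice(ctx.n, size=k, replace=False)) for _ in range(40)
    )
    assert wins >= 38


def test_en_avoids_clone_pairs(small_panel):
    """Under EN-MR no two members of one clone group are co-selected."""
    g, _, truth = small_panel
    groups = truth.table["cluster_label"]
    core = select_core(
        g, SelectionStrategy("unstratified", "EN_MR", 0.10, seed=1), groups=groups
    )
    clone_groups = truth.table.loc[core.selected, "clone_group"]
    dup = clone_groups.value_counts()
    # co-selected clone-group members must differ by somatic mutations
    pos = {a: i for i, a in enumerate(g.accession_ids)}
    for cg in dup[dup > 1].index:
        members = list(clone_groups.index[clone_groups == cg])
        for a, b in itertools.combinations(members, 2):
            assert not np.array_equal(g.dosage[pos[a]], g.dosage[pos[b]])


# ----------------------------------------------------------------------
# Strategy execution

def test_select_core_stratified_respects_allocation(small_panel):
    g, _, truth = small_panel
    groups = truth.table["cluster_label"]
    strategy = SelectionStrategy("stratified", "HE", 0.20, seed=2)
    core = select_core(g, strategy, groups=groups)
    assert core.allocation is not None
    assert sum(core.allocation.values()) == len(core.selected)
    sel_groups = groups.loc[core.selected]
    assert "hybrid" not in set(sel_groups)
    for name, q in core.allocation.items():
        assert (sel_groups == name).sum() == q


def test_select_core_unstratified_keeps_hybrids_eligible(small_panel):
    g, _, truth = small_panel
    groups = truth.table["cluster_label"]
    strategy = SelectionStrategy("unstratified", "HE", 0.20, seed=3)
    core = select_core(g, strategy, groups=groups)
    expected_k = int(np.floor(0.20 * g.n_accessions + 0.5))
    assert len(core.selected) == expected_k


def test_select_core_deterministic(small_panel):
    g, _, truth = small_panel
    groups = truth.table["cluster_label"]
    strategy = SelectionStrategy("stratified", "EN_CE", 0.15, seed=4)
    a = select_core(g, strategy, groups=groups)
    b = select_core(g, strategy, groups=groups)
    assert a.selected == b.selected
    assert a.objective_value == b.objective_value


def test_grid_cardinality_small(small_panel):
    g, _, truth = small_panel
    groups = truth.table["cluster_label"]
    cores, table = run_strategy_grid(
        g, groups, intensities=(0.1, 0.2), objectives=("HE", "AN_MR"), seed=5
    )
    assert len(cores) == 2 * 2 * 2
    assert len(table) == 8
    assert set(table["stratification"]) == {"stratified", "unstratified"}
    assert {"Ho", "He", "PIC", "I", "J'"} <= set(table.columns)
    # determinism of the whole grid
    cores2, _ = run_strategy_grid(
        g, groups, intensities=(0.1, 0.2), objectives=("HE", "AN_MR"), seed=5
    )
    assert [c.selected for c in cores] == [c.selected for c in cores2]
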