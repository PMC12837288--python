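"""Core-subset selection: objectives, local-search optimizer, stratification.

Seven selection objectives are supported, mirroring the standard
core-collection optimization families:

* EN_MR / EN_CE — entry-to-nearest-entry: maximize the mean distance from
  each selected accession to its closest neighbour inside the core
  (intra-core spread), under Modified Rogers' or Cavalli-Sforza & Edwards
  distance;
* AN_MR / AN_CE — accession-to-nearest-entry: minimize the mean distance
  from every accession in the collection to its closest core member
  (coverage);
* HE — maximize mean expected heterozygosity of the core;
* SH — maximize the Shannon index over all alleles pooled across loci
  (rare-allele weighted richness);
* ENMR0.5_SH0.5 — equally weighted combination of EN_MR and SH, each
  min-max normalized against bounds estimated from seeded random subsets.

The optimizer is a seeded random-descent over the single-swap
neighbourhood (drop one selected accession, add one unselected), stopping
after a fixed number of consecutive non-improving proposals or a total
evaluation budget, with best-of-restarts.  Stratified selection optimizes
each group independently at a largest-remainder proportional quota and
returns the union.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .metrics import DistanceMatrix, ce_distance_matrix, diversity_report, mr_distance_matrix

logger = logging.getLogger(__name__)

OBJECTIVES = ("EN_MR", "EN_CE", "AN_MR", "AN_CE", "SH", "HE", "ENMR0.5_SH0.5")
INTENSITIES = (0.10, 0.15, 0.20, 0.25, 0.30)
STRATIFICATIONS = ("stratified", "unstratified")

#: Objectives whose raw value is minimized (scores are negated internally
#: so the optimizer uniformly maximizes).
_MINIMIZED = {"AN_MR", "AN_CE"}


@dataclass(frozen=True)
class SelectionStrategy:
    stratification: str
    objective: str
    intensity: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stratification not in STRATIFICATIONS:
            raise ValueError(f"unknown stratification: {self.stratification}")
        if self.objective not in OBJECTIVES:
            raise ValueError(f"unknown objective: {self.objective}")
        if not (0.0 < self.intensity < 1.0):
            raise ValueError("intensity must be in (0, 1)")

    @property
    def label(self) -> str:
        prefix = "S" if self.stratification == "stratified" else "U"
        return f"{prefix}-{self.objective}{int(round(self.intensity * 100))}"


@dataclass
class ObjectiveSpec:
    """Declarative description of one (possibly composite) objective."""

    name: str
    direction: str  # "maximize" | "minimize"
    distance_metric: str | None = None  # "MR" | "CE" | None
    weights: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.weights:
            total = sum(w for _, w in self.weights)
            if abs(total - 1.0) > 1e-9:
                raise ValueError("composite weights must sum to 1")


OBJECTIVE_SPECS: dict[str, ObjectiveSpec] = {
    "EN_MR": ObjectiveSpec("EN_MR", "maximize", "MR"),
    "EN_CE": ObjectiveSpec("EN_CE", "maximize", "CE"),
    "AN_MR": ObjectiveSpec("AN_MR", "minimize", "MR"),
    "AN_CE": ObjectiveSpec("AN_CE", "minimize", "CE"),
    "SH": ObjectiveSpec("SH", "maximize"),
    "HE": ObjectiveSpec("HE", "maximize"),
    "ENMR0.5_SH0.5": ObjectiveSpec(
        "ENMR0.5_SH0.5", "maximize", "MR", (("EN_MR", 0.5), ("SH", 0.5))
    ),
}


@dataclass
class OptimizerConfig:
    """Stopping constants of the swap local search."""

    max_stale: int = 5000
    max_evals: int = 200_000
    restarts: int = 5
    n_norm_subsets: int = 100  # random subsets for composite normalization


@dataclass
class CoreSet:
    selected: list[str]
    strategy: SelectionStrategy
    objective_value: float
    allocation: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("core contains duplicate accessions")


# ----------------------------------------------------------------------
# Plain objective functions (id-level public surface)

def objective_en(core_ids: Sequence[str], d: DistanceMatrix) -> float:
    """Mean distance from each core member to its nearest core neighbour."""
    if len(core_ids) < 2:
        raise ValueError("entry-to-nearest-entry needs at least 2 accessions")
    sub = d.subset(core_ids).values.copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def objective_an(
    core_ids: Sequence[str], full_ids: Sequence[str], d: DistanceMatrix
) -> float:
    """Mean distance from each collection member to its nearest core entry."""
    if len(core_ids) == 0:
        raise ValueError("core must be nonempty")
    core_set = set(map(str, core_ids))
    if not core_set <= set(map(str, full_ids)):
        raise ValueError("core must be a subset of the full collection")
    pos = {a: i for i, a in enumerate(d.accession_ids)}
    rows = np.array([pos[str(a)] for a in full_ids])
    cols = np.array([pos[str(a)] for a in core_ids])
    return float(d.values[np.ix_(rows, cols)].min(axis=1).mean())


def _core_freqs(g: GenotypeMatrix, core_ids: Sequence[str]) -> np.ndarray:
    from .genotypes import allele_frequencies

    return allele_frequencies(g, core_ids)


def objective_he(core_ids: Sequence[str], g: GenotypeMatrix) -> float:
    """Mean expected heterozygosity 2p(1-p) over loci defined in the core."""
    p = _core_freqs(g, core_ids)
    ok = ~np.isnan(p)
    if not ok.any():
        raise ValueError("all loci undefined in core")
    return float(np.mean(2.0 * p[ok] * (1.0 - p[ok])))


def objective_sh(core_ids: Sequence[str], g: GenotypeMatrix) -> float:
    """Shannon index over all alleles pooled across loci.

    With q_la = p_la / sum_l sum_a p_la (the per-locus allele frequencies
    renormalized to a single distribution over 2L alleles), the value is
    -sum q ln q; rare alleles are weighted heavily, so losing one strictly
    decreases the value.
    """
    p = _core_freqs(g, core_ids)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("all loci undefined in core")
    return _pooled_shannon(p)


def _pooled_shannon(p: np.ndarray) -> float:
    l = p.size
    q = np.concatenate([p, 1.0 - p]) / l
    q = q[q > 0]
    return float(-(q * np.log(q)).sum())


# ----------------------------------------------------------------------
# Incremental swap evaluators

class _Evaluator:
    """Maximization-direction evaluator over a local candidate index space."""

    def reset(self, core: np.ndarray) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def try_swap(self, pos: int, new: int) -> float:  # pragma: no cover
        raise NotImplementedError

    def accept(self) -> None:  # pragma: no cover
        raise NotImplementedError


class _RecomputeEvaluator(_Evaluator):
    """From-scratch recomputation; fine for O(k^2)/O(nk) distance objectives."""

    def __init__(self, score_fn: Callable[[np.ndarray], float]):
        self.score_fn = score_fn
        self.core: np.ndarray | None = None
        self._cand: np.ndarray | None = None

    def reset(self, core: np.ndarray) -> float:
        self.core = core.copy()
        return self.score_fn(self.core)

    def try_swap(self, pos: int, new: int) -> float:
        cand = self.core.copy()
        cand[pos] = new
        self._cand = cand
        return self.score_fn(cand)

    def accept(self) -> None:
        self.core = self._cand


def _en_score(d_values: np.ndarray) -> Callable[[np.ndarray], float]:
    def score(core: np.ndarray) -> float:
        sub = d_values[np.ix_(core, core)].copy()
        np.fill_diagonal(sub, np.inf)
        return float(sub.min(axis=1).mean())

    return score


def _an_score(d_values: np.ndarray) -> Callable[[np.ndarray], float]:
    # negated: the optimizer maximizes
    def score(core: np.ndarray) -> float:
        return -float(d_values[:, core].min(axis=1).mean())

    return score


class _FreqEvaluator(_Evaluator):
    """Incremental allele-frequency objectives (HE, SH): O(L) per proposal."""

    def __init__(self, dosage: np.ndarray, kind: str):
        miss = dosage == MISSING
        self.x = np.where(miss, 0, dosage).astype(np.float64)
        self.m = (~miss).astype(np.float64)
        self.kind = kind
        self.core: np.ndarray | None = None

    def _value(self, s: np.ndarray, c: np.ndarray) -> float:
        ok = c > 0
        if not ok.any():
            raise ValueError("all loci undefined in core")
        p = s[ok] / (2.0 * c[ok])
        if self.kind == "HE":
            return float(np.mean(2.0 * p * (1.0 - p)))
        return _pooled_shannon(p)

    def reset(self, core: np.ndarray) -> float:
        self.core = core.copy()
        self.s = self.x[core].sum(axis=0)
        self.c = self.m[core].sum(axis=0)
        return self._value(self.s, self.c)

    def try_swap(self, pos: int, new: int) -> float:
        old = self.core[pos]
        self._ts = self.s - self.x[old] + self.x[new]
        self._tc = self.c - self.m[old] + self.m[new]
        self._pending = (pos, new)
        return self._value(self._ts, self._tc)

    def accept(self) -> None:
        pos, new = self._pending
        self.s, self.c = self._ts, self._tc
        self.core[pos] = new


class _WeightedEvaluator(_Evaluator):
    """Weighted sum of min-max normalized component scores."""

    def __init__(
        self,
        parts: Sequence[tuple[_Evaluator, float]],
        bounds: Sequence[tuple[float, float]],
    ):
        self.parts = list(parts)
        self.bounds = list(bounds)

    def _combine(self, raw: Sequence[float]) -> float:
        total = 0.0
        for v, (_, w), (lo, hi) in zip(raw, self.parts, self.bounds):
            if hi - lo <= 1e-15:
                norm = 0.5  # degenerate bounds: constant contribution
            else:
                norm = (v - lo) / (hi - lo)
            total += w * norm
        return total

    def reset(self, core: np.ndarray) -> float:
        return self._combine([ev.reset(core) for ev, _ in self.parts])

    def try_swap(self, pos: int, new: int) -> float:
        return self._combine([ev.try_swap(pos, new) for ev, _ in self.parts])

    def accept(self) -> None:
        for ev, _ in self.parts:
            ev.accept()


# ----------------------------------------------------------------------
# Selection context: one candidate pool, lazy distances, score functions

class SelectionContext:
    """Selection workspace over one candidate accession pool.

    Distances and zero-filled dosage views are restricted to the pool and
    computed lazily; ``score_fn`` exposes every objective as a
    maximization-direction function of a local index array, suitable both
    for the optimizer and for exhaustive-enumeration cross-checks.
    """

    def __init__(self, g: GenotypeMatrix, candidate_ids: Sequence[str] | None = None):
        self.g = g
        self.ids = list(map(str, candidate_ids)) if candidate_ids is not None else list(
            g.accession_ids
        )
        self._sub = g.subset_accessions(self.ids) if candidate_ids is not None else g
        self._dist: dict[str, np.ndarray] = {}

    @property
    def n(self) -> int:
        return len(self.ids)

    def distance(self, metric: str) -> np.ndarray:
        if metric not in self._dist:
            fn = mr_distance_matrix if metric == "MR" else ce_distance_matrix
            self._dist[metric] = fn(self._sub).values
        return self._dist[metric]

    def set_distance(self, metric: str, d: DistanceMatrix) -> None:
        """Install a precomputed whole-collection distance matrix (subset here)."""
        self._dist[metric] = d.subset(self.ids).values

    def _component(self, name: str) -> _Evaluator:
        if name in ("EN_MR", "EN_CE"):
            return _RecomputeEvaluator(_en_score(self.distance(name[-2:])))
        if name in ("AN_MR", "AN_CE"):
            return _RecomputeEvaluator(_an_score(self.distance(name[-2:])))
        if name in ("HE", "SH"):
            return _FreqEvaluator(self._sub.dosage, name)
        raise ValueError(f"unknown objective component: {name}")

    def evaluator(self, objective: str, k: int, seed: int, cfg: OptimizerConfig) -> _Evaluator:
        spec = OBJECTIVE_SPECS[objective]
        if not spec.weights:
            return self._component(objective)
        parts = [(self._component(n), w) for n, w in spec.weights]
        bounds = self._norm_bounds([p[0] for p in parts], k, seed, cfg.n_norm_subsets)
        return _WeightedEvaluator(parts, bounds)

    def _norm_bounds(
        self, evaluators: Sequence[_Evaluator], k: int, seed: int, n_subsets: int
    ) -> list[tuple[float, float]]:
        """Component bounds from seeded random subsets of the target size."""
        rng = np.random.default_rng(np.random.SeedSequence((seed, 0xB0)))
        vals = [[] for _ in evaluators]
        for _ in range(n_subsets):
            core = rng.choice(self.n, size=k, replace=False)
            for vlist, ev in zip(vals, evaluators):
                vlist.append(ev.reset(core))
        out = []
        for vlist in vals:
            lo, hi = float(min(vlist)), float(max(vlist))
            if hi - lo <= 1e-15:
                logger.warning("degenerate normalization bounds; component fixed at 0.5")
            out.append((lo, hi))
        return out

    def score_fn(
        self, objective: str, k: int, seed: int, cfg: OptimizerConfig | None = None
    ) -> Callable[[np.ndarray], float]:
        """Maximization-direction score of a local index array (from scratch)."""
        cfg = cfg or OptimizerConfig()
        ev = self.evaluator(objective, k, seed, cfg)
        return lambda core: ev.reset(np.asarray(core, dtype=int))

    def raw_value(self, objective: str, score: float) -> float:
        """Convert an optimizer score back to the objective's natural direction."""
        return -score if objective in _MINIMIZED else score


def objective_weighted(
    core_ids: Sequence[str],
    parts: Sequence[tuple[str, float]],
    context: SelectionContext,
    seed: int = 0,
) -> float:
    """Weighted sum of min-max normalized objectives (bounds from seeded
    random subsets of the core's size)."""
    if abs(sum(w for _, w in parts) - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    pos = {a: i for i, a in enumerate(context.ids)}
    core = np.array([pos[str(a)] for a in core_ids])
    evaluators = [context._component(n) for n, _ in parts]
    bounds = context._norm_bounds(evaluators, len(core), seed, 100)
    ev = _WeightedEvaluator(
        [(e, w) for e, (_, w) in zip(evaluators, parts)], bounds
    )
    return ev.reset(core)


# ----------------------------------------------------------------------
# Optimizer

def _local_search(
    evaluator: _Evaluator,
    n: int,
    k: int,
    rng: np.random.Generator,
    cfg: OptimizerConfig,
) -> tuple[np.ndarray, float, int]:
    """One random-descent run; returns (core indices, score, evaluations)."""
    perm = rng.permutation(n)
    core, pool = perm[:k].copy(), perm[k:].copy()
    value = evaluator.reset(core)
    best_core, best_value = core.copy(), value
    evals = 1
    stale = 0
    while pool.size and stale < cfg.max_stale and evals < cfg.max_evals:
        pos = int(rng.integers(k))
        j = int(rng.integers(pool.size))
        val = evaluator.try_swap(pos, int(pool[j]))
        evals += 1
        if val > value - 1e-12:
            # accept improvements and sideways (plateau) moves; only strict
            # improvement resets the stale counter
            improved = val > value + 1e-12
            evaluator.accept()
            core[pos], pool[j] = pool[j], core[pos]
            value = val
            stale = 0 if improved else stale + 1
            if value > best_value:
                best_core, best_value = core.copy(), value
        else:
            stale += 1
    return best_core, best_value, evals


def optimize_subset(
    context: SelectionContext,
    objective: str,
    k: int,
    seed: int,
    cfg: OptimizerConfig | None = None,
) -> tuple[list[str], float]:
    """Best-of-restarts swap search; returns (ids, score in max direction)."""
    cfg = cfg or OptimizerConfig()
    n = context.n
    if k > n:
        raise ValueError(f"requested core size {k} exceeds pool size {n}")
    if k < 1:
        raise ValueError("core size must be at least 1")
    spec = OBJECTIVE_SPECS[objective]
    if k == 1 and (objective.startswith("EN") or spec.weights):
        # entry-to-nearest-entry is undefined for a single entry; the best
        # single representative is the medoid (the k=1 AN optimum)
        objective = f"AN_{spec.distance_metric or 'MR'}"
        spec = OBJECTIVE_SPECS[objective]
    if k == n:
        core = np.arange(n)
        ev = context.evaluator(objective, k, seed, cfg)
        return list(context.ids), ev.reset(core)
    ev = context.evaluator(objective, k, seed, cfg)
    rngs = [np.random.default_rng(c) for c in np.random.SeedSequence(seed).spawn(cfg.restarts)]
    best_core, best_val = None, -np.inf
    for rng in rngs:
        core, val, _ = _local_search(ev, n, k, rng, cfg)
        if val > best_val:
            best_core, best_val = core, val
    return [context.ids[i] for i in sorted(best_core)], float(best_val)


# ----------------------------------------------------------------------
# Stratified allocation

def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5))


def allocate_stratified(
    group_sizes: Mapping[str, int],
    intensity: float,
    exclusions: Sequence[str] = (),
) -> dict[str, int]:
    """Largest-remainder proportional quotas over non-excluded groups.

    The total k is intensity times the non-excluded collection size,
    rounded half away from zero; every non-excluded group receives at
    least one slot (error if k cannot honor that); remainder ties are
    broken in favour of the first-listed group.
    """
    if not (0.0 < intensity < 1.0):
        raise ValueError("intensity must be in (0, 1)")
    names = [g for g in group_sizes if g not in set(exclusions)]
    sizes = {g: int(group_sizes[g]) for g in names}
    if any(s < 1 for s in sizes.values()):
        raise ValueError("group sizes must be positive")
    total = sum(sizes.values())
    k = _round_half_away(intensity * total)
    if k < len(names):
        raise ValueError(
            f"target size {k} cannot give every one of {len(names)} groups a member"
        )
    exact = {g: intensity * sizes[g] for g in names}
    quota = {g: math.floor(exact[g]) for g in names}
    # largest remainder, ties to earlier-listed group (stable sort)
    remainders = sorted(
        names, key=lambda g: (-(exact[g] - quota[g]), names.index(g))
    )
    i = 0
    while sum(quota.values()) < k:
        quota[remainders[i % len(names)]] += 1
        i += 1
    while sum(quota.values()) > k:
        # possible only via the minimum-1 fixups below; shrink the largest quota
        biggest = max(names, key=lambda g: (quota[g], -names.index(g)))
        quota[biggest] -= 1
    # enforce minimum of one per group and the group-size cap
    changed = True
    while changed:
        changed = False
        for g in names:
            if quota[g] < 1:
                donor = max(
                    (h for h in names if quota[h] > 1),
                    key=lambda h: (quota[h], -names.index(h)),
                )
                quota[donor] -= 1
                quota[g] += 1
                changed = True
            if quota[g] > sizes[g]:
                taker = max(
                    (h for h in names if quota[h] < sizes[h]),
                    key=lambda h: (exact[h] - quota[h], -names.index(h)),
                )
                quota[g] -= 1
                quota[taker] += 1
                changed = True
    assert sum(quota.values()) == k
    return quota


# ----------------------------------------------------------------------
# Strategy execution

def select_core(
    g: GenotypeMatrix,
    strategy: SelectionStrategy,
    groups: pd.Series | None = None,
    exclude_groups: Sequence[str] = ("hybrid",),
    cfg: OptimizerConfig | None = None,
    distance_cache: Mapping[str, DistanceMatrix] | None = None,
) -> CoreSet:
    """Run one selection strategy and return the resulting core.

    Stratified mode optimizes each non-excluded group independently at its
    proportional quota and returns the union; hybrids (or any excluded
    group) are dropped from the candidate pool.  Unstratified mode runs a
    single optimization over all accessions, hybrids included.  The
    reported objective value is recomputed over the whole candidate pool.
    """
    cfg = cfg or OptimizerConfig()

    def make_context(ids: Sequence[str] | None) -> SelectionContext:
        ctx = SelectionContext(g, ids)
        if distance_cache:
            spec = OBJECTIVE_SPECS[strategy.objective]
            if spec.distance_metric and spec.distance_metric in distance_cache:
                ctx.set_distance(spec.distance_metric, distance_cache[spec.distance_metric])
        return ctx

    if strategy.stratification == "unstratified":
        ctx = make_context(None)
        k = _round_half_away(strategy.intensity * ctx.n)
        selected, score = optimize_subset(ctx, strategy.objective, k, strategy.seed, cfg)
        return CoreSet(
            selected=selected,
            strategy=strategy,
            objective_value=ctx.raw_value(strategy.objective, score),
        )

    if groups is None:
        raise ValueError("stratified selection requires group assignments")
    groups = groups.astype(str)
    groups.index = groups.index.astype(str)
    kept = groups[~groups.isin(set(exclude_groups))]
    group_names = list(dict.fromkeys(kept))  # first-appearance order
    sizes = {name: int((kept == name).sum()) for name in group_names}
    quota = allocate_stratified(sizes, strategy.intensity)
    seeds = np.random.SeedSequence(strategy.seed).spawn(len(group_names))
    selected: list[str] = []
    for name, child in zip(group_names, seeds):
        ids = list(kept.index[kept == name])
        if quota[name] > len(ids):
            raise ValueError(f"quota {quota[name]} exceeds group {name} size {len(ids)}")
        ctx = make_context(ids)
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        part, _ = optimize_subset(ctx, strategy.objective, quota[name], sub_seed, cfg)
        selected.extend(part)
    # report the union's objective value over the whole non-excluded pool
    pool_ctx = make_context(list(kept.index))
    pos = {a: i for i, a in enumerate(pool_ctx.ids)}
    core_idx = np.array([pos[a] for a in selected])
    score = pool_ctx.score_fn(strategy.objective, len(selected), strategy.seed, cfg)(core_idx)
    return CoreSet(
        selected=selected,
        strategy=strategy,
        objective_value=pool_ctx.raw_value(strategy.objective, score),
        allocation=quota,
    )


def run_strategy_grid(
    g: GenotypeMatrix,
    groups: pd.Series,
    intensities: Sequence[float] = INTENSITIES,
    objectives: Sequence[str] = OBJECTIVES,
    stratifications: Sequence[str] = STRATIFICATIONS,
    seed: int = 0,
    exclude_groups: Sequence[str] = ("hybrid",),
    cfg: OptimizerConfig | None = None,
) -> tuple[list[CoreSet], pd.DataFrame]:
    """Run the full stratification x objective x intensity factorial.

    Every candidate core gets a diversity report row; failures of single
    cells are recorded and the grid continues.  Deterministic given seed.
    """
    if not (len(intensities) and len(objectives) and len(stratifications)):
        raise ValueError("option lists must be nonempty")
    cfg = cfg or OptimizerConfig()
    cache = {
        "MR": mr_distance_matrix(g),
        "CE": ce_distance_matrix(g),
    }
    combos = [
        (s, o, i) for s in stratifications for o in objectives for i in intensities
    ]
    seeds = np.random.SeedSequence(seed).spawn(len(combos))
    cores: list[CoreSet] = []
    rows: list[dict] = []
    for (strat, obj, inten), child in zip(combos, seeds):
        run_seed = int(child.generate_state(1)[0] % (2**31))
        strategy = SelectionStrategy(strat, obj, inten, seed=run_seed)
        row = {
            "stratification": strat,
            "objective": obj,
            "intensity": inten,
            "label": strategy.label,
        }
        try:
            core = select_core(
                g, strategy, groups=groups, exclude_groups=exclude_groups, cfg=cfg,
                distance_cache=cache,
            )
            rep = diversity_report(g, core.selected)
            row.update(size=len(core.selected), objective_value=core.objective_value)
            row.update(rep.as_row())
            cores.append(core)
        except Exception as e:  # grid keeps going on single-cell failures
            logger.error("grid cell %s failed: %s", strategy.label, e)
            row.update(error=str(e))
        rows.append(row)
    return cores, pd.DataFrame(rows)
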