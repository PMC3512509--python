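"""Enhanced scatter search (eSS): a population-based global optimizer.

eSS keeps a small reference set (RefSet) of b solutions.  Every iteration
each member is recombined with every other member through hyper-rectangle
sampling, the best offspring may trigger a "go-beyond" intensification loop
that keeps pushing past improving solutions along the parent->offspring
direction, a derivative-free local search is launched periodically from an
offspring chosen by a quality/diversity balance, and stagnating or
near-duplicate members are replaced by fresh random points.  The population
update is a (1+1) strategy: a member can only be displaced by its own
offspring lineage or by the duplicate/stagnation policies.
"""

from __future__ import annotations

import math
import time
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import qmc

from .local_search import DhcSettings, LocalSearchResult, local_solver_contract
from .problem import BoxBounds, OptimizationProblem, Solution


# ---------------------------------------------------------------------------
# settings
# ---------------------------------------------------------------------------

@dataclass
class ThreadSettings:
    """All tuning parameters of one eSS run.

    Unset ``dim_refset`` / ``ndiverse`` are resolved from the problem
    dimension: ``dim_refset = max(3, ceil(0.7 n_par))`` and
    ``ndiverse = max(dim_refset, 10 n_par)``, both inside the recommended
    ranges ``0.5 n < dim_refset < 20 n`` and ``5 n < ndiverse < 20 n``
    (clipped for tiny problems so the RefSet has at least 3 members).
    ``local_n2`` is the minimum number of objective evaluations between two
    local searches; ``balance`` in [0, 0.5] weighs diversity against quality
    when picking local-search start points.
    """

    dim_refset: int | None = None
    local_n2: int = 50
    balance: float = 0.25
    ndiverse: int | None = None
    nchange: int = 20
    epsilon_dup: float = 1e-3
    rng_seed: int = 0
    max_evals: int = 100_000
    max_time_s: float | None = None
    target_cost: float | None = None
    local_solver: str = "dhc"
    local_settings: DhcSettings = field(default_factory=DhcSettings)

    def resolved(self, n_par: int) -> "ThreadSettings":
        s = ThreadSettings(**{**self.__dict__})
        if s.dim_refset is None:
            s.dim_refset = max(3, math.ceil(0.7 * n_par))
        if s.ndiverse is None:
            s.ndiverse = max(s.dim_refset, 10 * n_par)
        if s.dim_refset < 3:
            raise ValueError("dim_refset must be at least 3")
        if s.ndiverse < s.dim_refset:
            raise ValueError("ndiverse must be >= dim_refset")
        if not 0 <= s.balance <= 0.5:
            raise ValueError("balance must lie in [0, 0.5]")
        if s.local_n2 < 0 or s.nchange < 1 or s.epsilon_dup <= 0:
            raise ValueError("invalid local_n2 / nchange / epsilon_dup")
        if s.max_evals < s.ndiverse:
            raise ValueError(
                f"max_evals={s.max_evals} cannot even evaluate the initial "
                f"diverse set (ndiverse={s.ndiverse})"
            )
        return s


# ---------------------------------------------------------------------------
# state containers
# ---------------------------------------------------------------------------

@dataclass
class RefSet:
    """The ordered population: members sorted ascending by cost."""

    members: list[Solution]
    n_stuck: list[int]

    @classmethod
    def from_members(cls, members: Sequence[Solution]) -> "RefSet":
        rs = cls(list(members), [0] * len(members))
        rs.sort()
        return rs

    def __len__(self) -> int:
        return len(self.members)

    def sort(self) -> None:
        order = sorted(range(len(self.members)), key=lambda i: self.members[i].cost)
        self.members = [self.members[i] for i in order]
        self.n_stuck = [self.n_stuck[i] for i in order]

    @property
    def costs(self) -> np.ndarray:
        return np.array([m.cost for m in self.members])

    @property
    def best(self) -> Solution:
        return self.members[0]


@dataclass
class EssState:
    """Result bookkeeping of one eSS run."""

    refset: RefSet
    xbest: Solution
    fbest: float
    total_evals: int
    neval: int
    local_optima: list[Solution]
    trace: list[tuple[int, float, float]]  # (eval_count, elapsed_s, fbest)
    stop_reason: str = ""


class _StopSearch(Exception):
    def __init__(self, reason: str) -> None:
        self.reason = reason


class _Evaluator:
    """Wraps the problem objective with budget, target and incumbent tracking."""

    def __init__(
        self,
        problem: OptimizationProblem,
        max_evals: int,
        max_time_s: float | None,
        target_cost: float | None,
    ) -> None:
        self.problem = problem
        self.max_evals = max_evals
        self.max_time_s = max_time_s
        self.target_cost = target_cost
        self.count = 0
        self.t0 = time.perf_counter()
        self.best: Solution | None = None
        self.trace: list[tuple[int, float, float]] = []

    @property
    def elapsed(self) -> float:
        return time.perf_counter() - self.t0

    @property
    def remaining(self) -> int:
        return self.max_evals - self.count

    def __call__(self, x: np.ndarray) -> Solution:
        if self.count >= self.max_evals:
            raise _StopSearch("max_evals")
        if self.max_time_s is not None and self.elapsed > self.max_time_s:
            raise _StopSearch("max_time")
        cost = self.problem.evaluate(x)
        self.count += 1
        sol = Solution(np.array(x, dtype=float), cost, self.count)
        if self.best is None or cost < self.best.cost:
            self.best = sol
            self.trace.append((self.count, self.elapsed, cost))
            if self.target_cost is not None and cost <= self.target_cost:
                raise _StopSearch("target_cost")
        return sol

    def raw(self, x: np.ndarray) -> float:
        """Objective handle for the local solver (same accounting)."""
        return self(x).cost


# ---------------------------------------------------------------------------
# algorithm building blocks
# ---------------------------------------------------------------------------

def generate_diverse_set(
    bounds: BoxBounds, ndiverse: int, rng: np.random.Generator
) -> np.ndarray:
    """``ndiverse`` points in the box via Latin-hypercube stratification."""
    if ndiverse < 1:
        raise ValueError("ndiverse must be >= 1")
    degenerate = bounds.width == 0
    if np.any(degenerate):
        warnings.warn(
            "degenerate bounds: %d coordinate(s) are fixed" % int(degenerate.sum()),
            stacklevel=2,
        )
    sampler = qmc.LatinHypercube(d=bounds.n_par, seed=rng)
    u = sampler.random(ndiverse)
    return bounds.lower + u * bounds.width


def build_initial_refset(
    diverse: Sequence[Solution], dim_refset: int, rng: np.random.Generator
) -> RefSet:
    """ceil(b/2) best solutions plus floor(b/2) random others, sorted."""
    if len(diverse) < dim_refset:
        raise ValueError(
            f"need at least dim_refset={dim_refset} evaluated points, got {len(diverse)}"
        )
    ranked = sorted(diverse, key=lambda s: s.cost)
    n_quality = math.ceil(dim_refset / 2)
    chosen = ranked[:n_quality]
    rest = ranked[n_quality:]
    n_random = dim_refset - n_quality
    if n_random:
        idx = rng.choice(len(rest), size=n_random, replace=False)
        chosen += [rest[i] for i in idx]
    return RefSet.from_members(chosen)


def _relative_distance(xi: np.ndarray, xj: np.ndarray) -> float:
    """max over coordinates of |xi - xj| / |xj|, absolute where xj is 0."""
    diff = np.abs(xi - xj)
    denom = np.abs(xj)
    scaled = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0), diff)
    return float(np.max(scaled)) if scaled.size else 0.0


def refset_dedup(
    refset: RefSet,
    bounds: BoxBounds,
    evaluate: Callable[[np.ndarray], Solution],
    epsilon: float,
    rng: np.random.Generator,
) -> None:
    """Replace every member epsilon-duplicate of a better one by a fresh
    random evaluated point; re-sorts in place."""
    replaced = False
    for j in range(1, len(refset)):
        for i in range(j):
            if _relative_distance(refset.members[i].x, refset.members[j].x) <= epsilon:
                refset.members[j] = evaluate(bounds.sample_uniform(rng)[0])
                refset.n_stuck[j] = 0
                replaced = True
                break
    if replaced:
        refset.sort()


def combine_member(
    refset: RefSet,
    i: int,
    rng: np.random.Generator,
    bounds: BoxBounds,
    evaluate: Callable[[np.ndarray], Solution],
) -> list[Solution]:
    """b-1 offspring of member i: one uniform sample per partner j in the
    hyper-rectangle with corners ``x_i - d`` and ``x_i + d``,
    ``d = (x_j - x_i) / 2``, clipped to the box."""
    xi = refset.members[i].x
    offspring = []
    for j in range(len(refset)):
        if j == i:
            continue
        d = (refset.members[j].x - xi) / 2.0
        u = rng.random(xi.size)
        cand = bounds.clip(xi + (2.0 * u - 1.0) * d)
        offspring.append(evaluate(cand))
    return offspring


def go_beyond(
    parent: Solution,
    offspring: Solution,
    evaluate: Callable[[np.ndarray], Solution],
    rng: np.random.Generator,
    bounds: BoxBounds,
    sampler: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
) -> tuple[Solution, bool]:
    """Intensify past an improving offspring.

    While the new point keeps improving, sample the next candidate in the
    hyper-rectangle between ``x_off - (x_temp - x_off)/lambda`` and ``x_off``
    (per-coordinate interval, clipped to the box).  Every second consecutive
    improvement halves lambda, extending the reach.  Returns the best point
    of the lineage and whether the parent was outperformed at all.
    ``sampler(lo, hi)`` is a deterministic test hook replacing the uniform
    draw.
    """
    if offspring.cost >= parent.cost:
        return parent, False
    best = offspring
    x_temp, f_temp = parent.x, parent.cost
    x_off, f_off = offspring.x, offspring.cost
    lam = 1.0
    improvement = 1
    while f_off < f_temp:
        far_corner = x_off - (x_temp - x_off) / lam
        lo = np.minimum(far_corner, x_off)
        hi = np.maximum(far_corner, x_off)
        if sampler is None:
            x_new = lo + rng.random(x_off.size) * (hi - lo)
        else:
            x_new = sampler(lo, hi)
        x_new = bounds.clip(x_new)
        x_temp, f_temp = x_off, f_off
        new_sol = evaluate(x_new)
        x_off, f_off = new_sol.x, new_sol.cost
        if f_off < best.cost:
            best = new_sol
        improvement += 1
        if improvement == 2:
            lam /= 2.0
            improvement = 0
    return best, True


def select_local_start(
    pool: Sequence[Solution],
    archive: Sequence[Solution],
    balance: float,
) -> Solution:
    """Pick the local-search start from the offspring pool.

    Members are ranked by quality (cost ascending) and by diversity (minimum
    Euclidean distance to the archived local optima, descending); the member
    minimizing ``(1-balance)*quality_rank + balance*diversity_rank`` wins,
    ties resolved in favor of quality.  With an empty archive (or balance 0)
    the best-cost member is returned.
    """
    if not pool:
        raise ValueError("offspring pool is empty")
    by_quality = sorted(range(len(pool)), key=lambda k: pool[k].cost)
    if not archive or balance == 0.0:
        return pool[by_quality[0]]
    q_rank = {k: r for r, k in enumerate(by_quality)}
    arch = np.array([a.x for a in archive])
    dmin = [float(np.min(np.linalg.norm(arch - s.x, axis=1))) for s in pool]
    by_diversity = sorted(range(len(pool)), key=lambda k: -dmin[k])
    d_rank = {k: r for r, k in enumerate(by_diversity)}
    scores = [(1 - balance) * q_rank[k] + balance * d_rank[k] for k in range(len(pool))]
    best_k = min(range(len(pool)), key=lambda k: (scores[k], q_rank[k]))
    return pool[best_k]


def apply_stuck_policy(
    refset: RefSet,
    labels: Sequence[bool],
    replacements: Sequence[Solution | None],
    nchange: int,
    bounds: BoxBounds,
    evaluate: Callable[[np.ndarray], Solution],
    rng: np.random.Generator,
) -> None:
    """(1+1) update + stagnation replacement; re-sorts in place.

    Labeled members are replaced by their own go-beyond lineage result and
    their stagnation counter resets; every unlabeled member's counter grows,
    and counters above ``nchange`` force replacement by a fresh random point.
    """
    for i in range(len(refset)):
        if labels[i]:
            refset.members[i] = replacements[i]
            refset.n_stuck[i] = 0
        else:
            refset.n_stuck[i] += 1
    for i in range(len(refset)):
        if refset.n_stuck[i] > nchange:
            refset.members[i] = evaluate(bounds.sample_uniform(rng)[0])
            refset.n_stuck[i] = 0
    refset.sort()


def _is_new_optimum(z: Solution, archive: Sequence[Solution], epsilon: float) -> bool:
    return all(_relative_distance(z.x, a.x) > epsilon for a in archive)


# ---------------------------------------------------------------------------
# the full run
# ---------------------------------------------------------------------------

def ess_run(
    problem: OptimizationProblem,
    settings: ThreadSettings | None = None,
    initial_points: Sequence[np.ndarray] | None = None,
) -> tuple[Solution, EssState]:
    """One eSS run; returns the incumbent and the full solver state.

    ``initial_points`` (e.g. a cooperative Global_ref) are clipped to the
    box and injected into the diverse set before RefSet construction, so
    the quality half of the initial RefSet retains the best of them.
    """
    bounds = problem.bounds
    s = (settings or ThreadSettings()).resolved(bounds.n_par)
    rng = np.random.default_rng(s.rng_seed)
    # reserve part of the budget for the final local-search phase over
    # xbest, so that it actually runs and the total never exceeds max_evals
    reserve = 0
    if s.local_solver != "none":
        reserve = min(4 * s.local_settings.budget(bounds.n_par), s.max_evals // 3)
    ev = _Evaluator(problem, s.max_evals - reserve, s.max_time_s, s.target_cost)
    local = local_solver_contract(s.local_solver)

    archive: list[Solution] = []
    refset: RefSet | None = None
    neval = 0

    try:
        points = list(generate_diverse_set(bounds, s.ndiverse, rng))
        if initial_points is not None:
            points = [bounds.clip(np.asarray(p, float)) for p in initial_points] + points
        diverse = [ev(p) for p in points]
        neval = len(diverse)
        refset = build_initial_refset(diverse, s.dim_refset, rng)

        while True:
            refset.sort()
            refset_dedup(refset, bounds, ev, s.epsilon_dup, rng)

            count_before = ev.count
            labels = [False] * len(refset)
            replacements: list[Solution | None] = [None] * len(refset)
            pool: list[Solution] = []
            for i in range(len(refset)):
                offspring = combine_member(refset, i, rng, bounds, ev)
                pool.extend(offspring)
                x_off = min(offspring, key=lambda o: o.cost)
                rep, improved = go_beyond(refset.members[i], x_off, ev, rng, bounds)
                if improved:
                    labels[i] = True
                    replacements[i] = rep

            if s.local_solver != "none" and neval >= s.local_n2 and pool:
                z = select_local_start(pool, archive, s.balance)
                budget = min(s.local_settings.budget(bounds.n_par), ev.remaining)
                if budget > 0:
                    res = _run_local(local, ev, z, bounds, s.local_settings, budget)
                    if _is_new_optimum(res.optimum, archive, s.epsilon_dup):
                        archive.append(res.optimum)
                neval = 0

            neval += ev.count - count_before
            apply_stuck_policy(refset, labels, replacements, s.nchange, bounds, ev, rng)
    except _StopSearch as stop:
        reason = stop.reason
    else:  # pragma: no cover - loop only exits via _StopSearch
        reason = "unknown"

    # final local-search phase within the reserved budget: polish xbest and
    # the best distinct archived optima (they are candidate basins — the
    # slightly-worse archive entry may sit in the deeper basin), restarting
    # each while it keeps improving
    if reason != "target_cost" and s.local_solver != "none" and refset is not None:
        ev.max_evals = s.max_evals
        candidates = [ev.best] + sorted(
            (a for a in archive if _relative_distance(a.x, ev.best.x) > s.epsilon_dup),
            key=lambda a: a.cost,
        )[:2]
        try:
            for cand in candidates:
                start = cand
                while ev.remaining > 0:
                    budget = min(s.local_settings.budget(bounds.n_par), ev.remaining)
                    res = _run_local(local, ev, start, bounds, s.local_settings, budget)
                    if not res.optimum.cost < start.cost:
                        break
                    start = res.optimum
        except _StopSearch as stop:
            reason = stop.reason

    if ev.best is None:
        raise RuntimeError("stopping criteria allowed no evaluations at all")

    xbest = ev.best
    if refset is None:
        refset = RefSet.from_members([xbest])
    if not ev.trace or ev.count > ev.trace[-1][0]:
        ev.trace.append((ev.count, ev.elapsed, xbest.cost))
    state = EssState(
        refset=refset,
        xbest=xbest,
        fbest=xbest.cost,
        total_evals=ev.count,
        neval=neval,
        local_optima=archive,
        trace=ev.trace,
        stop_reason=reason,
    )
    return xbest, state


def _run_local(
    local: Callable,
    ev: _Evaluator,
    start: Solution,
    bounds: BoxBounds,
    settings: DhcSettings,
    budget: int,
) -> LocalSearchResult:
    capped = DhcSettings(
        initial_step_fraction=settings.initial_step_fraction,
        grow=settings.grow,
        shrink=settings.shrink,
        step_tolerance_fraction=settings.step_tolerance_fraction,
        max_local_evals=budget,
    )
    return local(ev.raw, start.x, bounds, capped, f_start=start.cost)
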