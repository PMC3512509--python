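"""Cooperative enhanced scatter search (CeSS).

A master coordinates eta concurrent eSS threads whose tuning spans a broad
spectrum of aggressiveness (conservative threads: large RefSet and diverse
set, sporadic local search; aggressive threads: the opposite).  At fixed
synchronization instants — every ``n_par * 10**tau`` objective evaluations
per thread, the machine-independent reading of the exchange-interval
parameter tau = log10(n_eval / n_par) — the threads' reference sets are
pooled into a master archive (Global_ref) which is deduplicated, sorted and
redistributed as initial points for the next epoch.  The final answer is the
archive's best entry.  Serial and process-parallel executors give identical
results for identical seeds because each thread is a pure function of its
settings, seed and the epoch-boundary archive snapshot.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from multiprocessing import get_context
from typing import Sequence

import numpy as np

from .ess import EssState, ThreadSettings, _relative_distance, ess_run
from .problem import OptimizationProblem, Solution

logger = logging.getLogger(__name__)


def sync_budget_from_tau(tau: float, n_par: int) -> int:
    """Per-thread evaluations between information-sharing instants.

    Inverts tau = log10(n_eval / n_par): returns round(n_par * 10**tau).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if n_par < 1:
        raise ValueError("n_par must be >= 1")
    return int(round(n_par * 10.0**tau))


@dataclass
class CooperationConfig:
    """Master-level settings: thread count, exchange interval, epochs."""

    eta: int = 10
    tau: float = 2.5
    n_iters: int = 4
    base_seed: int = 0
    evals_per_epoch: int | None = None  # overrides the tau-derived budget
    max_total_evals: int | None = None
    executor: str = "serial"  # "serial" | "process"
    archive_cap_factor: int = 20
    epsilon_dup: float = 1e-3

    def __post_init__(self) -> None:
        if self.eta < 1:
            raise ValueError("eta must be >= 1")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.n_iters < 1:
            raise ValueError("n_iters must be >= 1")
        if self.executor not in ("serial", "process"):
            raise ValueError("executor must be 'serial' or 'process'")

    def epoch_budget(self, n_par: int) -> int:
        if self.evals_per_epoch is not None:
            return self.evals_per_epoch
        return sync_budget_from_tau(self.tau, n_par)


# ---------------------------------------------------------------------------
# aggressiveness spectrum
# ---------------------------------------------------------------------------

# recommended tuning ranges, as multiples of n_par where dimensionful
_REFSET_RANGE = (0.5, 20.0)     # x n_par
_NDIVERSE_RANGE = (5.0, 20.0)   # x n_par
_LOCAL_N2_RANGE = (3.0, 90.0)   # evaluations (clipped inside the open (0,100))
_BALANCE_RANGE = (0.05, 0.45)


def _geom(lo: float, hi: float, frac: float) -> float:
    """Geometric interpolation from hi (frac=0) down to lo (frac=1)."""
    return hi * (lo / hi) ** frac


@dataclass
class AggressivenessArray:
    """Per-thread (dim_refset, ndiverse, local_n2, balance), row 0 most
    conservative, last row most aggressive."""

    dim_refset: list[int]
    ndiverse: list[int]
    local_n2: list[int]
    balance: list[float]

    @property
    def eta(self) -> int:
        return len(self.dim_refset)

    def row(self, j: int) -> dict:
        return {
            "dim_refset": self.dim_refset[j],
            "ndiverse": self.ndiverse[j],
            "local_n2": self.local_n2[j],
            "balance": self.balance[j],
        }

    def thread_settings(self, j: int, base: ThreadSettings | None = None) -> ThreadSettings:
        base = base or ThreadSettings()
        s = copy.deepcopy(base)
        s.dim_refset = self.dim_refset[j]
        s.ndiverse = self.ndiverse[j]
        s.local_n2 = self.local_n2[j]
        s.balance = self.balance[j]
        return s


def build_aggressiveness_array(
    eta: int,
    n_par: int,
    overrides: dict[str, Sequence] | None = None,
) -> AggressivenessArray:
    """Geometric spectrum across the recommended ranges (linear for balance).

    Row 0 is the most conservative thread (large RefSet / diverse set,
    sporadic local search, diversity-leaning balance); the last row the most
    aggressive.  eta=1 collapses to the midpoint of each range.  Values are
    clipped to the hard floors dim_refset >= 3 and ndiverse >= dim_refset;
    overrides outside those floors are rejected.
    """
    if eta < 1:
        raise ValueError("eta must be >= 1")
    fracs = [0.5] if eta == 1 else [j / (eta - 1) for j in range(eta)]

    dim_refset = [max(3, round(_geom(_REFSET_RANGE[0] * n_par, _REFSET_RANGE[1] * n_par, f)))
                  for f in fracs]
    ndiverse = [round(_geom(_NDIVERSE_RANGE[0] * n_par, _NDIVERSE_RANGE[1] * n_par, f))
                for f in fracs]
    local_n2 = [max(1, round(_geom(*_LOCAL_N2_RANGE, f))) for f in fracs]
    balance = [_BALANCE_RANGE[1] + f * (_BALANCE_RANGE[0] - _BALANCE_RANGE[1]) for f in fracs]

    psi = AggressivenessArray(dim_refset, ndiverse, local_n2, balance)
    if overrides:
        for name, values in overrides.items():
            if name not in ("dim_refset", "ndiverse", "local_n2", "balance"):
                raise ValueError(f"unknown aggressiveness column {name!r}")
            if len(values) != eta:
                raise ValueError(f"override {name!r} must have {eta} entries")
            setattr(psi, name, list(values))
    for j in range(eta):
        if psi.dim_refset[j] < 3:
            raise ValueError("dim_refset must be >= 3 in every row")
        psi.ndiverse[j] = max(psi.ndiverse[j], psi.dim_refset[j])
    return psi


# ---------------------------------------------------------------------------
# the master archive
# ---------------------------------------------------------------------------

@dataclass
class GlobalRefSet:
    """The master's pooled, deduplicated, cost-sorted archive."""

    epsilon_dup: float = 1e-3
    cap: int | None = None
    entries: list[Solution] = field(default_factory=list)
    provenance: list[tuple[int, int]] = field(default_factory=list)  # (thread, epoch)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def best(self) -> Solution | None:
        return self.entries[0] if self.entries else None

    def points(self) -> list[np.ndarray]:
        return [e.x for e in self.entries]

    def merge(self, refset_members: Sequence[Solution], thread_id: int, epoch: int) -> None:
        """Append members not epsilon-duplicate of archived entries."""
        for m in refset_members:
            if all(_relative_distance(m.x, e.x) > self.epsilon_dup for e in self.entries):
                self.entries.append(m)
                self.provenance.append((thread_id, epoch))
        self._maintain()

    def _maintain(self) -> None:
        order = sorted(range(len(self.entries)), key=lambda i: self.entries[i].cost)
        self.entries = [self.entries[i] for i in order]
        self.provenance = [self.provenance[i] for i in order]
        if self.cap is not None and len(self.entries) > self.cap:
            self.entries = self.entries[: self.cap]
            self.provenance = self.provenance[: self.cap]


def merge_global_refset(
    global_ref: GlobalRefSet,
    thread_refsets: Sequence[Sequence[Solution]],
    epoch: int = 0,
) -> GlobalRefSet:
    """Merge each thread's reference set into the master archive."""
    for j, members in enumerate(thread_refsets):
        global_ref.merge(members, j, epoch)
    return global_ref


# ---------------------------------------------------------------------------
# execution
# ---------------------------------------------------------------------------

@dataclass
class CessResult:
    best: Solution
    global_ref: GlobalRefSet
    thread_traces: list[list[tuple[int, int, float, float]]]  # (epoch, evals, s, fbest)
    total_evals: int
    epoch_best: list[float]


def _thread_task(args):
    """One thread-epoch: pure function of (problem, settings, initial points)."""
    problem, settings, initial_points, thread_id = args
    try:
        best, state = ess_run(problem, settings, initial_points=initial_points)
        # share the incumbent along with the RefSet: the best point can sit
        # outside the population (go-beyond lineage, dedup replacement)
        shared = [best] + [m for m in state.refset.members]
        return thread_id, best, shared, state.trace, state.total_evals, None
    except Exception as exc:  # noqa: BLE001 - a crashed worker must not kill the epoch
        return thread_id, None, [], [], 0, repr(exc)


def cess_run(
    problem: OptimizationProblem,
    coop: CooperationConfig | None = None,
    psi: AggressivenessArray | None = None,
    base_settings: ThreadSettings | None = None,
    thread_settings: Sequence[ThreadSettings] | None = None,
) -> CessResult:
    """Run the cooperative strategy and return the archive's best solution.

    Thread j of epoch e runs eSS with settings row j of ``psi`` (or the
    explicit ``thread_settings``), seed ``base_seed + j + e * eta``, initial
    points ``Global_ref`` and the per-epoch evaluation budget derived from
    tau.  Threads never share state except through the epoch-boundary merge,
    so the serial executor reproduces the process-parallel one exactly.
    """
    coop = coop or CooperationConfig()
    n_par = problem.bounds.n_par
    if thread_settings is not None:
        if len(thread_settings) != coop.eta:
            raise ValueError("thread_settings must have eta entries")
    elif psi is None:
        psi = build_aggressiveness_array(coop.eta, n_par)
    elif psi.eta != coop.eta:
        raise ValueError("psi must have eta rows")

    epoch_budget = coop.epoch_budget(n_par)
    cap_b = max(
        (thread_settings[j].resolved(n_par).dim_refset if thread_settings is not None
         else psi.dim_refset[j])
        for j in range(coop.eta)
    )
    global_ref = GlobalRefSet(
        epsilon_dup=coop.epsilon_dup, cap=coop.archive_cap_factor * cap_b
    )

    traces: list[list[tuple[int, int, float, float]]] = [[] for _ in range(coop.eta)]
    total_evals = 0
    epoch_best: list[float] = []
    ctx = get_context()

    for epoch in range(coop.n_iters):
        if coop.max_total_evals is not None and total_evals >= coop.max_total_evals:
            break
        init_pts = global_ref.points() or None
        tasks = []
        for j in range(coop.eta):
            if thread_settings is not None:
                s = copy.deepcopy(thread_settings[j])
            else:
                s = psi.thread_settings(j, base_settings)
            s.max_evals = 10**9  # placeholder; the epoch budget is set below
            s = s.resolved(n_par)
            s.rng_seed = int(coop.base_seed + j + epoch * coop.eta)
            s.max_evals = epoch_budget
            # very conservative rows may not fit their diverse set in one epoch
            s.ndiverse = max(s.dim_refset, min(s.ndiverse, epoch_budget - 1))
            if s.ndiverse >= epoch_budget:
                raise ValueError("epoch budget too small for the RefSet of thread %d" % j)
            tasks.append((copy.deepcopy(problem), s, init_pts, j))

        if coop.executor == "process" and coop.eta > 1:
            with ctx.Pool(processes=min(coop.eta, 4)) as pool:
                results = pool.map(_thread_task, tasks)
        else:
            results = [_thread_task(t) for t in tasks]

        refsets: list[Sequence[Solution]] = [[] for _ in range(coop.eta)]
        for thread_id, best, members, trace, n_evals, error in results:
            if error is not None:
                logger.warning("thread %d failed in epoch %d: %s", thread_id, epoch, error)
                continue
            refsets[thread_id] = members
            total_evals += n_evals
            for (cnt, secs, fb) in trace:
                traces[thread_id].append((epoch, cnt, secs, fb))
        merge_global_refset(global_ref, refsets, epoch)
        if global_ref.best is not None:
            epoch_best.append(global_ref.best.cost)

    if global_ref.best is None:
        raise RuntimeError("no thread produced any solution")
    return CessResult(
        best=global_ref.best,
        global_ref=global_ref,
        thread_traces=traces,
        total_evals=total_evals,
        epoch_best=epoch_best,
    )
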