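"""Derivative-free local search.

The default solver is a dynamic-hill-climbing (DHC) style direct search:
per-direction step sizes that grow on success and halve on failure,
successful directions ridden with doubling steps plus one parabolic line
refinement, a composite memory of each sweep's net move probed first, and
dynamic adaptation of the probe basis (direction replacement during
sweeps, re-orientation along accumulated progress at stalls).  No
gradients or sensitivities are ever computed, which is what makes it
affordable inside a metaheuristic on large dynamic models.  Solvers are
pluggable through a small registry so the local phase can be swapped or
disabled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .problem import BoxBounds, Solution

Objective = Callable[[np.ndarray], float]


@dataclass
class DhcSettings:
    """Tuning knobs for the DHC-style local solver.

    initial_step_fraction
        Initial step per coordinate, as a fraction of the box width.
    grow / shrink
        Multipliers applied to a step after a successful / failed probe.
    step_tolerance_fraction
        Convergence threshold: the search stops when every step falls below
        this fraction of its coordinate's box width.
    max_local_evals
        Evaluation budget; ``None`` means ``500 * n_par``.
    """

    initial_step_fraction: float = 0.1
    grow: float = 2.0
    shrink: float = 0.5
    step_tolerance_fraction: float = 1e-6
    max_local_evals: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.initial_step_fraction <= 1:
            raise ValueError("initial_step_fraction must be in (0, 1]")
        if self.grow <= 0 or self.shrink <= 0:
            raise ValueError("step factors must be positive")
        if not 0 < self.step_tolerance_fraction < self.initial_step_fraction:
            raise ValueError("step tolerance must be positive and below the initial step")

    def budget(self, n_par: int) -> int:
        return 500 * n_par if self.max_local_evals is None else self.max_local_evals


@dataclass
class LocalSearchResult:
    optimum: Solution
    evals_used: int
    converged: bool


def dhc_minimize(
    objective: Objective,
    start: np.ndarray,
    bounds: BoxBounds,
    settings: DhcSettings | None = None,
    f_start: float | None = None,
) -> LocalSearchResult:
    """Monotone DHC-style descent from ``start`` within ``bounds``.

    The search operates in box-scaled coordinates (the box mapped to the
    unit cube, so steps are commensurate across parameters of different
    magnitude).  Each direction keeps its own step size; a successful probe
    is ridden with doubling steps until it fails, and the final three
    collinear points feed one parabolic-interpolation probe (a cheap,
    derivative-free line refinement).  A composite memory of the last
    sweep's total move is probed before the coordinate sweep, and when
    every step has shrunk below the tolerance the direction set is
    re-orthogonalized around the displacement accumulated since the last
    re-orientation — the mechanism that lets the method follow curved
    valleys no fixed axis system can descend.  Convergence is declared
    when a stall produces no usable displacement.

    ``objective`` is called once per probe; a known ``f_start`` avoids the
    initial evaluation.  Probes are clipped to the box, so the boundary is
    reachable when the unconstrained minimizer lies outside.  The accepted
    cost sequence is nonincreasing by construction.
    """
    settings = settings or DhcSettings()
    n = bounds.n_par
    width = bounds.width
    active = width > 0
    scale = np.where(active, width, 1.0)
    budget = settings.budget(n)
    grow, shrink = settings.grow, settings.shrink
    evals = 0

    def to_x(z: np.ndarray) -> np.ndarray:
        return bounds.lower + np.clip(z, 0.0, 1.0) * scale

    x_start = bounds.clip(np.asarray(start, dtype=float))
    z = np.where(active, (x_start - bounds.lower) / scale, 0.0)
    if f_start is None:
        fx = objective(to_x(z))
        evals += 1
    else:
        fx = float(f_start)

    if not np.any(active):
        return LocalSearchResult(Solution(to_x(z), fx), evals, True)

    directions = np.eye(n)  # rows are probe directions in scaled space
    steps = np.full(n, settings.initial_step_fraction)
    steps[~active] = 0.0
    floor = settings.step_tolerance_fraction
    last_sign = np.ones(n)
    composite: np.ndarray | None = None
    anchor = z.copy()  # displacement reference for the next re-orientation
    converged = False

    def clipped(z_cand: np.ndarray) -> np.ndarray:
        z_cand = np.clip(z_cand, 0.0, 1.0)
        z_cand[~active] = z[~active]
        return z_cand

    def line_search(d: np.ndarray, step: float) -> tuple[bool, float, float]:
        """Descend along +-d from the current point.

        Finds an improving sign, rides it with doubling steps until the
        first failure, then refines once by parabolic interpolation of the
        last three collinear points.  Returns (improved, last successful
        step magnitude, successful sign).
        """
        nonlocal z, fx, evals
        z0, f0 = z, fx
        t1 = f1 = None
        sgn = 1.0
        for s in (1.0, -1.0):
            if evals >= budget:
                return False, step, 1.0
            zc = clipped(z0 + s * step * d)
            if np.array_equal(zc, z0):
                continue
            fc = objective(to_x(zc))
            evals += 1
            if fc < f0:
                t1, f1, sgn = s * step, fc, s
                z, fx = zc, fc
                break
        if t1 is None:
            return False, step, 1.0
        # ride with doubling
        t_prev, f_prev = 0.0, f0
        t_cur, f_cur = t1, f1
        stride = t1
        t_fail = f_fail = None
        while evals < budget:
            stride *= grow
            t_next = t_cur + stride
            zc = clipped(z0 + t_next * d)
            if np.array_equal(zc, z):
                break
            fc = objective(to_x(zc))
            evals += 1
            if fc < f_cur:
                t_prev, f_prev = t_cur, f_cur
                t_cur, f_cur = t_next, fc
                z, fx = zc, fc
            else:
                t_fail, f_fail = t_next, fc
                break
        # one parabolic refinement through (t_prev, t_cur, t_fail)
        if t_fail is not None and evals < budget:
            d21 = t_cur - t_prev
            d23 = t_cur - t_fail
            num = d21 * d21 * (f_cur - f_fail) - d23 * d23 * (f_cur - f_prev)
            den = d21 * (f_cur - f_fail) - d23 * (f_cur - f_prev)
            if den != 0.0:
                t_star = t_cur - 0.5 * num / den
                if np.isfinite(t_star) and t_star != t_cur:
                    zc = clipped(z0 + t_star * d)
                    if not np.array_equal(zc, z):
                        fc = objective(to_x(zc))
                        evals += 1
                        if fc < f_cur:
                            z, fx = zc, fc
        return True, abs(t_cur - t_prev) if t_cur != t_prev else abs(t1), sgn

    while evals < budget:
        improved = False

        if composite is not None:
            norm = float(np.linalg.norm(composite))
            if norm >= floor:
                ok, _, _ = line_search(composite / norm, norm)
                improved = improved or ok
            composite = None
            if evals >= budget:
                break

        sweep_start = z
        decrease = np.zeros(n)
        for i in range(n):
            if steps[i] == 0.0:
                continue
            f_before = fx
            moved, ride_step, sgn = line_search(last_sign[i] * directions[i], steps[i])
            if moved:
                # track the scale the line actually moved at: probing from
                # there re-brackets the next 1-D minimum in O(1) evaluations
                steps[i] = min(max(ride_step, 2.0 * floor), 1.0)
                last_sign[i] *= sgn
                decrease[i] = f_before - fx
                improved = True
            else:
                steps[i] *= shrink
            if evals >= budget:
                break

        delta = z - sweep_start
        if np.any(delta != 0):
            composite = delta
            # dynamic direction update: trade the direction that contributed
            # the largest single decrease for the sweep's net displacement
            # (it gradually aligns the set with the valley, conjugate-style);
            # the stall re-orthogonalization below repairs any degeneracy
            norm = float(np.linalg.norm(delta))
            total_dec = float(np.sum(decrease))
            if norm >= floor and total_dec > 0:
                j = int(np.argmax(decrease))
                # skip the swap when one direction produced nearly all the
                # progress: replacing it with (almost) itself would collapse
                # the direction set into a subspace
                if decrease[j] < 0.9 * total_dec:
                    directions[j] = delta / norm
                    steps[j] = min(max(norm, steps[j]), 1.0)
                    last_sign[j] = 1.0
                    # rank guard: swapped-in directions slowly align; restore
                    # a well-conditioned set once it degenerates
                    sv = np.linalg.svd(directions, compute_uv=False)
                    if sv[-1] < 0.1:
                        q, _ = np.linalg.qr(directions.T)
                        directions = q.T

        if not improved and np.all(steps[active] < floor):
            drift = z - anchor
            norm = float(np.linalg.norm(drift))
            if norm < max(floor, 1e-14):
                converged = True
                break
            # re-orient: first direction along the accumulated displacement,
            # the rest completed orthonormally; resume at the drift scale
            basis = np.concatenate([drift[:, None] / norm, np.eye(n)], axis=1)
            q, _ = np.linalg.qr(basis)
            directions = q[:, :n].T
            steps = np.full(n, max(norm, 100.0 * floor))
            steps[~active] = 0.0
            last_sign = np.ones(n)
            anchor = z.copy()
            composite = None

    return LocalSearchResult(Solution(to_x(z), fx), evals, converged)


def _none_minimize(objective, start, bounds, settings=None, f_start=None):
    """Disabled local phase: returns the start point untouched, zero evals."""
    if f_start is None:
        f_start = objective(np.asarray(start, dtype=float))
        return LocalSearchResult(Solution(np.asarray(start, float), float(f_start)), 1, True)
    return LocalSearchResult(Solution(np.asarray(start, float), float(f_start)), 0, True)


LOCAL_SOLVERS: dict[str, Callable] = {
    "dhc": dhc_minimize,
    "none": _none_minimize,
}


def local_solver_contract(name: str) -> Callable:
    """Look up a registered local solver by name."""
    try:
        return LOCAL_SOLVERS[name]
    except KeyError:
        raise KeyError(
            f"unknown local solver {name!r}; registered: {sorted(LOCAL_SOLVERS)}"
        ) from None
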