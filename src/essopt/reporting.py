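"""Convergence traces, residual reporting and the multistart baseline.

Wall-clock time is recorded in traces but never drives control flow; the
evaluation count is the machine-independent abscissa of record.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .local_search import DhcSettings, LocalSearchResult, local_solver_contract
from .problem import OptimizationProblem


@dataclass
class ConvergenceRecord:
    """The (eval_count, elapsed_s, fbest) series of one run."""

    points: list[tuple[int, float, float]]
    thread_id: int | None = None

    def __post_init__(self) -> None:
        counts = [p[0] for p in self.points]
        fbests = [p[2] for p in self.points]
        if any(b <= a for a, b in zip(counts, counts[1:])):
            raise ValueError("eval_count must be strictly increasing")
        if any(b > a for a, b in zip(fbests, fbests[1:])):
            raise ValueError("fbest must be nonincreasing")

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.points, columns=["eval_count", "elapsed_s", "fbest"])
        if self.thread_id is not None:
            frame.insert(0, "thread_id", self.thread_id)
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ConvergenceRecord":
        frame = pd.read_csv(path)
        tid = int(frame["thread_id"].iloc[0]) if "thread_id" in frame else None
        pts = [
            (int(r.eval_count), float(r.elapsed_s), float(r.fbest))
            for r in frame.itertuples()
        ]
        return cls(pts, thread_id=tid)


def relative_residuals(
    reference: np.ndarray, estimate: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Percentage residuals ``(estimate - reference) / reference * 100``.

    Entries with zero reference are reported as the absolute difference and
    flagged in the returned boolean mask (True = absolute, not percentage).
    Applies equally to observables and to parameter vectors.
    """
    reference = np.asarray(reference, float)
    estimate = np.asarray(estimate, float)
    if reference.shape != estimate.shape:
        raise ValueError("reference and estimate must align")
    zero = reference == 0.0
    out = np.empty_like(reference)
    out[~zero] = (estimate[~zero] - reference[~zero]) / reference[~zero] * 100.0
    out[zero] = estimate[zero] - reference[zero]
    return out, zero


def log_histogram(costs: Sequence[float], n_bins: int = 20) -> pd.DataFrame:
    """Logarithmically binned histogram of final costs (large-dispersion
    friendly).  Non-positive costs are collected into a single leading bin."""
    costs = np.asarray(costs, float)
    positive = costs[costs > 0]
    rows = []
    n_nonpos = int(np.sum(costs <= 0))
    if n_nonpos:
        rows.append({"bin_low": 0.0, "bin_high": 0.0, "count": n_nonpos})
    if positive.size:
        lo, hi = positive.min(), positive.max()
        if lo == hi:
            rows.append({"bin_low": lo, "bin_high": hi, "count": positive.size})
        else:
            edges = np.logspace(np.log10(lo), np.log10(hi), n_bins + 1)
            counts, _ = np.histogram(positive, bins=edges)
            for c, a, b in zip(counts, edges[:-1], edges[1:]):
                rows.append({"bin_low": a, "bin_high": b, "count": int(c)})
    return pd.DataFrame(rows)


@dataclass
class MultistartResult:
    results: list[LocalSearchResult]
    best: LocalSearchResult
    histogram: pd.DataFrame

    @property
    def final_costs(self) -> np.ndarray:
        return np.array([r.optimum.cost for r in self.results])


def multistart_run(
    problem: OptimizationProblem,
    m: int,
    seed: int = 0,
    local_solver: str = "dhc",
    dhc_settings: DhcSettings | None = None,
) -> MultistartResult:
    """The multistart baseline: ``m`` local searches from uniform random
    starts inside the box, reporting all finals, the best-of-m and a
    log-binned histogram of final costs."""
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = np.random.default_rng(seed)
    solver = local_solver_contract(local_solver)
    starts = problem.bounds.sample_uniform(rng, m)
    results = [
        solver(problem.evaluate, starts[i], problem.bounds, dhc_settings)
        for i in range(m)
    ]
    best = min(results, key=lambda r: r.optimum.cost)
    return MultistartResult(results, best, log_histogram([r.optimum.cost for r in results]))
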