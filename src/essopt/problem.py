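"""Optimization-problem definitions: box-bounded objectives and
ODE-constrained weighted least-squares calibration.

The calibration cost is the classic weighted sum of squared residuals

    J(p) = sum_eps sum_o sum_s  w_{eps,o} * (ym - y(p))^2

over experiments ``eps``, observables ``o`` and samples ``s``, with a
diagonal scaling matrix W that balances the contribution of each measured
series.  Every solver in this package consumes problems through a single
contract: :class:`OptimizationProblem`, a callable objective over a
box-bounded real parameter vector with an evaluation counter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import odeint

logger = logging.getLogger(__name__)

#: Sentinel cost for infeasible evaluations (failed integration, NaN, ...).
INFEASIBLE_COST = float("inf")

#: Tag used in the ``coordinate`` CSV column for steady-state (static) samples.
STEADY_STATE_TAG = "ss"


# ---------------------------------------------------------------------------
# bounds and solutions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoxBounds:
    """Box constraints ``lower <= p <= upper`` for the parameter vector."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if lower.ndim != 1 or lower.shape != upper.shape:
            raise ValueError("lower and upper bounds must be 1-D and same length")
        if not (np.isfinite(lower).all() and np.isfinite(upper).all()):
            raise ValueError("bounds must be finite")
        if np.any(lower > upper):
            raise ValueError("need lower <= upper in every coordinate")

    @property
    def n_par(self) -> int:
        return self.lower.size

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def clip(self, p: np.ndarray) -> np.ndarray:
        return np.clip(p, self.lower, self.upper)

    def contains(self, p: np.ndarray, rtol: float = 1e-12) -> bool:
        tol = rtol * np.maximum(1.0, np.abs(self.width))
        return bool(np.all(p >= self.lower - tol) and np.all(p <= self.upper + tol))

    def sample_uniform(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        """``n`` points drawn uniformly inside the box, shape (n, n_par)."""
        u = rng.random((n, self.n_par))
        return self.lower + u * self.width


@dataclass(frozen=True)
class Solution:
    """A parameter vector with its cost and the evaluation count at creation."""

    x: np.ndarray
    cost: float
    eval_index: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------

@dataclass
class MeasurementSeries:
    """One measured observable within one experiment.

    ``coords`` holds sample times (strictly increasing, seconds) for dynamic
    series, or is ``None`` for a static / steady-state series (the samples
    then carry the ``"ss"`` coordinate tag on disk).
    """

    experiment_id: str
    observable_id: str
    values: np.ndarray
    coords: np.ndarray | None = None
    weight: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError(
                f"empty measurement series ({self.experiment_id}, {self.observable_id})"
            )
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != self.values.shape:
                raise ValueError("coords and values must align")
            if np.any(np.diff(self.coords) <= 0):
                raise ValueError("sample times must be strictly increasing")
        if self.weight is not None and not (np.isfinite(self.weight) and self.weight >= 0):
            raise ValueError("weights must be nonnegative and finite")

    @property
    def is_static(self) -> bool:
        return self.coords is None

    @property
    def key(self) -> tuple[str, str]:
        return (self.experiment_id, self.observable_id)


@dataclass
class ObjectiveDataset:
    """The measured data entering the least-squares cost."""

    series: list[MeasurementSeries]

    def __post_init__(self) -> None:
        if not self.series:
            raise ValueError("dataset must contain at least one series")
        keys = [s.key for s in self.series]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (experiment, observable) series")

    def __iter__(self):
        return iter(self.series)

    def __len__(self) -> int:
        return len(self.series)

    @property
    def n_samples(self) -> int:
        return int(sum(s.values.size for s in self.series))

    @property
    def experiment_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.series:
            seen.setdefault(s.experiment_id, None)
        return list(seen)

    def to_frame(self, predictions: dict[tuple[str, str], np.ndarray] | None = None) -> pd.DataFrame:
        rows = []
        for s in self.series:
            pred = None if predictions is None else predictions.get(s.key)
            for i, v in enumerate(s.values):
                row = {
                    "experiment_id": s.experiment_id,
                    "observable_id": s.observable_id,
                    "coordinate": STEADY_STATE_TAG if s.is_static else s.coords[i],
                    "value": v,
                }
                if predictions is not None:
                    row["predicted"] = np.nan if pred is None else pred[i]
                rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path, predictions=None) -> None:
        self.to_frame(predictions).to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ObjectiveDataset":
        required = {"experiment_id", "observable_id", "coordinate", "value"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"measurements table missing columns: {sorted(missing)}")
        series = []
        for (exp, obs), grp in frame.groupby(["experiment_id", "observable_id"], sort=False):
            coord = grp["coordinate"].astype(str)
            static = (coord == STEADY_STATE_TAG).all()
            if static:
                series.append(MeasurementSeries(str(exp), str(obs), grp["value"].to_numpy()))
            else:
                t = grp["coordinate"].astype(float).to_numpy()
                order = np.argsort(t)
                series.append(
                    MeasurementSeries(
                        str(exp), str(obs), grp["value"].to_numpy()[order], coords=t[order]
                    )
                )
        return cls(series)

    @classmethod
    def from_csv(cls, path) -> "ObjectiveDataset":
        return cls.from_frame(pd.read_csv(path))


def build_weights(dataset: ObjectiveDataset) -> ObjectiveDataset:
    """Fill per-series weights, ``w = 1 / max_s |ym_s|^2``.

    A series whose maximum absolute value is zero gets weight 1, and weights
    already supplied by the user are preserved.  With these weights every
    series contributes O(1) to J regardless of its physical scale.
    """
    out = []
    for s in dataset.series:
        if s.weight is not None:
            out.append(s)
            continue
        peak = float(np.max(np.abs(s.values)))
        w = 1.0 if peak == 0.0 else 1.0 / peak**2
        out.append(replace(s, weight=w))
    return ObjectiveDataset(out)


def evaluate_cost(
    dataset: ObjectiveDataset,
    predictions: dict[tuple[str, str], np.ndarray],
) -> float:
    """Weighted least-squares cost J over all experiments/observables/samples.

    ``predictions`` maps ``(experiment_id, observable_id)`` to an array
    aligned 1:1 with the series' samples.  Any non-finite prediction makes
    the point infeasible (sentinel cost) rather than raising.
    """
    total = 0.0
    for s in dataset.series:
        if s.key not in predictions:
            raise ValueError(f"missing predictions for series {s.key}")
        y = np.asarray(predictions[s.key], dtype=float)
        if y.shape != s.values.shape:
            raise ValueError(f"prediction shape mismatch for series {s.key}")
        if not np.all(np.isfinite(y)):
            return INFEASIBLE_COST
        w = 1.0 if s.weight is None else s.weight
        r = s.values - y
        total += w * float(r @ r)
    return total


# ---------------------------------------------------------------------------
# dynamic model and simulation
# ---------------------------------------------------------------------------

@dataclass
class DynamicModel:
    """A dynamic (or static) observation model.

    For dynamic models the states follow ``dx/dt = rhs(x, p, t)`` from
    ``initial_state`` and predictions are ``observation(x, p, t)``, a vector
    whose entries correspond to ``observables`` (by name).  With
    ``static=True`` no integration happens: ``observation(initial_state, p, 0)``
    is evaluated directly (algebraic model outputs).
    """

    rhs: Callable[[np.ndarray, np.ndarray, float], np.ndarray] | None
    initial_state: np.ndarray | Callable[[np.ndarray], np.ndarray]
    observation: Callable[[np.ndarray, np.ndarray, float], np.ndarray]
    observables: Sequence[str]
    static: bool = False
    rtol: float = 1e-6
    atol: float = 1e-8
    max_steps: int = 5000
    #: optional factory p -> f(x, t) producing a specialized integrand; when
    #: given it replaces ``rhs`` inside the integrator (a pure optimization —
    #: the two must implement the same dynamics)
    make_rhs: Callable[[np.ndarray], Callable[[np.ndarray, float], np.ndarray]] | None = None
    #: optional full integrator hook (p, t_grid) -> trajectory array of shape
    #: (len(t_grid), n_states), or None on failure; replaces the default
    #: LSODA integration entirely (again a pure optimization with identical
    #: semantics — cross-checked against ``rhs`` in the tests)
    simulate: Callable[[np.ndarray, np.ndarray], np.ndarray | None] | None = None
    #: optional vectorized observation hook (traj, p, t_grid) -> matrix of
    #: shape (len(t_grid), n_observables); equivalent to applying
    #: ``observation`` row by row, provided purely for speed
    observe_trajectory: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray] | None = None
    #: per-experiment conditions (experiment_id -> arbitrary context object,
    #: e.g. boundary concentrations and initial state).  When set, every
    #: hook (rhs/make_rhs/simulate/observation/observe_trajectory) receives
    #: the experiment's condition as an extra trailing argument, and a
    #: condition may carry an "x0" entry overriding ``initial_state``.
    conditions: dict | None = None

    def x0(self, p: np.ndarray) -> np.ndarray:
        if callable(self.initial_state):
            return np.asarray(self.initial_state(p), dtype=float)
        return np.asarray(self.initial_state, dtype=float)

    def _obs_index(self, name: str) -> int:
        cache = self.__dict__.get("_obs_index_cache")
        if cache is None:
            cache = {n: i for i, n in enumerate(self.observables)}
            self.__dict__["_obs_index_cache"] = cache
        try:
            return cache[name]
        except KeyError:
            raise KeyError(f"model does not define observable {name!r}") from None


def _integrate(
    model: DynamicModel, p: np.ndarray, grid: np.ndarray, cond=None
) -> np.ndarray | None:
    """Trajectory over ``grid`` via the model's fast hook or LSODA; None on
    failure."""
    with_cond = model.conditions is not None
    if model.simulate is not None:
        traj = model.simulate(p, grid, cond) if with_cond else model.simulate(p, grid)
        if traj is None:
            return None
        traj = np.asarray(traj, float)
        return traj if np.all(np.isfinite(traj)) else None
    x0 = model.x0(p)
    if with_cond and isinstance(cond, dict) and "x0" in cond:
        x0 = np.asarray(cond["x0"], dtype=float)
    if model.make_rhs is not None:
        f = model.make_rhs(p, cond) if with_cond else model.make_rhs(p)
    elif with_cond:
        def f(x, t):
            return model.rhs(x, p, t, cond)
    else:
        def f(x, t):  # odeint ordering -> model ordering
            return model.rhs(x, p, t)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # promote lsoda warnings
            traj, info = odeint(
                f, x0, grid,
                rtol=model.rtol, atol=model.atol, mxstep=model.max_steps,
                full_output=True,
            )
    except Exception as exc:  # noqa: BLE001 - solver must survive
        logger.warning("integration failed: %s", exc)
        return None
    if info["message"] != "Integration successful." or not np.all(np.isfinite(traj)):
        logger.warning("integration did not converge")
        return None
    return traj


def _observe(model, traj, p, grid, cond=None) -> np.ndarray:
    with_cond = model.conditions is not None
    if model.observe_trajectory is not None:
        out = (model.observe_trajectory(traj, p, grid, cond) if with_cond
               else model.observe_trajectory(traj, p, grid))
        return np.asarray(out, float)
    if with_cond:
        return np.asarray(
            [model.observation(traj[k], p, grid[k], cond) for k in range(len(grid))]
        )
    return np.asarray(
        [model.observation(traj[k], p, grid[k]) for k in range(len(grid))]
    )


def _fill_dynamic(model, p, dyn, grid, traj, predictions, cond=None) -> None:
    """Map an integrated trajectory through g onto each dynamic series."""
    obs_matrix = _observe(model, traj, p, grid, cond)
    pos = {t: i for i, t in enumerate(grid)}
    for s in dyn:
        idx = [pos[t] for t in s.coords]
        predictions[s.key] = obs_matrix[idx, model._obs_index(s.observable_id)]


def simulate_observables(
    model: DynamicModel,
    p: np.ndarray,
    dataset: ObjectiveDataset,
) -> dict[tuple[str, str], np.ndarray] | None:
    """Predictions for every dataset sample, or None on integration failure.

    Dynamic series of one experiment share a single integration over the
    union of their sample times (LSODA, stiff-capable).  Failures are logged
    and reported as ``None`` so that callers can map them to the infeasible
    sentinel instead of aborting a solver run.
    """
    p = np.asarray(p, dtype=float)
    predictions: dict[tuple[str, str], np.ndarray] = {}

    if model.static:
        out = np.asarray(model.observation(model.x0(p), p, 0.0), dtype=float)
        for s in dataset.series:
            predictions[s.key] = np.repeat(out[model._obs_index(s.observable_id)], s.values.size)
        return predictions

    for exp in dataset.experiment_ids:
        dyn = [s for s in dataset.series if s.experiment_id == exp and not s.is_static]
        sta = [s for s in dataset.series if s.experiment_id == exp and s.is_static]
        cond = None if model.conditions is None else model.conditions.get(exp)
        if dyn:
            times = np.unique(np.concatenate([s.coords for s in dyn]))
            grid = times if times[0] == 0.0 else np.concatenate([[0.0], times])
            traj = _integrate(model, p, grid, cond)
            if traj is None:
                logger.warning("integration failed for experiment %s", exp)
                return None
            _fill_dynamic(model, p, dyn, grid, traj, predictions, cond)
        for s in sta:
            if model.conditions is not None:
                out = np.asarray(model.observation(model.x0(p), p, 0.0, cond), dtype=float)
            else:
                out = np.asarray(model.observation(model.x0(p), p, 0.0), dtype=float)
            predictions[s.key] = np.repeat(out[model._obs_index(s.observable_id)], s.values.size)
    return predictions


# ---------------------------------------------------------------------------
# the solver-facing problem contract
# ---------------------------------------------------------------------------

class OptimizationProblem:
    """A box-bounded objective with constraint penalties and an eval counter.

    ``objective`` maps a parameter vector to a scalar cost.  Optional
    ``h_eq`` / ``h_in`` callables return arrays of equality / inequality
    constraint values; violations are added as a static quadratic penalty

        J + penalty_weight * (sum h_eq^2 + sum max(0, h_in)^2).

    Box bounds themselves are enforced natively by the solvers (clipping),
    never through the penalty.
    """

    def __init__(
        self,
        objective: Callable[[np.ndarray], float],
        bounds: BoxBounds,
        name: str = "",
        penalty_weight: float = 1e3,
        h_eq: Callable[[np.ndarray], np.ndarray] | None = None,
        h_in: Callable[[np.ndarray], np.ndarray] | None = None,
        optimum_x: np.ndarray | None = None,
        optimum_f: float | None = None,
    ) -> None:
        if penalty_weight < 0:
            raise ValueError("penalty_weight must be nonnegative")
        self.objective = objective
        self.bounds = bounds
        self.name = name
        self.penalty_weight = penalty_weight
        self.h_eq = h_eq
        self.h_in = h_in
        self.optimum_x = None if optimum_x is None else np.asarray(optimum_x, float)
        self.optimum_f = optimum_f
        self.n_evals = 0

    @property
    def n_par(self) -> int:
        return self.bounds.n_par

    def evaluate(self, p: np.ndarray) -> float:
        """Penalized cost at ``p``; increments the evaluation counter once."""
        self.n_evals += 1
        value = self.objective(np.asarray(p, dtype=float))
        if value is None or not np.isfinite(value):
            return INFEASIBLE_COST
        value = float(value)
        if self.h_eq is not None:
            g = np.asarray(self.h_eq(p), dtype=float)
            value += self.penalty_weight * float(g @ g)
        if self.h_in is not None:
            g = np.maximum(0.0, np.asarray(self.h_in(p), dtype=float))
            value += self.penalty_weight * float(g @ g)
        return value

    def reset_counter(self) -> None:
        self.n_evals = 0


def penalized_objective(problem: OptimizationProblem, p: np.ndarray) -> float:
    """Functional form of :meth:`OptimizationProblem.evaluate`."""
    return problem.evaluate(p)


def make_calibration_problem(
    model: DynamicModel,
    dataset: ObjectiveDataset,
    bounds: BoxBounds,
    name: str = "calibration",
    penalty_weight: float = 1e3,
    auto_weights: bool = True,
    log_scale: bool = False,
) -> "CalibrationProblem":
    """Assemble a :class:`CalibrationProblem` from model + measurements.

    With ``log_scale=True`` the solver-facing decision variables are
    ``log10(p)`` and the box becomes ``[log10 lower, log10 upper]`` — the
    standard parametrization for kinetic constants with multiplicative
    bounds, which conditions the search far better than the raw scale.
    ``encode`` / ``decode`` map model parameters to and from search space.
    """
    data = build_weights(dataset) if auto_weights else dataset

    if log_scale:
        if np.any(bounds.lower <= 0):
            raise ValueError("log_scale requires strictly positive bounds")
        search_bounds = BoxBounds(np.log10(bounds.lower), np.log10(bounds.upper))

        def decode(q: np.ndarray) -> np.ndarray:
            return 10.0 ** np.asarray(q, dtype=float)

        def encode(p: np.ndarray) -> np.ndarray:
            return np.log10(np.asarray(p, dtype=float))
    else:
        search_bounds = bounds
        decode = encode = lambda q: np.asarray(q, dtype=float)

    # Precompiled evaluation plan: per experiment, the union time grid and
    # per-series (grid indices, observable column, values, weight).  This is
    # pure bookkeeping hoisted out of the hot loop; semantics are identical
    # to simulate_observables + evaluate_cost (cross-checked in the tests).
    static_entries: list[tuple[int, np.ndarray, float]] = []
    dynamic_plan: list[tuple[np.ndarray, list[tuple[np.ndarray, int, np.ndarray, float]]]] = []
    if model.static:
        for s in data.series:
            static_entries.append(
                (model._obs_index(s.observable_id), s.values,
                 1.0 if s.weight is None else s.weight)
            )
    else:
        for exp in data.experiment_ids:
            dyn = [s for s in data.series if s.experiment_id == exp and not s.is_static]
            sta = [s for s in data.series if s.experiment_id == exp and s.is_static]
            for s in sta:
                static_entries.append(
                    (model._obs_index(s.observable_id), s.values,
                     1.0 if s.weight is None else s.weight)
                )
            if dyn:
                times = np.unique(np.concatenate([s.coords for s in dyn]))
                grid = times if times[0] == 0.0 else np.concatenate([[0.0], times])
                pos = {t: i for i, t in enumerate(grid)}
                entries = [
                    (np.array([pos[t] for t in s.coords]),
                     model._obs_index(s.observable_id), s.values,
                     1.0 if s.weight is None else s.weight)
                    for s in dyn
                ]
                cond = None if model.conditions is None else model.conditions.get(exp)
                dynamic_plan.append((grid, entries, cond))

    def objective(q: np.ndarray) -> float:
        p = decode(q)
        total = 0.0
        for grid, entries, cond in dynamic_plan:
            traj = _integrate(model, p, grid, cond)
            if traj is None:
                return INFEASIBLE_COST
            obs = _observe(model, traj, p, grid, cond)
            for idx, col, vals, w in entries:
                r = vals - obs[idx, col]
                total += w * float(r @ r)
        if static_entries:
            out = np.asarray(model.observation(model.x0(p), p, 0.0), dtype=float)
            if not np.all(np.isfinite(out)):
                return INFEASIBLE_COST
            for col, vals, w in static_entries:
                r = vals - out[col]
                total += w * float(r @ r)
        return total if np.isfinite(total) else INFEASIBLE_COST

    prob = CalibrationProblem(objective, search_bounds, name=name,
                              penalty_weight=penalty_weight)
    prob.model = model
    prob.dataset = data
    prob.decode = decode
    prob.encode = encode
    prob.model_bounds = bounds
    return prob


class CalibrationProblem(OptimizationProblem):
    """OptimizationProblem carrying its model and dataset for reporting.

    ``decode`` maps a search-space point to model parameters (identity
    unless the problem was assembled with ``log_scale=True``)."""

    model: DynamicModel
    dataset: ObjectiveDataset
    model_bounds: BoxBounds

    @staticmethod
    def decode(q: np.ndarray) -> np.ndarray:  # replaced at assembly
        return np.asarray(q, dtype=float)

    @staticmethod
    def encode(p: np.ndarray) -> np.ndarray:  # replaced at assembly
        return np.asarray(p, dtype=float)

    def predictions(self, q: np.ndarray) -> dict[tuple[str, str], np.ndarray] | None:
        return simulate_observables(self.model, self.decode(q), self.dataset)
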