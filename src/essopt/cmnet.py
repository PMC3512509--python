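"""Synthetic metabolic-network calibration fixtures.

Reaction kinetics use the common modular (CM) rate law, a generalized
reversible Michaelis-Menten form valid for any stoichiometry.  For a
reaction with substrates S (concentrations s, constants kM_s, molecularities
m_s) and products P:

    v = u * [ k+ prod_S (s/kM_s)^m_s  -  k- prod_P (p/kM_p)^m_p ]
        / [ prod_S (1 + s/kM_s)^m_s + prod_P (1 + p/kM_p)^m_p - 1 ]

with u an enzyme level (mmol), k+/k- turnover rates (1/s) and kM reactant
constants (mM).  Note the denominator differs from convenience kinetics
whenever a molecularity exceeds 1 (for A + B <-> 2C the product term is
(1 + c/kM_C)^2, not 1 + c/kM_C + (c/kM_C)^2).  The flux is zero exactly at
detailed balance and its sign follows the thermodynamic direction.

The toy fixture is a linear pathway X0 <-> S1 <-> ... <-> X_end with fixed
boundary concentrations, one CM reaction per step, and nominal parameters
drawn log-uniformly.  It mirrors the two calibration setups used for
realistic kinetic models: a *static* variant whose observables are internal
concentrations and reaction fluxes evaluated algebraically, and a *dynamic*
variant whose observables are concentration time courses on a uniform grid.
Bounds are a factor 10 above/below the nominal values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .problem import (
    BoxBounds,
    CalibrationProblem,
    DynamicModel,
    MeasurementSeries,
    ObjectiveDataset,
    make_calibration_problem,
)

try:  # compiled integrator for the (non-stiff) chain dynamics
    import numba as _numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False


# ---------------------------------------------------------------------------
# the CM rate law
# ---------------------------------------------------------------------------

@dataclass
class CMRateLawSpec:
    """Kinetic constants of one CM-rate-law reaction."""

    u: float                      # enzyme level, mmol
    k_plus: float                 # forward turnover, 1/s
    k_minus: float                # backward turnover, 1/s
    km_sub: np.ndarray            # substrate reactant constants, mM
    km_prod: np.ndarray           # product reactant constants, mM
    m_sub: np.ndarray | None = None   # substrate molecularities (default 1)
    m_prod: np.ndarray | None = None  # product molecularities (default 1)

    def __post_init__(self) -> None:
        self.km_sub = np.atleast_1d(np.asarray(self.km_sub, float))
        self.km_prod = np.atleast_1d(np.asarray(self.km_prod, float))
        self.m_sub = (
            np.ones_like(self.km_sub) if self.m_sub is None
            else np.atleast_1d(np.asarray(self.m_sub, float))
        )
        self.m_prod = (
            np.ones_like(self.km_prod) if self.m_prod is None
            else np.atleast_1d(np.asarray(self.m_prod, float))
        )
        for name, arr in (("u", self.u), ("k_plus", self.k_plus), ("k_minus", self.k_minus)):
            if arr <= 0:
                raise ValueError(f"{name} must be positive")
        if np.any(self.km_sub <= 0) or np.any(self.km_prod <= 0):
            raise ValueError("reactant constants must be positive")
        if np.any(self.m_sub < 1) or np.any(self.m_prod < 1):
            raise ValueError("molecularities must be positive integers")


def cm_rate_law(
    spec: CMRateLawSpec,
    substrate_conc: Sequence[float],
    product_conc: Sequence[float],
) -> float:
    """Reaction flux (mol/s) of the CM rate law at the given concentrations."""
    s = np.atleast_1d(np.asarray(substrate_conc, float))
    p = np.atleast_1d(np.asarray(product_conc, float))
    if np.any(s < 0) or np.any(p < 0):
        raise ValueError("concentrations must be nonnegative")
    s_ratio = s / spec.km_sub
    p_ratio = p / spec.km_prod
    numerator = spec.u * (
        spec.k_plus * np.prod(s_ratio**spec.m_sub)
        - spec.k_minus * np.prod(p_ratio**spec.m_prod)
    )
    denominator = (
        np.prod((1.0 + s_ratio) ** spec.m_sub)
        + np.prod((1.0 + p_ratio) ** spec.m_prod)
        - 1.0
    )
    return float(numerator / denominator)


def _cm_rate_11(u, kp, km, kms, kmp, s, c):
    """Fast scalar path: one substrate, one product, molecularity 1."""
    rs = s / kms
    rp = c / kmp
    return u * (kp * rs - km * rp) / (1.0 + rs + 1.0 + rp - 1.0)


if _HAVE_NUMBA:

    @_numba.njit(cache=True)
    def _chain_derivative(x, pars, bs, bp, dx):
        """dx/dt of the linear CM chain; pars has shape (R, 5)."""
        R = pars.shape[0]
        n = R - 1
        v_prev = 0.0
        for r in range(R):
            s = bs if r == 0 else (x[r - 1] if x[r - 1] > 0.0 else 0.0)
            c = bp if r == R - 1 else (x[r] if x[r] > 0.0 else 0.0)
            rs = s / pars[r, 3]
            rp = c / pars[r, 4]
            v = pars[r, 0] * (pars[r, 1] * rs - pars[r, 2] * rp) / (1.0 + rs + rp)
            if r > 0:
                dx[r - 1] = v_prev - v
            v_prev = v
        return n

    @_numba.njit(cache=True)
    def _chain_obs_matrix(traj, pars, bs, bp):
        """(concentrations | fluxes) for every trajectory row."""
        m, n = traj.shape
        R = pars.shape[0]
        out = np.empty((m, n + R))
        for k in range(m):
            for i in range(n):
                out[k, i] = traj[k, i]
            for r in range(R):
                s = bs if r == 0 else (traj[k, r - 1] if traj[k, r - 1] > 0.0 else 0.0)
                c = bp if r == R - 1 else (traj[k, r] if traj[k, r] > 0.0 else 0.0)
                rs = s / pars[r, 3]
                rp = c / pars[r, 4]
                out[k, n + r] = (
                    pars[r, 0] * (pars[r, 1] * rs - pars[r, 2] * rp) / (1.0 + rs + rp)
                )
        return out

    @_numba.njit(cache=True)
    def _chain_rk45(pars, bs, bp, x0, t_eval, rtol, atol, max_steps):
        """Adaptive Dormand-Prince (RK45) integration of the chain over
        ``t_eval`` (which must start at the initial time)."""
        n = x0.size
        m = t_eval.size
        traj = np.empty((m, n))
        traj[0] = x0
        x = x0.copy()
        k1 = np.empty(n); k2 = np.empty(n); k3 = np.empty(n); k4 = np.empty(n)
        k5 = np.empty(n); k6 = np.empty(n); k7 = np.empty(n)
        xt = np.empty(n); x5 = np.empty(n); x4 = np.empty(n)
        t = t_eval[0]
        h = 0.01 * max(1e-6, t_eval[m - 1] - t)
        steps = 0
        _chain_derivative(x, pars, bs, bp, k1)
        for idx in range(1, m):
            target = t_eval[idx]
            while t < target:
                if steps > max_steps:
                    traj[0, 0] = np.nan
                    return traj
                steps += 1
                if h > target - t:
                    h = target - t
                # Dormand-Prince coefficients
                for i in range(n):
                    xt[i] = x[i] + h * (1.0 / 5.0) * k1[i]
                _chain_derivative(xt, pars, bs, bp, k2)
                for i in range(n):
                    xt[i] = x[i] + h * (3.0 / 40.0 * k1[i] + 9.0 / 40.0 * k2[i])
                _chain_derivative(xt, pars, bs, bp, k3)
                for i in range(n):
                    xt[i] = x[i] + h * (44.0 / 45.0 * k1[i] - 56.0 / 15.0 * k2[i]
                                        + 32.0 / 9.0 * k3[i])
                _chain_derivative(xt, pars, bs, bp, k4)
                for i in range(n):
                    xt[i] = x[i] + h * (19372.0 / 6561.0 * k1[i]
                                        - 25360.0 / 2187.0 * k2[i]
                                        + 64448.0 / 6561.0 * k3[i]
                                        - 212.0 / 729.0 * k4[i])
                _chain_derivative(xt, pars, bs, bp, k5)
                for i in range(n):
                    xt[i] = x[i] + h * (9017.0 / 3168.0 * k1[i]
                                        - 355.0 / 33.0 * k2[i]
                                        + 46732.0 / 5247.0 * k3[i]
                                        + 49.0 / 176.0 * k4[i]
                                        - 5103.0 / 18656.0 * k5[i])
                _chain_derivative(xt, pars, bs, bp, k6)
                for i in range(n):
                    x5[i] = x[i] + h * (35.0 / 384.0 * k1[i]
                                        + 500.0 / 1113.0 * k3[i]
                                        + 125.0 / 192.0 * k4[i]
                                        - 2187.0 / 6784.0 * k5[i]
                                        + 11.0 / 84.0 * k6[i])
                _chain_derivative(x5, pars, bs, bp, k7)
                for i in range(n):
                    x4[i] = x[i] + h * (5179.0 / 57600.0 * k1[i]
                                        + 7571.0 / 16695.0 * k3[i]
                                        + 393.0 / 640.0 * k4[i]
                                        - 92097.0 / 339200.0 * k5[i]
                                        + 187.0 / 2100.0 * k6[i]
                                        + 1.0 / 40.0 * k7[i])
                err = 0.0
                for i in range(n):
                    sc = atol + rtol * max(abs(x[i]), abs(x5[i]))
                    e = (x5[i] - x4[i]) / sc
                    err += e * e
                err = (err / n) ** 0.5
                if err <= 1.0:
                    t += h
                    for i in range(n):
                        x[i] = x5[i]
                        k1[i] = k7[i]  # FSAL
                    if err == 0.0:
                        h *= 5.0
                    else:
                        h *= min(5.0, max(0.2, 0.9 * err ** -0.2))
                else:
                    h *= max(0.2, 0.9 * err ** -0.2)
            traj[idx] = x
        return traj


# ---------------------------------------------------------------------------
# the toy linear pathway
# ---------------------------------------------------------------------------

_PARS_PER_REACTION = 5  # (u, k+, k-, kM_substrate, kM_product)
#: estimated entries within each reaction's block: the enzyme level and the
#: two reactant constants.  Turnover rates k+/k- are treated as known (the
#: in-vitro-characterized quantities), the usual setup in CM-rate-law
#: calibration; estimating them jointly with u is structurally hopeless
#: anyway since only the products u*k+ and u*k- enter the rate.
_FREE_IN_REACTION = (0, 3, 4)


@dataclass
class ToyNetworkProblem:
    """A linear CM-kinetics pathway with known ground truth.

    ``nominal_dynamic`` stacks the full kinetics (u, k+, k-, kM_sub,
    kM_prod) per reaction.  The *estimated* parameter vector is the subset
    (u, kM_sub, kM_prod) per reaction — enzyme levels and reactant
    constants — with the turnover rates treated as known constants; the
    static variant appends the internal concentrations as additional
    decision variables.  Bounds are nominal x [0.1, 10] per estimated
    coordinate.

    The dynamic variant is observed under two experimental conditions with
    opposite boundary driving (forward flux from a high substrate pool, and
    near-reversed flux from a high product pool).  Probing the kinetics over
    two concentration regimes is what makes the reactant constants
    practically identifiable — a single slow relaxation leaves most of the
    parameter space flat.
    """

    n_reactions: int
    seed: int
    boundary_substrate: float = 2.0
    boundary_product: float = 0.2
    x0_internal: float = 0.5
    nominal_dynamic: np.ndarray = field(init=False)
    nominal_internal_conc: np.ndarray = field(init=False)

    @property
    def experiments(self) -> dict[str, dict]:
        """Per-experiment boundary concentrations and initial state."""
        n = self.n_internal
        return {
            "exp1": {"bs": self.boundary_substrate, "bp": self.boundary_product,
                     "x0": np.full(n, 0.2)},
            "exp2": {"bs": 0.4, "bp": 2.5, "x0": np.full(n, 1.5)},
        }

    def __post_init__(self) -> None:
        if not 2 <= self.n_reactions <= 20:
            raise ValueError("n_reactions must be in [2, 20]")
        rng = np.random.default_rng(self.seed)
        n_kin = _PARS_PER_REACTION * self.n_reactions
        # log-uniform nominal parameters in [0.2, 5]
        self.nominal_dynamic = np.exp(rng.uniform(np.log(0.2), np.log(5.0), size=n_kin))
        self.nominal_internal_conc = np.exp(
            rng.uniform(np.log(0.2), np.log(5.0), size=self.n_internal)
        )

    # -- parameter layout ----------------------------------------------

    @property
    def free_indices(self) -> np.ndarray:
        """Indices of the estimated entries within the full kinetic vector."""
        return np.array(
            [_PARS_PER_REACTION * r + i
             for r in range(self.n_reactions) for i in _FREE_IN_REACTION]
        )

    @property
    def n_free_kinetic(self) -> int:
        return len(_FREE_IN_REACTION) * self.n_reactions

    def embed(self, p_free: np.ndarray) -> np.ndarray:
        """Full kinetic vector from the estimated subvector (fixed entries
        taken from the ground truth, i.e. treated as known constants)."""
        full = self.nominal_dynamic.copy()
        full[self.free_indices] = np.asarray(p_free, float)[: self.n_free_kinetic]
        return full

    @property
    def param_names(self) -> list[str]:
        labels = ("u", "kM_sub", "kM_prod")
        return [f"{lbl}_R{r + 1}" for r in range(self.n_reactions) for lbl in labels]

    # -- structure -----------------------------------------------------

    @property
    def n_internal(self) -> int:
        return self.n_reactions - 1

    @property
    def species_names(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_internal)]

    @property
    def reaction_names(self) -> list[str]:
        return [f"R{r + 1}" for r in range(self.n_reactions)]

    @property
    def stoichiometry(self) -> np.ndarray:
        """Internal-species stoichiometry matrix (n_internal x n_reactions)."""
        S = np.zeros((self.n_internal, self.n_reactions))
        for i in range(self.n_internal):
            S[i, i] = 1.0       # produced by reaction i
            S[i, i + 1] = -1.0  # consumed by reaction i+1
        return S

    @property
    def nominal_free(self) -> np.ndarray:
        return self.nominal_dynamic[self.free_indices]

    @property
    def nominal_static(self) -> np.ndarray:
        return np.concatenate([self.nominal_free, self.nominal_internal_conc])

    def bounds(self, variant: str = "dynamic") -> BoxBounds:
        nominal = self.nominal_free if variant == "dynamic" else self.nominal_static
        return BoxBounds(nominal * 0.1, nominal * 10.0)

    def reaction_spec(self, r: int, p_free: np.ndarray) -> CMRateLawSpec:
        full = self.embed(p_free)
        u, kp, km, kms, kmp = full[_PARS_PER_REACTION * r: _PARS_PER_REACTION * (r + 1)]
        return CMRateLawSpec(u, kp, km, np.array([kms]), np.array([kmp]))

    # -- kinetics ------------------------------------------------------

    def _boundaries(self, cond: dict | None) -> tuple[float, float]:
        if cond is None:
            return self.boundary_substrate, self.boundary_product
        return float(cond["bs"]), float(cond["bp"])

    def fluxes(
        self, p_free: np.ndarray, internal_conc: np.ndarray, cond: dict | None = None
    ) -> np.ndarray:
        """Per-reaction CM fluxes given the estimated parameters and internal
        concentrations (negative transients are clamped at zero)."""
        full = self.embed(p_free)
        bs, bp = self._boundaries(cond)
        chain = np.concatenate([[bs], np.asarray(internal_conc, float), [bp]])
        chain = np.maximum(chain, 0.0)
        v = np.empty(self.n_reactions)
        for r in range(self.n_reactions):
            u, kp, km, kms, kmp = full[_PARS_PER_REACTION * r: _PARS_PER_REACTION * (r + 1)]
            v[r] = _cm_rate_11(u, kp, km, kms, kmp, chain[r], chain[r + 1])
        return v

    def rhs(self, x: np.ndarray, p: np.ndarray, t: float, cond: dict | None = None) -> np.ndarray:
        v = self.fluxes(p, x, cond)
        return v[:-1] - v[1:]

    # -- models and problems -------------------------------------------

    def make_rhs(self, p: np.ndarray, cond: dict | None = None):
        """Specialized integrand with parameters unpacked to plain floats."""
        R = self.n_reactions
        full = self.embed(p)
        pars = [
            tuple(float(v) for v in full[_PARS_PER_REACTION * r: _PARS_PER_REACTION * (r + 1)])
            for r in range(R)
        ]
        bs, bp = self._boundaries(cond)

        def f(x, t):
            chain = [bs] + [xi if xi > 0.0 else 0.0 for xi in x.tolist()] + [bp]
            v = []
            for r in range(R):
                u, kp, km, kms, kmp = pars[r]
                rs = chain[r] / kms
                rp = chain[r + 1] / kmp
                v.append(u * (kp * rs - km * rp) / (1.0 + rs + rp))
            return [v[i] - v[i + 1] for i in range(R - 1)]

        return f

    def simulate_trajectory(
        self, p: np.ndarray, t_grid: np.ndarray, cond: dict | None = None
    ) -> np.ndarray | None:
        """Compiled adaptive RK45 integration of the (non-stiff) chain;
        returns None when numba is unavailable (the generic LSODA path is
        used instead) and a NaN-marked array on step-limit failure."""
        if not _HAVE_NUMBA:
            return None
        bs, bp = self._boundaries(cond)
        if cond is not None and "x0" in cond:
            x0 = np.asarray(cond["x0"], dtype=float)
        else:
            x0 = np.full(self.n_internal, self.x0_internal)
        # tighter than the generic LSODA defaults: an explicit pair runs at
        # its error estimate, so the extra two digits keep the cost surface
        # smooth enough for fine local descent
        return _chain_rk45(
            self._kin_matrix(p), bs, bp,
            x0, np.asarray(t_grid, float), 1e-8, 1e-10, 200_000,
        )

    def _kin_matrix(self, p_free: np.ndarray) -> np.ndarray:
        return np.ascontiguousarray(
            self.embed(p_free).reshape(self.n_reactions, _PARS_PER_REACTION)
        )

    def observe_trajectory(self, traj, p, t_grid, cond: dict | None = None) -> np.ndarray:
        bs, bp = self._boundaries(cond)
        if _HAVE_NUMBA:
            return _chain_obs_matrix(
                np.ascontiguousarray(np.asarray(traj, float)),
                self._kin_matrix(p), bs, bp,
            )
        return np.asarray(
            [np.concatenate([traj[k], self.fluxes(p, traj[k], cond)])
             for k in range(len(traj))]
        )

    def dynamic_model(self) -> DynamicModel:
        """Dynamic calibration model.

        Observables are the internal-concentration time courses *and* the
        per-reaction flux time courses, under two boundary conditions:
        fluxes pin down the boundary reactions (which concentration
        profiles alone leave almost unconstrained), and the second
        condition probes the kinetics in a different saturation regime.
        """
        return DynamicModel(
            rhs=self.rhs,
            initial_state=np.full(self.n_internal, self.x0_internal),
            observation=lambda x, p, t, cond=None: np.concatenate(
                [x, self.fluxes(p, x, cond)]
            ),
            observables=self.species_names + self.reaction_names,
            make_rhs=self.make_rhs,
            simulate=self.simulate_trajectory if _HAVE_NUMBA else None,
            observe_trajectory=self.observe_trajectory,
            conditions=self.experiments,
        )

    def static_model(self) -> DynamicModel:
        n_kin = self.n_free_kinetic

        def observation(x, p, t):
            conc = p[n_kin:]
            return np.concatenate([conc, self.fluxes(p[:n_kin], conc)])

        return DynamicModel(
            rhs=None,
            initial_state=np.zeros(0),
            observation=observation,
            observables=self.species_names + self.reaction_names,
            static=True,
        )

    def model(self, variant: str) -> DynamicModel:
        if variant == "dynamic":
            return self.dynamic_model()
        if variant == "static":
            return self.static_model()
        raise ValueError("variant must be 'dynamic' or 'static'")

    def nominal(self, variant: str) -> np.ndarray:
        """Ground-truth values of the estimated parameter vector."""
        return self.nominal_free if variant == "dynamic" else self.nominal_static

    def make_problem(
        self, dataset: ObjectiveDataset, variant: str = "dynamic",
        log_scale: bool = True,
    ) -> CalibrationProblem:
        """The calibration problem for this network.

        Kinetic constants span orders of magnitude and carry multiplicative
        bounds, so the search runs in log10 parameters by default;
        ``problem.encode`` / ``problem.decode`` convert to and from the
        model scale (the measurements, cost and bounds are unaffected).
        """
        return make_calibration_problem(
            self.model(variant),
            dataset,
            self.bounds(variant),
            name=f"toy_cm_{variant}_{self.n_reactions}r",
            log_scale=log_scale,
        )


def build_toy_network_problem(n_reactions: int = 3, seed: int = 0) -> ToyNetworkProblem:
    """A seeded linear CM pathway with entry/exit exchange reactions."""
    return ToyNetworkProblem(n_reactions=n_reactions, seed=seed)


# ---------------------------------------------------------------------------
# synthetic measurements
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """A generated calibration dataset plus its provenance."""

    dataset: ObjectiveDataset
    variant: str
    noise_cv: float
    seed: int
    grid: np.ndarray | None


def default_grid(n_samples: int = 15, spacing: float = 1.0) -> np.ndarray:
    """Uniform sampling grid (every ``spacing`` seconds, ``n_samples`` points)."""
    return spacing * np.arange(1, n_samples + 1, dtype=float)


def generate_synthetic_data(
    network: ToyNetworkProblem,
    variant: str = "dynamic",
    grid: np.ndarray | None = None,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> SyntheticDataset:
    """Simulate the network at its nominal parameters and sample it.

    Dynamic variant: every internal concentration sampled on the uniform
    ``grid``.  Static variant: one steady-state-tagged sample per observable
    (concentrations and fluxes).  Noise is proportional Gaussian,
    ``y * (1 + cv * zeta)`` with standard-normal zeta, floored at zero;
    ``noise_cv=0`` gives exact data with zero residuals at the nominal point.
    """
    from .problem import simulate_observables  # local import avoids cycle at module load

    rng = np.random.default_rng(seed)
    model = network.model(variant)
    nominal = network.nominal(variant)

    if variant == "dynamic":
        grid = default_grid() if grid is None else np.asarray(grid, float)
        skeleton = ObjectiveDataset(
            [
                MeasurementSeries(exp, name, np.zeros_like(grid), coords=grid)
                for exp in network.experiments
                for name in network.species_names + network.reaction_names
            ]
        )
    else:
        skeleton = ObjectiveDataset(
            [
                MeasurementSeries("exp1", name, np.zeros(1))
                for name in network.species_names + network.reaction_names
            ]
        )
        grid = None

    predictions = simulate_observables(model, nominal, skeleton)
    if predictions is None:
        raise RuntimeError("nominal simulation failed; fixture is unusable")

    series = []
    conc_names = set(network.species_names)
    for s in skeleton.series:
        y = predictions[s.key].astype(float)
        if noise_cv > 0:
            y = y * (1.0 + noise_cv * rng.standard_normal(y.shape))
            if s.observable_id in conc_names:  # concentrations cannot go negative
                y = np.maximum(y, 0.0)
        series.append(
            MeasurementSeries(s.experiment_id, s.observable_id, y, coords=s.coords)
        )
    return SyntheticDataset(ObjectiveDataset(series), variant, noise_cv, seed, grid)
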