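# Methods

This note records the model, the algorithmic choices, the defaults and
their rationale, what the synthetic fixtures do and do not emulate, and the
known limitations.  It states no empirical numbers beyond what the test
suite and `scripts/acceptance.py` themselves compute.

## Calibration objective

The cost is the weighted least-squares functional over all experiments,
observables and samples, with a diagonal scaling matrix W.  Each measured
series gets weight `1 / max_s |ym_s|²` so that every series contributes
O(1) to J regardless of physical scale; a series that is identically zero
falls back to weight 1.  The squared form (rather than `1 / max|ym|`) was
an open choice; it is adopted because it makes the weighted residuals
dimensionless, and it is documented here because user-supplied weights
(which are always preserved) are the escape hatch if the other convention
is wanted.

Equality and inequality constraints beyond the box are handled by a static
quadratic penalty `J + w_pen (Σ h_eq² + Σ max(0, h_in)²)`, default
w_pen = 10³, configurable.  Box bounds are native: every solver clips
candidate points into the box before evaluation, and the penalty never sees
them.

Dynamic models are integrated with LSODA (`scipy.integrate.odeint`), which
switches automatically between stiff and non-stiff methods; defaults
rtol = 1e-6, atol = 1e-8, 5000 step maximum.  An integration failure (or
any non-finite model output) yields a `+inf` sentinel cost and a logged
warning, never an exception: a metaheuristic must survive evaluation in
pathological corners of the box.  Models may supply a specialized
integrand factory (`make_rhs`) that pre-binds the parameter vector; this is
a pure speed optimization and the generic `rhs` remains the reference
implementation (they are cross-checked in the tests).

### Log-scale search for kinetic parameters

Kinetic constants are positive, span orders of magnitude, and carry
multiplicative bounds (a fixed factor above/below nominal).  Calibration
problems can therefore be assembled with `log_scale=True` (the toy-network
fixture's default): the solver sees `log10 p` with the box
`[log10 p^L, log10 p^U]`, while measurements, weights, cost and reported
parameters stay on the model scale.  This is the standard parametrization
in kinetic-model calibration; it conditions the search dramatically better
(multiplicative compensation between an enzyme level and its turnover
numbers becomes a linear, easily-traversed direction) and is recorded here
as a deliberate design choice of the calibration layer, not of the solvers,
which are scale-agnostic.

## eSS

The single-thread solver follows the reference-set scheme described in the
README.  Choices that were genuinely open, and how they were resolved:

* **Offspring count.** Each member is combined with every *other* member,
  giving b−1 offspring per member per iteration.
* **Combination hyper-rectangle.** The box with corners x_i − d and
  x_i + d, d = (x_j − x_i)/2: symmetric around the parent, spanning both
  toward and away from the partner, preserving direction information with
  a simple testable rule.
* **Duplicate test.** Pairwise relative distance
  `max_c |x_i,c − x_j,c| / |x_j,c| ≤ ε`, with the absolute difference used
  on coordinates where x_j,c = 0.  Default ε = 1e-3, configurable.
* **First local search.** The trigger `neval ≥ local_n2` fires
  unconditionally the first time (there is no archived local optimum yet,
  so the diversity ranking is skipped until the archive is nonempty).
* **Stagnation.** A member not improved by its own offspring for more than
  `nchange` (default 20) iterations is replaced by a fresh random point.
* **Stopping.** Primary criterion: a maximum number of objective
  evaluations (machine-independent).  Optional: wall-clock cap and a
  target cost (value-to-reach), the latter being the natural criterion for
  recovery experiments where the attainable optimum is known.
* **Final local-search phase.** Up to a third of the evaluation budget (at
  most four local-solver budgets) is reserved so that the concluding
  refinement always runs: the incumbent and the best two ε-distinct
  archived local optima — they are candidate basins, and the slightly
  worse archive entry may sit in the deeper one — are each polished with
  restarts while they keep improving.  The total never exceeds
  `max_evals`.
* **Defaults as a function of dimension n.**  dim_refset = max(3,
  ⌈0.7 n⌉), ndiverse = 10 n, local_n2 = 50, balance = 0.25 — all inside
  the recommended tuning ranges (0.5 n < dim_refset < 20 n,
  0 < local_n2 < 100, 0 < balance < 0.5, 5 n < ndiverse < 20 n), clipped
  for very small n so the RefSet keeps at least 3 members.
* **Randomness.** One seeded `numpy` generator per run drives every
  stochastic choice; identical seeds replay identical runs bit for bit.

Invariants maintained (and asserted in tests): the incumbent cost is
nonincreasing; every evaluated point is inside the box; the RefSet is
sorted and ε-separated after every maintenance pass; go-beyond returns a
cost no worse than either input; the reported evaluation total equals the
wrapped counter.

## Local solver

The local phase is a dynamic-hill-climbing style direct search, pluggable
through a registry (`"dhc"`, `"none"`, or any user-registered callable
with the same signature).  The search operates in box-scaled coordinates
(the box mapped to the unit cube) so steps are commensurate across
parameters of very different magnitude.  Mechanisms, all derivative-free:

* per-direction step sizes, initial 0.1 of the box width, growing after a
  successful probe (capped at the box width) and halving after failures;
* line riding: a successful direction is followed with doubling steps
  until the first failure, and the last three collinear points feed one
  parabolic-interpolation probe — a cheap approximate line minimization;
* a composite memory of the last sweep's net move, line-searched before
  the next coordinate sweep;
* dynamic direction replacement: after a sweep, the direction that
  contributed the largest single decrease is swapped for the sweep's net
  displacement (skipped when that direction alone produced almost all the
  progress, which would collapse the set), with an SVD rank guard that
  re-orthonormalizes the set when it degenerates.  This gradually aligns
  the probe basis with the valley, conjugate-direction style;
* stall re-orientation: when every step has shrunk below the tolerance
  (default 1e-6 of the box width) the basis is re-orthogonalized with its
  first direction along the displacement accumulated since the last
  re-orientation, and the search resumes at that displacement scale;
* default budget 500 n evaluations; budget exhaustion is a normal outcome,
  convergence means a stall with no usable accumulated displacement.

This design was validated against an independent direction-set oracle
(scipy's Powell method) on calibration valleys during development: simple
axis-aligned probing stalls at points where both refine further, which is
why the line refinement and direction adaptation are part of the default
solver rather than options.

The method is monotone (never accepts a worsening point) and every probe
is clipped to the box.  The original dynamic-hill-climbing publication
specifies its internals only loosely; this implementation is documented as
"DHC-style" — faithful to the signature properties the surrounding
algorithm relies on (no gradients, no sensitivities, cheap iterations,
adaptive step lengths and directions), with no claim of line-by-line
fidelity to the original.

## CeSS

* **Exchange interval.** Synchronization is evaluation-count-based:
  each thread runs `n_par · 10^τ` evaluations per epoch (τ default 2.5,
  recommended 2.5–3.5).  A wall-clock reading of the interval would make
  results hardware-dependent; the evaluation-based definition is the
  machine-independent statement and is what `sync_budget_from_tau`
  implements.  An optional wall-clock cap exists for very expensive
  objectives.
* **What is shared.** Each thread's full reference set plus its incumbent
  (the incumbent can live outside the population, e.g. a go-beyond
  product, and sharing it also makes the η = 1, single-epoch configuration
  collapse exactly to plain eSS).
* **How shared points are consumed.** Global_ref entries are injected into
  the diverse set before RefSet construction, so the quality half of each
  new RefSet retains the best shared solutions.
* **Aggressiveness spectrum Ψ.** Geometric interpolation across the
  recommended ranges for dim_refset (0.5 n → 20 n), ndiverse (5 n → 20 n)
  and local_n2 (clipped to [3, 90], since the open interval (0, 100) has
  no usable geometric endpoints), linear for balance (0.05 → 0.45); row 1
  is the most conservative thread.  η = 1 degenerates to midpoints.
  Overrides can replace any column, floors (dim_refset ≥ 3,
  ndiverse ≥ dim_refset) are enforced.  A very conservative row whose
  diverse set would not fit in one epoch budget is clipped to the budget.
* **Archive.** ε-deduplicated, cost-sorted, capped at 20 · max(dim_refset)
  entries (truncation keeps the best) to bound memory; the cap is an
  engineering addition, the exchange logic itself only appends.
* **Determinism.** Thread j of epoch e is seeded `base_seed + j + e·η` and
  is a pure function of (settings, seed, archive snapshot); the serial and
  process-parallel executors therefore produce identical archives.  A
  crashed worker is logged and the epoch proceeds with the surviving
  results.

## Synthetic fixtures

`benchmarks` provides sphere, Rosenbrock, Rastrigin, Ackley and Griewank
with their canonical boxes and known minima, plus `shifted_` variants whose
optimum is displaced by a deterministic dimension-keyed offset (up to a
quarter of the half-width) so origin-biased behavior cannot pass silently.

`cmnet` builds a linear metabolic pathway X0 ↔ S1 ↔ … ↔ X_end with one
common-modular-rate-law reaction per step and fixed boundary
concentrations — the smallest structure exercising both concentration and
flux observables.  The full nominal kinetics (u, k⁺, k⁻, kM per side; 5
per reaction) are drawn log-uniformly from [0.2, 5] (seeded), a range that
keeps the dynamics well-scaled around concentrations of order 1 mM.  The
*estimated* parameter vector is (u, kM_sub, kM_prod) per reaction, with
the turnover rates treated as known constants: only the products u·k± ever
enter the rate law, so estimating them jointly with u is structurally
impossible, and fixing in-vitro-characterized turnovers is the standard
calibration setup.  Bounds are nominal × [0.1, 10] per estimated
coordinate, and the search runs in log10 parameters.

Two variants mirror the two calibration settings the method targets: a
*static* problem whose decision variables additionally include the
internal concentrations and whose observables (concentrations and CM
fluxes) are evaluated algebraically, and a *dynamic* problem whose
observables are the internal-concentration *and* per-reaction flux time
courses, sampled uniformly (default every 1 s, 15 samples — the toy-scale
analogue of sampling a slow cellular adaptation every 1000 s) under two
boundary conditions with opposite driving.  Both design elements are
identifiability-motivated and were validated during development: with
concentration-only, single-condition data the boundary reactions are
essentially unconstrained, and solvers converge to spurious optima with
those parameters pinned at the bounds behind a genuine cost barrier.
Flux observations pin the boundary reactions, and the second condition
probes the kinetics in a different saturation regime.  The dynamic toy is
integrated by a compiled adaptive Dormand–Prince (RK45) routine at
rtol 1e-8 / atol 1e-10 — the chain is non-stiff by construction, and an
explicit pair runs at its error estimate, so the tight tolerances keep
the cost surface smooth for fine local descent; it is cross-checked
against the generic LSODA path in the tests, and data generation shares
it, so the nominal cost is exactly zero.

Measurement noise is proportional Gaussian, `y (1 + cv ζ)` with
concentration series floored at zero (fluxes may legitimately be
negative), default cv = 0 (artificial calibration data in this setting
are conventionally noise-free); the noisy variant's cost floor has the
closed-form expectation `Σ_series w cv² Σ_t y_t²`, which the tests verify
by Monte Carlo.

What the fixtures deliberately do **not** emulate: realistic network
topology (branching, cofactors, regulation), measurement error structure
beyond i.i.d. proportional noise, model misspecification (the generating
model is the fitted model), and realistic scale — the full-size
applications of this method involve hundreds of parameters and hours-long
objective evaluations.  Passing tests therefore demonstrate the
correctness and the relative behavior of the algorithms, not performance
on any real organism's data.  Non-identifiability, however, is genuinely
present (u and k± enter as products), which is why recovery is judged on
J rather than on parameter equality — good fits with poorly determined
parameters are expected and realistic.

## Problem sizes used in the automated checks

The acceptance checks run on desk-scale instances chosen so the whole
suite completes on a single CPU: quadratics up to dimension 50 for the
local solver, 10-D Rastrigin (2·10⁵ evaluations) for global capability,
the 3-reaction dynamic pathway (9 parameters, 150 samples, 2·10⁵
evaluations) for recovery, and a 30-D shifted-Rastrigin comparison of
CeSS (η = 4, 4 epochs, τ = 2.5) against best-of-4 independent runs at
equal total budget over 11 seeds.  `scripts/acceptance.py` recomputes the same
quantities with seed-controlled randomness, using slightly fewer repeats
where a quantity is expensive; every reported number is computed at run
time, never stored.

## Known limitations

* Continuous box-bounded problems only; no integer or mixed-integer
  scatter search, no surrogate models.
* Constraint handling is a static penalty; no feasibility-restoration
  phase.
* The process-parallel executor targets a single machine
  (`multiprocessing`); no MPI/distributed execution, and exchanges are
  synchronous epochs, not the asynchronous adaptive sharing explored
  elsewhere in the literature.
* No SBML import; models are plain Python callables behind the
  `DynamicModel` contract.
* The local solver's convergence guarantee is empirical (direct searches
  can stall on non-smooth objectives); the registry makes it swappable.
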