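"""Standard continuous benchmark objectives with their canonical boxes.

These serve as download-free regression fixtures for the solvers: each
problem carries its known global minimizer and minimum value as metadata.
Shifted variants move the optimum to a reproducible off-center point so that
origin-biased behavior cannot pass unnoticed.
"""

from __future__ import annotations

import numpy as np

from .problem import BoxBounds, OptimizationProblem


class _Benchmark:
    """Picklable benchmark callable with an optional optimum shift."""

    name = ""
    half_width = 1.0

    def __init__(self, n_par: int, shift: np.ndarray | None = None):
        self.n_par = n_par
        self.shift = np.zeros(n_par) if shift is None else np.asarray(shift, float)

    def __call__(self, p: np.ndarray) -> float:
        return self._f(np.asarray(p, float) - self.shift)

    def _f(self, z: np.ndarray) -> float:  # pragma: no cover - abstract
        raise NotImplementedError

    def _raw_optimum(self) -> np.ndarray:
        return np.zeros(self.n_par)

    @property
    def optimum_x(self) -> np.ndarray:
        return self.shift + self._raw_optimum()


class Sphere(_Benchmark):
    name = "sphere"
    half_width = 5.12

    def _f(self, z):
        return float(z @ z)


class Rosenbrock(_Benchmark):
    name = "rosenbrock"
    half_width = 5.0  # symmetric [-5, 5] box containing the (1, ..., 1) optimum

    def _f(self, x):
        return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2))

    def _raw_optimum(self):
        return np.ones(self.n_par)


class Rastrigin(_Benchmark):
    name = "rastrigin"
    half_width = 5.12

    def _f(self, z):
        return float(10.0 * z.size + np.sum(z * z - 10.0 * np.cos(2.0 * np.pi * z)))


class Ackley(_Benchmark):
    name = "ackley"
    half_width = 32.768

    def _f(self, z):
        n = z.size
        return float(
            -20.0 * np.exp(-0.2 * np.sqrt(np.sum(z * z) / n))
            - np.exp(np.sum(np.cos(2.0 * np.pi * z)) / n)
            + 20.0
            + np.e
        )


class Griewank(_Benchmark):
    name = "griewank"
    half_width = 600.0

    def _f(self, z):
        i = np.arange(1, z.size + 1)
        return float(np.sum(z * z) / 4000.0 - np.prod(np.cos(z / np.sqrt(i))) + 1.0)


_FUNCTIONS = {c.name: c for c in (Sphere, Rosenbrock, Rastrigin, Ackley, Griewank)}


def benchmark_objective(name: str, n_par: int) -> OptimizationProblem:
    """A named benchmark as an :class:`OptimizationProblem`.

    ``shifted_<name>`` variants displace the optimum by a deterministic
    (dimension-keyed) offset of up to a quarter of the box half-width.
    Unknown names raise with the list of available functions.
    """
    if n_par < 1:
        raise ValueError("n_par must be >= 1")
    shifted = name.startswith("shifted_")
    base = name.removeprefix("shifted_")
    try:
        cls = _FUNCTIONS[base]
    except KeyError:
        options = sorted(_FUNCTIONS) + [f"shifted_{k}" for k in sorted(_FUNCTIONS)]
        raise KeyError(f"unknown benchmark {name!r}; available: {options}") from None
    shift = None
    if shifted:
        rng = np.random.default_rng(20_0000 + 97 * n_par)
        shift = rng.uniform(-0.25, 0.25, size=n_par) * cls.half_width
    fn = cls(n_par, shift)
    bounds = BoxBounds(-cls.half_width * np.ones(n_par), cls.half_width * np.ones(n_par))
    return OptimizationProblem(
        fn, bounds, name=name, optimum_x=fn.optimum_x, optimum_f=0.0
    )
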