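import numpy as np
import pytest

from essopt import BoxBounds, OptimizationProblem


class BoundCheckingProblem(OptimizationProblem):
    """Wraps an objective with an assertion that every evaluated point is
    inside the box — used to verify solver feasibility guarantees."""

    def evaluate(self, p):
        assert self.bounds.contains(np.asarray(p, float)), "evaluation outside bounds"
        return super().evaluate(p)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def quadratic_2d():
    center = np.array([1.0, -2.0])

    def f(p):
        d = p - center
        return float(d @ d)

    return OptimizationProblem(
        f,
        BoxBounds(np.array([-5.0, -5.0]), np.array([5.0, 5.0])),
        name="quadratic2",
        optimum_x=center,
        optimum_f=0.0,
    )


def make_quadratic(n, seed=0, coupled=True, lo=-5.0, hi=5.0):
    """Convex quadratic f = (x-c)^T A (x-c) with moderate conditioning."""
    rng = np.random.default_rng(seed)
    center = rng.uniform(lo * 0.5, hi * 0.5, size=n)
    if coupled:
        q, _ = np.linalg.qr(rng.standard_normal((n, n)))
        eig = rng.uniform(0.5, 2.0, size=n)
        a = (q * eig) @ q.T
    else:
        a = np.diag(rng.uniform(0.5, 2.0, size=n))

    def f(p):
        d = p - center
        return float(d @ a @ d)

    return OptimizationProblem(
        f,
        BoxBounds(np.full(n, lo), np.full(n, hi)),
        name=f"quadratic{n}",
        optimum_x=center,
        optimum_f=0.0,
    )
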