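import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from evrank import DecisionMatrix, Direction, FactorSpec

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


def make_matrix(values, directions=None, alternatives=None, factors=None,
                shifts=None, weights=None):
    """Build a validated DecisionMatrix from plain arrays."""
    arr = np.asarray(values, dtype=float)
    n, k = arr.shape
    alternatives = alternatives or [f"A{i+1}" for i in range(n)]
    factors = factors or [f"f{j+1}" for j in range(k)]
    directions = directions or [Direction.MAXIMIZE] * k
    shifts = shifts or [100.0] * k
    weights = weights or [1.0 / k] * k
    specs = [
        FactorSpec(name, d, shift=s, weight=w)
        for name, d, s, w in zip(factors, directions, shifts, weights)
    ]
    return DecisionMatrix(pd.DataFrame(arr, index=alternatives, columns=factors), specs)


@pytest.fixture
def simple_matrix():
    """3 preparations x 3 factors, mixed directions, no ties."""
    return make_matrix(
        [[2.0, 8.0, -40.0], [4.0, 4.0, -10.0], [8.0, 2.0, -25.0]],
        directions=[Direction.MAXIMIZE, Direction.MINIMIZE,
                    Direction.SHIFTED_MINIMIZE],
        factors=["recovery", "size", "zeta"],
    )


@pytest.fixture
def dominant_matrix():
    """First alternative is per-factor best everywhere; last is worst."""
    return make_matrix(
        [[10.0, 1.0], [5.0, 2.0], [2.0, 8.0]],
        directions=[Direction.MAXIMIZE, Direction.MINIMIZE],
        alternatives=["best", "mid", "worst"],
    )


def random_matrix(rng, n_alt=None, n_fac=None):
    """Random strictly-positive matrix with random directions and weights."""
    n = n_alt or rng.integers(2, 16)
    k = n_fac or rng.integers(1, 14)
    vals = rng.uniform(0.5, 100.0, size=(n, k))
    choices = [Direction.MAXIMIZE, Direction.MINIMIZE, Direction.SHIFTED_MINIMIZE]
    dirs = [choices[i] for i in rng.integers(0, 3, size=k)]
    w = rng.dirichlet(np.ones(k))
    return make_matrix(vals, directions=list(dirs), weights=list(w))
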