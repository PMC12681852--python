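"""Closeness to best- and worst-case profiles (TOPSIS-style).

Beyond the weighted score, each alternative is located between the
*ideal* profile (the per-factor best achieved in the dataset) and the
*worst-case* profile (the per-factor worst). On the weighted normalized
matrix V_ij = w_j * N_ij:

    v+_j = max_i V_ij         v-_j = min_i V_ij
    D+_i = ||V_i - v+||_2     D-_i = ||V_i - v-||_2
    C_i  = D-_i / (D+_i + D-_i)

C_i is 1 exactly when an alternative is per-factor best everywhere and 0 when
it is per-factor worst everywhere. This is the classical TOPSIS closeness
coefficient; note the ideal is defined per-dataset (column extrema of V), not
as the absolute vector of ones, so a closeness of 100 % is attainable only by
an alternative that dominates on every factor. The closeness ordering need
not coincide with the weighted-score ordering — the two views are
complementary, not redundant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import EVRankWarning, ValidationError
from .factors import WeightVector
from .normalize import NormalizedMatrix

__all__ = ["ProximityResult", "closeness_coefficients", "proximity_table"]


@dataclass(frozen=True)
class ProximityResult:
    """One alternative's Euclidean distances to the ideal / worst profiles and
    the resulting closeness coefficient in [0, 1]."""

    alternative: str
    distance_to_ideal: float
    distance_to_worst: float
    closeness: float


def closeness_coefficients(
    n: NormalizedMatrix, w: WeightVector
) -> list[ProximityResult]:
    """TOPSIS closeness of every alternative, in input row order.

    Degenerate case: if all alternatives are identical, both distances vanish
    for every row; closeness is then defined as 1 for all, with a warning
    (there is nothing to discriminate).
    """
    if len(w) != len(n.factors):
        raise ValidationError(f"{len(w)} weights for {len(n.factors)} factors")
    v = n.array * w.array[None, :]
    v_plus = v.max(axis=0)
    v_minus = v.min(axis=0)
    d_plus = np.linalg.norm(v - v_plus[None, :], axis=1)
    d_minus = np.linalg.norm(v - v_minus[None, :], axis=1)
    denom = d_plus + d_minus
    if np.all(denom == 0):
        warnings.warn(
            "all alternatives identical; closeness defined as 1 for all",
            EVRankWarning,
            stacklevel=2,
        )
        closeness = np.ones_like(denom)
    else:
        with np.errstate(invalid="ignore"):
            closeness = np.where(denom > 0, d_minus / np.where(denom > 0, denom, 1.0), 1.0)
    return [
        ProximityResult(str(a), float(dp), float(dm), float(c))
        for a, dp, dm, c in zip(n.values.index, d_plus, d_minus, closeness)
    ]


def proximity_table(n: NormalizedMatrix, w: WeightVector) -> pd.DataFrame:
    """Closeness results as a DataFrame indexed by alternative."""
    res = closeness_coefficients(n, w)
    return pd.DataFrame(
        {
            "distance_to_ideal": [r.distance_to_ideal for r in res],
            "distance_to_worst": [r.distance_to_worst for r in res],
            "closeness": [r.closeness for r in res],
        },
        index=[r.alternative for r in res],
    )
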