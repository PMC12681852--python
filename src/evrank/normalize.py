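"""Quotient normalization of decision-matrix columns.

Each factor column is mapped into (0, 1] so heterogeneous units become
comparable, with 1 always attained by the best alternative on that factor:

* maximize:          N_ij = X_ij / max_i X_ij
* minimize:          N_ij = min_i X_ij / X_ij
* shifted_minimize:  Y = X + shift, then N_ij = min_i Y_ij / Y_ij

The shifted form exists for signed quantities — zeta potential in particular,
where +100 moves the conventional (-100, +50) mV range onto the positive axis
and "more negative is better" becomes an ordinary minimization. Note the
shifted form is deliberately *not* scale-invariant: rescaling mV would change
the meaning of the +100 offset.

A constant column (max = min) normalizes to all ones: it carries no
discriminating information but the quotient is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .factors import DecisionMatrix, Direction, FactorSpec

__all__ = ["NormalizedMatrix", "normalize_factor", "normalize_matrix"]


@dataclass
class NormalizedMatrix:
    """Alternatives x factors matrix of normalized values N_ij in (0, 1]."""

    values: pd.DataFrame
    factors: list[FactorSpec] = field(default_factory=list)

    @property
    def alternatives(self) -> list[str]:
        return [str(a) for a in self.values.index]

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def normalize_factor(
    column, direction: Direction | str, shift: float = 100.0
) -> np.ndarray:
    """Normalize one factor column according to its direction.

    Positivity prerequisites (positive max for maximize, strictly positive
    values for minimize, positive shifted values for shifted_minimize) are
    checked here as well as by the matrix validator, so the function is safe
    standalone; violations raise :class:`ValidationError`, never NaN/Inf.
    """
    x = np.asarray(column, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValidationError("column must be a non-empty 1-D sequence")
    if np.any(~np.isfinite(x)):
        raise ValidationError("column contains non-finite values")
    direction = Direction.coerce(direction)

    if direction is Direction.MAXIMIZE:
        top = x.max()
        if not top > 0:
            raise ValidationError("maximize factor requires a positive maximum")
        if np.any(x <= 0):
            raise ValidationError(
                "maximize factor requires strictly positive values for "
                "normalized output in (0, 1]"
            )
        return x / top
    if direction is Direction.MINIMIZE:
        if not np.all(x > 0):
            raise ValidationError(
                "minimize factor requires strictly positive values"
            )
        return x.min() / x
    # shifted_minimize
    if not shift > 0:
        raise ValidationError("shifted_minimize requires shift > 0")
    y = x + shift
    if not np.all(y > 0):
        raise ValidationError(
            f"shifted_minimize: values + shift {shift} must be strictly positive"
        )
    return y.min() / y


def normalize_matrix(m: DecisionMatrix) -> NormalizedMatrix:
    """Column-wise normalization of a validated decision matrix.

    Row and column order are preserved; every output column attains exactly 1
    at its best alternative.
    """
    out = {}
    for f in m.factors:
        out[f.name] = normalize_factor(
            m.values[f.name].to_numpy(), f.direction, f.shift
        )
    df = pd.DataFrame(out, index=m.values.index)[m.factor_names]
    return NormalizedMatrix(df, list(m.factors))
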