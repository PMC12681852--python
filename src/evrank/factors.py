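"""Decision-problem data model: factors, directions, weights and the raw matrix.

An *alternative* is one candidate EV preparation (typically the product of one
isolation method); a *factor* is one numeric characterization criterion (mean
size, zeta potential, particle recovery, purity ratio, ...). Each factor
carries an optimization direction:

``maximize``
    larger raw values are preferable (recovery, purity, antioxidant activity);
``minimize``
    smaller raw values are preferable (mean size, total phenolic content);
``shifted_minimize``
    minimize after adding a positive shift, so signed quantities such as zeta
    potential (more negative = more colloidally stable) become positive before
    the quotient normalization. The default shift of 100 covers the
    conventional zeta range of (-100, +50) mV.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError, ValidationError

__all__ = [
    "Direction",
    "FactorSpec",
    "WeightVector",
    "DecisionMatrix",
    "build_decision_problem",
    "resolve_weights",
    "WEIGHT_SUM_TOL",
]

#: tolerance on |sum(w) - 1| before auto-normalization is required
WEIGHT_SUM_TOL = 1e-6


class Direction(str, Enum):
    """Optimization direction of a factor."""

    MAXIMIZE = "maximize"
    MINIMIZE = "minimize"
    SHIFTED_MINIMIZE = "shifted_minimize"

    @classmethod
    def coerce(cls, value: "Direction | str") -> "Direction":
        if isinstance(value, Direction):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise ConfigurationError(
                f"unknown direction {value!r}; expected one of "
                f"{[d.value for d in cls]}"
            ) from None


@dataclass(frozen=True)
class FactorSpec:
    """One criterion: name, direction, shift constant and weight.

    Parameters
    ----------
    name
        Non-empty identifier, unique within a decision problem.
    direction
        Optimization direction; see :class:`Direction`.
    shift
        Offset added to raw values before normalization. Only meaningful for
        ``shifted_minimize``; default 100 (zeta-potential convention).
    weight
        Relative importance in [0, 1]. Weights across a problem sum to 1.
    units
        Free-text label carried through to reports; never interpreted.
    """

    name: str
    direction: Direction = Direction.MAXIMIZE
    shift: float = 100.0
    weight: float = 0.0
    units: str = ""

    def __post_init__(self) -> None:
        if not self.name or not str(self.name).strip():
            raise ConfigurationError("factor name must be a non-empty string")
        object.__setattr__(self, "direction", Direction.coerce(self.direction))
        if not (0.0 <= self.weight <= 1.0):
            raise ValidationError(
                f"factor {self.name!r}: weight {self.weight} outside [0, 1]"
            )
        if self.direction is Direction.SHIFTED_MINIMIZE and not self.shift > 0:
            raise ValidationError(
                f"factor {self.name!r}: shifted_minimize requires shift > 0, "
                f"got {self.shift}"
            )

    def with_weight(self, weight: float) -> "FactorSpec":
        return FactorSpec(self.name, self.direction, self.shift, weight, self.units)


@dataclass(frozen=True)
class WeightVector:
    """Weights aligned to a problem's factor order; non-negative, sum to 1."""

    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.size == 0:
            raise ValidationError("weight vector must be a non-empty 1-D sequence")
        if np.any(w < 0) or np.any(w > 1):
            raise ValidationError("weights must lie in [0, 1]")
        if abs(w.sum() - 1.0) > WEIGHT_SUM_TOL:
            raise ValidationError(
                f"weights must sum to 1 within {WEIGHT_SUM_TOL}; got sum {w.sum()!r}"
            )
        object.__setattr__(self, "weights", tuple(float(x) for x in w))

    def __len__(self) -> int:
        return len(self.weights)

    def __iter__(self):
        return iter(self.weights)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)


def resolve_weights(
    n_factors: int,
    user_weights: Sequence[float] | None = None,
    auto_normalize: bool = False,
) -> WeightVector:
    """Return the weight vector to use for ``n_factors`` criteria.

    With no ``user_weights`` the equal-weight default ``1/n`` each is returned
    (the reference configuration of the scoring model). User weights are
    accepted as-is when they already sum to 1 within :data:`WEIGHT_SUM_TOL`;
    otherwise they are rescaled to sum 1 only when ``auto_normalize`` is set
    (a warning records the rescaling), else a :class:`ValidationError` is
    raised.
    """
    if n_factors < 1:
        raise ValidationError("need at least one factor")
    if user_weights is None:
        return WeightVector(tuple([1.0 / n_factors] * n_factors))
    w = np.asarray(list(user_weights), dtype=float)
    if w.size != n_factors:
        raise ValidationError(
            f"expected {n_factors} weights, got {w.size}"
        )
    if np.any(~np.isfinite(w)):
        raise ValidationError("weights must be finite")
    if np.any(w < 0):
        raise ValidationError("weights must be non-negative")
    total = w.sum()
    if total == 0:
        raise ValidationError("weights sum to zero; cannot normalize")
    if abs(total - 1.0) <= WEIGHT_SUM_TOL:
        return WeightVector(tuple(w))
    if not auto_normalize:
        raise ValidationError(
            f"weights sum to {total!r}, not 1; pass auto_normalize=True to rescale"
        )
    warnings.warn(
        f"weights summed to {total:.6g}; rescaled to sum 1",
        stacklevel=2,
    )
    return WeightVector(tuple(w / total))


@dataclass
class DecisionMatrix:
    """Alternatives x factors raw value matrix plus factor metadata.

    ``values`` is a pandas DataFrame whose index holds the alternative names
    and whose columns follow ``factors`` order exactly. Construction
    validates every model invariant; instances are therefore safe inputs for
    normalization without further checks.
    """

    values: pd.DataFrame
    factors: list[FactorSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def alternatives(self) -> list[str]:
        return [str(a) for a in self.values.index]

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def weights(self) -> WeightVector:
        return WeightVector(tuple(f.weight for f in self.factors))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_weights(self, w: WeightVector | Sequence[float]) -> "DecisionMatrix":
        if not isinstance(w, WeightVector):
            w = WeightVector(tuple(w))
        if len(w) != len(self.factors):
            raise ValidationError(
                f"{len(w)} weights for {len(self.factors)} factors"
            )
        specs = [f.with_weight(x) for f, x in zip(self.factors, w)]
        return DecisionMatrix(self.values.copy(), specs)

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        df = self.values
        if df.ndim != 2 or df.shape[0] < 2 or df.shape[1] < 1:
            raise ValidationError(
                f"need >= 2 alternatives and >= 1 factor; got shape {df.shape}"
            )
        if len(self.factors) != df.shape[1]:
            raise ConfigurationError(
                f"{len(self.factors)} factor specs for {df.shape[1]} columns"
            )
        names = [f.name for f in self.factors]
        if list(df.columns) != names:
            raise ConfigurationError(
                f"column order {list(df.columns)} does not match factor specs {names}"
            )
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ConfigurationError(f"duplicate factor names: {dupes}")
        alts = list(df.index)
        if len(set(alts)) != len(alts):
            dupes = sorted({a for a in alts if alts.count(a) > 1})
            raise ValidationError(f"duplicate alternative names: {dupes}")

        arr = df.to_numpy(dtype=float)
        bad = np.argwhere(~np.isfinite(arr))
        if bad.size:
            i, j = bad[0]
            raise DataError(
                f"non-finite value at alternative {df.index[i]!r}, "
                f"factor {df.columns[j]!r}"
            )

        for j, f in enumerate(self.factors):
            col = arr[:, j]
            if f.direction is Direction.MAXIMIZE and not col.max() > 0:
                raise ValidationError(
                    f"maximize factor {f.name!r} requires a positive maximum"
                )
            if f.direction is Direction.MINIMIZE and not np.all(col > 0):
                raise ValidationError(
                    f"minimize factor {f.name!r} requires strictly positive values"
                )
            if f.direction is Direction.SHIFTED_MINIMIZE and not np.all(
                col + f.shift > 0
            ):
                raise ValidationError(
                    f"shifted_minimize factor {f.name!r}: values + shift "
                    f"{f.shift} must be strictly positive"
                )

        wsum = sum(f.weight for f in self.factors)
        if abs(wsum - 1.0) > WEIGHT_SUM_TOL:
            raise ValidationError(
                f"factor weights sum to {wsum!r}, not 1 (tolerance {WEIGHT_SUM_TOL})"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DecisionMatrix):
            return NotImplemented
        return (
            self.factors == other.factors
            and list(self.values.index) == list(other.values.index)
            and np.array_equal(self.values.to_numpy(), other.values.to_numpy())
        )


def build_decision_problem(
    raw_table: pd.DataFrame,
    factor_config: Sequence[FactorSpec],
    *,
    weights: Sequence[float] | None = None,
    auto_normalize_weights: bool = False,
) -> DecisionMatrix:
    """Assemble and validate a :class:`DecisionMatrix` from a named table.

    ``raw_table`` columns must match the configured factor names exactly
    (order-insensitive; the result follows config order). When ``weights`` is
    given, or when the configured weights do not already sum to 1, weights are
    resolved through :func:`resolve_weights` — so a config with all-zero
    weights silently receives the equal-weight default.
    """
    config = list(factor_config)
    if not config:
        raise ConfigurationError("factor_config must not be empty")
    names = [f.name for f in config]
    if len(set(names)) != len(names):
        raise ConfigurationError(
            f"duplicate factor names in config: "
            f"{sorted({n for n in names if names.count(n) > 1})}"
        )
    cols = [str(c) for c in raw_table.columns]
    missing = [n for n in names if n not in cols]
    extra = [c for c in cols if c not in names]
    if missing or extra:
        raise ConfigurationError(
            f"table/config column mismatch; missing from table: {missing}; "
            f"not in config: {extra}"
        )

    df = raw_table.loc[:, names].copy()
    for col in df.columns:
        for row in df.index:
            v = df.at[row, col]
            try:
                fv = float(v)
            except (TypeError, ValueError):
                raise DataError(
                    f"cell at alternative {row!r}, factor {col!r} is not "
                    f"numeric: {v!r}"
                ) from None
            if not math.isfinite(fv):
                raise DataError(
                    f"cell at alternative {row!r}, factor {col!r} is not "
                    f"finite: {v!r}"
                )
    df = df.astype(float)
    df.index = [str(i) for i in df.index]

    config_wsum = sum(f.weight for f in config)
    if weights is not None or abs(config_wsum - 1.0) > WEIGHT_SUM_TOL:
        wv = resolve_weights(
            len(config),
            weights if weights is not None else (None if config_wsum == 0 else [f.weight for f in config]),
            auto_normalize=auto_normalize_weights,
        )
        config = [f.with_weight(x) for f, x in zip(config, wv)]

    return DecisionMatrix(df, config)
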