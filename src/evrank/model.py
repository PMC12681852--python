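"""Model / Results interface over the decision pipeline.

:class:`DecisionModel` holds a validated decision problem (data + factor
configuration); :meth:`DecisionModel.fit` evaluates it under a weight vector
and returns a :class:`DecisionResults` carrying normalized values, weighted
scores, competition ranks and TOPSIS closeness, with ``summary()``,
sensitivity analysis and plotting attached — the familiar
model-object / results-object split.

Example
-------
>>> from evrank import DecisionModel, preset_spec, generate_dataset
>>> dm, _ = generate_dataset(preset_spec("ev8x13", seed=7))
>>> res = DecisionModel(dm.values, dm.factors).fit()
>>> res.ranks.iloc[:3]          # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .factors import (
    DecisionMatrix,
    FactorSpec,
    WeightVector,
    build_decision_problem,
    resolve_weights,
)
from .normalize import NormalizedMatrix, normalize_matrix
from .proximity import proximity_table
from .scoring import assign_ranks, weighted_scores
from .sensitivity import SensitivityReport, dirichlet_scenarios, weight_sweep

__all__ = ["DecisionModel", "DecisionResults"]


class DecisionModel:
    """A multi-criteria EV ranking problem ready to evaluate.

    Parameters
    ----------
    data
        Alternatives x factors table of raw characterization values; the
        index names the preparations, columns must match the factor names.
    factors
        One :class:`FactorSpec` per column (direction, shift, weight, units).
    weights, auto_normalize_weights
        Optional weight override, resolved as in :func:`resolve_weights`.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        factors: Sequence[FactorSpec],
        *,
        weights: Sequence[float] | None = None,
        auto_normalize_weights: bool = False,
    ) -> None:
        self.matrix = build_decision_problem(
            data,
            factors,
            weights=weights,
            auto_normalize_weights=auto_normalize_weights,
        )

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_decision_matrix(cls, m: DecisionMatrix) -> "DecisionModel":
        obj = cls.__new__(cls)
        obj.matrix = m
        return obj

    @classmethod
    def from_csv(cls, matrix_path, config_path) -> "DecisionModel":
        from .io import read_matrix

        return cls.from_decision_matrix(read_matrix(matrix_path, config_path))

    # -- accessors -------------------------------------------------------
    @property
    def alternatives(self) -> list[str]:
        return self.matrix.alternatives

    @property
    def factor_names(self) -> list[str]:
        return self.matrix.factor_names

    def fit(
        self,
        weights: Sequence[float] | None = None,
        *,
        auto_normalize_weights: bool = False,
    ) -> "DecisionResults":
        """Evaluate the problem: normalize, score, rank, locate vs ideal.

        ``weights`` overrides the configured factor weights for this fit
        only (resolved through :func:`resolve_weights`).
        """
        if weights is not None:
            w = resolve_weights(
                len(self.matrix.factors), weights, auto_normalize_weights
            )
            m = self.matrix.with_weights(w)
        else:
            m = self.matrix
        normalized = normalize_matrix(m)
        wv = m.weights
        scores = weighted_scores(normalized, wv)
        ranks = assign_ranks(scores)
        prox = proximity_table(normalized, wv)
        return DecisionResults(
            model=self,
            matrix=m,
            weights=wv,
            normalized=normalized,
            scores=scores,
            ranks=ranks,
            proximity=prox,
        )


@dataclass
class DecisionResults:
    """Fitted ranking: scores, ranks, closeness and diagnostics."""

    model: DecisionModel
    matrix: DecisionMatrix
    weights: WeightVector
    normalized: NormalizedMatrix
    scores: pd.Series
    ranks: pd.Series
    proximity: pd.DataFrame
    _sensitivity: SensitivityReport | None = field(default=None, repr=False)

    # -- tables ----------------------------------------------------------
    @property
    def table(self) -> pd.DataFrame:
        """Per-alternative results ordered by rank (ties in input order)."""
        df = pd.DataFrame(
            {
                "score": self.scores,
                "rank": self.ranks,
                "closeness": self.proximity["closeness"],
            }
        )
        order = np.argsort(self.ranks.to_numpy(), kind="stable")
        return df.iloc[order]

    def top(self, k: int = 3) -> list[str]:
        """Names of the k best-ranked alternatives."""
        return list(self.table.index[:k])

    # -- sensitivity -----------------------------------------------------
    def sensitivity(
        self,
        n_scenarios: int = 1000,
        concentration: float = 1.0,
        seed: int = 0,
    ) -> SensitivityReport:
        """Dirichlet weight-perturbation analysis around this fit's weights."""
        rep = dirichlet_scenarios(
            self.matrix,
            n_scenarios=n_scenarios,
            concentration=concentration,
            seed=seed,
            baseline_weights=self.weights,
        )
        self._sensitivity = rep
        return rep

    def weight_sweep(self, factor: str, grid) -> SensitivityReport:
        """One-at-a-time weight sweep for a single factor."""
        return weight_sweep(self.matrix, factor, grid, baseline_weights=self.weights)

    # -- presentation ----------------------------------------------------
    def summary(self, top_k: int = 3) -> str:
        """Human-readable results table (scores to 3 decimals)."""
        lines = []
        n_alt, n_fac = self.matrix.shape
        lines.append("EV preparation ranking")
        lines.append("=" * 58)
        lines.append(f"alternatives: {n_alt}    factors: {n_fac}")
        w = self.weights.array
        equal = np.allclose(w, 1.0 / len(w))
        lines.append(
            "weights: equal (1/%d each)" % len(w)
            if equal
            else "weights: " + ", ".join(f"{x:.3f}" for x in w)
        )
        lines.append("-" * 58)
        lines.append(f"{'alternative':<24}{'score':>8}{'rank':>6}{'closeness':>12}")
        for alt, row in self.table.iterrows():
            lines.append(
                f"{alt:<24}{row['score']:>8.3f}{int(row['rank']):>6}"
                f"{row['closeness']:>12.3f}"
            )
        lines.append("-" * 58)
        lines.append("top-%d: %s" % (top_k, " > ".join(self.top(top_k))))
        if self._sensitivity is not None:
            s = self._sensitivity
            lines.append(
                f"rank stability ({s.n_scenarios} scenarios, seed {s.seed}): "
                f"top-1 retention {s.top1_retention:.3f}, "
                f"bottom retention {s.bottom_retention:.3f}"
            )
        return "\n".join(lines)

    # -- plots (thin wrappers; see plots module) -------------------------
    def plot_scores(self, ax=None):
        from .plots import plot_scores

        return plot_scores(self, ax=ax)

    def plot_normalized(self, ax=None):
        from .plots import plot_normalized

        return plot_normalized(self, ax=ax)

    def plot_radar(self, top_k: int = 3, ax=None):
        from .plots import plot_radar

        return plot_radar(self, top_k=top_k, ax=ax)

    def plot_decision_space(self, ax=None):
        from .plots import plot_decision_space

        return plot_decision_space(self, ax=ax)
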