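"""Pearson correlation between characterization factors and bioactivity.

Bioactivity is supplied as a long table of cancer-cell viability percentages,
one row per (preparation, cell line, dose). For every factor and every
(cell line, dose) condition, the sample Pearson r is computed across the
preparations present in both tables, with the two-sided p-value from the
exact t transform ``t = r * sqrt((n-2) / (1-r^2))`` on n-2 degrees of
freedom. Significance stars follow the usual thresholds: * p <= 0.05,
** p <= 0.01, *** p <= 0.001, else ns.

No multiple-testing correction is applied by default (each cell is starred
on its own); a Benjamini-Hochberg adjusted column can be requested.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError, ValidationError
from .factors import DecisionMatrix

__all__ = [
    "pearson_r",
    "significance_label",
    "bioactivity_correlation",
    "correlation_matrix_layout",
]

_STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))

#: expected columns of the long-format bioactivity table
BIOACTIVITY_COLUMNS = ("alternative", "cell_line", "dose", "viability_percent")


def significance_label(p_value: float) -> str:
    """Star label for a p-value: *** <= 0.001 < ** <= 0.01 < * <= 0.05 < ns."""
    for thr, label in _STAR_THRESHOLDS:
        if p_value <= thr:
            return label
    return "ns"


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation and two-sided p-value.

    Requires n >= 3 paired observations and nonzero variance in both
    arguments; perfectly collinear data return r = +/-1 with p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D sequences of equal length")
    if x.size < 3:
        raise ValidationError(f"need at least 3 pairs, got {x.size}")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise DataError("correlation inputs must be finite")
    if np.isclose(np.std(x), 0) or np.isclose(np.std(y), 0):
        raise ValidationError("undefined correlation: an input has zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _validate_bioactivity(b: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in BIOACTIVITY_COLUMNS if c not in b.columns]
    if missing:
        raise ValidationError(f"bioactivity table missing columns {missing}")
    if b.duplicated(["alternative", "cell_line", "dose"]).any():
        raise ValidationError(
            "duplicate (alternative, cell_line, dose) rows in bioactivity table"
        )
    if np.any(~np.isfinite(b["viability_percent"].to_numpy(dtype=float))):
        raise DataError("non-finite viability values")
    return b


def bioactivity_correlation(
    m: DecisionMatrix,
    b: pd.DataFrame,
    *,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Factor-vs-viability Pearson correlations for every condition.

    Returns a long DataFrame with one row per (cell_line, dose, factor):
    columns r, p_value, n, significance and, when ``bh_adjust`` is set, a
    Benjamini-Hochberg adjusted ``p_adj`` column. Rows are ordered by
    condition (cell line, then dose, in order of first appearance) then by
    factor order of the decision matrix.
    """
    b = _validate_bioactivity(b)
    unknown = sorted(set(b["alternative"].astype(str)) - set(m.alternatives))
    if unknown:
        raise ValidationError(
            f"bioactivity rows reference unknown alternatives: {unknown}"
        )
    rows = []
    conditions = b.drop_duplicates(["cell_line", "dose"])[["cell_line", "dose"]]
    for _, (line, dose) in conditions.iterrows():
        sub = b[(b["cell_line"] == line) & (b["dose"] == dose)]
        alts = [str(a) for a in sub["alternative"]]
        if len(alts) < 3:
            raise ValidationError(
                f"condition ({line!r}, {dose!r}) has {len(alts)} paired "
                "alternatives; need >= 3"
            )
        viability = sub["viability_percent"].to_numpy(dtype=float)
        for f in m.factors:
            x = m.values.loc[alts, f.name].to_numpy(dtype=float)
            r, p = pearson_r(x, viability)
            rows.append(
                {
                    "cell_line": line,
                    "dose": dose,
                    "factor": f.name,
                    "r": r,
                    "p_value": p,
                    "n": len(alts),
                    "significance": significance_label(p),
                }
            )
    out = pd.DataFrame(rows)
    if bh_adjust:
        out["p_adj"] = _benjamini_hochberg(out["p_value"].to_numpy())
        out["significance_adj"] = [significance_label(p) for p in out["p_adj"]]
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    return stats.false_discovery_control(p, method="bh")


def correlation_matrix_layout(long_table: pd.DataFrame, value: str = "r") -> pd.DataFrame:
    """Pivot the long correlation table into a factor x (cell line, dose) grid
    — the heat-map layout."""
    return long_table.pivot_table(
        index="factor",
        columns=["cell_line", "dose"],
        values=value,
        sort=False,
    )
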