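"""Derived characterization metrics: instrument readouts -> decision-matrix columns.

These are the bench-level formulas that turn NTA, NanoDrop, BCA and DPPH
readouts into the factors the decision model scores:

* particle recovery %  = (C_EV * V_EV) / (C_sup * V_sup) * 100
* internal content     = total - outside       (nucleic acids or protein)
* purity ratio         = particle concentration / reference mass concentration
* antioxidant %        = (A_control - A_sample) / A_control * 100   (DPPH)

All four accept pre-averaged triplicate values; :func:`aggregate_replicates`
does the averaging. Physically suspect results (recovery above 100 %,
negative internal content, negative scavenging) are preserved and flagged
with a warning rather than clamped — positivity is enforced later by the
decision-matrix validator, where direction context is known.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import EVRankWarning, ValidationError

__all__ = [
    "RecoveryInput",
    "particle_recovery",
    "internal_content",
    "purity_ratio",
    "antioxidant_percent",
    "aggregate_replicates",
]


@dataclass(frozen=True)
class RecoveryInput:
    """Operands of the particle-recovery ratio; all strictly positive.

    Concentrations are particles per volume (e.g. particles/mL from NTA),
    volumes in any single consistent unit.
    """

    ev_concentration: float
    ev_volume: float
    supernatant_concentration: float
    supernatant_volume: float

    def __post_init__(self) -> None:
        for name in (
            "ev_concentration",
            "ev_volume",
            "supernatant_concentration",
            "supernatant_volume",
        ):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be strictly positive, got {v!r}")


def particle_recovery(r: RecoveryInput) -> float:
    """Percent of supernatant particles retained by an isolation.

    Values above 100 % (more particles in the isolate than measured in the
    supernatant, an NTA artifact) are returned as-is with a warning.
    """
    pct = 100.0 * (r.ev_concentration * r.ev_volume) / (
        r.supernatant_concentration * r.supernatant_volume
    )
    if pct > 100.0:
        warnings.warn(
            f"particle recovery {pct:.3g}% exceeds 100%; check NTA inputs",
            EVRankWarning,
            stacklevel=2,
        )
    return pct


def internal_content(total: float, outside: float) -> float:
    """Internal (intravesicular) concentration: total minus outside.

    Covers both nucleic acids (with/without lysis) and protein (with/without
    RIPA lysis). A negative result — measurement noise when outside exceeds
    total — is returned with a warning.
    """
    if total < 0 or outside < 0:
        raise ValidationError("concentrations must be non-negative")
    inner = total - outside
    if inner < 0:
        warnings.warn(
            f"internal content negative ({inner:.4g}); outside measurement "
            "exceeds total (noise)",
            EVRankWarning,
            stacklevel=2,
        )
    return inner


def purity_ratio(
    mean_particle_concentration: float, mean_reference_concentration: float
) -> float:
    """Particles per unit co-isolated mass (protein or residual nucleic acid).

    Protein-based purity divides by the external (no-lysis) protein
    concentration; nucleic-acid-based purity divides by the residual
    (no-lysis) nucleic-acid concentration. Units are carried as labels only.
    """
    if not mean_particle_concentration > 0:
        raise ValidationError("particle concentration must be strictly positive")
    if not mean_reference_concentration > 0:
        raise ValidationError("reference concentration must be strictly positive")
    return mean_particle_concentration / mean_reference_concentration


def antioxidant_percent(control_absorbance: float, sample_absorbance: float) -> float:
    """DPPH radical-scavenging percent from control vs sample absorbance.

    Negative output (sample absorbs more than the reagent control — a
    pro-oxidant artifact) is preserved with a warning.
    """
    if not control_absorbance > 0:
        raise ValidationError("control absorbance must be strictly positive")
    if sample_absorbance < 0:
        raise ValidationError("sample absorbance must be non-negative")
    pct = 100.0 * (control_absorbance - sample_absorbance) / control_absorbance
    if pct < 0:
        warnings.warn(
            f"antioxidant activity negative ({pct:.3g}%)",
            EVRankWarning,
            stacklevel=2,
        )
    return pct


def aggregate_replicates(
    long_table: pd.DataFrame,
    *,
    alternative_col: str = "alternative",
    factor_col: str = "factor",
    value_col: str = "value",
) -> pd.DataFrame:
    """Arithmetic-mean replicate aggregation of a long table to a wide matrix.

    Input rows are (alternative, factor, replicate, value); output is one row
    per alternative, one column per factor, each cell the mean over
    replicates — the matrix form the decision model consumes.
    """
    for c in (alternative_col, factor_col, value_col):
        if c not in long_table.columns:
            raise ValidationError(f"replicate table missing column {c!r}")
    wide = (
        long_table.groupby([alternative_col, factor_col], sort=False)[value_col]
        .mean()
        .unstack(factor_col)
    )
    wide.index.name = None
    wide.columns.name = None
    return wide
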