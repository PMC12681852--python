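"""Weighted scores and competition ranking.

The overall score of alternative i is the convex combination
``S_i = sum_j w_j * N_ij`` of its normalized factor values; with the
equal-weight default this is the row mean. Ranks are assigned by descending
score with competition ("1224") tie handling: tied alternatives share the
smallest applicable rank and the next distinct score skips accordingly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .factors import WeightVector
from .normalize import NormalizedMatrix

__all__ = ["weighted_scores", "assign_ranks", "score_table"]


def weighted_scores(n: NormalizedMatrix, w: WeightVector) -> pd.Series:
    """Per-alternative weighted score S_i = sum_j w_j N_ij.

    Returns a float Series indexed by alternative, in input row order.
    """
    if len(w) != len(n.factors):
        raise ValidationError(
            f"{len(w)} weights for {len(n.factors)} factors"
        )
    s = n.array @ w.array
    return pd.Series(s, index=n.values.index, name="score")


def assign_ranks(scores: pd.Series) -> pd.Series:
    """Descending competition ranks: rank_i = 1 + #{k : S_k > S_i}.

    Ties share the minimal rank; the next distinct score skips ranks.
    """
    s = scores.to_numpy(dtype=float)
    if np.any(~np.isfinite(s)):
        raise ValidationError("scores must be finite")
    ranks = 1 + (s[None, :] > s[:, None]).sum(axis=1)
    return pd.Series(ranks, index=scores.index, name="rank")


def score_table(n: NormalizedMatrix, w: WeightVector) -> pd.DataFrame:
    """Score + rank table ordered by rank, ties in input order."""
    s = weighted_scores(n, w)
    r = assign_ranks(s)
    df = pd.DataFrame({"score": s, "rank": r})
    order = np.argsort(r.to_numpy(), kind="stable")
    return df.iloc[order]
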