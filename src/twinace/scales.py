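"""Likert-scale scoring and internal consistency.

Questionnaire scales are scored as the mean of available item responses after
reversing negatively keyed items (x -> min + max - x, i.e. 6 - x on a 1-5
scale).  Internal consistency is Cronbach's alpha on complete rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError, RangeError


@dataclass(frozen=True)
class ScaleKey:
    """Scoring key for one questionnaire scale.

    Attributes
    ----------
    name : str
        Scale name (e.g. ``"grit"``).
    items : tuple of str
        Item identifiers, in any order (scoring is order-invariant).
    reversed_items : frozenset of str
        Items keyed in the opposite direction.
    response_min, response_max : int
        Valid response range (default 1-5 Likert).
    min_items_fraction : float
        Minimum fraction of items that must be answered for a score to be
        produced (default: at least half).
    """

    name: str
    items: tuple
    reversed_items: frozenset = field(default_factory=frozenset)
    response_min: int = 1
    response_max: int = 5
    min_items_fraction: float = 0.5

    def __post_init__(self):
        if len(self.items) < 1:
            raise ValueError("a scale needs at least one item")
        unknown = set(self.reversed_items) - set(self.items)
        if unknown:
            raise ValueError(f"reversed items not in item list: {sorted(unknown)}")


def score_scale(item_responses: pd.DataFrame, key: ScaleKey) -> pd.Series:
    """Score a scale: reverse keyed items, then average available responses.

    Parameters
    ----------
    item_responses : DataFrame
        One row per individual, one column per item in ``key.items``.
        Values in [response_min, response_max] or missing (NaN).

    Returns
    -------
    Series of scale scores; missing where fewer than
    ``ceil(min_items_fraction * k)`` items were answered.
    """
    missing_cols = [i for i in key.items if i not in item_responses.columns]
    if missing_cols:
        raise RangeError(f"items absent from response matrix: {missing_cols}")
    x = item_responses[list(key.items)].astype(float).copy()
    lo, hi = key.response_min, key.response_max
    out_of_range = (x < lo) | (x > hi)
    if out_of_range.any().any():
        bad = [c for c in x.columns if out_of_range[c].any()]
        raise RangeError(f"responses outside [{lo}, {hi}] in item(s): {bad}")
    for item in key.reversed_items:
        x[item] = lo + hi - x[item]
    answered = x.notna().sum(axis=1)
    need = int(np.ceil(key.min_items_fraction * len(key.items)))
    scores = x.mean(axis=1)
    scores[answered < max(need, 1)] = np.nan
    return scores.rename(key.name)


def cronbach_alpha(item_responses: pd.DataFrame) -> float:
    """Cronbach's alpha: (k/(k-1)) * (1 - sum(item variances)/var(total)).

    Computed on complete rows with sample (n-1) variances.  Requires at least
    two items and three complete rows.
    """
    x = pd.DataFrame(item_responses).astype(float).dropna()
    k = x.shape[1]
    if k < 2:
        raise InsufficientDataError("Cronbach's alpha needs at least 2 items")
    if len(x) < 3:
        raise InsufficientDataError("Cronbach's alpha needs at least 3 complete rows")
    item_var = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))
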