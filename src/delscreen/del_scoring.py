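"""Activity scoring of DEL selection records.

Each compound's post-selection count and enrichment fold (EF) are observed
under three conditions: target-on-beads, blank beads, and DNA-tag-only.  Per
condition, counts and EFs are normalized across the library (min-max by
default) to remove the scale differences between conditions, then background
channels are subtracted::

    count = count_norm_target - count_norm_beads - count_norm_tag
    EF    = EF_norm_target    - EF_norm_beads    - EF_norm_tag
    score = a * count + b * EF        (defaults a = 0.8, b = 0.2)

High count and EF in the target channel, not explained by the matrix or tag
backgrounds, indicate affinity; the count term carries more weight because
post-selection counts are the more reliable readout.  Assay-derived analogues
are mapped onto the same 0-1 scale by bucketing their IC50 (µM):
< 10 -> 1, [10, 20) -> 0.9, [20, 30) -> 0.8, [30, 40) -> 0.7, [40, 50] -> 0.6,
> 50 -> 0.

Scores are deliberately not clipped: a matrix binder can legitimately score
below zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .chem_enum import InputError
from .synthetic_del import CONDITIONS, SelectionRecord


@dataclass(frozen=True)
class ScoreWeights:
    """Weights of the count and EF terms in the combined score."""

    a: float = 0.8
    b: float = 0.2

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise InputError("score weights must be non-negative")


@dataclass
class ScoredCompound:
    compound_id: str
    count_norm_target: float
    count_norm_beads: float
    count_norm_tag: float
    ef_norm_target: float
    ef_norm_beads: float
    ef_norm_tag: float
    count_diff: float
    ef_diff: float
    score: float


def normalize_condition(values: Sequence[float], method: str = "minmax") -> np.ndarray:
    """Normalize one condition's values across the library.

    ``minmax`` maps onto [0, 1]; a constant vector maps to all zeros (a
    channel with no variation carries no signal).  ``zscore`` is offered as an
    alternative and is not bounded.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise InputError("cannot normalize an empty vector")
    if np.any(x < 0):
        raise InputError("condition values must be non-negative")
    if method == "minmax":
        lo, hi = x.min(), x.max()
        if hi == lo:
            return np.zeros_like(x)
        return (x - lo) / (hi - lo)
    if method == "zscore":
        sd = x.std()
        if sd == 0:
            return np.zeros_like(x)
        return (x - x.mean()) / sd
    raise InputError(f"unknown normalization method {method!r}")


def weighted_score(
    count_diff: float, ef_diff: float, weights: ScoreWeights = ScoreWeights()
) -> float:
    """score = a * count + b * EF."""
    return weights.a * count_diff + weights.b * ef_diff


def compute_scores(
    records: Sequence[SelectionRecord],
    weights: ScoreWeights = ScoreWeights(),
    method: str = "minmax",
) -> list[ScoredCompound]:
    """Score every compound; normalization is per condition over the whole input.

    Output order preserves input order.
    """
    if len(records) == 0:
        raise InputError("no selection records supplied")
    count_norm = {
        cond: normalize_condition(
            [getattr(r, f"post_{cond}") for r in records], method
        )
        for cond in CONDITIONS
    }
    ef_norm = {
        cond: normalize_condition([getattr(r, f"ef_{cond}") for r in records], method)
        for cond in CONDITIONS
    }
    count_diff = count_norm["target"] - count_norm["beads"] - count_norm["tag"]
    ef_diff = ef_norm["target"] - ef_norm["beads"] - ef_norm["tag"]
    score = weights.a * count_diff + weights.b * ef_diff
    return [
        ScoredCompound(
            compound_id=r.compound_id,
            count_norm_target=float(count_norm["target"][i]),
            count_norm_beads=float(count_norm["beads"][i]),
            count_norm_tag=float(count_norm["tag"][i]),
            ef_norm_target=float(ef_norm["target"][i]),
            ef_norm_beads=float(ef_norm["beads"][i]),
            ef_norm_tag=float(ef_norm["tag"][i]),
            count_diff=float(count_diff[i]),
            ef_diff=float(ef_diff[i]),
            score=float(score[i]),
        )
        for i, r in enumerate(records)
    ]


#: IC50 bucket upper edges (µM) and the score assigned below each edge.
#: Buckets are half-open [lo, hi); exactly 50 µM still counts as the last
#: measured bucket (0.6); anything above 50 scores 0.
IC50_BUCKETS: tuple[tuple[float, float], ...] = (
    (10.0, 1.0),
    (20.0, 0.9),
    (30.0, 0.8),
    (40.0, 0.7),
    (50.0, 0.6),
)


def ic50_to_score(ic50_uM: float) -> float:
    """Map a measured (or censored > 50) IC50 in µM onto the DEL score scale."""
    if not ic50_uM > 0:
        raise InputError(f"IC50 must be positive, got {ic50_uM!r}")
    for edge, score in IC50_BUCKETS:
        if ic50_uM < edge:
            return score
    if ic50_uM == 50.0:
        return 0.6
    return 0.0


def scored_to_frame(scored: Sequence[ScoredCompound]) -> pd.DataFrame:
    cols = [
        "compound_id", "count_norm_target", "count_norm_beads", "count_norm_tag",
        "ef_norm_target", "ef_norm_beads", "ef_norm_tag",
        "count_diff", "ef_diff", "score",
    ]
    return pd.DataFrame({c: [getattr(s, c) for s in scored] for c in cols})


def scored_from_frame(df: pd.DataFrame) -> list[ScoredCompound]:
    return [
        ScoredCompound(
            compound_id=str(row.compound_id),
            count_norm_target=float(row.count_norm_target),
            count_norm_beads=float(row.count_norm_beads),
            count_norm_tag=float(row.count_norm_tag),
            ef_norm_target=float(row.ef_norm_target),
            ef_norm_beads=float(row.ef_norm_beads),
            ef_norm_tag=float(row.ef_norm_tag),
            count_diff=float(row.count_diff),
            ef_diff=float(row.ef_diff),
            score=float(row.score),
        )
        for row in df.itertuples()
    ]
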