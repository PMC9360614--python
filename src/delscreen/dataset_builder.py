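"""Imbalance-corrected training sets and the five-way data split.

A DEL screen with a single true binder is an extreme-imbalance regression
problem: nearly every score is ~0.  The training set is therefore built from

* **undersampling** — sort all compounds by score ascending and keep every
  N-th one, which thins the zero-score bulk while always retaining the
  neighbourhood of the extremes;
* **oversampling** — repeat each of the top-k highest-scored compounds a fixed
  number of times;
* optional **positive-sample generation** — replace exact repeats with
  bit-perturbed fingerprint copies (set random zero bits, or flip random
  bits) whose scores get uniform jitter.  Generated fingerprints are flagged
  synthetic: they correspond to no molecule and are excluded from attribution.

Evaluation data are held out as: valid1/test1 (random DEL compounds disjoint
from the training ids) and valid2/test2 (the derivative panel, ranked by
activity with odd ranks -> valid2 and even ranks -> test2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem_enum import Fingerprint, FingerprintConfig, InputError, fingerprint_matrix
from .del_scoring import ScoredCompound, ic50_to_score
from .synthetic_del import DerivativePanel


@dataclass(frozen=True)
class SamplingConfig:
    """Knobs of the imbalance correction.

    ``modify_type`` 1 sets randomly chosen zero bits to one; type 2 flips
    randomly chosen bits.  ``modify_bit`` is how many bits each generated
    sample perturbs.  ``augment`` turns generation on, replacing all but one
    of each oversampled compound's repeats with generated variants.
    """

    undersample_interval_n: int = 8
    oversample_multiple: int = 800
    oversample_top_k: int = 100
    modify_bit: int = 2
    modify_type: int = 1
    jitter_halfwidth: float = 0.1
    augment: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.undersample_interval_n, self.oversample_multiple,
               self.oversample_top_k) < 1:
            raise InputError("interval, multiple and top_k must be positive")
        if not 1 <= self.modify_bit <= 4:
            raise InputError("modify_bit must be in [1, 4]")
        if self.modify_type not in (1, 2):
            raise InputError("modify_type must be 1 or 2")
        if self.jitter_halfwidth < 0:
            raise InputError("jitter_halfwidth must be >= 0")


@dataclass
class SplitBundle:
    """Train / valid1 / test1 (DEL) and valid2 / test2 (derivatives) arrays."""

    X_train: np.ndarray
    y_train: np.ndarray
    train_row_ids: list[str]
    train_synthetic: np.ndarray
    X_valid1: np.ndarray
    y_valid1: np.ndarray
    valid1_ids: list[str]
    X_test1: np.ndarray
    y_test1: np.ndarray
    test1_ids: list[str]
    X_valid2: np.ndarray
    y_valid2: np.ndarray
    valid2_ids: list[str]
    valid2_ic50: np.ndarray
    X_test2: np.ndarray
    y_test2: np.ndarray
    test2_ids: list[str]
    test2_ic50: np.ndarray
    config: SamplingConfig | None = None

    @property
    def train_ids(self) -> set[str]:
        return set(self.train_row_ids)

    def manifest(self) -> pd.DataFrame:
        rows = []
        for split, ids, scores in (
            ("train", self.train_row_ids, self.y_train),
            ("valid1", self.valid1_ids, self.y_valid1),
            ("test1", self.test1_ids, self.y_test1),
            ("valid2", self.valid2_ids, self.y_valid2),
            ("test2", self.test2_ids, self.y_test2),
        ):
            rows.extend(
                {"id": i, "split": split, "score": float(s)}
                for i, s in zip(ids, scores)
            )
        return pd.DataFrame(rows)


def _sort_ascending(scored: Sequence[ScoredCompound]) -> list[ScoredCompound]:
    # ties broken by compound_id for a stable, reproducible order
    return sorted(scored, key=lambda s: (s.score, s.compound_id))


def undersample_indices(scores: np.ndarray, ids: Sequence[str], n: int) -> np.ndarray:
    """Indices kept by interval-N undersampling of a score array (ascending)."""
    if n < 1:
        raise InputError("interval N must be >= 1")
    scores = np.asarray(scores, dtype=float)
    order = np.lexsort((np.asarray(ids), scores))
    return order[::n]


def undersample(scored: Sequence[ScoredCompound], n: int) -> list[ScoredCompound]:
    """Every N-th compound of the score-ascending order; size = ceil(len/N)."""
    if not scored:
        raise InputError("cannot undersample an empty score list")
    if n < 1:
        raise InputError("interval N must be >= 1")
    return _sort_ascending(scored)[::n]


def oversample(
    scored: Sequence[ScoredCompound], top_k: int = 100, multiple: int = 1
) -> list[ScoredCompound]:
    """The top-k highest-scored compounds, each repeated ``multiple`` times."""
    if len(scored) < top_k:
        raise InputError(f"need at least top_k={top_k} compounds, got {len(scored)}")
    if multiple < 1 or top_k < 1:
        raise InputError("top_k and multiple must be positive")
    top = sorted(scored, key=lambda s: (-s.score, s.compound_id))[:top_k]
    return [s for s in top for _ in range(multiple)]


def generate_positives(
    fp: Fingerprint | np.ndarray,
    score: float,
    config: SamplingConfig,
    count: int,
    rng: np.random.Generator | None = None,
) -> list[tuple[np.ndarray, float]]:
    """Bit-perturbed copies of a positive sample with jittered scores.

    Returned fingerprints are plain bit vectors (no atom-environment map):
    they do not correspond to a real molecule.
    """
    bits = fp.bits if isinstance(fp, Fingerprint) else np.asarray(fp, dtype=np.uint8)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    zeros = np.flatnonzero(bits == 0)
    if config.modify_type == 1 and zeros.size < config.modify_bit:
        raise InputError(
            f"type-1 generation needs >= {config.modify_bit} zero bits, "
            f"found {zeros.size}"
        )
    if config.modify_type == 2 and bits.size < config.modify_bit:
        raise InputError("fingerprint shorter than modify_bit")
    out: list[tuple[np.ndarray, float]] = []
    for _ in range(count):
        new = bits.copy()
        if config.modify_type == 1:
            chosen = rng.choice(zeros, size=config.modify_bit, replace=False)
            new[chosen] = 1
        else:
            chosen = rng.choice(bits.size, size=config.modify_bit, replace=False)
            new[chosen] ^= 1
        jitter = rng.uniform(-config.jitter_halfwidth, config.jitter_halfwidth)
        out.append((new, float(score + jitter)))
    return out


def rank_derivatives(panel: DerivativePanel):
    """Panel records ordered most-active first (censored last, ties by id)."""
    return sorted(
        panel.records, key=lambda r: (r.censored, r.ic50_uM, r.derivative_id)
    )


def build_splits(
    scored: Sequence[ScoredCompound],
    derivatives: DerivativePanel,
    config: SamplingConfig,
    fingerprints: Mapping[str, np.ndarray],
    valid1_size: int = 100_000,
    test1_size: int = 100_000,
    derivative_fingerprints: Mapping[str, np.ndarray] | None = None,
    fp_config: FingerprintConfig = FingerprintConfig(),
) -> SplitBundle:
    """Assemble the five-way split; fully reproducible from ``config.seed``.

    ``fingerprints`` maps every DEL compound_id to its bit vector.  Derivative
    fingerprints are computed from the panel SMILES with ``fp_config`` unless
    supplied.  Train, valid1 and test1 are pairwise disjoint by compound_id
    (oversampled repeats count as one id).
    """
    rng = np.random.default_rng(config.seed)
    under = undersample(scored, config.undersample_interval_n)
    top = oversample(scored, config.oversample_top_k, 1)

    rows: list[np.ndarray] = []
    ys: list[float] = []
    row_ids: list[str] = []
    synthetic: list[bool] = []

    def _add(cid: str, y: float, fp: np.ndarray | None = None, syn: bool = False):
        rows.append(fingerprints[cid] if fp is None else fp)
        ys.append(y)
        row_ids.append(cid)
        synthetic.append(syn)

    for s in under:
        _add(s.compound_id, s.score)
    for s in top:
        _add(s.compound_id, s.score)
        extra = config.oversample_multiple - 1
        if extra <= 0:
            continue
        if config.augment:
            for bits, y in generate_positives(
                fingerprints[s.compound_id], s.score, config, extra, rng
            ):
                _add(s.compound_id, y, fp=bits, syn=True)
        else:
            for _ in range(extra):
                _add(s.compound_id, s.score)

    train_ids = set(row_ids)
    pool = [s for s in scored if s.compound_id not in train_ids]
    if len(pool) < valid1_size + test1_size:
        raise InputError(
            f"library too small: {len(pool)} compounds left after training "
            f"exclusion, need {valid1_size + test1_size} (reduce split sizes)"
        )
    perm = rng.permutation(len(pool))
    valid1 = [pool[i] for i in perm[:valid1_size]]
    test1 = [pool[i] for i in perm[valid1_size:valid1_size + test1_size]]

    ranked = rank_derivatives(derivatives)
    valid2_recs = ranked[0::2]  # 1-based odd ranks
    test2_recs = ranked[1::2]
    if derivative_fingerprints is None:
        mat = fingerprint_matrix([r.smiles for r in ranked], fp_config)
        derivative_fingerprints = {
            r.derivative_id: mat[i] for i, r in enumerate(ranked)
        }

    def _stack(items, fps):
        return np.asarray([fps[i] for i in items], dtype=np.float32)

    return SplitBundle(
        X_train=np.asarray(rows, dtype=np.float32),
        y_train=np.asarray(ys, dtype=np.float64),
        train_row_ids=row_ids,
        train_synthetic=np.asarray(synthetic, dtype=bool),
        X_valid1=_stack([s.compound_id for s in valid1], fingerprints),
        y_valid1=np.asarray([s.score for s in valid1]),
        valid1_ids=[s.compound_id for s in valid1],
        X_test1=_stack([s.compound_id for s in test1], fingerprints),
        y_test1=np.asarray([s.score for s in test1]),
        test1_ids=[s.compound_id for s in test1],
        X_valid2=_stack([r.derivative_id for r in valid2_recs], derivative_fingerprints),
        y_valid2=np.asarray([ic50_to_score(r.ic50_uM) for r in valid2_recs]),
        valid2_ids=[r.derivative_id for r in valid2_recs],
        valid2_ic50=np.asarray([r.ic50_uM for r in valid2_recs]),
        X_test2=_stack([r.derivative_id for r in test2_recs], derivative_fingerprints),
        y_test2=np.asarray([ic50_to_score(r.ic50_uM) for r in test2_recs]),
        test2_ids=[r.derivative_id for r in test2_recs],
        test2_ic50=np.asarray([r.ic50_uM for r in test2_recs]),
        config=config,
    )
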