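"""Evaluation metrics and bit-masking structure-activity attribution.

The screening models are judged by regression error (MSE) on the DEL-derived
splits and, on the derivative panel, by the *hit rate*: among derivatives the
model scores above a threshold, the fraction that are experimentally active
(IC50 below 50 µM).  An empty high-score set leaves the rate undefined
(``None``), never zero — a conservative model is not thereby penalized.

Attribution follows the fingerprint bit-masking recipe: the weight of each set
bit is the drop in predicted score when that one bit is cleared.  Bit weights
are normalized by the largest absolute weight, distributed to the center atom
of each environment that fired the bit, and rendered as atom-centered Gaussian
blobs on the 2-D depiction (positive = favourable, drawn in green).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Protocol, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Draw
from rdkit.Chem.Draw import SimilarityMaps

from .chem_enum import Fingerprint, InputError


class RegressionModel(Protocol):
    def predict(self, X: np.ndarray) -> np.ndarray: ...


def mse(pred: Sequence[float], truth: Sequence[float]) -> float:
    """Mean squared error."""
    p = np.asarray(pred, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape or p.size == 0:
        raise InputError("pred and truth must be equal-length and non-empty")
    return float(np.mean((p - t) ** 2))


@dataclass(frozen=True)
class HitRateResult:
    threshold: float
    n_high: int
    n_active_high: int

    @property
    def ratio(self) -> float | None:
        if self.n_high == 0:
            return None
        return self.n_active_high / self.n_high


def hit_rate(
    scores: Sequence[float],
    ic50s: Sequence[float],
    threshold: float,
    active_cutoff_uM: float = 50.0,
) -> HitRateResult:
    """Fraction of predicted-high derivatives that are actually active."""
    s = np.asarray(scores, dtype=float)
    ic = np.asarray(ic50s, dtype=float)
    if s.shape != ic.shape or s.size == 0:
        raise InputError("scores and ic50s must be equal-length and non-empty")
    high = s > threshold
    return HitRateResult(
        threshold=threshold,
        n_high=int(high.sum()),
        n_active_high=int((high & (ic < active_cutoff_uM)).sum()),
    )


def bit_weights(model: RegressionModel, fp: Fingerprint | np.ndarray) -> dict[int, float]:
    """weight(bit) = predict(fp) - predict(fp with that set bit cleared).

    Unset bits get weight 0 implicitly (they are absent from the map).  Each
    mask is independent, so the result does not depend on probing order.
    """
    bits = fp.bits if isinstance(fp, Fingerprint) else np.asarray(fp, dtype=np.uint8)
    on = np.flatnonzero(bits)
    base = bits.astype(np.float32)[None, :]
    if on.size == 0:
        return {}
    masked = np.repeat(base, on.size, axis=0)
    masked[np.arange(on.size), on] = 0.0
    preds = np.asarray(model.predict(np.vstack([base, masked])), dtype=float)
    return {int(b): float(preds[0] - preds[1 + i]) for i, b in enumerate(on)}


@dataclass
class AtomWeightMap:
    """Per-atom attribution weights of one molecule, normalized to |w| <= 1."""

    smiles: str
    atom_weights: np.ndarray
    bit_weights: dict[int, float]

    def to_dict(self) -> dict:
        return {
            "smiles": self.smiles,
            "atom_weights": [float(w) for w in self.atom_weights],
            "bit_weights": {str(k): float(v) for k, v in self.bit_weights.items()},
        }


def atom_weights(bits_w: Mapping[int, float], fp: Fingerprint) -> AtomWeightMap:
    """Project normalized bit weights onto environment center atoms.

    Bit weights are first divided by the largest absolute weight (all-zero
    weights stay zero).  Every environment that fired a bit adds the bit's
    normalized weight to its center atom; if the summed per-atom magnitudes
    exceed 1 the map is rescaled so the largest stays at 1.
    """
    if fp.bit_atoms is None or fp.smiles is None:
        raise InputError(
            "fingerprint carries no atom-environment map (synthetic fingerprint?)"
        )
    mol = Chem.MolFromSmiles(fp.smiles)
    n_atoms = mol.GetNumAtoms()
    weights = np.zeros(n_atoms, dtype=float)
    max_abs = max((abs(w) for w in bits_w.values()), default=0.0)
    if max_abs > 0:
        for bit, w in bits_w.items():
            norm = w / max_abs
            for center, _radius in fp.bit_atoms.get(bit, ()):
                if not 0 <= center < n_atoms:
                    raise InputError(f"bit {bit}: invalid center atom {center}")
                weights[center] += norm
        peak = np.abs(weights).max()
        if peak > 1:
            weights /= peak
    return AtomWeightMap(smiles=fp.smiles, atom_weights=weights,
                         bit_weights=dict(bits_w))


def render_map(
    awmap: AtomWeightMap,
    path: str,
    sigma: float = 0.3,
    size: int = 400,
) -> str:
    """Draw the atom-centered Gaussian attribution map to a PNG file."""
    mol = Chem.MolFromSmiles(awmap.smiles)
    if mol is None:
        raise InputError(f"unparseable SMILES: {awmap.smiles!r}")
    drawer = Draw.MolDraw2DCairo(size, size)
    weights = [float(w) for w in awmap.atom_weights]
    if any(w != 0.0 for w in weights):
        SimilarityMaps.GetSimilarityMapFromWeights(
            mol, weights, draw2d=drawer, sigma=sigma
        )
    else:
        drawer.DrawMolecule(mol)  # nothing to colour
    drawer.FinishDrawing()
    with open(path, "wb") as fh:
        fh.write(drawer.GetDrawingText())
    return path
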