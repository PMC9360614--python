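import numpy as np
import pytest

from delscreen.chem_enum import Fingerprint, FingerprintConfig, InputError, compute_fingerprint
from delscreen.eval_sar import (
    atom_weights,
    bit_weights,
    hit_rate,
    mse,
    render_map,
)


class LinearModel:
    """Oracle model: additive in bits with known coefficients."""

    kind = "linear"

    def __init__(self, coef, intercept=0.0):
        self.coef = np.asarray(coef, dtype=float)
        self.intercept = intercept

    def predict(self, X):
        return np.asarray(X, dtype=float) @ self.coef + self.intercept


class TestMse:
    def test_identical_vectors(self):
        assert mse([1, 2, 3], [1, 2, 3]) == 0.0

    def test_constant_offset(self):
        truth = np.arange(5, dtype=float)
        assert mse(truth + 0.3, truth) == pytest.approx(0.09, abs=1e-12)

    def test_matches_brute_force_sum(self, rng):
        p, t = rng.random(100), rng.random(100)
        brute = sum((a - b) ** 2 for a, b in zip(p, t)) / 100
        assert mse(p, t) == pytest.approx(brute, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            mse([1.0], [1.0, 2.0])


class TestHitRate:
    def test_seven_of_nine_high_scored_active(self):
        # 9 derivatives above threshold, 7 of them active
        scores = [0.9] * 9 + [0.1] * 5
        ic50s = [5.0] * 7 + [60.0, 60.0] + [60.0] * 5
        res = hit_rate(scores, ic50s, threshold=0.5)
        assert res.n_high == 9 and res.n_active_high == 7
        assert res.ratio == pytest.approx(7 / 9)  # the 78% regime

    def test_none_above_threshold_is_undefined(self):
        res = hit_rate([0.1, 0.2], [5.0, 5.0], threshold=0.5)
        assert res.n_high == 0 and res.ratio is None

    def test_all_high_and_active(self):
        assert hit_rate([0.9, 0.8], [1.0, 2.0], 0.5).ratio == 1.0

    def test_permutation_invariance(self, rng):
        scores = rng.random(30)
        ic50s = rng.uniform(1, 100, 30)
        perm = rng.permutation(30)
        a = hit_rate(scores, ic50s, 0.5)
        b = hit_rate(scores[perm], ic50s[perm], 0.5)
        assert (a.n_high, a.n_active_high) == (b.n_high, b.n_active_high)


def _toy_fp(n_bits=16, on=(1, 4, 9), bit_atoms=None, smiles="CCO"):
    bits = np.zeros(n_bits, dtype=np.uint8)
    bits[list(on)] = 1
    return Fingerprint(bits=bits, bit_atoms=bit_atoms, smiles=smiles)


class TestBitWeights:
    def test_linear_model_recovers_coefficients(self, rng):
        coef = rng.normal(size=32)
        model = LinearModel(coef, intercept=0.3)
        fp = _toy_fp(32, on=(0, 5, 17, 30))
        weights = bit_weights(model, fp)
        assert set(weights) == {0, 5, 17, 30}
        for bit, w in weights.items():
            assert w == pytest.approx(coef[bit], abs=1e-6)

    def test_constant_model_all_zero(self):
        model = LinearModel(np.zeros(16), intercept=1.0)
        assert all(w == 0 for w in bit_weights(model, _toy_fp()).values())

    def test_mask_order_independence(self, rng):
        model = LinearModel(rng.normal(size=16))
        fp = _toy_fp()
        assert bit_weights(model, fp) == bit_weights(model, fp)


class TestAtomWeights:
    def test_single_bit_normalizes_to_one(self):
        fp = _toy_fp(on=(4,), bit_atoms={4: [(2, 1)]}, smiles="CCO")
        awmap = atom_weights({4: 0.25}, fp)
        assert awmap.atom_weights.tolist() == [0.0, 0.0, 1.0]

    def test_two_bits_relative_normalization(self):
        fp = _toy_fp(on=(1, 4), bit_atoms={1: [(0, 0)], 4: [(2, 1)]}, smiles="CCO")
        awmap = atom_weights({1: 2.0, 4: 1.0}, fp)
        assert awmap.atom_weights.tolist() == [1.0, 0.0, 0.5]

    def test_all_zero_weights_give_zero_map(self):
        fp = _toy_fp(on=(1,), bit_atoms={1: [(0, 0)]}, smiles="CCO")
        awmap = atom_weights({1: 0.0}, fp)
        assert np.all(awmap.atom_weights == 0)

    def test_magnitudes_capped_at_one(self):
        # two equal-weight bits sharing a center atom
        fp = _toy_fp(on=(1, 4), bit_atoms={1: [(0, 0)], 4: [(0, 1)]}, smiles="CCO")
        awmap = atom_weights({1: 1.0, 4: 1.0}, fp)
        assert np.abs(awmap.atom_weights).max() == pytest.approx(1.0)

    def test_real_molecule_against_hand_assembled_map(self, rng):
        """Linear-model attribution equals manual bit->center bookkeeping."""
        fp = compute_fingerprint("CC(=O)NCC", FingerprintConfig(128, 1))
        coef = rng.normal(size=128)
        model = LinearModel(coef)
        weights = bit_weights(model, fp)
        awmap = atom_weights(weights, fp)
        # independent assembly from the environment map
        max_abs = max(abs(w) for w in weights.values())
        expected = np.zeros_like(awmap.atom_weights)
        for bit, envs in fp.bit_atoms.items():
            for center, _r in envs:
                expected[center] += weights[bit] / max_abs
        if np.abs(expected).max() > 1:
            expected /= np.abs(expected).max()
        assert np.allclose(awmap.atom_weights, expected, atol=1e-9)

    def test_synthetic_fingerprint_rejected(self):
        fp = Fingerprint(bits=np.ones(8, dtype=np.uint8))  # no atom map
        with pytest.raises(InputError):
            atom_weights({0: 1.0}, fp)


class TestRenderMap:
    def test_renders_png(self, tmp_path, rng):
        fp = compute_fingerprint("CC(=O)NCc1ccccc1", FingerprintConfig(256, 2))
        model = LinearModel(rng.normal(size=256))
        awmap = atom_weights(bit_weights(model, fp), fp)
        out = render_map(awmap, str(tmp_path / "map.png"))
        data = (tmp_path / "map.png").read_bytes()
        assert data[:8] == b"\x89PNG\r\n\x1a\n" and len(data) > 500

    def test_all_zero_map_renders_plain_molecule(self, tmp_path):
        fp = compute_fingerprint("CCO", FingerprintConfig(64, 1))
        awmap = atom_weights({b: 0.0 for b in fp.on_bits()}, fp)
        render_map(awmap, str(tmp_path / "zero.png"))
        assert (tmp_path / "zero.png").stat().st_size > 0

    def test_rendering_is_byte_stable(self, tmp_path):
        fp = compute_fingerprint("CCO", FingerprintConfig(64, 1))
        awmap = atom_weights({int(fp.on_bits()[0]): 1.0}, fp)
        render_map(awmap, str(tmp_path / "a.png"))
        render_map(awmap, str(tmp_path / "b.png"))
        assert (tmp_path / "a.png").read_bytes() == (tmp_path / "b.png").read_bytes()
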