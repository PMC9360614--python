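import math

import numpy as np
import pytest

from delscreen.chem_enum import FingerprintConfig, InputError
from delscreen.dataset_builder import (
    SamplingConfig,
    build_splits,
    generate_positives,
    oversample,
    rank_derivatives,
    undersample,
    undersample_indices,
)
from delscreen.del_scoring import ScoredCompound, ic50_to_score
from delscreen.synthetic_del import DerivativePanel, DerivativeRecord


def _scored(cid, score):
    return ScoredCompound(cid, 0, 0, 0, 0, 0, 0, 0, 0, score)


def _scored_list(scores):
    return [_scored(f"c{i:04d}", s) for i, s in enumerate(scores)]


class TestUndersample:
    def test_interval_two_keeps_even_sorted_positions(self):
        scored = _scored_list([0.9, 0.1, 0.5, 0.3, 0.7, 0.0, 0.2, 0.4, 0.6, 0.8])
        kept = undersample(scored, 2)
        ranks = sorted(range(10), key=lambda i: scored[i].score)
        expected = {scored[i].compound_id for i in ranks[::2]}
        assert {s.compound_id for s in kept} == expected

    def test_interval_one_is_identity_up_to_order(self):
        scored = _scored_list([0.3, 0.1, 0.2])
        assert {s.compound_id for s in undersample(scored, 1)} == {
            s.compound_id for s in scored
        }

    def test_ceil_size_at_screen_scale(self, rng):
        scores = rng.random(1_104_808)
        ids = np.arange(scores.size).astype("U8")
        kept = undersample_indices(scores, ids, 8)
        assert kept.size == 138_101  # ceil(1,104,808 / 8)

    def test_retains_the_score_extremes_neighbourhood(self, rng):
        scores = rng.random(1000)
        scored = _scored_list(scores)
        n = 7
        kept_max = max(s.score for s in undersample(scored, n))
        rank_of_kept = sorted(scores).index(kept_max)
        assert rank_of_kept >= scores.size - n

    def test_ties_broken_stably_by_id(self):
        scored = _scored_list([0.0] * 6)
        kept = undersample(scored, 3)
        assert [s.compound_id for s in kept] == ["c0000", "c0003"]


class TestOversample:
    @pytest.mark.parametrize("top_k,multiple", [(100, 800), (100, 400), (5, 1)])
    def test_output_size(self, top_k, multiple, rng):
        scored = _scored_list(rng.random(200))
        out = oversample(scored, top_k, multiple)
        assert len(out) == top_k * multiple
        top_ids = {
            s.compound_id
            for s in sorted(scored, key=lambda s: -s.score)[:top_k]
        }
        assert {s.compound_id for s in out} == top_ids

    def test_requires_enough_compounds(self):
        with pytest.raises(InputError):
            oversample(_scored_list([0.1, 0.2]), top_k=5, multiple=2)


class TestGeneratePositives:
    def test_type2_single_flip_hamming_distance(self, rng):
        bits = (rng.random(512) < 0.1).astype(np.uint8)
        cfg = SamplingConfig(modify_bit=1, modify_type=2)
        for new, _ in generate_positives(bits, 0.9, cfg, 20, rng):
            assert int(np.sum(new != bits)) == 1

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_type1_adds_exactly_k_bits(self, k, rng):
        bits = (rng.random(512) < 0.1).astype(np.uint8)
        cfg = SamplingConfig(modify_bit=k, modify_type=1)
        for new, _ in generate_positives(bits, 0.9, cfg, 10, rng):
            assert new.sum() == bits.sum() + k
            assert np.all(new[bits == 1] == 1)  # original bits untouched

    def test_jitter_follows_uniform_law(self, rng):
        bits = np.zeros(64, dtype=np.uint8)
        cfg = SamplingConfig(modify_bit=1, modify_type=1, jitter_halfwidth=0.1)
        scores = np.array(
            [y for _, y in generate_positives(bits, 0.5, cfg, 10_000, rng)]
        )
        assert np.all(np.abs(scores - 0.5) <= 0.1 + 1e-12)
        assert abs(scores.mean() - 0.5) < 0.005

    def test_insufficient_zero_bits_rejected(self, rng):
        bits = np.ones(4, dtype=np.uint8)
        cfg = SamplingConfig(modify_bit=2, modify_type=1)
        with pytest.raises(InputError):
            generate_positives(bits, 0.5, cfg, 1, rng)

    def test_config_validation(self):
        with pytest.raises(InputError):
            SamplingConfig(modify_bit=5)
        with pytest.raises(InputError):
            SamplingConfig(modify_type=3)


def _panel(n=10, n_active=4):
    recs = []
    for i in range(n):
        active = i < n_active
        recs.append(
            DerivativeRecord(
                f"a{i + 1}",
                "CC(=O)NC(C)C(=O)NCc1ccccc1",
                ic50_uM=5.0 + 3 * i if active else 51.0,
                censored=not active,
            )
        )
    return DerivativePanel(records=recs)


@pytest.fixture
def small_world(rng):
    n = 400
    fps = {f"c{i:04d}": (rng.random(64) < 0.2).astype(np.uint8) for i in range(n)}
    scored = _scored_list(rng.random(n))
    return scored, fps


class TestBuildSplits:
    CFG = dict(valid1_size=50, test1_size=50, fp_config=FingerprintConfig(64, 2))

    def _config(self, **kw):
        base = dict(
            undersample_interval_n=4, oversample_multiple=5,
            oversample_top_k=10, seed=11,
        )
        base.update(kw)
        return SamplingConfig(**base)

    def test_disjoint_splits_and_sizes(self, small_world):
        scored, fps = small_world
        bundle = build_splits(scored, _panel(), self._config(), fps, **self.CFG)
        train = bundle.train_ids
        assert len(bundle.valid1_ids) == 50 and len(bundle.test1_ids) == 50
        assert train.isdisjoint(bundle.valid1_ids)
        assert train.isdisjoint(bundle.test1_ids)
        assert set(bundle.valid1_ids).isdisjoint(bundle.test1_ids)

    def test_odd_even_derivative_split(self, small_world):
        scored, fps = small_world
        bundle = build_splits(scored, _panel(), self._config(), fps, **self.CFG)
        assert len(bundle.valid2_ids) == 5 and len(bundle.test2_ids) == 5
        ranked = rank_derivatives(_panel())
        assert bundle.valid2_ids[0] == ranked[0].derivative_id  # most active
        assert bundle.y_valid2[0] == ic50_to_score(ranked[0].ic50_uM)

    def test_same_seed_identical_bundles(self, small_world):
        scored, fps = small_world
        a = build_splits(scored, _panel(), self._config(), fps, **self.CFG)
        b = build_splits(scored, _panel(), self._config(), fps, **self.CFG)
        assert np.array_equal(a.X_train, b.X_train)
        assert np.array_equal(a.y_train, b.y_train)
        assert a.valid1_ids == b.valid1_ids
        assert a.test1_ids == b.test1_ids

    def test_train_size_formula(self, small_world):
        scored, fps = small_world
        cfg = self._config()
        bundle = build_splits(scored, _panel(), cfg, fps, **self.CFG)
        expected = math.ceil(400 / 4) + 10 * 5
        assert len(bundle.y_train) == expected
        assert not bundle.train_synthetic.any()

    def test_augmented_positives_flagged_synthetic(self, small_world):
        scored, fps = small_world
        cfg = self._config(augment=True, modify_type=1, modify_bit=2)
        bundle = build_splits(scored, _panel(), cfg, fps, **self.CFG)
        assert bundle.train_synthetic.sum() == 10 * (5 - 1)

    def test_library_too_small_rejected(self, small_world):
        scored, fps = small_world
        with pytest.raises(InputError, match="too small"):
            build_splits(
                scored, _panel(), self._config(), fps,
                valid1_size=300, test1_size=300,
                fp_config=FingerprintConfig(64, 2),
            )
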