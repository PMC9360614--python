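import numpy as np
import pytest

from delscreen.chem_enum import FingerprintConfig, InputError
from delscreen.dataset_builder import SamplingConfig
from delscreen.del_scoring import compute_scores
from delscreen.modeling import (
    EvalReport,
    GBMConfig,
    MLPConfig,
    ModelSelectionError,
    grid_search,
    select_model,
    train_model,
)
from delscreen.synthetic_del import (
    AffinityLandscape,
    generate_derivative_panel,
    simulate_selection,
)

TOY_MLP = MLPConfig(input_dim=64, hidden_units=32, dropout_rate=0.0,
                    epochs=80, learning_rate=0.01, batch_size=32, seed=1)
TOY_GBM = GBMConfig(min_data_in_leaf=2, lambda_l1=0.0, lambda_l2=0.0,
                    learning_rate=0.2, num_boost_round=200, seed=1)


@pytest.fixture(scope="module")
def toy_data():
    rng = np.random.default_rng(0)
    X = (rng.random((200, 64)) < 0.3).astype(np.float64)
    y = X[:, 0].copy()  # one bit carries the whole signal
    return X, y


class TestTraining:
    @pytest.mark.parametrize("kind,config", [("mlp", TOY_MLP), ("gbm", TOY_GBM)])
    def test_overfits_linearly_separable_toy(self, kind, config, toy_data):
        X, y = toy_data
        model = train_model(kind, config, X, y)
        assert np.mean((model.predict(X) - y) ** 2) < 0.01

    @pytest.mark.parametrize("kind,config", [("mlp", TOY_MLP), ("gbm", TOY_GBM)])
    def test_same_seed_identical_predictions(self, kind, config, toy_data):
        X, y = toy_data
        a = train_model(kind, config, X, y).predict(X)
        b = train_model(kind, config, X, y).predict(X)
        assert np.max(np.abs(a - b)) < 1e-6

    def test_constant_target_degenerate_fit(self, toy_data):
        X, _ = toy_data
        y = np.full(len(X), 0.5)
        gbm = train_model("gbm", TOY_GBM, X, y)
        assert np.ptp(gbm.predict(X)) < 1e-3
        assert np.mean((gbm.predict(X) - 0.5) ** 2) < 1e-6
        mlp = train_model("mlp", TOY_MLP, X, y)
        assert np.mean((mlp.predict(X) - 0.5) ** 2) < 1e-4

    def test_training_does_not_mutate_inputs(self, toy_data):
        X, y = toy_data
        X0, y0 = X.copy(), y.copy()
        train_model("gbm", TOY_GBM, X, y)
        train_model("mlp", TOY_MLP, X, y)
        assert np.array_equal(X, X0) and np.array_equal(y, y0)

    def test_mlp_outputs_are_non_negative(self, toy_data):
        X, y = toy_data
        model = train_model("mlp", TOY_MLP, X, y - 0.8)  # mostly negative targets
        assert np.all(model.predict(X) >= 0)

    def test_batch_equals_single_item_prediction(self, toy_data):
        X, y = toy_data
        model = train_model("gbm", TOY_GBM, X, y)
        batch = model.predict(X[:5])
        singles = [model.predict(X[i]) [0] for i in range(5)]
        assert np.allclose(batch, singles)

    def test_monotone_response_to_signal_bit(self, toy_data):
        X, y = toy_data
        model = train_model("gbm", TOY_GBM, X, y)
        probe = X[:20].copy()
        probe[:, 0] = 0
        off = model.predict(probe)
        probe[:, 0] = 1
        on = model.predict(probe)
        assert np.all(on >= off)

    def test_dimension_mismatch_rejected(self, toy_data):
        X, y = toy_data
        model = train_model("mlp", TOY_MLP, X, y)
        with pytest.raises(InputError):
            model.predict(np.zeros((3, 32)))
        with pytest.raises(InputError):
            train_model("gbm", TOY_GBM, np.zeros((0, 4)), np.zeros(0))

    def test_invalid_configs_rejected(self):
        with pytest.raises(InputError):
            MLPConfig(dropout_rate=1.0)
        with pytest.raises(InputError):
            GBMConfig(feature_fraction=0.0)


def _report(ratio, v1, v2):
    return EvalReport(
        hyperparameters={}, train_mse=0.0, valid1_mse=v1, valid2_mse=v2,
        test1_mse=0.0, test2_mse=0.0, valid2_ratio=ratio, test2_ratio=None,
    )


class TestSelectModel:
    def test_budget_excludes_higher_ratio(self):
        winner = select_model([_report(0.67, 0.04, 0.10), _report(0.70, 0.05, 0.15)])
        assert winner.valid2_ratio == 0.67

    def test_single_qualifying_report(self):
        rep = _report(0.5, 0.01, 0.05)
        assert select_model([rep]) is rep

    def test_empty_feasible_set_raises_with_advisory(self):
        reports = [_report(0.4, 0.10, 0.10), _report(0.6, 0.20, 0.10)]
        with pytest.raises(ModelSelectionError) as exc:
            select_model(reports)
        assert exc.value.best_advisory.valid2_ratio == 0.6

    def test_tie_broken_by_smaller_mse_sum(self):
        winner = select_model([_report(0.5, 0.05, 0.05), _report(0.5, 0.01, 0.05)])
        assert winner.valid_mse_sum == pytest.approx(0.06)

    def test_undefined_ratio_never_wins(self):
        reports = [_report(None, 0.01, 0.01), _report(0.2, 0.01, 0.01)]
        assert select_model(reports).valid2_ratio == 0.2


@pytest.fixture(scope="module")
def tiny_screen():
    """A 100-compound screen with scores, SMILES and a derivative panel."""
    from delscreen.chem_enum import default_templates, enumerate_trisynthons
    from delscreen.synthetic_del import generate_building_blocks

    blocks = generate_building_blocks((5, 5, 4))
    library = enumerate_trisynthons(blocks, default_templates()).products
    landscape = AffinityLandscape(
        binder_ids=frozenset({"A01.B01.C01"}), sticky_fraction=0.0
    )
    records = simulate_selection(library, landscape, 20_000, seed=5)
    scored = compute_scores(records)
    smiles = {t.compound_id: t.product_smiles for t in library}
    hit = smiles["A01.B01.C01"]
    panel = generate_derivative_panel(hit, n=10, seed=5, active_fraction=0.4)
    return scored, smiles, panel


GRID_KW = dict(
    base_sampling=SamplingConfig(oversample_top_k=10, seed=2),
    valid1_size=15, test1_size=15,
)
FAST_GBM = GBMConfig(num_boost_round=30, min_data_in_leaf=5, seed=2)


class TestGridSearch:
    def test_one_report_per_grid_point(self, tiny_screen):
        scored, smiles, panel = tiny_screen
        reports = grid_search(
            scored, panel, smiles,
            n_values=[2, 3], multiple_values=[2, 3],
            fp_configs=[FingerprintConfig(256, 2)],
            model_kind="gbm", model_config=FAST_GBM, **GRID_KW,
        )
        assert len(reports) == 4
        stamps = {
            (r.hyperparameters["undersample_interval_n"],
             r.hyperparameters["oversample_multiple"])
            for r in reports
        }
        assert stamps == {(2, 2), (2, 3), (3, 2), (3, 3)}

    def test_single_point_grid_equals_direct_run(self, tiny_screen):
        scored, smiles, panel = tiny_screen
        a = grid_search(
            scored, panel, smiles, [2], [3],
            [FingerprintConfig(256, 2)], "gbm", FAST_GBM, **GRID_KW,
        )[0]
        b = grid_search(
            scored, panel, smiles, [2], [3],
            [FingerprintConfig(256, 2)], "gbm", FAST_GBM, **GRID_KW,
        )[0]
        assert a.to_dict() == b.to_dict()

    def test_empty_grid_rejected(self, tiny_screen):
        scored, smiles, panel = tiny_screen
        with pytest.raises(InputError):
            grid_search(scored, panel, smiles, [], [2],
                        [FingerprintConfig(256, 2)], "gbm", FAST_GBM, **GRID_KW)
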