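"""Fingerprint-to-score regression: a small MLP and gradient-boosted trees.

Two model families are trained on (fingerprint, score) pairs:

* a multilayer perceptron — one hidden layer of 256 rectified units with
  heavy dropout (drop probability 0.8, counteracting the near-duplicate
  oversampled positives), a softplus output that keeps predictions
  non-negative, and Adam at learning rate 0.005.  Implemented directly on
  numpy so training is exactly reproducible from the seed;
* a LightGBM regressor with bagging 0.8, feature fraction 0.76, L1/L2
  penalties of 10 and learning rate 0.5.

Model selection follows a constrained rule: among configurations whose
valid1 + valid2 MSE stays under a budget (default 0.15), pick the one with
the highest valid2 hit ratio.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import lightgbm as lgb
import numpy as np

from .chem_enum import FingerprintConfig, InputError, fingerprint_matrix
from .dataset_builder import SamplingConfig, SplitBundle, build_splits
from .del_scoring import ScoredCompound
from .eval_sar import hit_rate, mse
from .synthetic_del import DerivativePanel

#: Default high-score thresholds used for the valid2/test2 hit ratios.
DEFAULT_THRESHOLDS = {"gbm": 0.5, "mlp": 0.4}


@dataclass(frozen=True)
class MLPConfig:
    input_dim: int = 1024
    hidden_layers: int = 1
    hidden_units: int = 256
    activation: str = "relu"
    dropout_rate: float = 0.8  # drop probability, not keep probability
    output_activation: str = "softplus"
    optimizer: str = "adam"
    learning_rate: float = 0.005
    epochs: int = 30
    batch_size: int = 256
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_rate < 1:
            raise InputError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0:
            raise InputError("learning_rate must be > 0")
        if self.activation != "relu" or self.output_activation != "softplus":
            raise InputError("only relu hidden / softplus output are supported")
        if self.optimizer != "adam":
            raise InputError("only the adam optimizer is supported")


@dataclass(frozen=True)
class GBMConfig:
    bagging_fraction: float = 0.8
    feature_fraction: float = 0.76
    lambda_l1: float = 10.0
    lambda_l2: float = 10.0
    learning_rate: float = 0.5
    num_boost_round: int = 200
    num_leaves: int = 31
    min_data_in_leaf: int = 20
    #: Early stopping is off by default: the DEL validation split contains
    #: essentially no positives, so held-out MSE is blind to how well the
    #: booster has fit the (oversampled) binder and stops after one round.
    early_stopping_rounds: int | None = None
    num_threads: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.bagging_fraction, self.feature_fraction):
            if not 0 < frac <= 1:
                raise InputError("fractions must be in (0, 1]")
        if self.lambda_l1 < 0 or self.lambda_l2 < 0:
            raise InputError("penalties must be >= 0")
        if self.learning_rate <= 0:
            raise InputError("learning_rate must be > 0")


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class MLPModel:
    """Dense rectifier network with dropout and a softplus output unit."""

    kind = "mlp"

    def __init__(self, config: MLPConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        sizes = (
            [config.input_dim]
            + [config.hidden_units] * config.hidden_layers
            + [1]
        )
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for d_in, d_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / d_in)  # He initialisation for relu stacks
            self.weights.append(rng.normal(0.0, scale, (d_in, d_out)))
            self.biases.append(np.zeros(d_out))
        self._rng = rng

    # -- forward -----------------------------------------------------------
    def _forward(self, X, rng=None):
        """Returns (activations per layer, pre-activation of output)."""
        acts = [X]
        h = X
        keep = 1.0 - self.config.dropout_rate
        masks = []
        for i in range(len(self.weights) - 1):
            z = h @ self.weights[i] + self.biases[i]
            h = np.maximum(z, 0.0)
            if rng is not None and keep < 1.0:
                m = (rng.random(h.shape) < keep) / keep  # inverted dropout
                h = h * m
                masks.append(m)
            else:
                masks.append(None)
            acts.append(h)
        z_out = h @ self.weights[-1] + self.biases[-1]
        return acts, masks, z_out

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.config.input_dim:
            raise InputError(
                f"fingerprint length {X.shape[1]} != input_dim {self.config.input_dim}"
            )
        _, _, z = self._forward(X)
        return _softplus(z).ravel()

    # -- training ----------------------------------------------------------
    def fit(self, X, y, valid: tuple[np.ndarray, np.ndarray] | None = None) -> "MLPModel":
        cfg = self.config
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).ravel()
        if X.shape[1] != cfg.input_dim:
            raise InputError(
                f"fingerprint length {X.shape[1]} != input_dim {cfg.input_dim}"
            )
        rng = self._rng
        m_t = [np.zeros_like(w) for w in self.weights]
        v_t = [np.zeros_like(w) for w in self.weights]
        mb_t = [np.zeros_like(b) for b in self.biases]
        vb_t = [np.zeros_like(b) for b in self.biases]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        best = (np.inf, None)
        stall = 0
        for _epoch in range(cfg.epochs):
            order = rng.permutation(len(X))
            for start in range(0, len(X), cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                xb, yb = X[idx], y[idx]
                acts, masks, z_out = self._forward(xb, rng=rng)
                out = _softplus(z_out).ravel()
                # d MSE / d z_out
                delta = (2.0 / len(xb)) * (out - yb) * _sigmoid(z_out.ravel())
                delta = delta[:, None]
                grads_w, grads_b = [None] * len(self.weights), [None] * len(self.biases)
                for layer in range(len(self.weights) - 1, -1, -1):
                    grads_w[layer] = acts[layer].T @ delta
                    grads_b[layer] = delta.sum(axis=0)
                    if layer > 0:
                        delta = delta @ self.weights[layer].T
                        if masks[layer - 1] is not None:
                            delta = delta * masks[layer - 1]
                        delta = delta * (acts[layer] > 0)
                step += 1
                corr = np.sqrt(1 - beta2 ** step) / (1 - beta1 ** step)
                for layer in range(len(self.weights)):
                    m_t[layer] = beta1 * m_t[layer] + (1 - beta1) * grads_w[layer]
                    v_t[layer] = beta2 * v_t[layer] + (1 - beta2) * grads_w[layer] ** 2
                    self.weights[layer] -= cfg.learning_rate * corr * m_t[layer] / (
                        np.sqrt(v_t[layer]) + eps
                    )
                    mb_t[layer] = beta1 * mb_t[layer] + (1 - beta1) * grads_b[layer]
                    vb_t[layer] = beta2 * vb_t[layer] + (1 - beta2) * grads_b[layer] ** 2
                    self.biases[layer] -= cfg.learning_rate * corr * mb_t[layer] / (
                        np.sqrt(vb_t[layer]) + eps
                    )
            if valid is not None:
                v_mse = mse(self.predict(valid[0]), valid[1])
                if v_mse < best[0] - 1e-9:
                    best = (v_mse, [w.copy() for w in self.weights]
                            + [b.copy() for b in self.biases])
                    stall = 0
                else:
                    stall += 1
                    if stall >= cfg.patience:
                        break
        if valid is not None and best[1] is not None:
            k = len(self.weights)
            self.weights = best[1][:k]
            self.biases = best[1][k:]
        return self

    # -- persistence -------------------------------------------------------
    def save(self, path: str) -> None:
        arrays = {f"w{i}": w for i, w in enumerate(self.weights)}
        arrays.update({f"b{i}": b for i, b in enumerate(self.biases)})
        np.savez(path, n_layers=len(self.weights), **arrays)

    @classmethod
    def load(cls, path: str, config: MLPConfig) -> "MLPModel":
        data = np.load(path)
        model = cls(config)
        n = int(data["n_layers"])
        model.weights = [data[f"w{i}"] for i in range(n)]
        model.biases = [data[f"b{i}"] for i in range(n)]
        return model


class GBMModel:
    """Thin wrapper around a trained LightGBM booster."""

    kind = "gbm"

    def __init__(self, booster: lgb.Booster, config: GBMConfig):
        self.booster = booster
        self.config = config

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.booster.num_feature():
            raise InputError(
                f"fingerprint length {X.shape[1]} != model features "
                f"{self.booster.num_feature()}"
            )
        return np.asarray(self.booster.predict(X))

    def save(self, path: str) -> None:
        self.booster.save_model(path)

    @classmethod
    def load(cls, path: str, config: GBMConfig) -> "GBMModel":
        return cls(lgb.Booster(model_file=path), config)


def _train_gbm(config: GBMConfig, X, y, valid=None) -> GBMModel:
    params = {
        "objective": "regression",
        "metric": "l2",
        "learning_rate": config.learning_rate,
        "bagging_fraction": config.bagging_fraction,
        "bagging_freq": 1,
        "feature_fraction": config.feature_fraction,
        "lambda_l1": config.lambda_l1,
        "lambda_l2": config.lambda_l2,
        "num_leaves": config.num_leaves,
        "min_data_in_leaf": config.min_data_in_leaf,
        "seed": config.seed,
        "deterministic": True,
        "force_row_wise": True,
        "num_threads": config.num_threads,
        "verbosity": -1,
    }
    X = np.asarray(X, dtype=np.float32)
    train_set = lgb.Dataset(X, label=np.asarray(y, dtype=np.float64))
    kwargs: dict = {}
    if valid is not None and config.early_stopping_rounds is not None:
        vX = np.asarray(valid[0], dtype=np.float32)
        kwargs["valid_sets"] = [lgb.Dataset(vX, label=np.asarray(valid[1]))]
        kwargs["callbacks"] = [
            lgb.early_stopping(config.early_stopping_rounds, verbose=False)
        ]
    booster = lgb.train(params, train_set, num_boost_round=config.num_boost_round,
                        **kwargs)
    return GBMModel(booster, config)


def train_model(
    kind: str,
    config: MLPConfig | GBMConfig,
    X: np.ndarray,
    y: np.ndarray,
    valid: tuple[np.ndarray, np.ndarray] | None = None,
):
    """Train one regressor on (fingerprint, score) data.

    ``valid`` enables early stopping on held-out MSE.  Training is
    deterministic given the config seed.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    if len(X) == 0 or len(X) != len(y):
        raise InputError("training data must be non-empty and aligned")
    if kind == "mlp":
        if not isinstance(config, MLPConfig):
            raise InputError("kind 'mlp' requires an MLPConfig")
        return MLPModel(config).fit(X, y, valid=valid)
    if kind == "gbm":
        if not isinstance(config, GBMConfig):
            raise InputError("kind 'gbm' requires a GBMConfig")
        return _train_gbm(config, X, y, valid=valid)
    raise InputError(f"unknown model kind {kind!r}")


def predict(model, fps: np.ndarray) -> np.ndarray:
    """Order-preserving batch prediction."""
    return model.predict(np.asarray(fps))


# ---------------------------------------------------------------------------
# Evaluation reports, grid search, model selection


@dataclass
class EvalReport:
    hyperparameters: dict
    train_mse: float
    valid1_mse: float
    valid2_mse: float
    test1_mse: float
    test2_mse: float
    valid2_ratio: float | None
    test2_ratio: float | None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @property
    def valid_mse_sum(self) -> float:
        return self.valid1_mse + self.valid2_mse


def evaluate_model(model, bundle: SplitBundle, threshold: float | None = None,
                   hyperparameters: dict | None = None) -> EvalReport:
    """MSE on every split plus the valid2/test2 hit ratios at the threshold."""
    if threshold is None:
        threshold = DEFAULT_THRESHOLDS.get(getattr(model, "kind", ""), 0.5)
    pred_v2 = model.predict(bundle.X_valid2)
    pred_t2 = model.predict(bundle.X_test2)
    return EvalReport(
        hyperparameters=dict(hyperparameters or {}),
        train_mse=mse(model.predict(bundle.X_train), bundle.y_train),
        valid1_mse=mse(model.predict(bundle.X_valid1), bundle.y_valid1),
        valid2_mse=mse(pred_v2, bundle.y_valid2),
        test1_mse=mse(model.predict(bundle.X_test1), bundle.y_test1),
        test2_mse=mse(pred_t2, bundle.y_test2),
        valid2_ratio=hit_rate(pred_v2, bundle.valid2_ic50, threshold).ratio,
        test2_ratio=hit_rate(pred_t2, bundle.test2_ic50, threshold).ratio,
    )


def grid_search(
    scored: Sequence[ScoredCompound],
    derivatives: DerivativePanel,
    smiles_by_id: Mapping[str, str],
    n_values: Iterable[int],
    multiple_values: Iterable[int],
    fp_configs: Iterable[FingerprintConfig],
    model_kind: str,
    model_config: MLPConfig | GBMConfig,
    base_sampling: SamplingConfig = SamplingConfig(),
    valid1_size: int = 100_000,
    test1_size: int = 100_000,
    threshold: float | None = None,
) -> list[EvalReport]:
    """One fresh split + training + evaluation per grid point.

    Fingerprints are recomputed once per fingerprint config.  Reports are
    sorted by valid2_ratio (descending, undefined last) then valid MSE sum,
    mirroring how a model is chosen.
    """
    n_values = list(n_values)
    multiple_values = list(multiple_values)
    fp_configs = list(fp_configs)
    if not (n_values and multiple_values and fp_configs):
        raise InputError("grid must be non-empty")
    reports: list[EvalReport] = []
    ids = [s.compound_id for s in scored]
    for fp_config in fp_configs:
        X = fingerprint_matrix([smiles_by_id[c] for c in ids], fp_config)
        fps = dict(zip(ids, X))
        model_cfg = model_config
        if model_kind == "mlp" and model_config.input_dim != fp_config.n_bits:
            model_cfg = replace(model_config, input_dim=fp_config.n_bits)
        for n in n_values:
            for mult in multiple_values:
                sampling = replace(
                    base_sampling, undersample_interval_n=n, oversample_multiple=mult
                )
                bundle = build_splits(
                    scored, derivatives, sampling, fps,
                    valid1_size=valid1_size, test1_size=test1_size,
                    fp_config=fp_config,
                )
                model = train_model(
                    model_kind, model_cfg, bundle.X_train, bundle.y_train,
                    valid=(bundle.X_valid1, bundle.y_valid1),
                )
                reports.append(
                    evaluate_model(
                        model, bundle, threshold,
                        hyperparameters={
                            "model": model_kind,
                            "undersample_interval_n": n,
                            "oversample_multiple": mult,
                            "n_bits": fp_config.n_bits,
                            "radius": fp_config.radius,
                        },
                    )
                )
    reports.sort(
        key=lambda r: (
            -(r.valid2_ratio if r.valid2_ratio is not None else -1.0),
            r.valid_mse_sum,
        )
    )
    return reports


class ModelSelectionError(RuntimeError):
    """No grid point met the validation MSE budget."""

    def __init__(self, message: str, best_advisory: EvalReport | None = None):
        super().__init__(message)
        self.best_advisory = best_advisory


def select_model(reports: Sequence[EvalReport], mse_budget: float = 0.15) -> EvalReport:
    """Highest valid2_ratio among reports with valid1+valid2 MSE under budget.

    Ties go to the smaller MSE sum.  Raises :class:`ModelSelectionError`
    (carrying the best-ratio report as advisory) when nothing qualifies.
    """
    if not reports:
        raise InputError("no reports supplied")
    feasible = [
        r for r in reports
        if r.valid2_ratio is not None and r.valid_mse_sum < mse_budget
    ]
    if not feasible:
        defined = [r for r in reports if r.valid2_ratio is not None]
        best = max(defined, key=lambda r: r.valid2_ratio) if defined else None
        raise ModelSelectionError(
            f"no configuration had valid1_mse + valid2_mse < {mse_budget}",
            best_advisory=best,
        )
    return max(feasible, key=lambda r: (r.valid2_ratio, -r.valid_mse_sum))
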