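"""The three logS0 predictors: feed-forward network, GSE, null model.

The network is a standard three-layer perceptron (10 inputs - n_hidden -
1 output by default) with a logistic activation on *both* the hidden and
the output layer, trained by full-batch Adam on the mean-squared error of
the (0,1)-scaled target plus an L2 penalty.  Because the output unit is
logistic, predictions mapped back through the inverse target scaling are
confined to the training logS0 range by construction.

The general solubility equation (GSE) is the closed form

    logS0 = 0.5 - logP - 0.001 * (Tmp - 25)

from the experimental octanol-water partition coefficient and the Celsius
melting point.  The null model predicts the training-mean logS0 for every
compound; any useful predictor must beat it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .features import ScalingParams

__all__ = [
    "MlpConfig",
    "MlpRegressor",
    "TrainedModel",
    "train_mlp",
    "null_fit",
    "gse_predict",
    "save_model",
    "load_model",
]


@dataclass
class MlpConfig:
    """Hyper-parameters of the solubility network.

    Defaults follow the selected architecture: 25 hidden neurons, L2
    strength 0.2, Adam with step 1e-3, at most 4000 full-batch epochs and
    no early stopping.
    """

    n_hidden: int = 25
    l2_alpha: float = 0.2
    learning_rate: float = 1e-3
    max_iterations: int = 4000
    seed: int = 0

    def validate(self) -> None:
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if self.l2_alpha < 0:
            raise ValueError("l2_alpha must be >= 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


class MlpRegressor:
    """Three-layer perceptron, logistic-logistic, full-batch Adam.

    Operates on already-scaled inputs; targets are expected in (0, 1).
    Deterministic given ``config.seed``.
    """

    def __init__(self, config: MlpConfig | None = None):
        self.config = config or MlpConfig()
        self.config.validate()
        self.loss_curve_: list[float] = []
        self.n_iter_: int = 0

    def _loss(self, err: np.ndarray, n: int) -> float:
        penalty = 0.5 * self.config.l2_alpha / n * (
            np.sum(self.W1_ ** 2) + np.sum(self.W2_ ** 2))
        return float(0.5 * np.mean(err ** 2) + penalty)

    def fit(self, X, y) -> "MlpRegressor":
        cfg = self.config
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1, 1)
        if np.isnan(X).any() or np.isnan(y).any():
            raise ValueError("NaN in training inputs")
        n, d = X.shape
        rng = np.random.default_rng(cfg.seed)
        h = cfg.n_hidden
        b1 = np.sqrt(6.0 / (d + h))
        b2 = np.sqrt(6.0 / (h + 1))
        self.W1_ = rng.uniform(-b1, b1, size=(d, h))
        self.b1_ = np.zeros(h)
        self.W2_ = rng.uniform(-b2, b2, size=(h, 1))
        self.b2_ = np.zeros(1)

        params = [self.W1_, self.b1_, self.W2_, self.b2_]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        lr = cfg.learning_rate
        alpha_n = cfg.l2_alpha / n
        self.loss_curve_ = []

        for t in range(1, cfg.max_iterations + 1):
            A1 = expit(X @ self.W1_ + self.b1_)
            out = expit(A1 @ self.W2_ + self.b2_)
            err = out - y
            if t == 1 or t % 50 == 0:
                self.loss_curve_.append(self._loss(err, n))
            dZ2 = err * out * (1.0 - out) / n
            gW2 = A1.T @ dZ2 + alpha_n * self.W2_
            gb2 = dZ2.sum(axis=0)
            dA1 = dZ2 @ self.W2_.T
            dZ1 = dA1 * A1 * (1.0 - A1)
            gW1 = X.T @ dZ1 + alpha_n * self.W1_
            gb1 = dZ1.sum(axis=0)
            for p, g, mi, vi in zip(params, (gW1, gb1, gW2, gb2), m, v):
                mi *= beta1
                mi += (1 - beta1) * g
                vi *= beta2
                vi += (1 - beta2) * g * g
                mhat = mi / (1 - beta1 ** t)
                vhat = vi / (1 - beta2 ** t)
                p -= lr * mhat / (np.sqrt(vhat) + eps)
        self.n_iter_ = cfg.max_iterations
        A1 = expit(X @ self.W1_ + self.b1_)
        err = expit(A1 @ self.W2_ + self.b2_) - y
        self.loss_curve_.append(self._loss(err, n))
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        A1 = expit(X @ self.W1_ + self.b1_)
        return expit(A1 @ self.W2_ + self.b2_).ravel()

    # weight (de)serialisation for the model bundle
    def weights_to_dict(self) -> dict:
        return {"W1": self.W1_.tolist(), "b1": self.b1_.tolist(),
                "W2": self.W2_.tolist(), "b2": self.b2_.tolist()}

    @classmethod
    def from_weights(cls, config: MlpConfig, weights: dict) -> "MlpRegressor":
        net = cls(config)
        net.W1_ = np.asarray(weights["W1"], dtype=float)
        net.b1_ = np.asarray(weights["b1"], dtype=float)
        net.W2_ = np.asarray(weights["W2"], dtype=float)
        net.b2_ = np.asarray(weights["b2"], dtype=float)
        return net


@dataclass
class TrainedModel:
    """A fitted predictor plus everything needed to apply it to raw tables.

    ``predict`` takes a table of *unscaled* descriptors (must contain the
    model's feature columns), applies the stored training scaling, runs the
    network and inverse-scales the output back to log molar.  Null models
    ignore the features entirely but still validate the columns when
    feature names are attached.
    """

    kind: str                                  # "mlp" | "null"
    feature_names: list[str] = field(default_factory=list)
    scaling: ScalingParams | None = None
    net: MlpRegressor | None = None
    training_target_mean: float | None = None

    def _validate_columns(self, table: pd.DataFrame) -> None:
        missing = [c for c in self.feature_names if c not in table.columns]
        if missing:
            raise ValueError(f"prediction table missing feature column(s): {missing}")

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        if self.kind == "null":
            return np.full(len(table), float(self.training_target_mean))
        self._validate_columns(table)
        if self.scaling is None or self.net is None:
            raise ValueError("mlp model lacks scaling parameters or weights")
        Xs = self.scaling.transform_features(table[self.feature_names])
        scaled = self.net.predict(Xs.to_numpy())
        return self.scaling.inverse_target(scaled)


def train_mlp(X_scaled, y_scaled, config: MlpConfig | None = None,
              scaling: ScalingParams | None = None,
              feature_names: list[str] | None = None) -> TrainedModel:
    """Train the network on an already-scaled table and (0,1) target.

    When ``scaling``/``feature_names`` are supplied the returned model
    predicts directly from raw descriptor tables.
    """
    config = config or MlpConfig()
    if isinstance(X_scaled, pd.DataFrame):
        feature_names = feature_names or list(X_scaled.columns)
        X_arr = X_scaled.to_numpy(dtype=float)
    else:
        X_arr = np.asarray(X_scaled, dtype=float)
        feature_names = feature_names or []
    net = MlpRegressor(config).fit(X_arr, y_scaled)
    return TrainedModel(kind="mlp", feature_names=feature_names,
                        scaling=scaling, net=net)


def null_fit(y_train) -> TrainedModel:
    """The predict-average-for-all baseline (training mean, log molar)."""
    y = np.asarray(y_train, dtype=float)
    if y.size == 0:
        raise ValueError("cannot fit the null model on an empty target")
    return TrainedModel(kind="null", training_target_mean=float(y.mean()))


def gse_predict(logP, Tmp) -> np.ndarray | float:
    """General solubility equation: logS0 = 0.5 - logP - 0.001 (Tmp - 25).

    Accepts scalars or aligned arrays; missing (NaN) inputs raise rather
    than impute.
    """
    logP = np.asarray(logP, dtype=float)
    Tmp = np.asarray(Tmp, dtype=float)
    if np.isnan(logP).any() or np.isnan(Tmp).any():
        raise ValueError("GSE requires experimental logP and melting point; got NaN")
    out = 0.5 - logP - 0.001 * (Tmp - 25.0)
    return float(out) if out.ndim == 0 else out


def save_model(model: TrainedModel, path) -> None:
    """Serialise a model (weights, scaling, features, config) to one JSON file."""
    d: dict = {"kind": model.kind, "feature_names": model.feature_names,
               "training_target_mean": model.training_target_mean}
    if model.scaling is not None:
        d["scaling"] = model.scaling.to_dict()
    if model.net is not None:
        d["config"] = asdict(model.net.config)
        d["weights"] = model.net.weights_to_dict()
    Path(path).write_text(json.dumps(d))


def load_model(path) -> TrainedModel:
    d = json.loads(Path(path).read_text())
    scaling = ScalingParams.from_dict(d["scaling"]) if "scaling" in d else None
    net = None
    if "weights" in d:
        net = MlpRegressor.from_weights(MlpConfig(**d["config"]), d["weights"])
    return TrainedModel(kind=d["kind"], feature_names=list(d["feature_names"]),
                        scaling=scaling, net=net,
                        training_target_mean=d.get("training_target_mean"))
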