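"""A one-hidden-layer tan-sigmoid backpropagation regressor, from scratch.

The network maps the six image features (energy, entropy, contrast,
homogeneity, correlation, mean HU) to a normalized Young's modulus:

    y = tanh(W2 · tanh(W1·x + b1) + b2)

with W1 an (N × 6) weight matrix, W2 a (1 × N) matrix, and biases b1, b2.
Weights are initialized uniformly in [−1, 1] and biases in [0, 1].  Training
is classical batch backpropagation: full-batch gradient descent with
momentum on the mean squared error, with early stopping when the validation
error has not improved for a configured number of consecutive epochs; the
parameters returned are those of the best-validation epoch.

Because the output unit is a tanh, inputs and targets are min-max scaled to
[−1, 1]; the scalers are fitted on the training split only and predictions
are mapped back to MPa through the inverse output scaler.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import FitError, InputError

N_INPUTS = 6


# ---------------------------------------------------------------------------
# scaling


@dataclass
class MinMaxScaler:
    """Per-column min-max scaling onto a fixed feature range (default [−1, 1]).

    ``inverse(transform(x)) == x`` to floating-point precision.  A constant
    column (max == min) is mapped to the centre of the feature range and
    inverted back to the constant.
    """

    data_min: np.ndarray | None = None
    data_max: np.ndarray | None = None
    feature_range: tuple[float, float] = (-1.0, 1.0)

    def fit(self, x: np.ndarray) -> "MinMaxScaler":
        x = np.atleast_2d(np.asarray(x, dtype=float))
        self.data_min = x.min(axis=0)
        self.data_max = x.max(axis=0)
        return self

    def _span(self) -> np.ndarray:
        span = self.data_max - self.data_min
        return np.where(span == 0, 1.0, span)

    def transform(self, x: np.ndarray) -> np.ndarray:
        if self.data_min is None:
            raise InputError("scaler is not fitted")
        x = np.asarray(x, dtype=float)
        lo, hi = self.feature_range
        unit = (x - self.data_min) / self._span()
        constant = self.data_max == self.data_min
        unit = np.where(constant, 0.5, unit)
        return lo + unit * (hi - lo)

    def inverse(self, y: np.ndarray) -> np.ndarray:
        if self.data_min is None:
            raise InputError("scaler is not fitted")
        y = np.asarray(y, dtype=float)
        lo, hi = self.feature_range
        unit = (y - lo) / (hi - lo)
        out = self.data_min + unit * self._span()
        # a constant column was pinned to mid-range; invert back to the constant
        return np.where(self.data_max == self.data_min, self.data_min, out)


# ---------------------------------------------------------------------------
# model


@dataclass
class NetworkModel:
    """Parameters of the 6-N-1 tanh network."""

    W1: np.ndarray  # (N, 6)
    b1: np.ndarray  # (N,)
    W2: np.ndarray  # (1, N)
    b2: np.ndarray  # (1,)

    def __post_init__(self) -> None:
        self.W1 = np.asarray(self.W1, dtype=float)
        self.b1 = np.asarray(self.b1, dtype=float)
        self.W2 = np.asarray(self.W2, dtype=float)
        self.b2 = np.atleast_1d(np.asarray(self.b2, dtype=float))
        n = self.W1.shape[0]
        if self.W1.ndim != 2 or self.b1.shape != (n,) or self.W2.shape != (1, n):
            raise InputError("inconsistent network parameter shapes")
        for p in (self.W1, self.b1, self.W2, self.b2):
            if not np.all(np.isfinite(p)):
                raise InputError("network parameters must be finite")

    @property
    def hidden_size(self) -> int:
        return self.W1.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.W1.shape[1]

    def copy(self) -> "NetworkModel":
        return NetworkModel(
            self.W1.copy(), self.b1.copy(), self.W2.copy(), self.b2.copy()
        )


def init_network(
    hidden_size: int, seed: int, n_inputs: int = N_INPUTS
) -> NetworkModel:
    """Random initial parameters: weights U[−1, 1], biases U[0, 1]."""
    if hidden_size < 1:
        raise InputError("hidden_size must be >= 1")
    rng = np.random.default_rng(seed)
    return NetworkModel(
        W1=rng.uniform(-1.0, 1.0, size=(hidden_size, n_inputs)),
        b1=rng.uniform(0.0, 1.0, size=hidden_size),
        W2=rng.uniform(-1.0, 1.0, size=(1, hidden_size)),
        b2=rng.uniform(0.0, 1.0, size=1),
    )


def forward(net: NetworkModel, x: np.ndarray) -> np.ndarray:
    """Network output tanh(W2·tanh(W1·x + b1) + b2), in (−1, 1).

    ``x`` is one feature vector (shape ``(n_inputs,)``) or a batch
    ``(n_samples, n_inputs)``; the output matches (scalar-per-sample).
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InputError("network input must be finite")
    single = x.ndim == 1
    xb = np.atleast_2d(x)
    if xb.shape[1] != net.n_inputs:
        raise InputError(f"expected {net.n_inputs} inputs, got {xb.shape[1]}")
    h = np.tanh(xb @ net.W1.T + net.b1)
    y = np.tanh(h @ net.W2.T + net.b2)
    return float(y[0, 0]) if single else y[:, 0]


@dataclass
class Gradients:
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray


def backprop_gradient(
    net: NetworkModel, x: np.ndarray, y: np.ndarray
) -> tuple[Gradients, float]:
    """Analytic gradient of the batch MSE w.r.t. every parameter.

    Returns (gradients, mse).  MSE = mean over the batch of (ŷ − y)²; the
    gradients are exact derivatives of that quantity (batch-mean scaling
    included), obtained by backpropagating through both tanh layers.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float).reshape(-1)
    if x.shape[0] == 0:
        raise InputError("batch must be non-empty")
    if x.shape[0] != y.shape[0]:
        raise InputError("batch inputs and targets differ in length")
    n = x.shape[0]

    z1 = x @ net.W1.T + net.b1  # (n, N)
    h = np.tanh(z1)
    z2 = h @ net.W2.T + net.b2  # (n, 1)
    yhat = np.tanh(z2)[:, 0]

    err = yhat - y
    mse = float(np.mean(err**2))

    # dMSE/dyhat = 2 err / n ; chain through tanh'(z) = 1 - tanh(z)^2
    delta2 = (2.0 * err / n) * (1.0 - yhat**2)  # (n,)
    gW2 = delta2[None, :] @ h  # (1, N)
    gb2 = np.array([delta2.sum()])
    delta1 = np.outer(delta2, net.W2[0]) * (1.0 - h**2)  # (n, N)
    gW1 = delta1.T @ x  # (N, n_inputs)
    gb1 = delta1.sum(axis=0)
    return Gradients(W1=gW1, b1=gb1, W2=gW2, b2=gb2), mse


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainConfig:
    """Backpropagation hyperparameters.

    ``max_validation_failures`` is the early-stopping patience: the number
    of consecutive epochs the validation MSE may fail to improve before
    training halts (≥ 1).
    """

    max_epochs: int = 1000
    learning_rate: float = 0.01
    momentum: float = 0.9
    max_validation_failures: int = 6
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0
    goal_mse: float = 0.0

    def __post_init__(self) -> None:
        if self.max_epochs < 1 or self.learning_rate <= 0:
            raise InputError("max_epochs and learning_rate must be positive")
        if not 0 <= self.momentum < 1:
            raise InputError("momentum must be in [0, 1)")
        if self.max_validation_failures < 1:
            raise InputError("max_validation_failures must be >= 1")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise InputError("split fractions must sum to 1")
        if any(f <= 0 for f in self.split_fractions):
            raise InputError("split fractions must be positive")


@dataclass
class TrainingHistory:
    """Per-epoch error traces and the stopping diagnosis."""

    train_mse: list[float] = field(default_factory=list)
    val_mse: list[float] = field(default_factory=list)
    test_mse: list[float] = field(default_factory=list)
    gradient_norm: list[float] = field(default_factory=list)
    stop_epoch: int = 0
    stop_reason: str = ""
    best_epoch: int = 0


def split_dataset(
    n: int,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random disjoint train/validation/test index sets.

    Sizes: floor(f_train·n) training, floor(f_val·n) validation, remainder
    test — so n = 300 with the 70/15/15 split gives 210/45/45 and n = 10
    gives 7/1/2.
    """
    if n < 10:
        raise InputError("need at least 10 samples to split")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise InputError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(math.floor(fractions[0] * n))
    n_val = int(math.floor(fractions[1] * n))
    if n_train < 1 or n_val < 1 or n - n_train - n_val < 1:
        raise InputError("split produced an empty subset")
    return perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :]


def train(
    net: NetworkModel,
    x: np.ndarray,
    y: np.ndarray,
    config: TrainConfig,
    val: tuple[np.ndarray, np.ndarray] | None = None,
    test: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[NetworkModel, TrainingHistory]:
    """Batch gradient descent with momentum and validation early stopping.

    ``x``/``y`` are the scaled training inputs/targets; ``val`` and ``test``
    are optional scaled (inputs, targets) pairs.  Training stops when the
    goal MSE is reached, the validation MSE fails to improve for
    ``max_validation_failures`` consecutive epochs, or ``max_epochs`` is
    exhausted; the returned model carries the parameters of the epoch with
    the lowest validation MSE (lowest training MSE when no validation set
    is given).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float).reshape(-1)
    net = net.copy()
    hist = TrainingHistory()

    vel = Gradients(
        W1=np.zeros_like(net.W1),
        b1=np.zeros_like(net.b1),
        W2=np.zeros_like(net.W2),
        b2=np.zeros_like(net.b2),
    )
    best = net.copy()
    best_score = math.inf
    failures = 0
    stop_reason = "max_epochs"

    for epoch in range(1, config.max_epochs + 1):
        grads, train_mse = backprop_gradient(net, x, y)
        if not math.isfinite(train_mse):
            raise FitError(
                f"training diverged (non-finite MSE) at epoch {epoch}; "
                f"history so far: {len(hist.train_mse)} epochs"
            )
        gnorm = math.sqrt(
            sum(float(np.sum(g**2)) for g in (grads.W1, grads.b1, grads.W2, grads.b2))
        )
        for name in ("W1", "b1", "W2", "b2"):
            v = config.momentum * getattr(vel, name) - config.learning_rate * getattr(
                grads, name
            )
            setattr(vel, name, v)
            setattr(net, name, getattr(net, name) + v)

        hist.train_mse.append(train_mse)
        hist.gradient_norm.append(gnorm)

        if val is not None:
            val_mse = float(np.mean((forward(net, val[0]) - val[1].reshape(-1)) ** 2))
            hist.val_mse.append(val_mse)
            score = val_mse
        else:
            score = train_mse
        if test is not None:
            hist.test_mse.append(
                float(np.mean((forward(net, test[0]) - test[1].reshape(-1)) ** 2))
            )

        if score < best_score:
            best_score = score
            best = net.copy()
            hist.best_epoch = epoch
            failures = 0
        else:
            failures += 1

        hist.stop_epoch = epoch
        if train_mse <= config.goal_mse:
            stop_reason = "goal"
            break
        if val is not None and failures >= config.max_validation_failures:
            stop_reason = "validation_failures"
            break

    hist.stop_reason = stop_reason
    return best, hist


@dataclass(frozen=True)
class EvalResult:
    mse: float
    r: float
    r_defined: bool = True


def evaluate(net: NetworkModel, x: np.ndarray, y: np.ndarray) -> EvalResult:
    """MSE (on the scale of x/y given) and Pearson R of predictions vs targets.

    R is scale-invariant, so it is the same on the normalized and physical
    scales.  Constant targets or constant predictions leave R undefined;
    the result is then flagged with ``r_defined=False`` and R = 0.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float).reshape(-1)
    if y.size == 0:
        raise InputError("cannot evaluate on an empty split")
    pred = forward(net, x)
    mse = float(np.mean((pred - y) ** 2))
    if y.size < 2 or np.std(y) == 0 or np.std(pred) == 0:
        return EvalResult(mse=mse, r=0.0, r_defined=False)
    from scipy.stats import pearsonr

    r = float(pearsonr(pred, y).statistic)
    return EvalResult(mse=mse, r=r)


# ---------------------------------------------------------------------------
# end-to-end fitting and the hidden-size parametric study


@dataclass
class FitResult:
    """A trained modulus regressor with its scalers and split diagnostics."""

    net: NetworkModel
    x_scaler: MinMaxScaler
    y_scaler: MinMaxScaler
    history: TrainingHistory
    metrics: dict[str, EvalResult]
    splits: dict[str, np.ndarray]
    config: TrainConfig
    texture_config: dict | None = None

    def predict(self, features: np.ndarray) -> np.ndarray:
        """Predict Young's modulus (physical units) from raw feature rows."""
        xs = self.x_scaler.transform(np.atleast_2d(np.asarray(features, float)))
        ys = forward(self.net, xs)
        return self.y_scaler.inverse(np.atleast_1d(ys))


def fit_modulus_network(
    features: np.ndarray,
    targets: np.ndarray,
    hidden_size: int = 40,
    config: TrainConfig | None = None,
    init_seed: int | None = None,
    texture_config: dict | None = None,
) -> FitResult:
    """Scale, split, train, and evaluate on all three splits.

    Scalers are fitted on the training split only; MSE metrics are on the
    normalized scale and R is computed on de-normalized predictions.
    """
    config = config or TrainConfig()
    x = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(targets, dtype=float).reshape(-1)
    if x.shape[0] != y.size:
        raise InputError("features and targets differ in length")
    tr, va, te = split_dataset(y.size, config.split_fractions, seed=config.seed)

    x_scaler = MinMaxScaler().fit(x[tr])
    y_scaler = MinMaxScaler().fit(y[tr, None])
    xs = {k: x_scaler.transform(x[idx]) for k, idx in (("train", tr), ("val", va), ("test", te))}
    ys = {k: y_scaler.transform(y[idx, None])[:, 0] for k, idx in (("train", tr), ("val", va), ("test", te))}

    net0 = init_network(
        hidden_size, seed=config.seed if init_seed is None else init_seed
    )
    net, hist = train(
        net0,
        xs["train"],
        ys["train"],
        config,
        val=(xs["val"], ys["val"]),
        test=(xs["test"], ys["test"]),
    )
    metrics = {k: evaluate(net, xs[k], ys[k]) for k in ("train", "val", "test")}
    return FitResult(
        net=net,
        x_scaler=x_scaler,
        y_scaler=y_scaler,
        history=hist,
        metrics=metrics,
        splits={"train": tr, "val": va, "test": te},
        config=config,
        texture_config=texture_config,
    )


def parametric_study(
    features: np.ndarray,
    targets: np.ndarray,
    hidden_sizes: Sequence[int],
    config: TrainConfig | None = None,
) -> "tuple[pandas.DataFrame, FitResult]":
    """Sweep the hidden-layer size and tabulate per-size performance.

    Returns a table with one row per size (train/validation MSE and R,
    epochs run) plus the best fit, selected by validation R with ties going
    to the smaller network.
    """
    import pandas as pd

    if len(hidden_sizes) < 1:
        raise InputError("need at least one hidden size")
    config = config or TrainConfig()
    rows = []
    fits: list[FitResult] = []
    for n in hidden_sizes:
        fit = fit_modulus_network(features, targets, hidden_size=n, config=config)
        fits.append(fit)
        rows.append(
            {
                "hidden_size": n,
                "n_train": len(fit.splits["train"]),
                "n_val": len(fit.splits["val"]),
                "train_mse": fit.metrics["train"].mse,
                "train_r": fit.metrics["train"].r,
                "val_mse": fit.metrics["val"].mse,
                "val_r": fit.metrics["val"].r if fit.metrics["val"].r_defined else float("nan"),
                "epochs": fit.history.stop_epoch,
                "stop_reason": fit.history.stop_reason,
            }
        )
    table = pd.DataFrame(rows)
    # best by validation R; ties (within 1e-12) to the smaller network
    order = sorted(
        range(len(fits)),
        key=lambda i: (-(table.loc[i, "val_r"] if np.isfinite(table.loc[i, "val_r"]) else -np.inf), table.loc[i, "hidden_size"]),
    )
    best_i = order[0]
    table["best"] = [i == best_i for i in range(len(fits))]
    return table, fits[best_i]


# ---------------------------------------------------------------------------
# persistence


def save_model(fit: FitResult, path: str | Path) -> None:
    """Persist a trained model (weights, scalers, config) as JSON."""
    payload = {
        "hidden_size": fit.net.hidden_size,
        "n_inputs": fit.net.n_inputs,
        "W1": fit.net.W1.tolist(),
        "b1": fit.net.b1.tolist(),
        "W2": fit.net.W2.tolist(),
        "b2": fit.net.b2.tolist(),
        "x_scaler": {
            "data_min": fit.x_scaler.data_min.tolist(),
            "data_max": fit.x_scaler.data_max.tolist(),
            "feature_range": list(fit.x_scaler.feature_range),
        },
        "y_scaler": {
            "data_min": fit.y_scaler.data_min.tolist(),
            "data_max": fit.y_scaler.data_max.tolist(),
            "feature_range": list(fit.y_scaler.feature_range),
        },
        "config": asdict(fit.config),
        "texture_config": fit.texture_config,
        "metrics": {
            k: {"mse": v.mse, "r": v.r, "r_defined": v.r_defined}
            for k, v in fit.metrics.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_model(path: str | Path) -> FitResult:
    """Load a model persisted by :func:`save_model`."""
    payload = json.loads(Path(path).read_text())
    net = NetworkModel(
        W1=np.array(payload["W1"]),
        b1=np.array(payload["b1"]),
        W2=np.array(payload["W2"]),
        b2=np.array(payload["b2"]),
    )

    def scaler(d):
        return MinMaxScaler(
            data_min=np.array(d["data_min"]),
            data_max=np.array(d["data_max"]),
            feature_range=tuple(d["feature_range"]),
        )

    cfg = payload["config"]
    cfg["split_fractions"] = tuple(cfg["split_fractions"])
    metrics = {
        k: EvalResult(mse=v["mse"], r=v["r"], r_defined=v["r_defined"])
        for k, v in payload.get("metrics", {}).items()
    }
    return FitResult(
        net=net,
        x_scaler=scaler(payload["x_scaler"]),
        y_scaler=scaler(payload["y_scaler"]),
        history=TrainingHistory(),
        metrics=metrics,
        splits={},
        config=TrainConfig(**cfg),
        texture_config=payload.get("texture_config"),
    )
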