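"""Comparison methods sharing the emulator data interface.

Identical-architecture networks trained with the symmetric l2 or Huber
losses (the architecture-selection rule is the same one the calibration
predictor uses, so parameter counts match exactly), an MC-dropout
variant that averages T stochastic forward passes at inference, and
random-forest / gradient-boosting ensembles with 100 trees via
scikit-learn. All trained objects expose ``predict(features)`` in
original response units, so the cross-validation harness treats every
method interchangeably.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.multioutput import MultiOutputRegressor

from ._nn import MLP, Adam
from .interface import (
    NormalizationState,
    RegressionDataset,
    denormalize_predictions,
    logger,
    normalize_dataset,
)
from .core import select_architecture

DNN_LOSSES = ("l2", "huber")


@dataclass
class DNNTrainConfig:
    """Optimiser settings for the baseline networks: Adam at 1e-4 with
    mini-batches of 8, mirroring the calibration predictor's setup; the
    Huber transition threshold is on the normalised response scale."""

    lr: float = 1e-4
    batch_size: int = 8
    epochs: int = 200
    huber_delta: float = 1.0
    seed: int = 0
    early_stopping_patience: int | None = 10
    val_fraction: float = 0.1
    # None -> sample-size rule; set to match a specific experiment
    hidden_widths: tuple[int, ...] | None = None


@dataclass
class DropoutConfig:
    """MC-dropout settings: T stochastic forward passes at dropout rate
    tau, averaged into the final prediction."""

    n_passes: int = 20
    dropout_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_passes < 1:
            raise ValueError("n_passes must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")


@dataclass
class TrainedDNN:
    network: MLP
    normalization: NormalizationState
    loss_name: str
    dropout: DropoutConfig | None = None
    loss_history: list[float] = field(default_factory=list)

    def predict(self, features: np.ndarray) -> np.ndarray:
        xn = self.normalization.normalize_features(np.atleast_2d(features))
        return denormalize_predictions(self.network.forward(xn)[0], self.normalization)

    def n_parameters(self) -> int:
        return self.network.n_parameters()


def _loss_grad(name: str, yhat: np.ndarray, y: np.ndarray, delta: float):
    """Mean loss over all entries and its gradient w.r.t. yhat."""
    r = yhat - y
    nm = r.size
    if name == "l2":
        return float(np.mean(r * r)), 2.0 * r / nm
    # Huber: quadratic inside |r| <= delta, linear outside
    a = np.abs(r)
    quad = a <= delta
    loss = np.where(quad, 0.5 * r * r, delta * (a - 0.5 * delta))
    return float(loss.mean()), np.clip(r, -delta, delta) / nm


def train_dnn(
    data: RegressionDataset,
    loss: str = "l2",
    config: DNNTrainConfig | None = None,
    dropout: DropoutConfig | None = None,
) -> TrainedDNN:
    """Train a network with the same architecture-selection rule as the
    calibration predictor, minimising l2 or Huber loss with Adam. When a
    dropout config is given, inverted dropout is active after every
    hidden layer during training and the layers are retained for
    stochastic inference."""
    if loss not in DNN_LOSSES:
        raise ValueError(f"unknown loss {loss!r}; choose one of {DNN_LOSSES}")
    config = config or DNNTrainConfig()
    norm_data, norm_state = normalize_dataset(data)
    x, y = norm_data.features, norm_data.responses
    n, d = x.shape
    m = y.shape[1]

    ss = np.random.SeedSequence(config.seed)
    rng_init, rng_batch, rng_drop, rng_split = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    val_x = val_y = None
    if config.early_stopping_patience is not None and n >= 20:
        n_val = max(1, int(round(config.val_fraction * n)))
        perm = rng_split.permutation(n)
        val_x, val_y = x[perm[:n_val]], y[perm[:n_val]]
        x, y = x[perm[n_val:]], y[perm[n_val:]]
        n = x.shape[0]

    spec, _ = select_architecture(n, d, m, 1)
    if config.hidden_widths is not None:
        spec.hidden_widths = list(config.hidden_widths)
    net = MLP(spec, rng_init)
    adam = Adam(net.parameters(), lr=config.lr)
    bs = min(config.batch_size, n)
    rate = dropout.dropout_rate if dropout is not None else 0.0

    history: list[float] = []
    best = np.inf
    best_state = None
    stale = 0
    for epoch in range(config.epochs):
        order = rng_batch.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n - bs + 1, bs):
            b = order[start : start + bs]
            yhat, cache = net.forward(
                x[b], dropout_rate=rate, dropout_rng=rng_drop if rate > 0 else None
            )
            value, grad = _loss_grad(loss, yhat, y[b], config.huber_delta)
            adam.step(net.parameters(), net.backward(cache, grad))
            epoch_loss += value
            n_batches += 1
        history.append(epoch_loss / max(n_batches, 1))
        if val_x is not None:
            val_rmse = float(np.sqrt(np.mean((net.forward(val_x)[0] - val_y) ** 2)))
            if val_rmse < best - 1e-6:
                best, best_state, stale = val_rmse, net.get_state(), 0
            else:
                stale += 1
                if stale >= config.early_stopping_patience:
                    logger.info("dnn(%s) early stop at epoch %d", loss, epoch)
                    break
    if best_state is not None:
        net.set_state(best_state)
    return TrainedDNN(
        network=net,
        normalization=norm_state,
        loss_name=loss,
        dropout=dropout,
        loss_history=history,
    )


def mc_dropout_predict(
    model: TrainedDNN, features: np.ndarray, config: DropoutConfig | None = None
) -> np.ndarray:
    """Average of T stochastic forward passes with dropout active;
    seeded, so repeated calls with the same config agree exactly."""
    config = config or model.dropout
    if config is None:
        raise ValueError("model was not trained with dropout; no dropout config available")
    if config.n_passes < 1:
        raise ValueError("n_passes must be >= 1")
    xn = model.normalization.normalize_features(np.atleast_2d(features))
    rng = np.random.default_rng(config.seed)
    total = np.zeros((xn.shape[0], model.network.spec.output_dim))
    for _ in range(config.n_passes):
        total += model.network.forward(
            xn, dropout_rate=config.dropout_rate, dropout_rng=rng
        )[0]
    return denormalize_predictions(total / config.n_passes, model.normalization)


@dataclass
class TrainedEnsemble:
    """Tree ensembles are scale-invariant, so they fit raw features and
    responses directly; predictions are already in original units."""

    model: object
    kind: str
    n_responses: int = 1

    def predict(self, features: np.ndarray) -> np.ndarray:
        yhat = np.asarray(self.model.predict(np.atleast_2d(features)))
        if yhat.ndim == 1:
            yhat = yhat[:, None]
        return yhat


def train_forest(
    data: RegressionDataset, n_trees: int = 100, seed: int = 0
) -> TrainedEnsemble:
    """Random forest with squared-error splitting (default 100 trees)."""
    if data.n_samples < 2:
        raise ValueError("need at least two samples to fit an ensemble")
    y = data.responses
    rf = RandomForestRegressor(
        n_estimators=n_trees, criterion="squared_error", random_state=seed
    )
    rf.fit(data.features, y[:, 0] if y.shape[1] == 1 else y)
    return TrainedEnsemble(model=rf, kind="rf", n_responses=y.shape[1])


def train_gbt(
    data: RegressionDataset, n_trees: int = 100, seed: int = 0
) -> TrainedEnsemble:
    """Gradient-boosted trees under squared-error loss (default 100
    trees); multi-output responses are fitted one dimension at a time."""
    if data.n_samples < 2:
        raise ValueError("need at least two samples to fit an ensemble")
    y = data.responses
    base = GradientBoostingRegressor(
        n_estimators=n_trees, loss="squared_error", random_state=seed
    )
    if y.shape[1] == 1:
        base.fit(data.features, y[:, 0])
        model = base
    else:
        model = MultiOutputRegressor(base)
        model.fit(data.features, y)
    return TrainedEnsemble(model=model, kind="gbt", n_responses=y.shape[1])
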