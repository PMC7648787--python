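"""Interval-calibrated regression training ("learn-by-calibrating").

Instead of fitting a point predictor under a symmetric discrepancy such
as squared error — which silently assumes symmetric observation noise —
this module trains two networks jointly:

* a predictor ``f(x; theta)`` producing point estimates ``yhat``, and
* an interval estimator ``g(x; phi)`` producing nonnegative lower/upper
  interval widths ``(delta_l, delta_u)`` for every response dimension at
  every confidence level ``alpha`` in a fixed grid ``A``.

The interval network minimises an empirical calibration loss: the gap
between the nominal level ``alpha`` and the observed fraction of
responses falling inside ``[yhat - delta_l, yhat + delta_u]``, plus
small penalties on the interval size to rule out trivially wide
intervals. The predictor minimises a hinge loss that pushes each
response inside its current interval with margin ``gamma``, weighting
samples by their relative interval size. Alternating these two updates
solves the bilevel problem without any prior on the residual
distribution, which is what makes the method robust to skewed noise and
outliers. At inference time only ``f`` is evaluated, so the deployed
model has exactly the parameter count of an ordinary network.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.special import expit

from ._nn import MLP, Adam, NetworkSpec
from .interface import (
    NormalizationState,
    RegressionDataset,
    denormalize_predictions,
    logger,
    normalize_dataset,
)

# Hidden-layer widths by sample-size regime: deep for >= LARGE_DATA_N
# samples, shallow otherwise.
LARGE_DATA_N = 5000
DEEP_HIDDEN = [64, 128, 512, 256, 32]
SHALLOW_HIDDEN = [64, 256, 32]

DEFAULT_LEVELS = (0.1, 0.3, 0.5, 0.7, 0.9, 0.99)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class LbCConfig:
    """Hyperparameters of the alternating calibration training loop.

    Defaults are the published operating point: confidence grid
    ``A = [0.1, 0.3, 0.5, 0.7, 0.9, 0.99]``, interval-size penalties
    ``lambda1 = lambda2 = 0.05``, hinge margin ``gamma = 0.05`` (both on
    the [0, 1]-normalised response scale), Adam learning rates 1e-5
    (predictor) and 1e-4 (interval estimator), mini-batches of 8, and a
    (2, 1) schedule: each outer iteration trains the predictor for two
    epochs and the interval estimator for one.
    """

    confidence_levels: tuple[float, ...] = DEFAULT_LEVELS
    lambda1: float = 0.05
    lambda2: float = 0.05
    gamma: float = 0.05
    lr_predictor: float = 1e-5
    lr_interval: float = 1e-4
    batch_size: int = 8
    outer_iterations: int = 1000
    epochs_predictor_per_iter: int = 2
    epochs_interval_per_iter: int = 1
    data_split_mode: str = "disjoint_halves"  # or "shared"
    indicator_temperature: float = 50.0
    seed: int = 0
    # None -> pick hidden widths from the sample-size rule; the 1D
    # illustration experiments use a single hidden layer of 100 units
    hidden_widths: tuple[int, ...] | None = None
    # extra interval-only epochs after the alternation (predictor frozen,
    # cycling deterministically through every confidence level) so the
    # interval heads settle against the final predictor
    final_interval_iterations: int = 0
    # "none" keeps the predictor learning rate constant; "cosine"
    # anneals it to 10% of its initial value across the outer
    # iterations, which settles the hinge-driven predictor (its
    # gradients do not shrink near an optimum the way squared-error
    # gradients do). The interval network keeps its full rate so it can
    # track the predictor throughout.
    lr_schedule: str = "none"
    # convergence control (not part of the published recipe)
    monitor_validation: bool = False
    early_stopping_patience: int | None = None
    val_fraction: float = 0.1
    eval_every: int = 10

    def __post_init__(self) -> None:
        levels = tuple(float(a) for a in self.confidence_levels)
        if not levels or any(not (0.0 < a < 1.0) for a in levels):
            raise ValueError("confidence levels must lie strictly in (0, 1)")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError("confidence levels must be strictly increasing")
        self.confidence_levels = levels
        for name in ("lambda1", "lambda2", "gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("lr_predictor", "lr_interval", "indicator_temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "batch_size",
            "outer_iterations",
            "epochs_predictor_per_iter",
            "epochs_interval_per_iter",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.data_split_mode not in ("shared", "disjoint_halves"):
            raise ValueError("data_split_mode must be 'shared' or 'disjoint_halves'")
        if self.lr_schedule not in ("none", "cosine"):
            raise ValueError("lr_schedule must be 'none' or 'cosine'")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class IntervalBundle:
    """Point predictions with per-level interval widths.

    The interval at level ``alpha`` for sample ``i``, response dim ``j``
    is ``[point[i, j] - lower_width[i, j, a], point[i, j] + upper_width[i, j, a]]``
    where ``a`` indexes ``levels``.
    """

    point: np.ndarray  # (n, m)
    lower_width: np.ndarray  # (n, m, n_levels), >= 0
    upper_width: np.ndarray  # (n, m, n_levels), >= 0
    levels: tuple[float, ...]

    def _level_index(self, alpha: float) -> int:
        for k, a in enumerate(self.levels):
            if abs(a - alpha) < 1e-9:
                return k
        raise ValueError(
            f"confidence level {alpha} not available; choose one of {list(self.levels)}"
        )

    def interval(self, alpha: float) -> tuple[np.ndarray, np.ndarray]:
        """Return (lower, upper) interval endpoints at level ``alpha``."""
        k = self._level_index(alpha)
        return (
            self.point - self.lower_width[:, :, k],
            self.point + self.upper_width[:, :, k],
        )


@dataclass
class TrainedEmulator:
    """A fitted calibration-trained model: both networks, the
    normalisation state needed to map to/from original units, the config
    it was trained with, and the per-iteration loss history."""

    predictor: MLP
    interval_net: MLP
    normalization: NormalizationState
    config: LbCConfig
    loss_history: list[dict] = field(default_factory=list)

    @property
    def n_responses(self) -> int:
        return self.predictor.spec.output_dim

    def n_predictor_parameters(self) -> int:
        return self.predictor.n_parameters()


# ---------------------------------------------------------------------------
# architecture selection
# ---------------------------------------------------------------------------

def select_architecture(
    n_samples: int, input_dim: int, response_dim: int, n_levels: int
) -> tuple[NetworkSpec, NetworkSpec]:
    """Pick the hidden-layer stack by sample size and build matching
    predictor / interval-estimator specs.

    Datasets with at least 5000 samples get five hidden layers
    [64, 128, 512, 256, 32]; smaller ones get [64, 256, 32]. The interval
    network emits a lower and an upper width per response dimension per
    confidence level, passed through softplus to keep widths nonnegative.
    """
    for name, v in (
        ("n_samples", n_samples),
        ("input_dim", input_dim),
        ("response_dim", response_dim),
        ("n_levels", n_levels),
    ):
        if int(v) < 1:
            raise ValueError(f"{name} must be >= 1, got {v}")
    hidden = DEEP_HIDDEN if n_samples >= LARGE_DATA_N else SHALLOW_HIDDEN
    predictor = NetworkSpec(
        input_dim=input_dim,
        hidden_widths=list(hidden),
        output_dim=response_dim,
        output_transform="identity",
    )
    interval = NetworkSpec(
        input_dim=input_dim,
        hidden_widths=list(hidden),
        output_dim=2 * response_dim * n_levels,
        output_transform="softplus",
    )
    return predictor, interval


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def smooth_indicator(
    y: np.ndarray | float,
    lower_bound: np.ndarray | float,
    upper_bound: np.ndarray | float,
    temperature: float,
) -> np.ndarray | float:
    """Differentiable surrogate for ``1[lower <= y <= upper]``:
    ``sigmoid(t (y - lower)) * sigmoid(t (upper - y))``. Converges to the
    hard indicator pointwise as the temperature grows, except exactly at
    the endpoints."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return expit(temperature * (np.asarray(y) - lower_bound)) * expit(
        temperature * (np.asarray(upper_bound) - y)
    )


def _as_2d(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=np.float64)
    return a[:, None] if a.ndim == 1 else a


def _check_shapes(y, point, lower_width, upper_width):
    y, point = _as_2d(y), _as_2d(point)
    lw, uw = _as_2d(lower_width), _as_2d(upper_width)
    if not (y.shape == point.shape == lw.shape == uw.shape):
        raise ValueError(
            f"shape mismatch: y {y.shape}, point {point.shape}, "
            f"lower {lw.shape}, upper {uw.shape}"
        )
    return y, point, lw, uw


def calibration_loss(
    y: np.ndarray,
    point: np.ndarray,
    lower_width: np.ndarray,
    upper_width: np.ndarray,
    alpha: float,
    lambda1: float = 0.05,
    lambda2: float = 0.05,
    temperature: float = 50.0,
    hard: bool = False,
) -> float:
    """Empirical calibration loss at one confidence level.

    ``|alpha - coverage|`` plus ``lambda1``/``lambda2`` times the mean
    absolute distance of the response from the lower/upper interval
    endpoints; the penalties keep the coverage term from being satisfied
    by arbitrarily wide intervals. Coverage is the mean indicator over
    all samples and response dimensions — the hard indicator when
    ``hard=True`` (reporting), the smooth surrogate otherwise
    (gradients).
    """
    y, point, lw, uw = _check_shapes(y, point, lower_width, upper_width)
    lower = point - lw
    upper = point + uw
    if hard:
        inside = (y >= lower) & (y <= upper)
        coverage = float(inside.mean())
    else:
        coverage = float(smooth_indicator(y, lower, upper, temperature).mean())
    penalty = lambda1 * float(np.abs(y - lower).mean()) + lambda2 * float(
        np.abs(upper - y).mean()
    )
    return abs(alpha - coverage) + penalty


def sample_weights(lower_width: np.ndarray, upper_width: np.ndarray) -> np.ndarray:
    """Per-sample weights proportional to total interval size.

    ``w_i = sum_j (delta_l[i,j] + delta_u[i,j]) / sum_k sum_j (...)``;
    samples with wider (less certain) intervals receive more weight in
    the predictor's hinge loss. If every width is zero the weights are
    undefined; uniform weights are returned with a warning.
    """
    lw, uw = _as_2d(lower_width), _as_2d(upper_width)
    if lw.shape != uw.shape:
        raise ValueError("lower_width and upper_width shapes differ")
    totals = (lw + uw).sum(axis=1)
    denom = totals.sum()
    if denom <= 0.0:
        warnings.warn("all interval widths are zero; falling back to uniform weights")
        return np.full(lw.shape[0], 1.0 / lw.shape[0])
    return totals / denom


def predictor_loss(
    y: np.ndarray,
    point: np.ndarray,
    lower_width: np.ndarray,
    upper_width: np.ndarray,
    gamma: float = 0.05,
    weights: np.ndarray | None = None,
) -> float:
    """Weighted two-sided hinge loss on interval membership.

    Zero exactly when every response entry sits inside its interval with
    slack at least ``gamma`` on both sides; grows linearly as entries
    approach or leave the interval.
    """
    y, point, lw, uw = _check_shapes(y, point, lower_width, upper_width)
    if weights is None:
        weights = np.full(y.shape[0], 1.0 / y.shape[0])
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape != (y.shape[0],):
        raise ValueError(f"weights must have shape ({y.shape[0]},), got {weights.shape}")
    lower_hinge = np.maximum(0.0, (point - lw) - y + gamma)
    upper_hinge = np.maximum(0.0, y - (point + uw) + gamma)
    return float(weights @ (lower_hinge + upper_hinge).sum(axis=1))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _interval_forward(net: MLP, x: np.ndarray, m: int, n_levels: int):
    """Forward the interval network; widths reshaped to (n, 2, m, K)."""
    out, cache = net.forward(x)
    return out.reshape(-1, 2, m, n_levels), cache


def _rmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((a - b) ** 2)))


def _interval_epoch(
    f_net: MLP,
    g_net: MLP,
    adam_g: Adam,
    xg: np.ndarray,
    yg: np.ndarray,
    k_alpha: int,
    alpha: float,
    config: "LbCConfig",
    order: np.ndarray,
) -> None:
    """One epoch of interval-network updates at a fixed confidence level,
    predictor frozen. Gradients use the sigmoid-product surrogate for the
    coverage indicator; the lambda penalties are exact subgradients."""
    m = yg.shape[1]
    n_levels = len(config.confidence_levels)
    bs = config.batch_size
    t = config.indicator_temperature
    for start in range(0, len(order) - bs + 1, bs):
        b = order[start : start + bs]
        xb, yb = xg[b], yg[b]
        yhat = f_net.forward(xb)[0]
        widths, cache = _interval_forward(g_net, xb, m, n_levels)
        lw = widths[:, 0, :, k_alpha]
        uw = widths[:, 1, :, k_alpha]
        lower = yhat - lw
        upper = yhat + uw
        a_sig = expit(t * (yb - lower))
        b_sig = expit(t * (upper - yb))
        coverage = float((a_sig * b_sig).mean())
        nm = yb.size
        cov_sign = np.sign(coverage - alpha)
        g_lw = (
            cov_sign * t * a_sig * (1.0 - a_sig) * b_sig
            + config.lambda1 * np.sign(yb - lower)
        ) / nm
        g_uw = (
            cov_sign * t * a_sig * b_sig * (1.0 - b_sig)
            + config.lambda2 * np.sign(upper - yb)
        ) / nm
        grad_full = np.zeros_like(widths)
        grad_full[:, 0, :, k_alpha] = g_lw
        grad_full[:, 1, :, k_alpha] = g_uw
        adam_g.step(
            g_net.parameters(), g_net.backward(cache, grad_full.reshape(len(b), -1))
        )


def train_lbc(
    train_data: RegressionDataset,
    config: LbCConfig | None = None,
    validation_data: RegressionDataset | None = None,
) -> TrainedEmulator:
    """Fit predictor and interval estimator by alternating optimisation.

    Features and responses are min-max normalised to [0, 1] internally
    (the hinge margin and interval penalties are defined on that scale).
    Each outer iteration draws a single confidence level alpha uniformly
    from the grid, trains the predictor for ``epochs_predictor_per_iter``
    epochs against the frozen intervals at that alpha, then trains the
    interval network for ``epochs_interval_per_iter`` epochs against the
    frozen predictor, both with Adam. Under ``disjoint_halves`` the
    training rows are split 50/50 once (seeded) and each network sees
    only its own half.
    """
    config = config or LbCConfig()
    n = train_data.n_samples
    if n < 2 * config.batch_size:
        raise ValueError(
            f"need at least {2 * config.batch_size} samples for batch size "
            f"{config.batch_size}, got {n}"
        )
    norm_data, norm_state = normalize_dataset(train_data)
    x_all = norm_data.features
    y_all = norm_data.responses
    d = x_all.shape[1]
    m = y_all.shape[1]
    levels = np.asarray(config.confidence_levels)
    n_levels = levels.size

    ss = np.random.SeedSequence(config.seed)
    rng_init_f, rng_init_g, rng_split, rng_train = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    # optional validation carve-out: tracks held-out RMSE, restores the
    # best iterate at the end, and stops early once patience (if any)
    # is exhausted
    monitor = config.monitor_validation or config.early_stopping_patience is not None
    val_x = val_y = None
    if validation_data is not None:
        val_x = norm_state.normalize_features(validation_data.features)
        val_y = norm_state.normalize_responses(validation_data.responses)
    elif monitor:
        n_val = max(1, int(round(config.val_fraction * n)))
        perm = rng_split.permutation(n)
        val_idx, fit_idx = perm[:n_val], perm[n_val:]
        val_x, val_y = x_all[val_idx], y_all[val_idx]
        x_all, y_all = x_all[fit_idx], y_all[fit_idx]
        n = x_all.shape[0]

    if config.data_split_mode == "disjoint_halves":
        perm = rng_split.permutation(n)
        half = n // 2
        idx_f, idx_g = perm[:half], perm[half:]
    else:
        idx_f = idx_g = np.arange(n)
    xf, yf = x_all[idx_f], y_all[idx_f]
    xg, yg = x_all[idx_g], y_all[idx_g]

    spec_f, spec_g = select_architecture(n, d, m, n_levels)
    if config.hidden_widths is not None:
        spec_f.hidden_widths = list(config.hidden_widths)
        spec_g.hidden_widths = list(config.hidden_widths)
    f_net = MLP(spec_f, rng_init_f)
    g_net = MLP(spec_g, rng_init_g)
    adam_f = Adam(f_net.parameters(), lr=config.lr_predictor)
    adam_g = Adam(g_net.parameters(), lr=config.lr_interval)

    bs = config.batch_size
    history: list[dict] = []
    best_val = np.inf
    best_state: tuple | None = None
    stale = 0

    for it in range(config.outer_iterations):
        if config.lr_schedule == "cosine":
            frac_done = it / max(config.outer_iterations - 1, 1)
            scale = 0.1 + 0.9 * 0.5 * (1.0 + np.cos(np.pi * frac_done))
            adam_f.lr = config.lr_predictor * scale
        k_alpha = int(rng_train.integers(n_levels))
        alpha = float(levels[k_alpha])

        # --- predictor update (interval network frozen) ---
        for _ in range(config.epochs_predictor_per_iter):
            order = rng_train.permutation(len(xf))
            for start in range(0, len(order) - bs + 1, bs):
                b = order[start : start + bs]
                xb, yb = xf[b], yf[b]
                widths = _interval_forward(g_net, xb, m, n_levels)[0]
                lw = widths[:, 0, :, k_alpha]
                uw = widths[:, 1, :, k_alpha]
                w = sample_weights(lw, uw)
                yhat, cache = f_net.forward(xb)
                low_active = ((yhat - lw) - yb + config.gamma) > 0.0
                up_active = (yb - (yhat + uw) + config.gamma) > 0.0
                grad = w[:, None] * (
                    low_active.astype(np.float64) - up_active.astype(np.float64)
                )
                adam_f.step(f_net.parameters(), f_net.backward(cache, grad))

        # --- interval update (predictor frozen) ---
        for _ in range(config.epochs_interval_per_iter):
            _interval_epoch(
                f_net, g_net, adam_g, xg, yg, k_alpha, alpha, config,
                rng_train.permutation(len(xg)),
            )

        # --- bookkeeping on the training partitions ---
        widths_g = _interval_forward(g_net, xg, m, n_levels)[0]
        lwg, uwg = widths_g[:, 0, :, k_alpha], widths_g[:, 1, :, k_alpha]
        yhat_g = f_net.forward(xg)[0]
        cal = calibration_loss(
            yg, yhat_g, lwg, uwg, alpha, config.lambda1, config.lambda2, hard=True
        )
        widths_f = _interval_forward(g_net, xf, m, n_levels)[0]
        lwf, uwf = widths_f[:, 0, :, k_alpha], widths_f[:, 1, :, k_alpha]
        yhat_f = f_net.forward(xf)[0]
        pl = predictor_loss(
            yf, yhat_f, lwf, uwf, config.gamma, sample_weights(lwf, uwf)
        )
        if not (np.isfinite(cal) and np.isfinite(pl)):
            raise RuntimeError(
                f"non-finite loss at iteration {it} (predictor {pl}, calibration {cal}); "
                "reduce the learning rates or check the input scaling"
            )
        record = {
            "iteration": it,
            "alpha": alpha,
            "predictor_loss": pl,
            "calibration_loss": cal,
        }
        logger.info(
            "iter %4d  alpha %.2f  L_f %.5f  L_g %.5f", it, alpha, pl, cal
        )
        if val_x is not None and (it + 1) % config.eval_every == 0:
            val_pred = f_net.forward(val_x)[0]
            val_rmse = _rmse(val_pred, val_y)
            # selection uses MAE: robust to the skewed noise the method
            # targets, where RMSE would favour mean-biased iterates
            val_mae = float(np.mean(np.abs(val_pred - val_y)))
            record["val_rmse"] = val_rmse
            record["val_mae"] = val_mae
            logger.info("iter %4d  held-out RMSE %.5f  MAE %.5f", it, val_rmse, val_mae)
            if val_mae < best_val - 1e-6:
                best_val = val_mae
                best_state = (f_net.get_state(), g_net.get_state())
                stale = 0
            else:
                stale += 1
                if (
                    config.early_stopping_patience is not None
                    and stale >= config.early_stopping_patience
                ):
                    history.append(record)
                    logger.info("early stop at iteration %d", it)
                    break
        history.append(record)

    if best_state is not None:
        f_net.set_state(best_state[0])
        g_net.set_state(best_state[1])

    # calibration refinement: with the predictor frozen at its final
    # (or restored) state, let the interval heads converge to it
    for it in range(config.final_interval_iterations):
        k_alpha = it % n_levels
        _interval_epoch(
            f_net, g_net, adam_g, xg, yg, k_alpha, float(levels[k_alpha]),
            config, rng_train.permutation(len(xg)),
        )

    return TrainedEmulator(
        predictor=f_net,
        interval_net=g_net,
        normalization=norm_state,
        config=config,
        loss_history=history,
    )


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def predict(emulator: TrainedEmulator, features: np.ndarray) -> np.ndarray:
    """Point predictions in original response units; evaluates only the
    predictor network, deterministically."""
    x = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if x.shape[1] != emulator.normalization.kept_features.size:
        raise ValueError(
            f"expected {emulator.normalization.kept_features.size} features, "
            f"got {x.shape[1]}"
        )
    xn = emulator.normalization.normalize_features(x)
    yhat = emulator.predictor.forward(xn)[0]
    return denormalize_predictions(yhat, emulator.normalization)


def predict_intervals(
    emulator: TrainedEmulator,
    features: np.ndarray,
    alpha: float | None = None,
) -> IntervalBundle:
    """Point predictions plus interval widths in original response units.

    ``alpha``, when given, must be one of the emulator's trained
    confidence levels (there is no interpolation between heads); the
    returned bundle always carries every level, and ``bundle.interval(alpha)``
    selects one.
    """
    levels = emulator.config.confidence_levels
    if alpha is not None and not any(abs(a - alpha) < 1e-9 for a in levels):
        raise ValueError(
            f"confidence level {alpha} was not trained; choose one of {list(levels)}"
        )
    x = np.atleast_2d(np.asarray(features, dtype=np.float64))
    xn = emulator.normalization.normalize_features(x)
    m = emulator.n_responses
    n_levels = len(levels)
    yhat = emulator.predictor.forward(xn)[0]
    widths = _interval_forward(emulator.interval_net, xn, m, n_levels)[0]
    lw = widths[:, 0]  # (n, m, K)
    uw = widths[:, 1]
    return IntervalBundle(
        point=denormalize_predictions(yhat, emulator.normalization),
        lower_width=emulator.normalization.denormalize_widths(lw),
        upper_width=emulator.normalization.denormalize_widths(uw),
        levels=tuple(levels),
    )


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_emulator(emulator: TrainedEmulator, directory: str | Path) -> None:
    """Write config, normalisation state and both parameter sets to a
    directory; the round trip reproduces predictions bit-for-bit on the
    same platform."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "config": asdict(emulator.config),
        "normalization": emulator.normalization.to_dict(),
        "predictor_spec": {
            "input_dim": emulator.predictor.spec.input_dim,
            "hidden_widths": emulator.predictor.spec.hidden_widths,
            "output_dim": emulator.predictor.spec.output_dim,
        },
        "interval_spec": {
            "input_dim": emulator.interval_net.spec.input_dim,
            "hidden_widths": emulator.interval_net.spec.hidden_widths,
            "output_dim": emulator.interval_net.spec.output_dim,
        },
    }
    (directory / "emulator.json").write_text(json.dumps(meta, indent=2))
    (directory / "loss_history.json").write_text(json.dumps(emulator.loss_history))
    np.savez(directory / "predictor.npz", **emulator.predictor.get_state())
    np.savez(directory / "interval.npz", **emulator.interval_net.get_state())


def load_emulator(directory: str | Path) -> TrainedEmulator:
    directory = Path(directory)
    meta = json.loads((directory / "emulator.json").read_text())
    cfg = meta["config"]
    cfg["confidence_levels"] = tuple(cfg["confidence_levels"])
    if cfg.get("hidden_widths") is not None:
        cfg["hidden_widths"] = tuple(cfg["hidden_widths"])
    config = LbCConfig(**cfg)
    rng = np.random.default_rng(0)  # immediately overwritten by saved state
    f_net = MLP(NetworkSpec(**meta["predictor_spec"]), rng)
    g_net = MLP(
        NetworkSpec(**meta["interval_spec"], output_transform="softplus"), rng
    )
    with np.load(directory / "predictor.npz") as st:
        f_net.set_state(dict(st))
    with np.load(directory / "interval.npz") as st:
        g_net.set_state(dict(st))
    history = json.loads((directory / "loss_history.json").read_text())
    return TrainedEmulator(
        predictor=f_net,
        interval_net=g_net,
        normalization=NormalizationState.from_dict(meta["normalization"]),
        config=config,
        loss_history=history,
    )
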