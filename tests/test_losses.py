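"""Unit tests for the calibration and hinge losses against independent
nested-loop oracles, plus the architecture-selection rule."""

import numpy as np
import pytest

from lbcreg import (
    LbCConfig,
    calibration_loss,
    predictor_loss,
    sample_weights,
    select_architecture,
    smooth_indicator,
)


# ---------------------------------------------------------------------------
# scalar-loop oracles, written independently of the vectorised code
# ---------------------------------------------------------------------------

def oracle_calibration_loss(y, point, lw, uw, alpha, lam1, lam2, temp, hard):
    n, m = y.shape
    cov = 0.0
    pen1 = 0.0
    pen2 = 0.0
    for i in range(n):
        for j in range(m):
            lo = point[i][j] - lw[i][j]
            hi = point[i][j] + uw[i][j]
            if hard:
                cov += 1.0 if (lo <= y[i][j] <= hi) else 0.0
            else:
                s1 = 1.0 / (1.0 + np.exp(-temp * (y[i][j] - lo)))
                s2 = 1.0 / (1.0 + np.exp(-temp * (hi - y[i][j])))
                cov += s1 * s2
            pen1 += abs(y[i][j] - lo)
            pen2 += abs(hi - y[i][j])
    nm = n * m
    return abs(alpha - cov / nm) + lam1 * pen1 / nm + lam2 * pen2 / nm


def oracle_predictor_loss(y, point, lw, uw, gamma, w):
    total = 0.0
    for i in range(y.shape[0]):
        inner = 0.0
        for j in range(y.shape[1]):
            inner += max(0.0, (point[i][j] - lw[i][j]) - y[i][j] + gamma)
            inner += max(0.0, y[i][j] - (point[i][j] + uw[i][j]) + gamma)
        total += w[i] * inner
    return total


def _random_batch(rng):
    n = int(rng.integers(1, 33))
    m = int(rng.integers(1, 5))
    y = rng.normal(0.5, 0.4, (n, m))
    point = rng.normal(0.5, 0.4, (n, m))
    lw = rng.uniform(0, 0.5, (n, m))
    uw = rng.uniform(0, 0.5, (n, m))
    return y, point, lw, uw


@pytest.mark.parametrize("hard", [True, False])
def test_calibration_loss_matches_loop_oracle(rng, hard):
    for _ in range(50):
        y, point, lw, uw = _random_batch(rng)
        alpha = float(rng.uniform(0.05, 0.99))
        got = calibration_loss(y, point, lw, uw, alpha, 0.05, 0.05, 50.0, hard=hard)
        want = oracle_calibration_loss(y, point, lw, uw, alpha, 0.05, 0.05, 50.0, hard)
        assert got == pytest.approx(want, abs=1e-8)


def test_predictor_loss_matches_loop_oracle(rng):
    for _ in range(50):
        y, point, lw, uw = _random_batch(rng)
        w = rng.uniform(0, 1, y.shape[0])
        w /= w.sum()
        got = predictor_loss(y, point, lw, uw, 0.05, w)
        want = oracle_predictor_loss(y, point, lw, uw, 0.05, w)
        assert got == pytest.approx(want, abs=1e-8)


# ---------------------------------------------------------------------------
# hand-computed examples
# ---------------------------------------------------------------------------

def test_calibration_loss_hand_example():
    # two samples, widths 1: coverage term 0 at alpha=0.5 (one in, one
    # out), size penalties 0.05*mean(1,11) + 0.05*mean(1,9) = 0.55
    y = np.array([[0.0], [10.0]])
    point = np.zeros((2, 1))
    w = np.ones((2, 1))
    assert calibration_loss(y, point, w, w, 0.5, 0.05, 0.05, hard=True) == pytest.approx(0.55)


def test_calibration_loss_point_interval_at_its_center():
    y = np.array([[0.3]])
    zero = np.zeros((1, 1))
    got = calibration_loss(y, y.copy(), zero, zero, 0.99, 0.05, 0.05, hard=True)
    assert got == pytest.approx(0.01)


def test_predictor_loss_hand_example():
    got = predictor_loss(
        np.array([[0.6]]), np.array([[0.0]]),
        np.array([[0.5]]), np.array([[0.5]]),
        gamma=0.05, weights=np.array([1.0]),
    )
    assert got == pytest.approx(0.15)


def test_predictor_loss_zero_iff_margin_satisfied(rng):
    # inside with slack >= gamma on both sides -> exactly zero
    y = rng.uniform(0.3, 0.7, (12, 2))
    lw = np.full((12, 2), 0.2)
    uw = np.full((12, 2), 0.2)
    assert predictor_loss(y, y.copy(), lw, uw, gamma=0.1) == 0.0
    # shrink one side below the margin -> strictly positive
    uw[3, 1] = 0.05
    assert predictor_loss(y, y.copy(), lw, uw, gamma=0.1) > 0.0


def test_loss_shape_mismatch_raises():
    y = np.zeros((3, 2))
    bad = np.zeros((3, 1))
    with pytest.raises(ValueError, match="shape"):
        calibration_loss(y, bad, y, y, 0.5)
    with pytest.raises(ValueError, match="shape"):
        predictor_loss(y, y, bad, y)


# ---------------------------------------------------------------------------
# smooth indicator
# ---------------------------------------------------------------------------

def test_smooth_indicator_properties():
    assert smooth_indicator(0.5, 0.0, 1.0, 50.0) > 0.99
    assert smooth_indicator(0.0, 0.0, 0.0, 50.0) == pytest.approx(0.25)
    assert smooth_indicator(-1.0, 0.0, 1.0, 50.0) < 0.01
    with pytest.raises(ValueError):
        smooth_indicator(0.0, 0.0, 1.0, temperature=0.0)


def test_smooth_indicator_converges_to_hard(rng):
    y = rng.uniform(-1, 2, 500)
    lo, hi = 0.0, 1.0
    clear = (np.abs(y - lo) >= 0.1) & (np.abs(y - hi) >= 0.1)
    hard = ((y >= lo) & (y <= hi)).astype(float)
    smooth = smooth_indicator(y, lo, hi, temperature=100.0)
    assert np.all(np.abs(smooth[clear] - hard[clear]) < 1e-3)


def test_coverage_term_bounded_by_worst_case(rng):
    # |alpha - coverage| can never exceed max(alpha, 1 - alpha)
    for _ in range(20):
        y, point, lw, uw = _random_batch(rng)
        alpha = float(rng.uniform(0.05, 0.99))
        loss = calibration_loss(y, point, lw, uw, alpha, 0.0, 0.0, hard=True)
        assert loss <= max(alpha, 1.0 - alpha) + 1e-12


def test_hard_coverage_monotone_under_widening(rng):
    y, point, lw, uw = _random_batch(rng)
    base = calibration_loss(y, point, lw, uw, 0.99, 0.0, 0.0, hard=True)
    wider = calibration_loss(y, point, lw + 0.3, uw + 0.3, 0.99, 0.0, 0.0, hard=True)
    # coverage only grows, so the gap to alpha=0.99 cannot grow
    assert wider <= base + 1e-12


# ---------------------------------------------------------------------------
# sample weights
# ---------------------------------------------------------------------------

def test_sample_weights_normalisation(rng):
    lw = rng.uniform(0, 1, (10, 3))
    uw = rng.uniform(0, 1, (10, 3))
    w = sample_weights(lw, uw)
    assert w.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.all(w >= 0)


def test_sample_weights_hand_example():
    lw = np.array([[0.5], [1.5]])
    uw = np.array([[0.5], [1.5]])
    assert sample_weights(lw, uw) == pytest.approx([0.25, 0.75])


def test_sample_weights_equal_widths_uniform():
    lw = np.full((8, 2), 0.3)
    w = sample_weights(lw, lw)
    assert w == pytest.approx(np.full(8, 1 / 8))


def test_sample_weights_all_zero_warns_uniform():
    z = np.zeros((4, 1))
    with pytest.warns(UserWarning, match="uniform"):
        w = sample_weights(z, z)
    assert w == pytest.approx(np.full(4, 0.25))


# ---------------------------------------------------------------------------
# architecture selection
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "n,d,m,k,hidden,interval_out",
    [
        (10_000, 5, 15, 6, [64, 128, 512, 256, 32], 180),
        (1030, 8, 1, 6, [64, 256, 32], 12),
        (4999, 1, 1, 1, [64, 256, 32], 2),
        (5000, 1, 1, 1, [64, 128, 512, 256, 32], 2),
    ],
)
def test_select_architecture_rule(n, d, m, k, hidden, interval_out):
    pred, interval = select_architecture(n, d, m, k)
    assert pred.hidden_widths == hidden
    assert interval.hidden_widths == hidden
    assert pred.output_dim == m
    assert interval.output_dim == interval_out == 2 * m * k
    assert pred.output_transform == "identity"
    assert interval.output_transform == "softplus"


def test_select_architecture_rejects_nonpositive():
    with pytest.raises(ValueError):
        select_architecture(0, 1, 1, 1)
    with pytest.raises(ValueError):
        select_architecture(100, 1, 0, 6)


# ---------------------------------------------------------------------------
# config validation
# ---------------------------------------------------------------------------

def test_config_defaults_match_published_recipe():
    cfg = LbCConfig()
    assert cfg.confidence_levels == (0.1, 0.3, 0.5, 0.7, 0.9, 0.99)
    assert cfg.lambda1 == cfg.lambda2 == 0.05
    assert cfg.gamma == 0.05
    assert cfg.lr_predictor == 1e-5
    assert cfg.lr_interval == 1e-4
    assert cfg.batch_size == 8
    assert (cfg.epochs_predictor_per_iter, cfg.epochs_interval_per_iter) == (2, 1)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"confidence_levels": (0.5, 0.3)},
        {"confidence_levels": (0.0, 0.5)},
        {"confidence_levels": ()},
        {"lambda1": -0.1},
        {"gamma": -1.0},
        {"lr_predictor": 0.0},
        {"batch_size": 0},
        {"data_split_mode": "thirds"},
        {"lr_schedule": "linear"},
    ],
)
def test_config_rejects_invalid(kwargs):
    with pytest.raises(ValueError):
        LbCConfig(**kwargs)
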