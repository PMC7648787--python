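"""Data loading, normalisation bookkeeping, run configs and the CLI."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import lbcreg as L
from lbcreg.cli import main as cli_main
from lbcreg.interface import RunConfig


# ---------------------------------------------------------------------------
# load_tabular
# ---------------------------------------------------------------------------

def test_load_csv_and_tsv_identical(tmp_path):
    frame = pd.DataFrame({"x": [0.1, 0.2, 0.3], "y": [1.0, 2.0, 3.0]})
    csv = tmp_path / "d.csv"
    tsv = tmp_path / "d.tsv"
    frame.to_csv(csv, index=False)
    frame.to_csv(tsv, index=False, sep="\t")
    a = L.load_tabular(csv, target_columns=["y"])
    b = L.load_tabular(tsv, target_columns=["y"])
    assert a.n_samples == 3 and a.n_features == 1 and a.n_responses == 1
    assert np.array_equal(a.features, b.features)
    assert np.array_equal(a.responses, b.responses)
    assert a.feature_names == ["x"] and a.response_names == ["y"]


def test_load_drops_malformed_rows(tmp_path):
    path = tmp_path / "d.csv"
    path.write_text("x,y\n1,2\nbad,3\n4,\n5,6\n")
    with pytest.warns(UserWarning, match="2 row"):
        ds = L.load_tabular(path, target_columns=["y"])
    assert ds.n_samples == 2
    assert ds.responses[:, 0] == pytest.approx([2.0, 6.0])


def test_load_errors(tmp_path):
    path = tmp_path / "d.csv"
    path.write_text("x,y\n1,2\n")
    with pytest.raises(ValueError, match="z"):
        L.load_tabular(path, target_columns=["z"])
    with pytest.raises(ValueError, match="w"):
        L.load_tabular(path, target_columns=["y"], feature_columns=["w"])
    bad = tmp_path / "empty.csv"
    bad.write_text("x,y\nnan,2\n")
    with pytest.warns(UserWarning):
        with pytest.raises(ValueError, match="usable"):
            L.load_tabular(bad, target_columns=["y"])
    with pytest.raises(FileNotFoundError):
        L.load_tabular(tmp_path / "missing.csv", target_columns=["y"])


def test_explicit_feature_selection(tmp_path):
    frame = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0], "y": [0.0, 1.0]})
    path = tmp_path / "d.csv"
    frame.to_csv(path, index=False)
    ds = L.load_tabular(path, target_columns=["y"], feature_columns=["b"])
    assert ds.feature_names == ["b"]
    assert ds.features[:, 0] == pytest.approx([3.0, 4.0])


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def test_normalize_affine_map(rng):
    y = np.array([[10.0], [20.0], [30.0]])
    x = rng.uniform(0, 1, (3, 1))
    ds = L.RegressionDataset(features=x, responses=y)
    normed, state = L.normalize_dataset(ds)
    assert normed.responses[:, 0] == pytest.approx([0.0, 0.5, 1.0])
    assert state.denormalize_responses(np.array([[0.5]]))[0, 0] == pytest.approx(20.0)


def test_normalize_round_trip(rng):
    ds = L.RegressionDataset(
        features=rng.uniform(-5, 7, (40, 3)),
        responses=rng.normal(0, 10, (40, 2)),
    )
    normed, state = L.normalize_dataset(ds)
    assert normed.features.min() >= 0 and normed.features.max() <= 1
    back = state.denormalize_responses(normed.responses)
    assert back == pytest.approx(ds.responses, abs=1e-12)
    assert L.denormalize_predictions(normed.responses, state) == pytest.approx(
        ds.responses, abs=1e-12
    )


def test_constant_feature_dropped_with_warning(rng):
    x = np.column_stack([rng.uniform(0, 1, 20), np.full(20, 7.0)])
    ds = L.RegressionDataset(features=x, responses=rng.uniform(0, 1, (20, 1)))
    with pytest.warns(UserWarning, match="constant"):
        normed, state = L.normalize_dataset(ds)
    assert normed.n_features == 1
    assert list(state.kept_features) == [0]


def test_constant_response_rejected(rng):
    ds = L.RegressionDataset(
        features=rng.uniform(0, 1, (10, 1)), responses=np.full((10, 1), 2.0)
    )
    with pytest.raises(ValueError, match="constant response"):
        L.normalize_dataset(ds)


def test_dataset_validation(rng):
    with pytest.raises(ValueError, match="equal length"):
        L.RegressionDataset(features=np.zeros((3, 1)), responses=np.zeros((2, 1)))
    with pytest.raises(ValueError, match="finite"):
        L.RegressionDataset(
            features=np.array([[np.nan]]), responses=np.array([[1.0]])
        )


# ---------------------------------------------------------------------------
# run config
# ---------------------------------------------------------------------------

def test_run_config_yaml_round_trip(tmp_path):
    cfg = RunConfig(command="train", methods=["lbc"], seed=7,
                    method_overrides={"outer_iterations": 50})
    cfg.to_yaml(tmp_path / "run.yaml")
    again = RunConfig.from_yaml(tmp_path / "run.yaml")
    assert again == cfg


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

@pytest.fixture
def runner():
    return CliRunner()


def test_cli_simulate_round_trip(runner, tmp_path):
    out = tmp_path / "d.csv"
    result = runner.invoke(cli_main, [
        "simulate", "--n", "200", "--positive-fraction", "0.9",
        "--seed", "7", "--out", str(out),
    ])
    assert result.exit_code == 0, result.output
    frame = pd.read_csv(out)
    assert list(frame.columns) == ["x", "y", "y_clean"]
    assert len(frame) == 200
    meta = out.with_suffix(".csv.meta.txt").read_text()
    assert "positive_fraction = 0.9" in meta and "seed = 7" in meta
    # reloading reproduces the in-memory dataset
    ds = L.generate_synthetic_1d(200, L.NoiseSpec(positive_fraction=0.9), seed=7)
    loaded = L.load_tabular(out, target_columns=["y"], feature_columns=["x"])
    assert loaded.responses[:, 0] == pytest.approx(ds.responses[:, 0])


def test_cli_train_predict_report(runner, tmp_path):
    data = tmp_path / "d.csv"
    runner.invoke(cli_main, ["simulate", "--n", "150", "--seed", "3",
                             "--out", str(data)])
    run_dir = tmp_path / "run"
    result = runner.invoke(cli_main, [
        "train", "--method", "lbc", "--data", str(data), "--targets", "y",
        "--features", "x",
        "--set", "outer_iterations=5,hidden_widths=[16],batch_size=8",
        "--seed", "1", "--out", str(run_dir),
    ])
    assert result.exit_code == 0, result.output
    assert (run_dir / "run_config.yaml").exists()
    assert (run_dir / "model" / "emulator.json").exists()
    assert (run_dir / "loss_history.csv").exists()

    pred_csv = tmp_path / "pred.csv"
    result = runner.invoke(cli_main, [
        "predict", "--model", str(run_dir), "--data", str(data),
        "--targets", "y,y_clean", "--alpha", "0.9", "--out", str(pred_csv),
    ])
    assert result.exit_code == 0, result.output
    pred = pd.read_csv(pred_csv)
    assert {"yhat0", "lower0", "upper0"} <= set(pred.columns)
    assert (pred.upper0 >= pred.lower0).all()

    result = runner.invoke(cli_main, [
        "report", "--model", str(run_dir), "--data", str(data),
        "--targets", "y", "--features", "x",
    ])
    assert result.exit_code == 0, result.output
    assert "alpha=0.99" in result.output
    assert "mean |coverage - alpha|" in result.output


def test_cli_evaluate_writes_tables(runner, tmp_path):
    data = tmp_path / "d.csv"
    runner.invoke(cli_main, ["simulate", "--n", "120", "--seed", "5",
                             "--out", str(data)])
    out_dir = tmp_path / "eval"
    result = runner.invoke(cli_main, [
        "evaluate", "--methods", "rf,gbt", "--data", str(data),
        "--targets", "y", "--features", "x", "--k", "3", "--seeds", "1,2",
        "--set", "n_trees=5", "--out", str(out_dir),
    ])
    assert result.exit_code == 0, result.output
    agg = pd.read_csv(out_dir / "aggregated.csv")
    assert set(agg.method) == {"rf", "gbt"}
    per_fold = pd.read_csv(out_dir / "per_fold.csv")
    assert len(per_fold) == 2 * 3 * 2  # methods x folds x seeds
    assert (out_dir / "summary.txt").exists()


def test_cli_unknown_subcommand(runner):
    result = runner.invoke(cli_main, ["frobnicate"])
    assert result.exit_code != 0
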