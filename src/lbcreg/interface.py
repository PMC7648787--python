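"""Data plumbing: dataset container, min-max normalisation bookkeeping,
delimited-text loading, and run configuration.

Normalisation matters more here than in ordinary regression packages:
the calibration margin ``gamma`` and the interval-size penalties
``lambda1/lambda2`` are absolute thresholds, so training always operates
on responses min-max scaled to [0, 1] per dimension and the state needed
to undo that map travels with every trained model.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("lbcreg")


# ---------------------------------------------------------------------------
# dataset container
# ---------------------------------------------------------------------------

@dataclass
class RegressionDataset:
    """Tabular regression sample {(x_i, y_i)}.

    ``clean_responses`` is populated only by the synthetic generators and
    holds the noise-free function values, so that benchmarks can score
    recovery of the true function rather than of the noisy observations.
    """

    features: np.ndarray
    responses: np.ndarray
    clean_responses: np.ndarray | None = None
    feature_names: list[str] = field(default_factory=list)
    response_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, dtype=np.float64))
        self.responses = np.asarray(self.responses, dtype=np.float64)
        if self.responses.ndim == 1:
            self.responses = self.responses[:, None]
        if self.clean_responses is not None:
            self.clean_responses = np.asarray(self.clean_responses, dtype=np.float64)
            if self.clean_responses.ndim == 1:
                self.clean_responses = self.clean_responses[:, None]
            if self.clean_responses.shape != self.responses.shape:
                raise ValueError("clean_responses shape must match responses")
        if self.features.shape[0] != self.responses.shape[0]:
            raise ValueError(
                f"features ({self.features.shape[0]} rows) and responses "
                f"({self.responses.shape[0]} rows) must have equal length"
            )
        if self.features.shape[0] < 1:
            raise ValueError("dataset must contain at least one row")
        if not np.isfinite(self.features).all() or not np.isfinite(self.responses).all():
            raise ValueError("dataset contains non-finite values")
        if not self.feature_names:
            self.feature_names = [f"x{j}" for j in range(self.features.shape[1])]
        if not self.response_names:
            self.response_names = [f"y{j}" for j in range(self.responses.shape[1])]

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_responses(self) -> int:
        return self.responses.shape[1]

    def subset(self, idx: np.ndarray) -> "RegressionDataset":
        return RegressionDataset(
            features=self.features[idx],
            responses=self.responses[idx],
            clean_responses=None if self.clean_responses is None else self.clean_responses[idx],
            feature_names=list(self.feature_names),
            response_names=list(self.response_names),
        )


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

@dataclass
class NormalizationState:
    """Per-dimension min/max for features and responses.

    ``kept_features`` records which feature columns survived (constant
    columns are dropped); the maps are affine so round trips are exact up
    to floating-point rounding.
    """

    feature_min: np.ndarray
    feature_max: np.ndarray
    response_min: np.ndarray
    response_max: np.ndarray
    kept_features: np.ndarray  # indices into the original feature columns

    def normalize_features(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        x = x[:, self.kept_features] if x.shape[1] != self.feature_min.size else x
        return (x - self.feature_min) / (self.feature_max - self.feature_min)

    def normalize_responses(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=np.float64)
        if y.ndim == 1:
            y = y[:, None]
        return (y - self.response_min) / (self.response_max - self.response_min)

    def denormalize_responses(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=np.float64)
        return y * (self.response_max - self.response_min) + self.response_min

    def denormalize_widths(self, w: np.ndarray) -> np.ndarray:
        """Interval widths scale by the response range only (no offset)."""
        span = self.response_max - self.response_min
        if w.ndim == 3:  # (n, m, levels)
            return w * span[None, :, None]
        return w * span

    def to_dict(self) -> dict:
        return {k: np.asarray(v).tolist() for k, v in dataclasses.asdict(self).items()}

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationState":
        return cls(
            feature_min=np.asarray(d["feature_min"], dtype=np.float64),
            feature_max=np.asarray(d["feature_max"], dtype=np.float64),
            response_min=np.asarray(d["response_min"], dtype=np.float64),
            response_max=np.asarray(d["response_max"], dtype=np.float64),
            kept_features=np.asarray(d["kept_features"], dtype=np.int64),
        )


def normalize_dataset(data: RegressionDataset) -> tuple[RegressionDataset, NormalizationState]:
    """Min-max map every feature and response dimension to [0, 1].

    Constant feature columns carry no information under an affine map and
    are dropped with a warning; a constant response dimension is an error
    because the inverse map would be undefined.
    """
    fmin = data.features.min(axis=0)
    fmax = data.features.max(axis=0)
    keep = np.flatnonzero(fmax > fmin)
    if keep.size == 0:
        raise ValueError("all feature columns are constant")
    if keep.size < data.n_features:
        dropped = [data.feature_names[j] for j in range(data.n_features) if j not in set(keep)]
        warnings.warn(f"dropping constant feature columns: {dropped}")
        logger.warning("dropping constant feature columns: %s", dropped)
    rmin = data.responses.min(axis=0)
    rmax = data.responses.max(axis=0)
    const = np.flatnonzero(rmax <= rmin)
    if const.size:
        names = [data.response_names[j] for j in const]
        raise ValueError(f"constant response dimension(s): {names}")
    state = NormalizationState(
        feature_min=fmin[keep],
        feature_max=fmax[keep],
        response_min=rmin,
        response_max=rmax,
        kept_features=keep,
    )
    normalized = RegressionDataset(
        features=state.normalize_features(data.features[:, keep]),
        responses=state.normalize_responses(data.responses),
        clean_responses=None
        if data.clean_responses is None
        else state.normalize_responses(data.clean_responses),
        feature_names=[data.feature_names[j] for j in keep],
        response_names=list(data.response_names),
    )
    return normalized, state


def denormalize_predictions(yhat: np.ndarray, state: NormalizationState) -> np.ndarray:
    """Map model-scale predictions back to the original response units."""
    return state.denormalize_responses(yhat)


# ---------------------------------------------------------------------------
# delimited-text loading
# ---------------------------------------------------------------------------

def load_tabular(
    path: str | Path,
    target_columns: list[str],
    feature_columns: list[str] | str = "all-but-targets",
) -> RegressionDataset:
    """Load a CSV/TSV file (delimiter sniffed) into a :class:`RegressionDataset`.

    Columns are selected by name. Rows with missing or non-numeric entries
    in any selected column are dropped and the count is logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path, sep=None, engine="python")
    if not target_columns:
        raise ValueError("at least one target column must be named")
    missing = [c for c in target_columns if c not in df.columns]
    if missing:
        raise ValueError(f"target column(s) not found in {path.name}: {missing}")
    if feature_columns == "all-but-targets":
        feature_columns = [c for c in df.columns if c not in set(target_columns)]
    else:
        missing = [c for c in feature_columns if c not in df.columns]
        if missing:
            raise ValueError(f"feature column(s) not found in {path.name}: {missing}")
    if not feature_columns:
        raise ValueError("no feature columns remain after excluding targets")
    cols = list(feature_columns) + list(target_columns)
    numeric = df[cols].apply(pd.to_numeric, errors="coerce")
    ok = numeric.notna().all(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("%s: dropped %d row(s) with missing/non-numeric entries", path.name, n_dropped)
        warnings.warn(f"{path.name}: dropped {n_dropped} row(s) with missing/non-numeric entries")
    numeric = numeric[ok]
    if numeric.empty:
        raise ValueError(f"{path.name}: no usable rows after dropping invalid entries")
    return RegressionDataset(
        features=numeric[feature_columns].to_numpy(dtype=np.float64),
        responses=numeric[target_columns].to_numpy(dtype=np.float64),
        feature_names=list(feature_columns),
        response_names=list(target_columns),
    )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Serialisable description of one CLI run; written to every output
    directory so any run can be reproduced from its artefacts."""

    command: str = ""
    data_path: str | None = None
    target_columns: list[str] = field(default_factory=list)
    methods: list[str] = field(default_factory=lambda: ["lbc"])
    method_overrides: dict = field(default_factory=dict)
    cv_folds: int = 5
    cv_seeds: list[int] = field(default_factory=lambda: [1, 2, 3])
    output_dir: str = "."
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)
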