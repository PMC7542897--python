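"""Tabular I/O, model persistence, and the repeated-run experiment driver.

Feature tables are plain CSV/TSV with samples in rows, numeric features in
columns and one categorical label column.  Expression matrices shipped
genes-by-samples can be transposed on load.  Features are min-max scaled to
[0, 1] by default (fitted on training data only): raw omics scales would
pin the sigmoid hidden layer to its saturated tails.

A fitted model is persisted as a single ``.npz`` archive holding the hidden
map arrays, the output weights, the class codebook and a JSON blob of the
hyperparameters; weights round-trip bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import Dataset
from .hidden import HiddenLayerMap
from .baselines import OutputWeights
from .metrics import MetricReport, classification_metrics
from .model import CSRGELMParams, TrainedELM, fit, predict

__all__ = [
    "RunConfig",
    "load_table",
    "MinMaxNormalizer",
    "save_model",
    "load_model",
    "run_experiment",
]

logger = logging.getLogger(__name__)

METHODS = ("relm", "l21rfelm", "lr21elm", "csrgelm")


def load_table(path: str | Path, label_column: str, transpose: bool = False) -> Dataset:
    """Read a CSV/TSV feature table into a Dataset.

    The dialect is chosen by extension (``.tsv``/``.tab`` -> tab separated,
    anything else comma separated).  The class codebook is the sorted set of
    label values, fixed at load time so one-hot columns and argmax
    tie-breaking are reproducible.  Non-numeric feature cells are rejected
    with a row/column-addressed error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    if transpose:
        # features-in-rows orientation: first column holds row names
        df = pd.read_csv(path, sep=sep, index_col=0).T
        df.columns = [str(c) for c in df.columns]
        df = df.reset_index(drop=True)
    else:
        df = pd.read_csv(path, sep=sep)
    if label_column not in df.columns:
        raise KeyError(
            f"label column {label_column!r} not found in {path.name} "
            f"(columns: {list(df.columns)[:10]}...)"
        )
    labels = df[label_column].astype(str).to_numpy()
    features = df.drop(columns=[label_column])
    for col in features.columns:
        numeric = pd.to_numeric(features[col], errors="coerce")
        if numeric.isna().to_numpy().any() and not features[col].isna().to_numpy().any():
            row = int(np.flatnonzero(numeric.isna().to_numpy())[0])
            raise ValueError(
                f"non-numeric feature cell at row {row}, column {col!r}: "
                f"{features[col].iloc[row]!r}"
            )
        features[col] = numeric
    classes = tuple(sorted(set(labels.tolist())))
    if len(classes) < 2:
        raise ValueError("label column contains a single class")
    codes = {c: k for k, c in enumerate(classes)}
    y = np.asarray([codes[v] for v in labels], dtype=int)
    return Dataset(X=features.to_numpy(dtype=float), y=y, classes=classes)


class MinMaxNormalizer:
    """Per-feature min-max scaling to [0, 1], fitted on training data only.

    Constant features map to 0.  Test-set values outside the training range
    are clipped implicitly by the affine map (they may fall outside [0, 1],
    which the sigmoid tolerates).
    """

    def fit(self, X: np.ndarray) -> "MinMaxNormalizer":
        X = np.asarray(X, dtype=float)
        self.min_ = X.min(axis=0)
        span = X.max(axis=0) - self.min_
        span[span == 0] = 1.0
        self.span_ = span
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.min_) / self.span_


def save_model(model: TrainedELM, path: str | Path) -> Path:
    """Persist a fitted model to a single .npz archive (bit-exact arrays)."""
    path = Path(path)
    if dataclasses.is_dataclass(model.params):
        params_blob = json.dumps(dataclasses.asdict(model.params))
        params_kind = type(model.params).__name__
    else:
        params_blob = json.dumps(model.params or {})
        params_kind = "dict"
    np.savez(
        path,
        input_weights=model.hidden.input_weights,
        biases=model.hidden.biases,
        hidden_seed=np.asarray(model.hidden.seed),
        beta=model.weights.beta,
        method=np.asarray(model.weights.method),
        n_iterations=np.asarray(model.weights.n_iterations),
        converged=np.asarray(model.weights.converged),
        classes=np.asarray([str(c) for c in model.classes]),
        classes_json=np.asarray(json.dumps(list(model.classes))),
        params_json=np.asarray(params_blob),
        params_kind=np.asarray(params_kind),
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_model(path: str | Path) -> TrainedELM:
    """Inverse of :func:`save_model`; predictions round-trip bit-exactly."""
    with np.load(Path(path), allow_pickle=False) as archive:
        hidden = HiddenLayerMap(
            input_weights=archive["input_weights"],
            biases=archive["biases"],
            seed=int(archive["hidden_seed"]),
        )
        weights = OutputWeights(
            beta=archive["beta"],
            method=str(archive["method"]),
            n_iterations=int(archive["n_iterations"]),
            converged=bool(archive["converged"]),
        )
        classes = tuple(json.loads(str(archive["classes_json"])))
        params = json.loads(str(archive["params_json"]))
        if str(archive["params_kind"]) == "CSRGELMParams":
            params = CSRGELMParams(**params)
    return TrainedELM(hidden=hidden, weights=weights, classes=classes, params=params)


@dataclass
class RunConfig:
    """Everything needed to re-execute an experiment exactly."""

    method: str = "csrgelm"
    input_path: str = ""
    label_column: str = "label"
    output_dir: str = "runs"
    normalize: bool = True
    transpose: bool = False
    test_size: float = 0.25
    n_repeats: int = 1
    seed: int = 0
    resample_splits: bool = False
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


def _train_test_split(y: np.ndarray, test_size: float, seed: int):
    """Stratified index split, deterministic given seed."""
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        members = rng.permutation(members)
        n_test = max(1, int(round(test_size * members.size)))
        test_idx.append(members[:n_test])
        train_idx.append(members[n_test:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def run_experiment(config: RunConfig, dataset: Dataset | None = None) -> dict:
    """Repeat fit/predict ``n_repeats`` times and aggregate the macro metrics.

    Each repeat draws a fresh hidden map from a seed derived from
    ``config.seed`` (the customary protocol for randomized-feature models);
    the stratified train/test split stays fixed unless
    ``config.resample_splits`` is set.  Writes to ``config.output_dir``:

    * ``metrics.csv`` — one row per repeat plus mean and variance rows,
    * ``objective_trace.csv`` — per-iteration objective of the last repeat
      (iterative methods only),
    * ``beta_row_norms.csv`` — output-weight row norms of the last repeat,
      the data behind weight-distribution histograms,
    * ``run_log.json`` — every resolved parameter, sufficient to re-run.

    Returns a dict with the per-repeat reports and the aggregate table.
    """
    if dataset is None:
        dataset = load_table(config.input_path, config.label_column,
                             transpose=config.transpose)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    seeds = [int(s) for s in
             np.random.SeedSequence(config.seed).generate_state(config.n_repeats)
             % (2**31)]
    rows, reports, last_model = [], [], None
    for r, run_seed in enumerate(seeds):
        split_seed = run_seed if config.resample_splits else seeds[0]
        train_idx, test_idx = _train_test_split(dataset.y, config.test_size,
                                                split_seed)
        X_train, X_test = dataset.X[train_idx], dataset.X[test_idx]
        if config.normalize:
            scaler = MinMaxNormalizer().fit(X_train)
            X_train, X_test = scaler.transform(X_train), scaler.transform(X_test)
        model = fit(X_train, dataset.y[train_idx], method=config.method,
                    seed=run_seed, classes=tuple(range(dataset.n_classes)),
                    **config.hyperparameters)
        report = classification_metrics(dataset.y[test_idx],
                                        predict(model, X_test))
        reports.append(report)
        rows.append({"repeat": r, "seed": run_seed, **report.as_dict()})
        last_model = model

    frame = pd.DataFrame(rows)
    metric_cols = ["accuracy", "precision", "recall", "f_measure"]
    summary = pd.DataFrame([
        {"repeat": "mean", "seed": "", **frame[metric_cols].mean().to_dict()},
        {"repeat": "variance", "seed": "",
         **(frame[metric_cols].var(ddof=1) if len(frame) > 1
            else frame[metric_cols].iloc[0] * 0).to_dict()},
    ])
    table = pd.concat([frame, summary], ignore_index=True)
    table.to_csv(out / "metrics.csv", index=False, float_format="%.10g")

    if last_model.weights.objective_trace:
        pd.DataFrame({
            "iteration": range(len(last_model.weights.objective_trace)),
            "objective": last_model.weights.objective_trace,
        }).to_csv(out / "objective_trace.csv", index=False, float_format="%.10g")
    row_norms = np.linalg.norm(last_model.weights.beta, axis=1)
    pd.DataFrame({"hidden_node": range(row_norms.size), "row_norm": row_norms}
                 ).to_csv(out / "beta_row_norms.csv", index=False,
                          float_format="%.10g")

    log = dataclasses.asdict(config)
    log["derived_seeds"] = seeds
    log["n_samples"] = dataset.n_samples
    log["n_features"] = dataset.n_features
    log["classes"] = [str(c) for c in dataset.classes]
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    logger.info("experiment written to %s", out)
    return {"reports": reports, "table": table, "last_model": last_model}
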