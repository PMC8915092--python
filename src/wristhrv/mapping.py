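"""Wrist-to-reference heart-rate mapping: model zoo, tuning, evaluation.

A wrist optical sensor systematically misestimates heart rate relative to
a chest-strap reference.  This stage learns the correction as a supervised
regression from paired (wrist, reference) samples: eight model families —
multinomial logistic regression (integer bpm treated as categories),
k-nearest neighbours, decision tree, random forest, AdaBoost, ordinary
linear regression, and two small recurrent nets (RNN, LSTM) over sliding
windows — tuned by 5-fold cross-validated grid search on negated MSE, and
compared by held-out test RMSE in bpm.

The train/test split is stratified by subject as a chronological 75/25
prefix/suffix so the contiguous test segment of each subject still
supports HRV computation downstream.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostRegressor, RandomForestRegressor
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.tree import DecisionTreeRegressor

from .nnets import LSTMRegressor, RNNRegressor
from .stats import rmse

__all__ = [
    "ALGORITHMS",
    "PairedDataset",
    "ModelSpec",
    "MappingReport",
    "default_model_specs",
    "split_train_test",
    "kfold_cv",
    "grid_search",
    "fit_predict",
    "evaluate_models",
]

ALGORITHMS = (
    "multinomial_logistic",
    "knn",
    "decision_tree",
    "random_forest",
    "adaboost",
    "linear_regression",
    "rnn",
    "lstm",
)

#: Fixed training settings for the recurrent nets.
NET_SETTINGS = {
    "batch_size": 64,
    "epochs": 15,
    "optimizer": "adam",
    "learning_rate": 0.1,
    "beta1": 0.5,  # Adam first-moment decay, standing in for "momentum"
    "dropout": 0.2,
    "window": 10,
}


@dataclass
class PairedDataset:
    """Time-aligned (wrist, reference) HR samples with subject labels."""

    wrist_hr: np.ndarray
    reference_hr: np.ndarray
    subject_ids: np.ndarray
    timestamps: np.ndarray
    split_assignment: np.ndarray | None = None  # "train" / "test" per row

    def __post_init__(self) -> None:
        self.wrist_hr = np.asarray(self.wrist_hr, dtype=float)
        self.reference_hr = np.asarray(self.reference_hr, dtype=float)
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        n = self.wrist_hr.size
        if not (self.reference_hr.size == self.subject_ids.size == self.timestamps.size == n):
            raise ValueError("all PairedDataset columns must have equal length")

    def __len__(self) -> int:
        return int(self.wrist_hr.size)

    @classmethod
    def from_frames(cls, frames: Sequence[pd.DataFrame]) -> "PairedDataset":
        """Stack per-subject alignment frames (from ``align_pair``)."""
        df = pd.concat(frames, ignore_index=True)
        return cls(
            wrist_hr=df["wrist_hr"].to_numpy(),
            reference_hr=df["reference_hr"].to_numpy(),
            subject_ids=df["subject_id"].to_numpy(),
            timestamps=df["timestamp"].to_numpy(),
        )

    def rows(self, which: str) -> "PairedDataset":
        if self.split_assignment is None:
            raise ValueError("dataset has no split assignment; call split_train_test first")
        mask = self.split_assignment == which
        return PairedDataset(
            wrist_hr=self.wrist_hr[mask],
            reference_hr=self.reference_hr[mask],
            subject_ids=self.subject_ids[mask],
            timestamps=self.timestamps[mask],
        )


@dataclass(frozen=True)
class ModelSpec:
    """An algorithm plus its hyperparameter grid and fixed settings."""

    algorithm: str
    hyperparameter_grid: Mapping[str, Sequence] = field(default_factory=dict)
    fixed_settings: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if not self.hyperparameter_grid and self.algorithm != "linear_regression":
            raise ValueError(f"{self.algorithm} requires a non-empty hyperparameter grid")

    def grid_points(self) -> list[dict]:
        if not self.hyperparameter_grid:
            return [{}]
        names = list(self.hyperparameter_grid)
        return [
            dict(zip(names, combo))
            for combo in itertools.product(*(self.hyperparameter_grid[n] for n in names))
        ]


def default_model_specs(algorithms: Sequence[str] = ALGORITHMS) -> list[ModelSpec]:
    """The eight default model families with their tuning grids."""
    grids = {
        "multinomial_logistic": {"C": [0.1, 1.0]},
        "knn": {"n_neighbors": [3, 5, 7, 11]},
        "decision_tree": {"max_depth": [3, 5, 10, None]},
        "random_forest": {"n_estimators": [50, 100, 200]},
        "adaboost": {"n_estimators": [25, 50, 100]},
        "linear_regression": {},
        "rnn": {"hidden_units": [8, 16]},
        "lstm": {"hidden_units": [8, 16]},
    }
    return [
        ModelSpec(a, grids[a], NET_SETTINGS if a in ("rnn", "lstm") else {})
        for a in algorithms
    ]


@dataclass(frozen=True)
class MappingReport:
    """Per-algorithm tuning results and test RMSE, sorted ascending."""

    entries: list[dict]  # {algorithm, best_hyperparameters, cv_score, test_rmse}
    failed: dict[str, str]
    winner: str

    def to_json(self, path: str | Path) -> None:
        payload = {"entries": self.entries, "failed": self.failed, "winner": self.winner}
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


# ---------------------------------------------------------------------------
# Splitting


def split_train_test(
    dataset: PairedDataset, train_fraction: float = 0.75, seed: int = 0
) -> PairedDataset:
    """Assign a chronological 75/25 prefix/suffix split per subject.

    Every subject contributes rows to both halves; fractions land within
    one row of the target.  ``seed`` is accepted for interface symmetry —
    the chronological split is deterministic.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1) so both halves are non-empty")
    split = np.empty(len(dataset), dtype=object)
    for subject in pd.unique(dataset.subject_ids):
        idx = np.flatnonzero(dataset.subject_ids == subject)
        if idx.size < 4:
            raise ValueError(f"subject {subject!r} has only {idx.size} rows; need >= 4")
        order = idx[np.argsort(dataset.timestamps[idx], kind="stable")]
        n_train = int(round(train_fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        split[order[:n_train]] = "train"
        split[order[n_train:]] = "test"
    return replace(dataset, split_assignment=split)


# ---------------------------------------------------------------------------
# Model wrappers (uniform fit/predict over subject-aware inputs)


class _SklearnMapper:
    def __init__(self, model, classify: bool = False):
        self.model = model
        self.classify = classify

    def fit(self, x, y, subjects=None):
        X = np.asarray(x, dtype=float).reshape(-1, 1)
        if self.classify:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                self.model.fit(X, np.round(np.asarray(y)).astype(int))
        else:
            self.model.fit(X, np.asarray(y, dtype=float))
        return self

    def predict(self, x, subjects=None):
        return np.asarray(self.model.predict(np.asarray(x, dtype=float).reshape(-1, 1)),
                          dtype=float)


class _NetMapper:
    """Sliding-window wrapper: per-subject windows, min-max scaling, sigmoid head."""

    def __init__(self, algorithm: str, hidden_units: int, settings: Mapping, seed: int):
        cls = LSTMRegressor if algorithm == "lstm" else RNNRegressor
        self.window = int(settings.get("window", NET_SETTINGS["window"]))
        self.net = cls(
            hidden_units,
            epochs=int(settings.get("epochs", 15)),
            batch_size=int(settings.get("batch_size", 64)),
            learning_rate=float(settings.get("learning_rate", 0.1)),
            beta1=float(settings.get("beta1", 0.5)),
            dropout=float(settings.get("dropout", 0.2)),
            seed=seed,
        )
        self.x_min = self.x_max = self.y_min = self.y_max = None

    def _windows(self, x: np.ndarray, subjects) -> np.ndarray:
        """Left-padded per-subject sliding windows, one per sample."""
        x = np.asarray(x, dtype=float)
        if subjects is None:
            subjects = np.zeros(x.size)
        subjects = np.asarray(subjects)
        out = np.empty((x.size, self.window))
        for subject in pd.unique(subjects):
            idx = np.flatnonzero(subjects == subject)
            xs = x[idx]
            padded = np.concatenate([np.full(self.window - 1, xs[0]), xs])
            for j in range(xs.size):
                out[idx[j]] = padded[j:j + self.window]
        return out

    def _scale_x(self, w):
        span = self.x_max - self.x_min
        return (w - self.x_min) / span if span > 0 else np.zeros_like(w)

    def fit(self, x, y, subjects=None):
        y = np.asarray(y, dtype=float)
        self.x_min, self.x_max = float(np.min(x)), float(np.max(x))
        self.y_min, self.y_max = float(np.min(y)), float(np.max(y))
        w = self._scale_x(self._windows(x, subjects))
        span = self.y_max - self.y_min
        ty = (y - self.y_min) / span if span > 0 else np.zeros_like(y)
        self.net.fit(w, ty)
        return self

    def predict(self, x, subjects=None):
        w = self._scale_x(self._windows(x, subjects))
        ty = self.net.predict(w)
        return ty * (self.y_max - self.y_min) + self.y_min

    @property
    def history(self):
        return self.net.history


def _build_mapper(spec: ModelSpec, hp: Mapping, seed: int):
    a = spec.algorithm
    if a == "multinomial_logistic":
        return _SklearnMapper(
            LogisticRegression(C=float(hp.get("C", 1.0)), max_iter=200), classify=True
        )
    if a == "knn":
        return _SklearnMapper(KNeighborsRegressor(n_neighbors=int(hp.get("n_neighbors", 5))))
    if a == "decision_tree":
        return _SklearnMapper(
            DecisionTreeRegressor(max_depth=hp.get("max_depth"), random_state=seed)
        )
    if a == "random_forest":
        return _SklearnMapper(
            RandomForestRegressor(n_estimators=int(hp.get("n_estimators", 100)),
                                  random_state=seed, n_jobs=1)
        )
    if a == "adaboost":
        return _SklearnMapper(
            AdaBoostRegressor(n_estimators=int(hp.get("n_estimators", 50)), random_state=seed)
        )
    if a == "linear_regression":
        return _SklearnMapper(LinearRegression())
    if a in ("rnn", "lstm"):
        settings = dict(spec.fixed_settings)
        if a == "rnn":
            settings["dropout"] = 0.0  # dropout regularises the LSTM stack only
        return _NetMapper(a, int(hp.get("hidden_units", 16)), settings, seed)
    raise ValueError(a)  # pragma: no cover


# ---------------------------------------------------------------------------
# Tuning and evaluation


def kfold_cv(
    spec: ModelSpec,
    hp: Mapping,
    train: PairedDataset,
    k: int = 5,
    seed: int = 0,
) -> float:
    """Mean negated MSE over k shuffled folds (larger is better)."""
    n = len(train)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot run {k}-fold CV on {n} rows")
    scores = []
    for fit_idx, val_idx in KFold(n_splits=k, shuffle=True, random_state=seed).split(
        np.arange(n)
    ):
        mapper = _build_mapper(spec, hp, seed)
        mapper.fit(train.wrist_hr[fit_idx], train.reference_hr[fit_idx],
                   train.subject_ids[fit_idx])
        pred = mapper.predict(train.wrist_hr[val_idx], train.subject_ids[val_idx])
        scores.append(-float(np.mean((pred - train.reference_hr[val_idx]) ** 2)))
    return float(np.mean(scores))


def grid_search(
    spec: ModelSpec,
    train: PairedDataset,
    k: int = 5,
    seed: int = 0,
) -> dict:
    """Exhaustive grid search on CV negated MSE; ties keep the first point."""
    best_hp, best_score = None, -np.inf
    for hp in spec.grid_points():
        score = kfold_cv(spec, hp, train, k=k, seed=seed)
        if score > best_score:
            best_hp, best_score = hp, score
    return {"best_hyperparameters": best_hp, "best_score": best_score}


def fit_predict(
    spec: ModelSpec,
    hyperparameters: Mapping,
    train: PairedDataset,
    eval_wrist_hr: np.ndarray,
    eval_subject_ids: np.ndarray | None = None,
    seed: int = 0,
):
    """Fit on the training rows and predict reference HR for eval inputs.

    Returns ``(predictions_bpm, fitted_mapper)``; the mapper exposes a
    per-epoch loss ``history`` for the recurrent nets.
    """
    mapper = _build_mapper(spec, hyperparameters, seed)
    mapper.fit(train.wrist_hr, train.reference_hr, train.subject_ids)
    pred = mapper.predict(np.asarray(eval_wrist_hr, dtype=float), eval_subject_ids)
    return pred, mapper


def evaluate_models(
    dataset: PairedDataset,
    specs: Sequence[ModelSpec] | None = None,
    k: int = 5,
    seed: int = 0,
) -> MappingReport:
    """Tune, refit and test every model family; report ascending by test RMSE.

    Requires a split assignment on ``dataset``.  Per-model failures are
    recorded in the report instead of aborting the run.
    """
    if specs is None:
        specs = default_model_specs()
    train = dataset.rows("train")
    test = dataset.rows("test")
    entries: list[dict] = []
    failed: dict[str, str] = {}
    for spec in specs:
        try:
            tuned = grid_search(spec, train, k=k, seed=seed)
            pred, _ = fit_predict(spec, tuned["best_hyperparameters"], train,
                                  test.wrist_hr, test.subject_ids, seed=seed)
            entries.append({
                "algorithm": spec.algorithm,
                "best_hyperparameters": tuned["best_hyperparameters"],
                "cv_score": tuned["best_score"],
                "test_rmse": rmse(pred, test.reference_hr),
            })
        except Exception as exc:  # keep evaluating the remaining families
            failed[spec.algorithm] = f"{type(exc).__name__}: {exc}"
    if not entries:
        raise RuntimeError(f"every model failed: {failed}")
    entries.sort(key=lambda e: e["test_rmse"])
    return MappingReport(entries=entries, failed=failed, winner=entries[0]["algorithm"])
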