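"""Model registry, evaluation protocols and gain-based explainability.

Five classical classifiers are exposed behind one registry (the
gradient-boosting model with 100 trees is the reference configuration).
Evaluation follows the benchmark protocol: repeated stratified 5-fold
cross-validation (10 repeats), leave-one-donor-out cross-validation, a
learning curve over stratified training fractions, and recursive channel
ablation that always keeps the stain-free brightfield channel.  Explanations
come from the in-model *gain*: the total loss improvement contributed by a
feature's splits divided by the number of those splits.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import entropy as _scipy_entropy
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix, f1_score
from sklearn.model_selection import (
    RepeatedStratifiedKFold,
    StratifiedShuffleSplit,
)
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .core_data import BRIGHTFIELD, CellRecord
from .features import FeatureTable, extract_features, full_inventory
from .selection import SelectionConfig, impute_median, preselect

logger = logging.getLogger(__name__)

MODEL_KINDS = (
    "logistic-regression",
    "linear-discriminant",
    "linear-SVM",
    "random-forest",
    "gradient-boosting",
)


@dataclass
class ModelSpec:
    kind: str = "gradient-boosting"
    n_trees: int = 100
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")

    def build(self):
        hp = dict(self.hyperparameters)
        if self.kind == "logistic-regression":
            return LogisticRegression(max_iter=2000, random_state=self.seed, **hp)
        if self.kind == "linear-discriminant":
            return LinearDiscriminantAnalysis(**hp)
        if self.kind == "linear-SVM":
            return SVC(
                kernel="linear", probability=True, random_state=self.seed, **hp
            )
        if self.kind == "random-forest":
            return RandomForestClassifier(
                n_estimators=self.n_trees, random_state=self.seed, n_jobs=1, **hp
            )
        return XGBClassifier(
            n_estimators=self.n_trees,
            random_state=self.seed,
            verbosity=0,
            n_jobs=1,
            **hp,
        )


@dataclass
class FittedModel:
    """A fitted estimator plus the label vocabulary and feature names."""

    spec: ModelSpec
    estimator: object
    classes: tuple
    feature_names: tuple


def fit(spec: ModelSpec, X: pd.DataFrame, y: Sequence) -> FittedModel:
    """Fit a model; X must be imputed (no NaN) beforehand."""
    X = pd.DataFrame(X)
    if X.isna().any().any():
        raise ValueError("X contains missing values; impute upstream")
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least two classes in y")
    est = spec.build()
    if spec.kind == "gradient-boosting":
        codes = np.searchsorted(classes, y)
        est.fit(X, codes)
    else:
        est.fit(X, y)
    return FittedModel(
        spec=spec,
        estimator=est,
        classes=tuple(classes),
        feature_names=tuple(X.columns),
    )


def predict_proba(model: FittedModel, X: pd.DataFrame) -> pd.DataFrame:
    """Class-probability simplex rows, columns ordered by class name."""
    X = pd.DataFrame(X)[list(model.feature_names)]
    probs = model.estimator.predict_proba(X)
    return pd.DataFrame(probs, index=X.index, columns=list(model.classes))


def predict(model: FittedModel, X: pd.DataFrame) -> np.ndarray:
    probs = predict_proba(model, X)
    return probs.columns.to_numpy()[np.argmax(probs.to_numpy(), axis=1)]


def predict_with_entropy(
    model: FittedModel, X: pd.DataFrame
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Predicted class, probability rows and Shannon entropy (nats)."""
    probs = predict_proba(model, X)
    ent = _scipy_entropy(probs.to_numpy(), axis=1)
    cls = probs.columns.to_numpy()[np.argmax(probs.to_numpy(), axis=1)]
    return cls, probs, ent


def f1_macro(y_true: Sequence, y_pred: Sequence) -> float:
    """Unweighted mean of per-class F1 over classes present in either input."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0 or len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must be non-empty and equal length")
    labels = np.unique(np.concatenate([y_true, y_pred]))
    return float(
        f1_score(y_true, y_pred, labels=labels, average="macro", zero_division=0)
    )


# ---------------------------------------------------------------------------
# Evaluation protocols
# ---------------------------------------------------------------------------

@dataclass
class EvalResult:
    fold_scores: list[float]
    confusion: pd.DataFrame
    per_class_f1: pd.Series
    per_fold_labels: list | None = None

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_scores))

    @property
    def sd(self) -> float:
        return float(np.std(self.fold_scores))

    def to_dict(self) -> dict:
        return {
            "fold_scores": [float(s) for s in self.fold_scores],
            "mean": self.mean,
            "sd": self.sd,
            "per_class_f1": {k: float(v) for k, v in self.per_class_f1.items()},
            "confusion": json.loads(self.confusion.to_json()),
        }


def _fold_fit_predict(spec, X_train, y_train, X_test, selection):
    """Impute (and optionally preselect) on the training fold only."""
    med = X_train.median()
    X_train = X_train.fillna(med).fillna(0.0)
    X_test = X_test.fillna(med).fillna(0.0)
    if selection is not None:
        cols, _ = preselect(X_train, y_train, selection)
        X_train = X_train[cols]
        X_test = X_test[cols]
    model = fit(spec, X_train, y_train)
    return model, predict(model, X_test)


def repeated_stratified_cv(
    X: pd.DataFrame,
    y: Sequence,
    spec: ModelSpec,
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
    selection: SelectionConfig | None = None,
) -> EvalResult:
    """Stratified k-fold CV with repetition; imputation/selection per fold."""
    X = pd.DataFrame(X)
    y = np.asarray(y)
    classes = np.unique(y)
    splitter = RepeatedStratifiedKFold(
        n_splits=folds, n_repeats=repeats, random_state=seed
    )
    scores: list[float] = []
    pooled_true: list = []
    pooled_pred: list = []
    for i, (tr, te) in enumerate(splitter.split(X, y)):
        _, pred = _fold_fit_predict(
            spec, X.iloc[tr], y[tr], X.iloc[te], selection
        )
        scores.append(f1_macro(y[te], pred))
        if i < folds:  # first repetition: each record predicted exactly once
            pooled_true.append(y[te])
            pooled_pred.append(pred)
    yt = np.concatenate(pooled_true)
    yp = np.concatenate(pooled_pred)
    conf = pd.DataFrame(
        confusion_matrix(yt, yp, labels=classes), index=classes, columns=classes
    )
    per_class = pd.Series(
        f1_score(yt, yp, labels=classes, average=None, zero_division=0), index=classes
    )
    return EvalResult(fold_scores=scores, confusion=conf, per_class_f1=per_class)


def leave_one_donor_out_cv(
    X: pd.DataFrame,
    y: Sequence,
    donors: Sequence,
    spec: ModelSpec,
    selection: SelectionConfig | None = None,
) -> EvalResult:
    """One fold per donor; reports per-donor F1 alongside the pooled result."""
    X = pd.DataFrame(X)
    y = np.asarray(y)
    donors = np.asarray(donors)
    unique_donors = np.unique(donors)
    if len(unique_donors) < 2:
        raise ValueError("leave-one-donor-out needs at least two donors")
    classes = np.unique(y)
    scores, fold_labels = [], []
    pooled_true, pooled_pred = [], []
    for donor in unique_donors:
        te = donors == donor
        tr = ~te
        _, pred = _fold_fit_predict(spec, X[tr], y[tr], X[te], selection)
        scores.append(f1_macro(y[te], pred))
        fold_labels.append(str(donor))
        pooled_true.append(y[te])
        pooled_pred.append(pred)
    yt = np.concatenate(pooled_true)
    yp = np.concatenate(pooled_pred)
    conf = pd.DataFrame(
        confusion_matrix(yt, yp, labels=classes), index=classes, columns=classes
    )
    per_class = pd.Series(
        f1_score(yt, yp, labels=classes, average=None, zero_division=0), index=classes
    )
    return EvalResult(
        fold_scores=scores,
        confusion=conf,
        per_class_f1=per_class,
        per_fold_labels=fold_labels,
    )


# ---------------------------------------------------------------------------
# Gain importance
# ---------------------------------------------------------------------------

def gain_importance(model: FittedModel) -> pd.Series:
    """Average split gain per feature, normalized to sum to one.

    For every feature the loss improvements of all splits using it are
    summed and divided by the number of those splits; features never used
    in any split score 0.
    """
    if model.spec.kind != "gradient-boosting":
        raise TypeError("gain importance requires a gradient-boosting model")
    booster = model.estimator.get_booster()
    raw = booster.get_score(importance_type="gain")
    scores = pd.Series(0.0, index=list(model.feature_names))
    for key, value in raw.items():
        scores[key] = value
    total = scores.sum()
    if total > 0:
        scores = scores / total
    return scores


def importance_protocol(
    X: pd.DataFrame,
    y: Sequence,
    selection: SelectionConfig | None = None,
    n_repeats: int = 100,
    k_range: tuple[int, int] = (30, 200),
    folds: int = 5,
    seed: int = 0,
    spec: ModelSpec | None = None,
) -> pd.Series:
    """Median gain ranking over ``folds * n_repeats`` models.

    Each repeat draws a random pre-selection size top-k uniformly from
    ``k_range``, re-runs the pre-selection inside every training fold and
    records the per-feature gain of the resulting model.  A feature's final
    score is the median gain across the models in which it was available;
    the default protocol trains 500 models.
    """
    from sklearn.model_selection import StratifiedKFold

    X = pd.DataFrame(X)
    y = np.asarray(y)
    spec = spec or ModelSpec()
    base = selection or SelectionConfig()
    rng = np.random.default_rng(seed)
    collected: dict[str, list[float]] = {name: [] for name in X.columns}
    for rep in range(n_repeats):
        k = int(rng.integers(k_range[0], k_range[1] + 1))
        cfg = SelectionConfig(
            pearson_threshold=base.pearson_threshold,
            top_k=k,
            n_clusters=min(base.n_clusters, k),
            seed=int(rng.integers(2**31)),
            methods=base.methods,
        )
        splitter = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31))
        )
        for tr, _ in splitter.split(X, y):
            X_tr = X.iloc[tr]
            med = X_tr.median()
            X_tr = X_tr.fillna(med).fillna(0.0)
            cols, _ = preselect(X_tr, y[tr], cfg)
            model = fit(spec, X_tr[cols], y[tr])
            gains = gain_importance(model)
            for name, g in gains.items():
                collected[name].append(float(g))
    medians = pd.Series(
        {
            name: (float(np.median(vals)) if vals else 0.0)
            for name, vals in collected.items()
        }
    )
    return medians.sort_values(ascending=False, kind="stable")


# ---------------------------------------------------------------------------
# Ablations
# ---------------------------------------------------------------------------

def channel_ablation(
    records: Sequence[CellRecord],
    labels: Sequence,
    fluor_channels: Sequence[str],
    spec: ModelSpec | None = None,
    folds: int = 5,
    repeats: int = 1,
    seed: int = 0,
    t_channel: str = "CD3",
    b_channel: str = "MHCII",
    n_jobs: int = 1,
) -> dict[tuple[str, ...], EvalResult]:
    """Recursive channel elimination, always keeping brightfield.

    Evaluates every non-empty subset of the fluorescent channels (15 subsets
    for a four-fluorochrome panel).  Features are extracted once from the
    full panel and column-filtered per subset, which is equivalent to
    rebuilding the inventory because every feature references only its own
    channels.
    """
    spec = spec or ModelSpec()
    panel = [BRIGHTFIELD] + list(fluor_channels)
    inventory = full_inventory(panel)
    table = extract_features(
        records, inventory, t_channel=t_channel, b_channel=b_channel, n_jobs=n_jobs
    )
    chan_of = {e.name: set(e.channels) for e in inventory.entries}
    results: dict[tuple[str, ...], EvalResult] = {}
    for r in range(1, len(fluor_channels) + 1):
        for subset in itertools.combinations(fluor_channels, r):
            allowed = set(subset) | {BRIGHTFIELD}
            # synaptic features need both conjugate partners' channels
            cols = [
                name
                for name in table.df.columns
                if chan_of[name] <= allowed
                and not (
                    name.startswith("enrichment of")
                    and not {t_channel, b_channel} <= allowed
                )
            ]
            results[tuple(subset)] = repeated_stratified_cv(
                table.df[cols], labels, spec, folds=folds, repeats=repeats, seed=seed
            )
    return results


def learning_curve(
    X_train: pd.DataFrame,
    y_train: Sequence,
    X_test: pd.DataFrame,
    y_test: Sequence,
    spec: ModelSpec | None = None,
    fractions: Sequence[float] = tuple(np.arange(0.05, 1.0, 0.10)),
    n_repeats: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Test-set F1 for stratified subsets of the training data.

    Returns one row per fraction with mean and sd over repeats; a fraction
    of 1.0 uses the full training set once.
    """
    spec = spec or ModelSpec()
    X_train = pd.DataFrame(X_train)
    y_train = np.asarray(y_train)
    med = X_train.median()
    Xtr_full = X_train.fillna(med).fillna(0.0)
    Xte = pd.DataFrame(X_test).fillna(med).fillna(0.0)
    rows = []
    for frac in fractions:
        scores = []
        if frac >= 1.0:
            model = fit(spec, Xtr_full, y_train)
            scores.append(f1_macro(y_test, predict(model, Xte)))
        else:
            sss = StratifiedShuffleSplit(
                n_splits=n_repeats, train_size=frac, random_state=seed
            )
            for sub, _ in sss.split(Xtr_full, y_train):
                model = fit(spec, Xtr_full.iloc[sub], y_train[sub])
                scores.append(f1_macro(y_test, predict(model, Xte)))
        rows.append(
            {
                "fraction": float(frac),
                "mean_f1": float(np.mean(scores)),
                "sd_f1": float(np.std(scores)),
                "n_train": int(round(frac * len(y_train))),
            }
        )
    return pd.DataFrame(rows)
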