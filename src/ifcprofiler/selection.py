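"""Ensemble feature pre-selection.

Three stages: (1) drop one of every pair of near-duplicate features
(|Pearson| above a threshold, random representative); (2) rank the
survivors with six heterogeneous methods — mutual information, linear-SVM
weights, L1- and L2-logistic regression, random-forest importance and
gradient-boosting gain — and take the union of the per-method top-k lists;
(3) spectral-cluster the candidates on |Spearman| affinity into m clusters
and keep one random feature per cluster, which breaks residual
multicollinearity.  Every stage is seeded and logs what it kept and why.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.cluster import SpectralClustering
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import mutual_info_classif
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC
from xgboost import XGBClassifier

logger = logging.getLogger(__name__)

RANKING_METHODS = (
    "mutual_information",
    "linear_svm",
    "l1_logistic",
    "l2_logistic",
    "random_forest",
    "gradient_boosting",
)


@dataclass
class SelectionConfig:
    pearson_threshold: float = 0.95
    top_k: int = 50
    n_clusters: int = 50
    seed: int = 0
    methods: Sequence[str] = RANKING_METHODS

    def __post_init__(self) -> None:
        if not 0.0 < self.pearson_threshold <= 1.0:
            raise ValueError("pearson_threshold must be in (0, 1]")
        if self.top_k < 1 or self.n_clusters < 1:
            raise ValueError("top_k and n_clusters must be >= 1")
        unknown = set(self.methods) - set(RANKING_METHODS)
        if unknown:
            raise ValueError(f"unknown ranking methods: {sorted(unknown)}")


@dataclass
class SelectionLog:
    """Audit trail: what each stage dropped or kept."""

    constant_dropped: list = field(default_factory=list)
    correlation_dropped: list = field(default_factory=list)
    correlation_kept: list = field(default_factory=list)
    method_rankings: dict = field(default_factory=dict)
    candidates: list = field(default_factory=list)
    clusters: dict = field(default_factory=dict)
    selected: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "constant_dropped": list(self.constant_dropped),
            "correlation_dropped": list(self.correlation_dropped),
            "correlation_kept": list(self.correlation_kept),
            "method_rankings": {k: list(v) for k, v in self.method_rankings.items()},
            "candidates": list(self.candidates),
            "clusters": {str(k): list(v) for k, v in self.clusters.items()},
            "selected": list(self.selected),
        }


def impute_median(df: pd.DataFrame) -> pd.DataFrame:
    """Median imputation per feature (all-NaN columns become 0)."""
    med = df.median()
    return df.fillna(med).fillna(0.0)


def correlation_prune(
    df: pd.DataFrame,
    threshold: float = 0.95,
    seed: int = 0,
    log: SelectionLog | None = None,
) -> pd.DataFrame:
    """Remove features until no pair has |Pearson| above the threshold.

    Features are visited in a seeded random order; each visited feature is
    kept and every not-yet-visited feature correlated with it beyond the
    threshold is eliminated, so the surviving representative of a correlated
    group is random but reproducible.  Constant columns (undefined
    correlation) are dropped with a warning.
    """
    log = log if log is not None else SelectionLog()
    variances = df.var(ddof=0)
    constant = sorted(variances.index[(variances == 0) | variances.isna()])
    if constant:
        logger.warning("dropping %d constant features: %s", len(constant), constant[:5])
        log.constant_dropped = constant
        df = df.drop(columns=constant)
    if df.shape[1] == 0:
        return df
    corr = np.abs(np.atleast_2d(np.corrcoef(df.to_numpy(dtype=float), rowvar=False)))
    names = list(df.columns)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(names))
    kept: list[int] = []
    dropped: set[int] = set()
    for i in order:
        if i in dropped:
            continue
        kept.append(i)
        over = np.nonzero(corr[i] > threshold)[0]
        dropped.update(j for j in over if j != i)
    kept_names = [names[i] for i in sorted(kept)]
    log.correlation_kept = kept_names
    log.correlation_dropped = [names[i] for i in sorted(dropped)]
    return df[kept_names]


def _rank_features(
    X: np.ndarray, y: np.ndarray, names: list[str], method: str, seed: int
) -> list[str]:
    """Feature names in decreasing relevance; ties broken by name."""
    Xs = StandardScaler().fit_transform(X)
    if method == "mutual_information":
        scores = mutual_info_classif(X, y, random_state=seed)
    elif method == "linear_svm":
        model = LinearSVC(dual="auto", random_state=seed, max_iter=5000)
        model.fit(Xs, y)
        scores = np.abs(model.coef_).sum(axis=0)
    elif method == "l1_logistic":
        model = LogisticRegression(
            l1_ratio=1.0, solver="liblinear", random_state=seed, max_iter=2000
        )
        model.fit(Xs, y)
        scores = np.abs(model.coef_).sum(axis=0)
    elif method == "l2_logistic":
        model = LogisticRegression(random_state=seed, max_iter=2000)
        model.fit(Xs, y)
        scores = np.abs(model.coef_).sum(axis=0)
    elif method == "random_forest":
        model = RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
        model.fit(X, y)
        scores = model.feature_importances_
    elif method == "gradient_boosting":
        model = XGBClassifier(
            n_estimators=50,
            max_depth=4,
            random_state=seed,
            importance_type="gain",
            verbosity=0,
            n_jobs=1,
        )
        model.fit(X, pd.factorize(pd.Series(y), sort=True)[0])
        scores = model.feature_importances_
    else:
        raise ValueError(f"unknown ranking method {method!r}")
    order = sorted(range(len(names)), key=lambda i: (-scores[i], names[i]))
    return [names[i] for i in order]


def rank_union(
    df: pd.DataFrame,
    labels: Sequence,
    config: SelectionConfig,
    log: SelectionLog | None = None,
) -> list[str]:
    """Union of the six per-method top-k feature lists (inventory order)."""
    log = log if log is not None else SelectionLog()
    names = list(df.columns)
    k = config.top_k
    if k > len(names):
        logger.warning("top_k=%d exceeds %d features; clamping", k, len(names))
        k = len(names)
    X = df.to_numpy(dtype=float)
    y = np.asarray(labels)
    union: set[str] = set()
    for method in config.methods:
        ranking = _rank_features(X, y, names, method, config.seed)
        log.method_rankings[method] = ranking
        union.update(ranking[:k])
    candidates = [n for n in names if n in union]
    log.candidates = candidates
    return candidates


def decorrelate_by_clustering(
    df: pd.DataFrame,
    n_clusters: int,
    seed: int = 0,
    log: SelectionLog | None = None,
) -> list[str]:
    """Spectral clustering on |Spearman| affinity; one random pick/cluster."""
    log = log if log is not None else SelectionLog()
    names = list(df.columns)
    if len(names) <= n_clusters:
        logger.warning(
            "only %d candidates for %d clusters; keeping all", len(names), n_clusters
        )
        log.selected = names
        return names
    rho = spearmanr(df.to_numpy(dtype=float)).statistic
    rho = np.atleast_2d(rho)
    affinity = np.abs(np.nan_to_num(rho, nan=0.0))
    np.fill_diagonal(affinity, 1.0)
    clustering = SpectralClustering(
        n_clusters=n_clusters, affinity="precomputed", random_state=seed
    )
    labels = clustering.fit_predict(affinity)
    rng = np.random.default_rng(seed)
    selected = []
    for c in range(n_clusters):
        members = [names[i] for i in np.nonzero(labels == c)[0]]
        log.clusters[c] = members
        if members:
            selected.append(members[rng.integers(len(members))])
    selected = [n for n in names if n in set(selected)]
    log.selected = selected
    return selected


def preselect(
    table: pd.DataFrame,
    labels: Sequence,
    config: SelectionConfig | None = None,
) -> tuple[list[str], SelectionLog]:
    """Full pipeline: prune -> rank union -> spectral decorrelation."""
    config = config or SelectionConfig()
    log = SelectionLog()
    df = impute_median(table)
    df = correlation_prune(df, config.pearson_threshold, config.seed, log)
    candidates = rank_union(df, labels, config, log)
    selected = decorrelate_by_clustering(
        df[candidates], config.n_clusters, config.seed, log
    )
    return selected, log
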