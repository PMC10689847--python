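"""Functional-readout regression from aggregated synapse features.

A downstream functional measurement (e.g. the frequency of Granzyme-B
positive T cells after 24 h) exists once per donor x condition, while the
imaging features exist per record.  Following a multiple-instance design,
records predicted as synapses (with or without signaling) are pooled per
donor x condition and each feature is aggregated with its 5th, 50th and
95th percentile, capturing the extremes and the average of the population.
A sparse linear model (L1-penalized least-angle regression, LassoLars) is
then trained under leave-one-donor-out or condition-holdout cross-validation
and feature importance is read from the coefficient magnitudes on the
standardized scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.linear_model import LassoLars, LassoLarsCV
from sklearn.model_selection import LeaveOneOut

logger = logging.getLogger(__name__)

SYNAPSE_CLASSES = ("synapse w/o signaling", "synapse w/ signaling")
AGG_PERCENTILES = (5, 50, 95)


def select_synapse_population(predictions: pd.DataFrame) -> pd.Index:
    """Record ids predicted as a synapse (with or without signaling)."""
    mask = predictions["predicted_class"].isin(SYNAPSE_CLASSES)
    return predictions.index[mask]


@dataclass
class AggregatedProfile:
    """donor x condition rows; ``feature (Pth perc.)`` columns."""

    table: pd.DataFrame  # MultiIndex (donor_id, condition)
    n_images: pd.Series

    @property
    def feature_columns(self) -> list[str]:
        return list(self.table.columns)


def aggregate(
    features: pd.DataFrame,
    meta: pd.DataFrame,
    feature_subset: Sequence[str] | None = None,
    percentiles: Sequence[int] = AGG_PERCENTILES,
) -> AggregatedProfile:
    """Percentile-aggregate record-level features per donor x condition.

    ``feature_subset`` is typically the cross-donor consistent features from
    a difference map.  Missing record values are ignored within a group; a
    feature missing everywhere in a group stays NaN.  Groups with no records
    are simply absent; aggregation is permutation-invariant by construction.
    """
    cols = list(feature_subset) if feature_subset is not None else list(features.columns)
    missing = [c for c in cols if c not in features.columns]
    if missing:
        raise KeyError(f"features absent from table: {missing[:5]}")
    meta = meta.loc[features.index]
    rows = {}
    counts = {}
    for (donor, cond), grp in features[cols].groupby(
        [meta["donor_id"], meta["condition"]], sort=True
    ):
        if len(grp) == 0:
            logger.warning("empty group %s/%s dropped", donor, cond)
            continue
        agg = {}
        for c in cols:
            vals = grp[c].dropna().to_numpy(dtype=float)
            for p in percentiles:
                agg[f"{c} ({p}th perc.)"] = (
                    float(np.percentile(vals, p)) if len(vals) else np.nan
                )
        rows[(donor, cond)] = agg
        counts[(donor, cond)] = len(grp)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index = pd.MultiIndex.from_tuples(table.index, names=["donor_id", "condition"])
    return AggregatedProfile(
        table=table, n_images=pd.Series(counts, name="n_images")
    )


@dataclass
class FunctionalModel:
    coefficients: pd.Series  # standardized scale, full-data fit
    coefficients_raw: pd.Series  # original feature scale
    intercept: float
    predictions: pd.Series  # pooled held-out predictions
    observed: pd.Series
    spearman: float

    @property
    def ranking(self) -> pd.Series:
        """Features by decreasing |coefficient| (standardized scale)."""
        return self.coefficients.reindex(
            self.coefficients.abs().sort_values(ascending=False, kind="stable").index
        )

    @property
    def active_set(self) -> list[str]:
        return [c for c, v in self.coefficients.items() if v != 0.0]


def _fit_lars(X: np.ndarray, y: np.ndarray, alpha: float | None, seed: int = 0):
    if np.std(y) == 0:
        model = LassoLars(alpha=np.inf)
        model.coef_ = np.zeros(X.shape[1])
        model.intercept_ = float(np.mean(y))
        return model
    if alpha is not None:
        model = LassoLars(alpha=alpha)
    else:
        # few samples: pick the L1 strength by inner leave-one-out over the path
        model = LassoLarsCV(cv=LeaveOneOut(), max_iter=500)
    model.fit(X, y)
    return model


def _standardize(train: pd.DataFrame, test: pd.DataFrame):
    mu = train.mean()
    sd = train.std(ddof=0).replace(0.0, 1.0)
    return (train - mu) / sd, (test - mu) / sd, mu, sd


def _prepare(table: pd.DataFrame) -> pd.DataFrame:
    df = table.copy()
    df = df.dropna(axis=1, how="all")
    return df.fillna(df.median())


def _cv_core(
    table: pd.DataFrame,
    y: pd.Series,
    fold_masks: list[np.ndarray],
    alpha: float | None,
) -> FunctionalModel:
    if len(table) < 2:
        raise ValueError("need at least two aggregated rows")
    X = _prepare(table)
    y = y.loc[X.index].astype(float)
    preds = pd.Series(np.nan, index=X.index)
    for test_mask in fold_masks:
        if not test_mask.any() or test_mask.all():
            continue
        Xtr, Xte, _, _ = _standardize(X[~test_mask], X[test_mask])
        model = _fit_lars(Xtr.to_numpy(), y[~test_mask].to_numpy(), alpha)
        preds[test_mask] = model.predict(Xte.to_numpy())
    done = preds.notna()
    rho = (
        float(spearmanr(preds[done], y[done]).statistic) if done.sum() >= 2 else np.nan
    )
    # final coefficients: full-data fit on standardized columns
    Xs, _, mu, sd = _standardize(X, X)
    final = _fit_lars(Xs.to_numpy(), y.to_numpy(), alpha)
    coef = pd.Series(final.coef_, index=X.columns)
    return FunctionalModel(
        coefficients=coef,
        coefficients_raw=coef / sd,
        intercept=float(final.intercept_),
        predictions=preds[done],
        observed=y[done],
        spearman=rho,
    )


def fit_predict_lodo(
    profile: AggregatedProfile,
    y: pd.Series,
    alpha: float | None = None,
) -> FunctionalModel:
    """Leave-one-donor-out CV: standardization and fitting never see the
    held-out donor's rows; reports pooled Spearman rho and |coef| ranking."""
    table = profile.table
    donors = table.index.get_level_values("donor_id")
    uniq = sorted(set(donors))
    if len(uniq) < 3:
        raise ValueError("leave-one-donor-out needs at least three donors")
    masks = [np.asarray(donors == d) for d in uniq]
    return _cv_core(table, y, masks, alpha)


def fit_predict_condition_holdout(
    profile: AggregatedProfile,
    y: pd.Series,
    rotating_conditions: Sequence[str],
    alpha: float | None = None,
) -> FunctionalModel:
    """Condition-rotation CV: each rotating condition (e.g. one activator
    antibody) is predicted from a model trained on all remaining conditions
    (the controls plus the other activators), across all donors."""
    table = profile.table
    conds = table.index.get_level_values("condition")
    masks = []
    for c in rotating_conditions:
        mask = np.asarray(conds == c)
        if not mask.any():
            raise ValueError(f"condition {c!r} absent from profile")
        masks.append(mask)
    return _cv_core(table, y, masks, alpha)
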