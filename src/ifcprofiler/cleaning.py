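"""Nine-rule post-prediction data cleaning.

After the classifier has labeled every record of a donor x condition sample,
low-quality and outlier records are excluded by, in order:

1. dead cells — mean viability intensity at or above its 90th percentile;
2. out-of-focus images — brightfield gradient RMS not strictly between its
   2nd and 90th percentiles;
3. uncertain predictions — class-probability entropy > 1.0 nat;
4. predicted B-LCLs with mean MHCII below its 5th percentile;
5. predicted B-LCLs with MHCII area below its 10th percentile;
6. predicted single T cells with mean CD3 below its 1st percentile;
7. predicted one-layer conjugates with MHCII area below its 20th percentile;
8. isolation-forest outliers on the top-importance features;
9. rare/noise records after UMAP embedding + DBSCAN clustering.

All percentile thresholds are computed on the sample being cleaned and
frozen before any rule runs; rules are applied in the listed order and the
first matching rule claims a record, so the per-rule removal sets are
disjoint and retained + removed always equals the input.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import entropy as _entropy
from sklearn.cluster import DBSCAN
from sklearn.ensemble import IsolationForest
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

T_CELL_CLASSES = ("single T cell w/o signaling", "single T cell w/ signaling")
B_LCL_CLASS = "single B-LCL"
ONE_LAYER_CLASS = "B-LCL and T cell in one layer"


@dataclass
class CleaningParams:
    viability_feature: str = "mean intensity of Live/Dead"
    viability_percentile: float = 90.0
    focus_feature: str = "gradient RMS of BF"
    focus_low_percentile: float = 2.0
    focus_high_percentile: float = 90.0
    entropy_threshold: float = 1.0
    mhcii_mean_feature: str = "mean intensity of MHCII"
    mhcii_mean_percentile: float = 5.0
    mhcii_area_feature: str = "area of MHCII"
    b_lcl_area_percentile: float = 10.0
    cd3_mean_feature: str = "mean intensity of CD3"
    cd3_mean_percentile: float = 1.0
    one_layer_area_percentile: float = 20.0
    iso_n_estimators: int = 100
    iso_max_samples: str | int = "auto"
    iso_contamination: str | float = "auto"
    iso_max_features: int = 20
    dbscan_eps: float = 0.09
    dbscan_min_samples: int = 5
    min_cluster_frequency: float = 1e-4
    umap_n_neighbors: int = 15
    umap_min_dist: float = 0.1
    top_features: Sequence[str] | None = None  # top-30 gain features for rules 8-9


@dataclass
class RuleOutcome:
    rule: int
    description: str
    parameters: dict
    removed: list[str]


@dataclass
class CleaningReport:
    n_input: int
    rules: list[RuleOutcome] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return sum(len(r.removed) for r in self.rules)

    def removed_by_rule(self) -> dict[int, list[str]]:
        return {r.rule: list(r.removed) for r in self.rules}

    def validate_conservation(self) -> None:
        if self.n_removed + len(self.retained) != self.n_input:
            raise AssertionError("cleaning report does not conserve records")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "n_input": self.n_input,
            "retained": list(self.retained),
            "rules": [
                {
                    "rule": r.rule,
                    "description": r.description,
                    "parameters": r.parameters,
                    "removed": list(r.removed),
                }
                for r in self.rules
            ],
        }
        path.write_text(json.dumps(payload, indent=1))
        return path


def _require(features: pd.DataFrame, name: str, rule: int) -> pd.Series:
    if name not in features.columns:
        raise KeyError(f"cleaning rule {rule} requires missing feature {name!r}")
    return features[name].astype(float)


def prediction_entropy(probs: pd.DataFrame) -> pd.Series:
    """Shannon entropy (nats) of each predicted class-probability row."""
    return pd.Series(_entropy(probs.to_numpy(dtype=float), axis=1), index=probs.index)


def flag_embedding_outliers(
    embedding: np.ndarray, params: CleaningParams | None = None
) -> np.ndarray:
    """Rule 9 decision core on a 2-D embedding: DBSCAN noise points and
    clusters rarer than the frequency cut are outliers."""
    params = params or CleaningParams()
    emb = np.asarray(embedding, dtype=float)
    n = emb.shape[0]
    labels = DBSCAN(eps=params.dbscan_eps, min_samples=params.dbscan_min_samples).fit(
        emb
    ).labels_
    bad = labels == -1
    for lab, count in zip(*np.unique(labels[labels >= 0], return_counts=True)):
        if count / n < params.min_cluster_frequency:
            bad |= labels == lab
    return bad


def _embedding_outliers(
    X: np.ndarray, params: CleaningParams, seed: int
) -> np.ndarray:
    """Rule 9: standardize, embed to 2-D with UMAP, flag noise/rare points."""
    import umap  # heavy import, local on purpose

    n = X.shape[0]
    n_neighbors = int(min(params.umap_n_neighbors, max(2, n - 1)))
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=n_neighbors,
        min_dist=params.umap_min_dist,
        random_state=seed,
    )
    emb = reducer.fit_transform(StandardScaler().fit_transform(X))
    return flag_embedding_outliers(emb, params)


def clean(
    features: pd.DataFrame,
    predicted_class: pd.Series,
    probs: pd.DataFrame,
    params: CleaningParams | None = None,
    seed: int = 0,
) -> tuple[list[str], CleaningReport]:
    """Apply the nine rules to one donor x condition sample.

    ``features`` rows, ``predicted_class`` and ``probs`` share the record-id
    index.  Returns the retained ids (input order) and a per-rule report.
    """
    params = params or CleaningParams()
    ids = list(features.index)
    report = CleaningReport(n_input=len(ids))
    if not ids:
        return [], report

    predicted_class = predicted_class.reindex(features.index)
    probs = probs.reindex(features.index)

    # ---- frozen thresholds and per-rule violator sets -----------------
    viab = _require(features, params.viability_feature, 1)
    v90 = np.nanpercentile(viab, params.viability_percentile)
    viol: dict[int, pd.Series] = {}
    viol[1] = viab >= v90

    focus = _require(features, params.focus_feature, 2)
    f_lo = np.nanpercentile(focus, params.focus_low_percentile)
    f_hi = np.nanpercentile(focus, params.focus_high_percentile)
    viol[2] = ~((focus > f_lo) & (focus < f_hi))

    ent = prediction_entropy(probs)
    viol[3] = ent > params.entropy_threshold

    mh_mean = _require(features, params.mhcii_mean_feature, 4)
    mh5 = np.nanpercentile(mh_mean, params.mhcii_mean_percentile)
    viol[4] = (predicted_class == B_LCL_CLASS) & (mh_mean < mh5)

    mh_area = _require(features, params.mhcii_area_feature, 5)
    mh_a10 = np.nanpercentile(mh_area, params.b_lcl_area_percentile)
    viol[5] = (predicted_class == B_LCL_CLASS) & (mh_area < mh_a10)

    cd3_mean = _require(features, params.cd3_mean_feature, 6)
    cd3_1 = np.nanpercentile(cd3_mean, params.cd3_mean_percentile)
    viol[6] = predicted_class.isin(T_CELL_CLASSES) & (cd3_mean < cd3_1)

    mh_a20 = np.nanpercentile(mh_area, params.one_layer_area_percentile)
    viol[7] = (predicted_class == ONE_LAYER_CLASS) & (mh_area < mh_a20)

    top = list(params.top_features or features.columns[:30])
    missing = [c for c in top if c not in features.columns]
    if missing:
        raise KeyError(f"cleaning rules 8-9 require missing features {missing[:3]}")
    sub = features[top].astype(float)
    sub = sub.fillna(sub.median()).fillna(0.0)
    X = sub.to_numpy()

    iso = IsolationForest(
        n_estimators=params.iso_n_estimators,
        max_samples=params.iso_max_samples,
        contamination=params.iso_contamination,
        max_features=min(params.iso_max_features, X.shape[1]),
        random_state=seed,
    )
    viol[8] = pd.Series(iso.fit_predict(X) == -1, index=features.index)

    viol[9] = pd.Series(_embedding_outliers(X, params, seed), index=features.index)

    # ---- first-match attribution --------------------------------------
    descriptions = {
        1: "dead cells (viability >= 90th percentile)",
        2: "out-of-focus (BF gradient RMS outside 2nd..90th percentile)",
        3: f"prediction entropy > {params.entropy_threshold}",
        4: "predicted B-LCL with mean MHCII < 5th percentile",
        5: "predicted B-LCL with MHCII area < 10th percentile",
        6: "predicted T cell with mean CD3 < 1st percentile",
        7: "predicted one-layer conjugate with MHCII area < 20th percentile",
        8: "isolation-forest outlier on top-importance features",
        9: "UMAP+DBSCAN noise or rare cluster",
    }
    parameters = {
        1: {"percentile": params.viability_percentile, "threshold": float(v90)},
        2: {
            "low": params.focus_low_percentile,
            "high": params.focus_high_percentile,
            "thresholds": [float(f_lo), float(f_hi)],
        },
        3: {"threshold": params.entropy_threshold},
        4: {"percentile": params.mhcii_mean_percentile, "threshold": float(mh5)},
        5: {"percentile": params.b_lcl_area_percentile, "threshold": float(mh_a10)},
        6: {"percentile": params.cd3_mean_percentile, "threshold": float(cd3_1)},
        7: {"percentile": params.one_layer_area_percentile, "threshold": float(mh_a20)},
        8: {
            "n_estimators": params.iso_n_estimators,
            "max_samples": str(params.iso_max_samples),
            "contamination": str(params.iso_contamination),
            "max_features": params.iso_max_features,
            "seed": seed,
        },
        9: {
            "eps": params.dbscan_eps,
            "min_samples": params.dbscan_min_samples,
            "min_cluster_frequency": params.min_cluster_frequency,
            "umap_n_neighbors": params.umap_n_neighbors,
            "umap_min_dist": params.umap_min_dist,
            "seed": seed,
        },
    }
    claimed: set[str] = set()
    for rule in range(1, 10):
        flagged = viol[rule].fillna(False)
        removed = [rid for rid in ids if flagged[rid] and rid not in claimed]
        claimed.update(removed)
        report.rules.append(
            RuleOutcome(
                rule=rule,
                description=descriptions[rule],
                parameters=parameters[rule],
                removed=removed,
            )
        )
    report.retained = [rid for rid in ids if rid not in claimed]
    report.validate_conservation()
    logger.info(
        "cleaning: %d in, %d removed, %d retained",
        report.n_input,
        report.n_removed,
        len(report.retained),
    )
    return report.retained, report
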