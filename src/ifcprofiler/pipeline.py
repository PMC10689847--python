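"""Configuration, seeding, logging and end-to-end orchestration.

A single :class:`RunConfig` drives the full analysis: simulate or load a
cohort, extract interpretable features, train and evaluate the classifier,
predict every record, clean per donor x condition, profile class
frequencies and feature differences between an antibody arm and its
control, and regress an optional functional readout on aggregated synapse
features.  One global seed derives a stable per-stage seed so each stage is
independently reproducible; worker count changes throughput, never results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import classify, cleaning, profiling, regression, selection, synthetic
from .core_data import DatasetIndex, default_taxonomy, stratified_split
from .features import FeatureTable, extract_features, full_inventory
from .synthetic import CohortSpec, ConditionSpec, generate_cohort

logger = logging.getLogger(__name__)


def configure_logging(level: int = logging.INFO) -> None:
    logging.basicConfig(
        level=level, format="%(asctime)s %(name)s %(levelname)s %(message)s"
    )


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31, derived from the global seed."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

def _from_mapping(cls, data: Mapping, context: str):
    """Strict dataclass construction: unknown keys are config errors."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config key(s) in {context}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class SimulateBlock:
    n_donors: int = 3
    records_per_group: int = 200
    donor_effect_sd: float = 0.15
    dead_fraction: float = 0.0
    conditions: dict = field(default_factory=dict)  # name -> {class_frequencies, channel_scale}


@dataclass
class ModelBlock:
    kind: str = "gradient-boosting"
    n_trees: int = 100
    folds: int = 5
    repeats: int = 2


@dataclass
class SelectionBlock:
    enabled: bool = False
    pearson_threshold: float = 0.95
    top_k: int = 50
    n_clusters: int = 50


@dataclass
class CleaningBlock:
    enabled: bool = True
    entropy_threshold: float = 1.0
    # DBSCAN eps is density-dependent: the default matches the reference
    # protocol at ~5e4 records per sample; small cohorts need a larger value
    dbscan_eps: float = 0.09


@dataclass
class ProfilingBlock:
    antibody: str = ""
    control: str = ""
    alpha: float = 0.05
    min_consistent_donors: int = 2


@dataclass
class RegressionBlock:
    enabled: bool = False
    readout_csv: str = ""  # donor_id,condition,readout
    planted_coefficients: dict = field(default_factory=dict)
    planted_noise_sd: float = 0.0
    rotating_conditions: list = field(default_factory=list)


@dataclass
class RunConfig:
    out_dir: str = "ifcprofiler-run"
    manifest: str = ""  # load a cohort instead of simulating
    train_fraction: float = 0.7
    seed: int = 0
    workers: int = 1
    simulate: SimulateBlock = field(default_factory=SimulateBlock)
    model: ModelBlock = field(default_factory=ModelBlock)
    selection: SelectionBlock = field(default_factory=SelectionBlock)
    cleaning: CleaningBlock = field(default_factory=CleaningBlock)
    profiling: ProfilingBlock = field(default_factory=ProfilingBlock)
    regression: RegressionBlock = field(default_factory=RegressionBlock)

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        data = dict(data)
        blocks = {
            "simulate": SimulateBlock,
            "model": ModelBlock,
            "selection": SelectionBlock,
            "cleaning": CleaningBlock,
            "profiling": ProfilingBlock,
            "regression": RegressionBlock,
        }
        for key, bcls in blocks.items():
            if key in data and isinstance(data[key], Mapping):
                data[key] = _from_mapping(bcls, data[key], key)
        return _from_mapping(cls, data, "run config")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _build_cohort_spec(block: SimulateBlock, seed: int) -> CohortSpec:
    if block.conditions:
        conditions = {
            name: ConditionSpec(
                class_frequencies=dict(c["class_frequencies"]),
                channel_scale=dict(c.get("channel_scale", {})),
            )
            for name, c in block.conditions.items()
        }
    else:
        uniform = {c: 1.0 / 9.0 for c in synthetic.CLASS_NAMES}
        conditions = {"control": ConditionSpec(class_frequencies=uniform)}
    donors = [f"donor{i+1}" for i in range(block.n_donors)]
    return CohortSpec(
        donors=donors,
        conditions=conditions,
        records_per_group=block.records_per_group,
        donor_effect_sd=block.donor_effect_sd,
        dead_fraction=block.dead_fraction,
        seed=seed,
    )


def run_pipeline(config: RunConfig, write_artifacts: bool = True) -> dict:
    """Execute every configured stage in order; returns the artifact map.

    Stages and their seeds derive from ``config.seed``; rerunning with the
    same config yields identical artifacts.  Artifacts are stamped with the
    config hash.
    """
    out = Path(config.out_dir)
    if write_artifacts:
        out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {"config_hash": config.config_hash, "seed": config.seed}
    taxonomy = default_taxonomy()

    # -- stage: cohort ---------------------------------------------------
    if config.manifest:
        index = DatasetIndex.from_csv(config.manifest)
        records = list(index.iter_records())
    else:
        cohort = generate_cohort(
            _build_cohort_spec(config.simulate, derive_seed(config.seed, "simulate"))
        )
        index, records = cohort.index, cohort.records
        artifacts["cohort_truth"] = cohort
    logger.info("cohort: %d records", len(records))

    # -- stage: features -------------------------------------------------
    panel = list(records[0].channels)
    inventory = full_inventory(panel)
    table = extract_features(records, inventory, n_jobs=config.workers)
    artifacts["feature_table"] = table
    labels = index.labels

    # -- stage: train/evaluate -------------------------------------------
    spec = classify.ModelSpec(
        kind=config.model.kind,
        n_trees=config.model.n_trees,
        seed=derive_seed(config.seed, "model"),
    )
    sel_cfg = None
    if config.selection.enabled:
        sel_cfg = selection.SelectionConfig(
            pearson_threshold=config.selection.pearson_threshold,
            top_k=config.selection.top_k,
            n_clusters=config.selection.n_clusters,
            seed=derive_seed(config.seed, "selection"),
        )
    train_idx, test_idx = stratified_split(
        index, train_fraction=config.train_fraction,
        seed=derive_seed(config.seed, "split"),
    )
    Xtr = table.df.loc[train_idx.record_ids]
    ytr = labels.loc[train_idx.record_ids].to_numpy()
    Xte = table.df.loc[test_idx.record_ids]
    yte = labels.loc[test_idx.record_ids].to_numpy()
    evaluation = classify.repeated_stratified_cv(
        Xtr, ytr, spec,
        folds=config.model.folds, repeats=config.model.repeats,
        seed=derive_seed(config.seed, "cv"), selection=sel_cfg,
    )
    med = Xtr.median()
    model = classify.fit(spec, Xtr.fillna(med).fillna(0.0), ytr)
    test_pred = classify.predict(model, Xte.fillna(med).fillna(0.0))
    artifacts["model"] = model
    artifacts["cv_eval"] = evaluation
    artifacts["test_f1_macro"] = classify.f1_macro(yte, test_pred)
    gains = classify.gain_importance(model)
    artifacts["gain_importance"] = gains

    # -- stage: predict all + clean per donor x condition ----------------
    X_all = table.df.fillna(med).fillna(0.0)
    cls_pred, probs, _ = classify.predict_with_entropy(model, X_all)
    predictions = pd.DataFrame(
        {
            "predicted_class": cls_pred,
            "donor_id": index.table.set_index("record_id")["donor_id"],
            "condition": index.table.set_index("record_id")["condition"],
        },
        index=X_all.index,
    )
    artifacts["predictions"] = predictions
    retained_ids: list[str] = []
    reports = {}
    if config.cleaning.enabled:
        top30 = [f for f in gains.sort_values(ascending=False).index[:30]]
        params = cleaning.CleaningParams(
            entropy_threshold=config.cleaning.entropy_threshold,
            dbscan_eps=config.cleaning.dbscan_eps,
            top_features=top30,
        )
        for (donor, cond), grp in predictions.groupby(["donor_id", "condition"]):
            kept, rep = cleaning.clean(
                table.df.loc[grp.index],
                grp["predicted_class"],
                probs.loc[grp.index],
                params,
                seed=derive_seed(config.seed, f"clean/{donor}/{cond}"),
            )
            retained_ids.extend(kept)
            reports[(donor, cond)] = rep
    else:
        retained_ids = list(predictions.index)
    artifacts["cleaning_reports"] = reports
    retained = predictions.loc[retained_ids]

    # -- stage: population profiling -------------------------------------
    freqs = profiling.class_frequencies(retained, taxonomy)
    artifacts["class_frequencies"] = freqs
    prof_cfg = config.profiling
    if prof_cfg.antibody and prof_cfg.control:
        artifacts["frequency_profile"] = profiling.frequency_test(
            freqs, prof_cfg.antibody, prof_cfg.control, prof_cfg.alpha, taxonomy
        )
        syn = retained[
            retained["predicted_class"] == profiling.SYNAPSE_SIGNALING_CLASS
        ]
        fluor_cols = [
            e.name for e in inventory.entries if e.family in
            ("intensity", "texture", "synaptic", "coloc")
            or (e.family == "morphology" and e.computation == "area")
        ]
        if len(syn):
            artifacts["difference_map"] = profiling.feature_difference(
                table.df.loc[syn.index, fluor_cols],
                syn[["donor_id", "condition"]],
                prof_cfg.antibody,
                prof_cfg.control,
                prof_cfg.alpha,
            )

    # -- stage: functional regression ------------------------------------
    reg = config.regression
    if reg.enabled:
        syn_ids = regression.select_synapse_population(retained)
        profile = regression.aggregate(
            table.df.loc[syn_ids], retained.loc[syn_ids, ["donor_id", "condition"]]
        )
        if reg.readout_csv:
            readout = pd.read_csv(reg.readout_csv).set_index(
                ["donor_id", "condition"]
            )["readout"]
            y = readout.reindex(profile.table.index)
        else:
            y = synthetic.functional_readout(
                profile.table,
                dict(reg.planted_coefficients),
                noise_sd=reg.planted_noise_sd,
                seed=derive_seed(config.seed, "readout"),
            )
        if reg.rotating_conditions:
            fm = regression.fit_predict_condition_holdout(
                profile, y, list(reg.rotating_conditions)
            )
        else:
            fm = regression.fit_predict_lodo(profile, y)
        artifacts["aggregated_profile"] = profile
        artifacts["functional_model"] = fm

    if write_artifacts:
        _write_artifacts(out, config, artifacts)
    return artifacts


def _write_artifacts(out: Path, config: RunConfig, artifacts: dict) -> None:
    config.to_yaml(out / "config.yaml")
    stamp = {"config_hash": artifacts["config_hash"], "seed": artifacts["seed"]}
    (out / "run.json").write_text(json.dumps(stamp, indent=1))
    artifacts["feature_table"].to_csv(out / "features.csv")
    artifacts["predictions"].to_csv(out / "predictions.csv")
    artifacts["class_frequencies"].to_csv(out / "class_frequencies.csv", index=False)
    (out / "cv_eval.json").write_text(json.dumps(artifacts["cv_eval"].to_dict(), indent=1))
    artifacts["gain_importance"].to_csv(out / "gain_importance.csv")
    if "frequency_profile" in artifacts:
        artifacts["frequency_profile"].stats.to_csv(
            out / "frequency_stats.csv", index=False
        )
    if "difference_map" in artifacts:
        artifacts["difference_map"].signs.to_csv(out / "difference_map.csv")
    if "functional_model" in artifacts:
        fm = artifacts["functional_model"]
        fm.coefficients.to_csv(out / "functional_coefficients.csv")
        pd.DataFrame(
            {"prediction": fm.predictions, "observed": fm.observed}
        ).to_csv(out / "functional_predictions.csv")
    for (donor, cond), rep in artifacts.get("cleaning_reports", {}).items():
        rep.to_json(out / f"cleaning_{donor}_{cond}.json")
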