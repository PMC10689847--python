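# ifcprofiler

Interpretable feature engineering and explainable machine learning for
imaging flow cytometry (IFC) of immune-cell conjugates.

IFC instruments record a multichannel microscopy image of every event, so a
single co-culture of T cells with antigen-presenting B cells (B-LCLs)
yields hundreds of thousands of single-cell images of would-be
immunological synapses. Profiling how a therapeutic antibody changes the
frequency and the morphology of those synapses — and whether that predicts
downstream T-cell function — requires classifying millions of images into
conjugate classes and comparing hand-interpretable features between
treatment arms. `ifcprofiler` implements that pipeline for scientists
working with such data:

* **records & cohorts** — one HDF5 file per event (channel stack +
  per-channel masks + donor/experiment/condition metadata), CSV manifests,
  stratified train/test splits;
* **interpretable features** — morphology (incl. Hu moments and Feret
  diameters), masked intensity statistics, GLCM texture, 17 co-localization
  measures per channel pair (Dice/Jaccard, Manders, ICQ, SSIM,
  Hausdorff, …), and synaptic enrichment ratios computed inside the
  contact-zone mask (dilated CD3 mask ∩ dilated MHCII mask);
* **ensemble feature pre-selection** — correlation pruning, a six-method
  ranking union, spectral decorrelation;
* **explainable classification** — five classical models behind one
  registry (gradient boosting with 100 trees as reference), repeated
  stratified 5-fold×10 cross-validation, leave-one-donor-out CV, learning
  curves, channel ablation, and gain-based feature importance
  (`sum of split improvements / number of splits`, normalized);
* **rule-based cleaning** — the nine-rule post-prediction filter (viability
  and focus percentiles, prediction entropy, class-conditional intensity/
  area cuts, isolation forest, UMAP+DBSCAN outliers) with a per-rule
  removal ledger;
* **population profiling** — per-donor class-frequency log2 fold changes
  with exact Wilcoxon signed-rank tests and Benjamini-Hochberg correction;
  per-donor feature-difference maps (Mann-Whitney U, exact for small arms)
  coded −1/0/+1 with cross-donor consistency counts;
* **functional regression** — 5th/50th/95th-percentile aggregation of
  synapse features per donor×condition and a LassoLars model under
  leave-one-donor-out or condition-rotation CV, ranking features by
  coefficient magnitude;
* **a synthetic cohort generator** that renders labeled conjugate images
  for all nine classes with planted class-frequency shifts, per-channel
  intensity effects, donor random effects and a linear functional readout,
  so the whole pipeline is testable offline.

The statistical core is summarized in `docs/methods.md`. For a frequency
comparison of class *C* between arms, the pipeline computes per donor
*F<sub>C</sub>* = (#records predicted *C*) / (#records), reports
log₂(*F<sub>C,antibody</sub>* / *F<sub>C,control</sub>*), tests it against
zero with the exact signed-rank null (all 2ⁿ sign patterns, n ≤ 12) and
adjusts across the seven non-artifact classes with BH.

## Worked example

Simulate a six-donor cohort in which the antibody doubles the frequency of
signaling synapses (planted log₂FC = 1), extract the full feature table,
benchmark the classifier and test the frequency shift:

```python
from ifcprofiler import (
    CohortSpec, ConditionSpec, generate_cohort, extract_features,
    full_inventory, ModelSpec, repeated_stratified_cv,
    class_frequencies, frequency_test,
)

base = {
    "single B-LCL": 0.22, "single T cell w/o signaling": 0.18,
    "single T cell w/ signaling": 0.08, "T cell w/ small B-LCL": 0.05,
    "B-LCL and T cell in one layer": 0.12, "synapse w/o signaling": 0.15,
    "synapse w/ signaling": 0.05, "no cell-cell interaction": 0.05,
    "multi-synapse": 0.10,
}
treated = dict(base, **{"synapse w/ signaling": 0.10,
                        "single T cell w/o signaling": 0.13})
spec = CohortSpec(
    donors=[f"donor{i}" for i in range(1, 7)],
    conditions={"control": ConditionSpec(base), "antibody": ConditionSpec(treated)},
    records_per_group=150, seed=7,
)
cohort = generate_cohort(spec)
table = extract_features(cohort.records,
                         full_inventory(list(cohort.records[0].channels)))
labels = cohort.index.labels.loc[table.df.index].to_numpy()

res = repeated_stratified_cv(table.df, labels, ModelSpec(seed=0),
                             folds=5, repeats=2, seed=0)
print(f"nine-class F1-macro: {res.mean:.3f} +/- {res.sd:.3f}")

preds = cohort.index.table.set_index("record_id")[["donor_id", "condition"]]
preds["predicted_class"] = labels
profile = frequency_test(class_frequencies(preds), "antibody", "control")
row = profile.stats.set_index("class").loc["synapse w/ signaling"]
print(f"synapse w/ signaling: median log2FC = {row['median_log2fc']:+.2f}, "
      f"p = {row['p']:.4f}, adjusted p = {row['p_adj']:.4f}")
```

Output:

```
nine-class F1-macro: 0.997 +/- 0.003
synapse w/ signaling: median log2FC = +1.10, p = 0.0312, adjusted p = 0.2188
```

Reading the numbers: the classifier separates the nine synthetic classes
almost perfectly (synthetic disks are far cleaner than real conjugates);
the planted doubling is recovered as a median log₂FC of 1.10 across the
six donors with the exact signed-rank p = 2/2⁶ = 0.03125 — all six donors
moved the same way. After BH correction across the seven analysis classes
the adjusted p is 0.03125 × 7 = 0.219, because only one class shifted in
this toy design; when most classes respond (as under a strong stimulus),
the same raw p adjusts to ≈ 0.036.

A command-line interface covers the same stages
(`ifcprofiler simulate | extract | preselect | evaluate | run-all`), with
`run-all` driven by a YAML config.

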