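"""Population-level statistical profiling.

Two analyses run on the classifier's predictions after cleaning:

* **class frequencies** — per donor x condition the fraction of records
  predicted as each non-artifact class; antibody and control arms are
  compared per class with the log2 fold change of the frequency, and a
  paired exact Wilcoxon signed-rank test of the per-donor log2FC against
  zero, Benjamini-Hochberg corrected across the non-artifact classes;
* **feature differences** — for records predicted as signaling synapses,
  each feature is compared between antibody and control per donor with a
  two-sided Mann-Whitney U test, BH-corrected across features within the
  donor, and coded -1/0/+1 by significance and the direction of the median
  difference.  The per-feature cross-donor consistency count identifies
  reproducible mode-of-action signatures.

The exact tests enumerate the full null (sign patterns for the signed-rank,
group assignments for Mann-Whitney) for small n and fall back to the
tie-corrected normal approximation beyond that.  The paired cohort design
(six to seven donors measured under both arms) is the reason the frequency
comparison uses the one-sample signed-rank on log2FC: with n=6 all-positive
changes it yields the exact two-sided p = 2/64 = 0.03125, and BH over seven
classes with one non-significant class gives 0.036.  A two-sample rank-sum
variant is available as an option.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_data import ClassTaxonomy, default_taxonomy

logger = logging.getLogger(__name__)

SYNAPSE_SIGNALING_CLASS = "synapse w/ signaling"


# ---------------------------------------------------------------------------
# Exact tests and BH
# ---------------------------------------------------------------------------

def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN-safe)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def wilcoxon_signed_rank_exact(
    diffs: Sequence[float], max_exact: int = 12
) -> float:
    """Two-sided one-sample Wilcoxon signed-rank p-value for ``diffs`` vs 0.

    Zeros are discarded; |diffs| are mid-ranked.  For n <= ``max_exact`` the
    null is enumerated over all 2^n sign patterns (valid under ties); larger
    n uses the normal approximation with tie correction.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n > max_exact:
        return float(stats.wilcoxon(d, method="approx").pvalue)
    signs = np.array(list(itertools.product([0.0, 1.0], repeat=n)))
    dist = signs @ ranks
    p_low = float((dist <= w + 1e-9).mean())
    p_high = float((dist >= w - 1e-9).mean())
    return min(1.0, 2.0 * min(p_low, p_high))


def mann_whitney_exact(
    x: Sequence[float], y: Sequence[float], max_exact: int = 8
) -> float:
    """Two-sided Mann-Whitney U p-value.

    Both arms at or below ``max_exact`` observations: the full permutation
    null over all C(n+m, n) group assignments of the pooled mid-ranks is
    enumerated (exact also under ties).  Larger arms use the tie-corrected
    normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both arms must be non-empty")
    if np.all(np.concatenate([x, y]) == np.concatenate([x, y])[0]):
        return 1.0  # constant in both arms
    if n > max_exact or m > max_exact:
        return float(
            stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
        )
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_obs = float(ranks[:n].sum()) - n * (n + 1) / 2.0
    idx = np.array(list(itertools.combinations(range(n + m), n)))
    dist = ranks[idx].sum(axis=1) - n * (n + 1) / 2.0
    p_low = float((dist <= u_obs + 1e-9).mean())
    p_high = float((dist >= u_obs - 1e-9).mean())
    return min(1.0, 2.0 * min(p_low, p_high))


# ---------------------------------------------------------------------------
# Class frequencies
# ---------------------------------------------------------------------------

def class_frequencies(
    predictions: pd.DataFrame,
    taxonomy: ClassTaxonomy | None = None,
) -> pd.DataFrame:
    """Per donor x condition class-frequency simplex over non-artifact classes.

    ``predictions`` needs columns ``donor_id``, ``condition`` and
    ``predicted_class``.  Artifact classes are excluded from both the
    numerator and the denominator, so each row sums to 1.
    """
    taxonomy = taxonomy or default_taxonomy()
    keep = list(taxonomy.analysis_classes)
    df = predictions[predictions["predicted_class"].isin(keep)]
    rows = []
    for (donor, cond), grp in df.groupby(["donor_id", "condition"], sort=True):
        counts = grp["predicted_class"].value_counts()
        total = int(counts.sum())
        rows.append(
            {"donor_id": donor, "condition": cond, "n_records": total}
            | {c: counts.get(c, 0) / total for c in keep}
        )
    return pd.DataFrame(rows)


@dataclass
class FrequencyProfile:
    frequencies: pd.DataFrame  # donor x condition simplex rows
    log2fc: pd.DataFrame  # classes x donors
    stats: pd.DataFrame  # class, median log2FC, raw p, BH-adjusted p


def frequency_test(
    frequencies: pd.DataFrame,
    antibody: str,
    control: str,
    alpha: float = 0.05,
    taxonomy: ClassTaxonomy | None = None,
    method: str = "signed-rank",
) -> FrequencyProfile:
    """Antibody-vs-control frequency comparison across donors.

    Computes the per-donor ``log2(F_antibody / F_control)`` per class, tests
    it against zero (paired exact signed-rank by default, or two-sample
    rank-sum between the two arms' frequencies with ``method='rank-sum'``)
    and BH-corrects across the non-artifact classes.  Donors missing either
    condition are dropped with a warning; zero frequencies leave that
    donor/class cell undefined (no pseudo-count).
    """
    taxonomy = taxonomy or default_taxonomy()
    classes = list(taxonomy.analysis_classes)
    piv = frequencies.set_index(["donor_id", "condition"])
    donors = sorted(frequencies["donor_id"].unique())
    usable = []
    for d in donors:
        if (d, antibody) in piv.index and (d, control) in piv.index:
            usable.append(d)
        else:
            logger.warning("donor %s lacks condition %s or %s; dropped",
                           d, antibody, control)
    log2fc = pd.DataFrame(index=classes, columns=usable, dtype=float)
    for d in usable:
        fa = piv.loc[(d, antibody)]
        fc = piv.loc[(d, control)]
        for c in classes:
            a, b = float(fa[c]), float(fc[c])
            if a > 0 and b > 0:
                log2fc.loc[c, d] = np.log2(a / b)
            else:
                logger.warning(
                    "zero frequency for class %r donor %s; log2FC undefined", c, d
                )
    rows = []
    for c in classes:
        vals = log2fc.loc[c].dropna().to_numpy(dtype=float)
        if len(vals) == 0:
            p = np.nan
        elif method == "signed-rank":
            p = wilcoxon_signed_rank_exact(vals)
        elif method == "rank-sum":
            a = [piv.loc[(d, antibody), c] for d in usable]
            b = [piv.loc[(d, control), c] for d in usable]
            p = mann_whitney_exact(a, b)
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append(
            {
                "class": c,
                "n_donors": int(log2fc.loc[c].notna().sum()),
                "median_log2fc": float(np.median(vals)) if len(vals) else np.nan,
                "p": p,
            }
        )
    stats_df = pd.DataFrame(rows)
    stats_df["p_adj"] = bh_adjust(stats_df["p"])
    stats_df["significant"] = stats_df["p_adj"] < alpha
    return FrequencyProfile(frequencies=frequencies, log2fc=log2fc, stats=stats_df)


# ---------------------------------------------------------------------------
# Feature differences
# ---------------------------------------------------------------------------

@dataclass
class DifferenceMap:
    """features x donors map of {-1, 0, +1} with the underlying p-values."""

    signs: pd.DataFrame
    p: pd.DataFrame
    p_adj: pd.DataFrame
    alpha: float

    @property
    def consistency(self) -> pd.DataFrame:
        """Per feature: the dominant nonzero sign and its donor count."""
        pos = (self.signs == 1).sum(axis=1)
        neg = (self.signs == -1).sum(axis=1)
        direction = np.where(pos >= neg, 1, -1)
        count = np.maximum(pos, neg)
        return pd.DataFrame(
            {"direction": direction, "n_donors": count}, index=self.signs.index
        )

    def per_donor_counts(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "increased": (self.signs == 1).sum(axis=0),
                "decreased": (self.signs == -1).sum(axis=0),
            }
        )


def feature_difference(
    features: pd.DataFrame,
    meta: pd.DataFrame,
    antibody: str,
    control: str,
    alpha: float = 0.05,
) -> DifferenceMap:
    """Per-donor antibody-vs-control Mann-Whitney map over all features.

    ``features`` rows are records (already restricted to the population of
    interest, e.g. predicted signaling synapses); ``meta`` aligns donor and
    condition on the same index.  P-values are BH-corrected across features
    within each donor; a cell is +1/-1 only when adjusted p < alpha, signed
    by the median difference (antibody minus control).
    """
    meta = meta.loc[features.index]
    donors = sorted(meta["donor_id"].unique())
    feats = list(features.columns)
    p = pd.DataFrame(np.nan, index=feats, columns=donors)
    signs = pd.DataFrame(0, index=feats, columns=donors, dtype=int)
    med_diff = pd.DataFrame(np.nan, index=feats, columns=donors)
    for d in donors:
        sel_a = (meta["donor_id"] == d) & (meta["condition"] == antibody)
        sel_c = (meta["donor_id"] == d) & (meta["condition"] == control)
        if not sel_a.any() or not sel_c.any():
            logger.warning("donor %s lacks one arm; left undefined", d)
            continue
        A = features.loc[sel_a.to_numpy()]
        C = features.loc[sel_c.to_numpy()]
        for f in feats:
            a = A[f].dropna().to_numpy(dtype=float)
            c = C[f].dropna().to_numpy(dtype=float)
            if len(a) == 0 or len(c) == 0:
                continue
            p.loc[f, d] = mann_whitney_exact(a, c)
            med_diff.loc[f, d] = float(np.median(a) - np.median(c))
    p_adj = p.copy()
    for d in donors:
        p_adj[d] = bh_adjust(p[d])
        sig = (p_adj[d] < alpha) & med_diff[d].notna() & (med_diff[d] != 0)
        signs.loc[sig, d] = np.sign(med_diff.loc[sig, d]).astype(int)
    return DifferenceMap(signs=signs, p=p, p_adj=p_adj, alpha=alpha)


def consistency_summary(dmap: DifferenceMap, min_donors: int) -> pd.DataFrame:
    """Features whose nonzero sign agrees in at least ``min_donors`` donors."""
    cons = dmap.consistency
    hit = cons[(cons["n_donors"] >= min_donors)]
    return hit.sort_values(["n_donors"], ascending=False, kind="stable")
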