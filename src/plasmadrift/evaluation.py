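"""Data-quality accounting before and after drift correction.

The quality metric is the per-feature coefficient of variation (CV) over all
samples spanning the pre-centrifugation time course: a drift-free feature's
CV reflects only analytical and biological noise, so effective correction
shrinks it.  Reports aggregate CVs per drift cluster (with a paired
significance test of the improvement over member features), globally, and as
the proportion of features exceeding CV 30%.  Deviation-percentile surfaces
summarize the distribution of relative intensity deviations from each
subject's reference-time sample as a function of delay time, and predicted
times for coarsely documented legacy samples are compared across groups by
one-way ANOVA with Tukey-HSD adjusted pairwise tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .dataio import FeatureTable
from .drift_model import DriftModel


class EvaluationError(ValueError):
    pass


def feature_cv(values: np.ndarray | pd.Series) -> float:
    """Coefficient of variation: sample standard deviation over mean."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise EvaluationError("CV needs a 1-d vector of length >= 2")
    m = v.mean()
    if m <= 0:
        raise EvaluationError("CV undefined for non-positive mean")
    return float(v.std(ddof=1) / m)


@dataclass
class CorrectionReport:
    """Per-feature, per-cluster and global CV accounting.

    ``per_cluster`` carries one row per drift cluster plus summary rows
    ``Modeled`` (all clustered features), ``Irreproducible`` (excluded) and
    ``Total``; improvement p-values are two-sided Wilcoxon signed-rank tests
    over member features' paired (original, corrected) CVs, reported as NaN
    where not computable (single-member clusters, or no nonzero pair
    differences) and star-coded at 0.05 / 0.01 / 0.001.
    """

    per_feature: pd.DataFrame
    per_cluster: pd.DataFrame
    global_stats: pd.DataFrame


def correction_report(
    original: FeatureTable,
    corrected_meta: FeatureTable,
    model: DriftModel,
    corrected_pred: FeatureTable | None = None,
    cv_threshold: float = 0.30,
) -> CorrectionReport:
    """Tabulate CV before/after correction with per-cluster significance."""
    approaches = {"metadata": corrected_meta}
    if corrected_pred is not None:
        approaches["prediction"] = corrected_pred
    for name, tab in approaches.items():
        if tab.sample_ids != original.sample_ids or tab.feature_ids != original.feature_ids:
            raise EvaluationError(f"{name}-corrected table does not match original")

    cluster_of = model.cluster_of()
    rows = []
    for fid in original.feature_ids:
        row = {
            "feature_id": fid,
            "cluster_id": int(cluster_of.get(fid, -1)),
            "cv_original": feature_cv(original.data[fid]),
        }
        for name, tab in approaches.items():
            row[f"cv_corrected_{name}"] = feature_cv(tab.data[fid])
        rows.append(row)
    per_feature = pd.DataFrame(rows)

    cluster_rows = []
    groupings = [(f"Cluster{c.cluster_id}", c.cluster_id,
                  per_feature[per_feature["cluster_id"] == c.cluster_id])
                 for c in model.clusters]
    modeled = per_feature[per_feature["cluster_id"] >= 0]
    excluded = per_feature[per_feature["cluster_id"] < 0]
    groupings += [("Modeled", None, modeled), ("Irreproducible", None, excluded),
                  ("Total", None, per_feature)]
    for label, cid, sub in groupings:
        if sub.empty:
            cluster_rows.append({"cluster": label, "cluster_id": cid, "n": 0})
            continue
        row = {
            "cluster": label,
            "cluster_id": cid,
            "n": len(sub),
            "cv_original": sub["cv_original"].mean(),
        }
        for name in approaches:
            cvs = sub[f"cv_corrected_{name}"]
            row[f"cv_corrected_{name}"] = cvs.mean()
            row[f"p_{name}"] = _paired_improvement_p(sub["cv_original"], cvs)
            row[f"stars_{name}"] = _stars(row[f"p_{name}"])
        cluster_rows.append(row)
    per_cluster = pd.DataFrame(cluster_rows)

    global_rows = [{"condition": "original",
                    "mean_cv": per_feature["cv_original"].mean(),
                    "prop_cv_gt_threshold": float((per_feature["cv_original"] > cv_threshold).mean())}]
    for name in approaches:
        cvs = per_feature[f"cv_corrected_{name}"]
        global_rows.append({
            "condition": f"corrected_{name}",
            "mean_cv": cvs.mean(),
            "prop_cv_gt_threshold": float((cvs > cv_threshold).mean()),
        })
    return CorrectionReport(per_feature, per_cluster, pd.DataFrame(global_rows))


def _paired_improvement_p(before: pd.Series, after: pd.Series) -> float:
    diff = (before - after).to_numpy()
    if len(diff) < 2:
        return np.nan  # single-member cluster: test not computable
    if np.all(diff == 0):
        return 1.0  # identical CVs: no evidence of change
    return float(stats.wilcoxon(diff, zero_method="wilcox").pvalue)


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


@dataclass
class DeviationSurface:
    """Percentiles of relative deviation from the reference state per time.

    ``values[i, j]`` is the ``percentile_levels[i]`` quantile at
    ``times[j]`` of ``x / x_ref(subject) - 1`` pooled over subjects and
    features; columns are non-decreasing in the percentile level.
    """

    times: np.ndarray
    percentile_levels: np.ndarray
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.percentile_levels, columns=self.times)


def deviation_surface(
    table: FeatureTable,
    meta: pd.DataFrame,
    t_ref: float = 1.0,
    percentile_levels: np.ndarray | list[float] = (0.05, 0.25, 0.5, 0.75, 0.95),
) -> DeviationSurface:
    """Pooled relative-deviation quantiles versus delay time.

    The reference is subject-specific: each measurement is compared with the
    same subject's own sample at ``t_ref``.
    """
    levels = np.asarray(percentile_levels, dtype=float)
    if np.any((levels <= 0) | (levels >= 1)):
        raise EvaluationError("percentile levels must lie in (0, 1)")
    levels = np.sort(levels)
    times = np.sort(meta["time_h"].unique())
    if not np.any(np.isclose(times, t_ref)):
        raise EvaluationError(f"no reference samples at {t_ref} h")

    meta_idx = meta.set_index("sample_id")
    ref_sample = {}
    for subj, sub in meta.groupby("subject_id"):
        at_ref = sub[np.isclose(sub["time_h"], t_ref)]
        if at_ref.empty:
            raise EvaluationError(f"subject {subj!r} lacks a sample at {t_ref} h")
        ref_sample[subj] = at_ref["sample_id"].iloc[0]

    data = table.data
    values = np.empty((len(levels), len(times)))
    for j, t in enumerate(times):
        ids = meta.loc[np.isclose(meta["time_h"], t), "sample_id"]
        devs = []
        for sid in ids:
            subj = meta_idx.loc[sid, "subject_id"]
            ref = data.loc[ref_sample[subj]].to_numpy()
            if np.any(ref <= 0):
                raise EvaluationError(
                    f"non-positive reference intensity for subject {subj!r}"
                )
            devs.append(data.loc[sid].to_numpy() / ref - 1.0)
        pooled = np.concatenate(devs)
        values[:, j] = np.quantile(pooled, levels)
    return DeviationSurface(times=times, percentile_levels=levels, values=values)


def compare_predicted_groups(
    predicted_times: np.ndarray | pd.Series,
    group_label: np.ndarray | pd.Series,
) -> tuple[float, pd.DataFrame]:
    """One-way ANOVA of predicted times across groups plus Tukey-HSD pairs.

    Emulates the comparison of predicted pre-centrifugation times across
    coarse documentation levels ("same day" / "next day" / ...) of legacy
    sample sets.  Returns the overall p-value and a pairwise table with
    Tukey-adjusted p-values.
    """
    y = np.asarray(predicted_times, dtype=float)
    labels = np.asarray(group_label)
    if len(y) != len(labels):
        raise EvaluationError("predicted times and labels differ in length")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise EvaluationError("need at least 2 groups")
    if np.any(counts < 2):
        bad = uniq[counts < 2].tolist()
        raise EvaluationError(f"groups with fewer than 2 members: {bad}")
    samples = [y[labels == u] for u in uniq]
    overall_p = float(stats.f_oneway(*samples).pvalue)
    tukey = pairwise_tukeyhsd(y, labels)
    pairwise = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    ).rename(columns={"p-adj": "p_adj"})
    pairwise["p_adj"] = tukey.pvalues
    return overall_p, pairwise
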