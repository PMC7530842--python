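"""Downstream evaluation of Motor Error Scores.

Covers the analyses that sit on top of the per-epoch MES: percentile-wise
correlation of MES with clinical motor scores, pairwise and pooled ROC-AUC
between patient and control MES distributions (with a permutation-bootstrap
p-value), metric-weight profiles across subjects and groups, and the
tremor-dominant / postural-instability-gait-difficulty (TD/PIGD) phenotype
ratio rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .classify import ClassifierReport, Hyperplane, fit_mes_classifier, metric_weights

__all__ = [
    "ClinicalScore",
    "PercentileCorrelationCurve",
    "roc_auc",
    "mes_percentile",
    "percentile_correlation_scan",
    "pairwise_auc",
    "pooled_roc",
    "phenotype_classify",
    "weight_profile_table",
    "group_mean_weights",
]


@dataclass(frozen=True)
class ClinicalScore:
    """Clinician-rated motor scores for one subject (MDS-UPDRS-III based).

    ``due_subscore`` sums the items assessing the dominant upper extremity;
    tremor / PIGD item means feed the phenotype ratio rule.  Which items
    enter each sum is the caller's choice — scores are opaque inputs here.
    """

    subject_id: str
    total_updrs3: int = 0
    due_subscore: int = 0
    tremor_item_mean: float = 0.0
    pigd_item_mean: float = 0.0

    def __post_init__(self) -> None:
        if self.total_updrs3 < 0 or self.due_subscore < 0:
            raise ValueError("scores must be non-negative")
        if self.due_subscore > self.total_updrs3:
            raise ValueError("subscore cannot exceed the total score")


@dataclass
class PercentileCorrelationCurve:
    """Spearman rho and p across MES percentiles 1..100."""

    percentiles: np.ndarray
    rho: np.ndarray
    pvalues: np.ndarray

    @property
    def best_percentile(self) -> int:
        return int(self.percentiles[int(np.nanargmax(self.rho))])

    @property
    def best_rho(self) -> float:
        return float(np.nanmax(self.rho))


def roc_auc(positive_scores, negative_scores) -> float:
    """AUC of the ROC separating positive from negative score distributions."""
    pos = np.asarray(positive_scores, dtype=float)
    neg = np.asarray(negative_scores, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both score sets must be non-empty")
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    s = np.concatenate([pos, neg])
    if np.ptp(s) == 0:
        warnings.warn("degenerate scores (all equal); AUC reported as 0.5")
        return 0.5
    return float(roc_auc_score(y, s))


def mes_percentile(series, p: float) -> float:
    """Empirical percentile of a subject's MES (linear interpolation)."""
    values = np.asarray(series, dtype=float)
    if len(values) == 0:
        raise ValueError("empty MES series")
    if not (0.0 <= p <= 100.0):
        raise ValueError("percentile must lie in [0, 100]")
    return float(np.percentile(values, p, method="linear"))


def percentile_correlation_scan(
    mes_by_subject: dict[str, np.ndarray],
    scores: dict[str, float],
    percentiles=None,
) -> PercentileCorrelationCurve:
    """Spearman correlation of per-subject percentile-MES with clinical scores.

    For each percentile p, every subject's session-wide MES is reduced to
    its p-th percentile and correlated (Spearman) with the clinical score
    across subjects.  Needs >= 5 subjects present in both mappings.
    Constant scores leave rho undefined (NaN, with a warning).
    """
    subjects = sorted(set(mes_by_subject) & set(scores))
    if len(subjects) < 5:
        raise ValueError("percentile correlation scan needs >= 5 scored subjects")
    y = np.array([scores[s] for s in subjects], dtype=float)
    ps = np.arange(1, 101) if percentiles is None else np.asarray(percentiles)
    rho = np.empty(len(ps))
    pv = np.empty(len(ps))
    constant = np.ptp(y) == 0
    if constant:
        warnings.warn("clinical scores are constant; correlations undefined (NaN)")
    for i, p in enumerate(ps):
        x = np.array([mes_percentile(mes_by_subject[s], p) for s in subjects])
        if constant or np.ptp(x) == 0:
            rho[i], pv[i] = np.nan, np.nan
        else:
            r = stats.spearmanr(x, y)
            rho[i], pv[i] = r.statistic, r.pvalue
    return PercentileCorrelationCurve(ps.astype(int), rho, pv)


def pairwise_auc(
    patient_vectors,
    control_vectors,
    n_iter: int = 10,
    rng=None,
    **fit_kwargs,
) -> float:
    """AUC of MES distributions from a dedicated per-pair classifier.

    A fresh classifier is fit for the (patient, control) pair; both sides'
    epochs are scored with its full-data hyperplane and the MES
    distributions compared by ROC (patient positive).  Session lengths vary
    by a few epochs, so when the patient session is the longer one its
    epochs are subsampled (without replacement) to the control count before
    fitting; all epochs still get scored.
    """
    rng = np.random.default_rng(rng)
    fit_patient = patient_vectors
    if len(patient_vectors) > len(control_vectors):
        idx = rng.choice(len(patient_vectors), size=len(control_vectors), replace=False)
        fit_patient = (
            patient_vectors.iloc[idx]
            if isinstance(patient_vectors, pd.DataFrame)
            else np.asarray(patient_vectors)[idx]
        )
    report = fit_mes_classifier(
        fit_patient, control_vectors, n_iter=n_iter, rng=rng, **fit_kwargs
    )
    plane = report.mes_hyperplane
    names = list(plane.metric_names)
    xp = patient_vectors[names].to_numpy(dtype=float) if isinstance(patient_vectors, pd.DataFrame) else np.asarray(patient_vectors)
    xc = control_vectors[names].to_numpy(dtype=float) if isinstance(control_vectors, pd.DataFrame) else np.asarray(control_vectors)
    return roc_auc(plane.mes(xp), plane.mes(xc))


def pooled_roc(
    group_mes,
    control_mes,
    n_boot: int = 100,
    rng=None,
) -> tuple[float, float]:
    """Pooled-epoch AUC with a label-permutation bootstrap p-value.

    p = (1 + #{null AUC >= observed}) / (n_boot + 1), so p is never zero at
    finite n_boot.
    """
    if n_boot < 20:
        warnings.warn(f"n_boot={n_boot} is small; bootstrap p will be coarse")
    rng = np.random.default_rng(rng)
    pos = np.asarray(group_mes, dtype=float)
    neg = np.asarray(control_mes, dtype=float)
    obs = roc_auc(pos, neg)
    pooled = np.concatenate([pos, neg])
    k = 0
    for _ in range(n_boot):
        perm = rng.permutation(len(pooled))
        a = roc_auc(pooled[perm[: len(pos)]], pooled[perm[len(pos) :]])
        if a >= obs:
            k += 1
    return obs, (k + 1) / (n_boot + 1)


def phenotype_classify(score: ClinicalScore) -> str:
    """TD / mixed / PIGD phenotype from the tremor-to-PIGD item-mean ratio.

    Ratio > 1.5 -> "TD"; ratio < 1 -> "PIGD"; between (inclusive) ->
    "mixed".  A zero PIGD mean with nonzero tremor counts as TD; both means
    zero is undefined and raises.
    """
    tr, pg = score.tremor_item_mean, score.pigd_item_mean
    if pg < 0 or tr < 0:
        raise ValueError("item means must be non-negative")
    if pg == 0:
        if tr == 0:
            raise ValueError(
                f"phenotype undefined for {score.subject_id}: both item means are zero"
            )
        return "TD"
    ratio = tr / pg
    if ratio > 1.5:
        return "TD"
    if ratio < 1.0:
        return "PIGD"
    return "mixed"


def weight_profile_table(
    planes: dict[str, tuple[str, Hyperplane]]
) -> pd.DataFrame:
    """Long-format metric-weight table across subjects.

    ``planes`` maps subject_id -> (group_label, hyperplane).  One row per
    subject x metric with its weight; weights of each subject sum to 1.
    """
    if not planes:
        raise ValueError("need at least one hyperplane")
    metric_sets = {tuple(h.metric_names) for _, h in planes.values()}
    if len(metric_sets) > 1:
        raise ValueError(f"mismatched metric sets across hyperplanes: {metric_sets}")
    rows = []
    for sid, (group, plane) in sorted(planes.items()):
        w = metric_weights(plane)
        for metric, weight in w.items():
            rows.append({"subject_id": sid, "group": group, "metric": metric, "weight": weight})
    return pd.DataFrame(rows)


def group_mean_weights(table: pd.DataFrame) -> pd.DataFrame:
    """Group-mean weight per metric from a long-format weight table."""
    return table.pivot_table(index="metric", columns="group", values="weight", aggfunc="mean")
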