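"""Statistical comparison pipeline over per-subject records.

Covers the study-style analyses: three-group comparison (one-way ANOVA or
Kruskal-Wallis chosen by a Shapiro normality screen, with Tukey or Dunn-Holm
post-hocs), paired comparison between the adjusted and unadjusted methods
(paired t-test plus mean percent difference), Pearson correlations, ROC/AUC
for DSPN discrimination with DeLong confidence intervals, a paired multi-AUC
equality chi² test (DeLong), and interobserver agreement (paired t-test and
coefficients of variation).

AUC orientation: nerve metrics fall with disease, so scores are negated by
default ("lower metric ⇒ disease"), putting an informative AUC above 0.5.
The AUC is computed as the concordant-pair fraction (Mann-Whitney form),
identical to the trapezoidal area under the empirical ROC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .data_model import GROUPS, SubjectRecord, ValidationError

__all__ = [
    "GroupComparison",
    "PairedReport",
    "CorrelationReport",
    "ROCReport",
    "AUCComparison",
    "InterobserverReport",
    "group_compare",
    "paired_methods_test",
    "correlate",
    "roc_analysis",
    "compare_aucs",
    "interobserver",
]


# ---------------------------------------------------------------------------
# report containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    mode: str
    test: str                      # "anova" or "kruskal"
    statistic: float
    p_value: float
    group_means: dict
    group_sds: dict
    group_ns: dict
    posthoc: pd.DataFrame          # pair, statistic, p_adjusted


@dataclass(frozen=True)
class PairedReport:
    metric: str
    method_a: str
    method_b: str
    t_statistic: float
    p_value: float
    mean_a: float
    mean_b: float
    percent_difference: float      # 100·(mean_a − mean_b)/mean_b
    n: int


@dataclass(frozen=True)
class CorrelationReport:
    r: float
    p_value: float
    slope: float
    intercept: float
    n: int


@dataclass(frozen=True)
class ROCReport:
    metric: str
    mode: str
    auc: float
    ci_low: float
    ci_high: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    scores: np.ndarray             # oriented scores (higher ⇒ more disease-like)
    labels: np.ndarray             # 1 = positive class
    subject_ids: tuple


@dataclass(frozen=True)
class AUCComparison:
    chi2: float
    p_value: float
    df: int
    aucs: tuple


@dataclass(frozen=True)
class InterobserverReport:
    per_metric: pd.DataFrame       # t, p, cv_a_percent, cv_b_percent
    n: int


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _metric_value(record: SubjectRecord, metric: str, mode: str) -> float:
    if metric == "ienfd":
        if record.ienfd is None:
            raise ValidationError(f"subject {record.subject_id!r} has no IENFD")
        return record.ienfd
    return getattr(record.metrics(mode), metric)


def _group_arrays(records: Sequence[SubjectRecord], metric: str, mode: str) -> dict:
    out: dict = {}
    for r in records:
        out.setdefault(r.group, []).append(_metric_value(r, metric, mode))
    return {g: np.asarray(v, dtype=float) for g, v in out.items()}


def _is_normal(x: np.ndarray, alpha: float) -> bool:
    if len(x) < 3 or np.ptp(x) == 0:
        return False
    try:
        return sps.shapiro(x).pvalue >= alpha
    except Exception:
        return False


def _dunn_posthoc(groups: dict) -> pd.DataFrame:
    """Dunn's rank-sum z-tests with tie correction, Holm-adjusted."""
    names = list(groups)
    all_vals = np.concatenate([groups[g] for g in names])
    n_total = len(all_vals)
    ranks = sps.rankdata(all_vals)
    mean_ranks, sizes, start = {}, {}, 0
    for g in names:
        k = len(groups[g])
        mean_ranks[g] = float(ranks[start : start + k].mean())
        sizes[g] = k
        start += k
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    rows, pvals = [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = 0.0 if se == 0 else (mean_ranks[a] - mean_ranks[b]) / se
            p = 2.0 * sps.norm.sf(abs(z))
            rows.append({"pair": f"{a} vs {b}", "statistic": z})
            pvals.append(p)
    adj = multipletests(pvals, method="holm")[1] if pvals else []
    df = pd.DataFrame(rows)
    df["p_adjusted"] = adj
    return df


def _tukey_posthoc(groups: dict) -> pd.DataFrame:
    names = list(groups)
    res = sps.tukey_hsd(*[groups[g] for g in names])
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append(
                {
                    "pair": f"{names[i]} vs {names[j]}",
                    "statistic": float(res.statistic[i, j]),
                    "p_adjusted": float(res.pvalue[i, j]),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def group_compare(
    records: Sequence[SubjectRecord],
    metric: str,
    mode: str = "adjusted",
    alpha: float = 0.05,
    force: str | None = None,
) -> GroupComparison:
    """Compare groups with one-way ANOVA or Kruskal-Wallis.

    A per-group Shapiro screen (at ``alpha``) picks the test: ANOVA when every
    group looks normal, Kruskal-Wallis otherwise; ``force`` overrides with
    ``"anova"`` or ``"kruskal"``.  Post-hoc pairs use Tukey's HSD after ANOVA
    and Dunn's test with Holm adjustment after Kruskal-Wallis.
    """
    groups = _group_arrays(records, metric, mode)
    if len(groups) < 2:
        raise ValidationError("group comparison needs ≥ 2 groups")
    for g, vals in groups.items():
        if len(vals) < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 subjects")
    if force is None:
        test = "anova" if all(_is_normal(v, alpha) for v in groups.values()) else "kruskal"
    elif force in ("anova", "kruskal"):
        test = force
    else:
        raise ValidationError("force must be 'anova' or 'kruskal'")
    arrays = list(groups.values())
    if all(np.ptp(np.concatenate(arrays)) == 0 for _ in (0,)):
        stat, p = 0.0, 1.0  # all observations identical: no evidence of any effect
    elif test == "anova":
        stat, p = sps.f_oneway(*arrays)
    else:
        try:
            stat, p = sps.kruskal(*arrays)
        except ValueError:  # all numbers identical
            stat, p = 0.0, 1.0
    posthoc = _tukey_posthoc(groups) if test == "anova" else _dunn_posthoc(groups)
    return GroupComparison(
        metric=metric,
        mode=mode,
        test=test,
        statistic=float(stat),
        p_value=float(p),
        group_means={g: float(v.mean()) for g, v in groups.items()},
        group_sds={g: float(v.std(ddof=1)) for g, v in groups.items()},
        group_ns={g: int(len(v)) for g, v in groups.items()},
        posthoc=posthoc,
    )


def paired_methods_test(
    records: Sequence[SubjectRecord],
    metric: str,
    method_a: str = "adjusted",
    method_b: str = "unadjusted",
) -> PairedReport:
    """Paired t-test between two modes plus the mean percent difference
    ``100·(mean_a − mean_b)/mean_b``."""
    a = np.array([_metric_value(r, metric, method_a) for r in records], dtype=float)
    b = np.array([_metric_value(r, metric, method_b) for r in records], dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValidationError("paired test needs ≥ 2 complete pairs")
    diffs = a - b
    if np.allclose(diffs, 0.0):
        t, p = 0.0, 1.0
    else:
        t, p = sps.ttest_rel(a, b)
    mean_b = float(b.mean())
    if mean_b == 0:
        raise ValidationError("method_b mean is zero; percent difference undefined")
    return PairedReport(
        metric=metric,
        method_a=method_a,
        method_b=method_b,
        t_statistic=float(t),
        p_value=float(p),
        mean_a=float(a.mean()),
        mean_b=mean_b,
        percent_difference=100.0 * (float(a.mean()) - mean_b) / mean_b,
        n=len(a),
    )


def correlate(x, y) -> CorrelationReport:
    """Pearson correlation with the least-squares line for scatter plots."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValidationError("correlation needs n ≥ 3")
    if np.any(np.isnan(x)) or np.any(np.isnan(y)):
        raise ValidationError("missing values in correlation input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance in correlation input")
    r, p = sps.pearsonr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    return CorrelationReport(
        r=float(r), p_value=float(p), slope=float(slope), intercept=float(intercept), n=len(x)
    )


# -- ROC / DeLong -----------------------------------------------------------


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray) -> tuple:
    """DeLong structural components for k paired score vectors.

    ``scores``: (k, n) matrix, higher ⇒ more positive-like.  Returns the AUC
    vector (k,) and its k×k covariance matrix.
    """
    pos = scores[:, labels == 1]
    neg = scores[:, labels == 0]
    m, n = pos.shape[1], neg.shape[1]
    k = scores.shape[0]
    aucs = np.empty(k)
    v10 = np.empty((k, m))
    v01 = np.empty((k, n))
    for i in range(k):
        all_r = _midrank(np.concatenate([pos[i], neg[i]]))
        pos_r = _midrank(pos[i])
        neg_r = _midrank(neg[i])
        aucs[i] = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        v10[i] = (all_r[:m] - pos_r) / n
        v01[i] = 1.0 - (all_r[m:] - neg_r) / m
    s10 = np.cov(v10) if k > 1 else np.atleast_2d(np.var(v10[0], ddof=1))
    s01 = np.cov(v01) if k > 1 else np.atleast_2d(np.var(v01[0], ddof=1))
    cov = np.atleast_2d(s10) / m + np.atleast_2d(s01) / n
    return aucs, cov


def roc_analysis(
    records: Sequence[SubjectRecord],
    metric: str,
    mode: str = "adjusted",
    positive_group: str = "dspn_plus",
    direction: str = "lower",
    alpha: float = 0.05,
) -> ROCReport:
    """Empirical ROC and AUC for discriminating the positive group.

    The negative class pools all remaining groups.  ``direction="lower"``
    (default for nerve metrics) negates the values so that lower metric values
    score as disease-like; ``"higher"`` leaves them as-is.  The AUC equals the
    Mann-Whitney concordant-pair fraction; its CI uses the DeLong variance.
    """
    if direction not in ("lower", "higher"):
        raise ValidationError("direction must be 'lower' or 'higher'")
    values, labels, ids = [], [], []
    for r in records:
        values.append(_metric_value(r, metric, mode))
        labels.append(1 if r.group == positive_group else 0)
        ids.append(r.subject_id)
    labels = np.asarray(labels)
    if labels.sum() < 2 or (labels == 0).sum() < 2:
        raise ValidationError("ROC needs at least 2 subjects in each class")
    scores = np.asarray(values, dtype=float)
    if direction == "lower":
        scores = -scores
    aucs, cov = _delong_components(scores[None, :], labels)
    auc = float(aucs[0])
    se = float(np.sqrt(max(cov[0, 0], 0.0)))
    z = sps.norm.ppf(1 - alpha / 2)
    from sklearn.metrics import roc_curve

    fpr, tpr, thresholds = roc_curve(labels, scores)
    return ROCReport(
        metric=metric,
        mode=mode,
        auc=auc,
        ci_low=max(0.0, auc - z * se),
        ci_high=min(1.0, auc + z * se),
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
        scores=scores,
        labels=labels,
        subject_ids=tuple(ids),
    )


def compare_aucs(*rocs: ROCReport) -> AUCComparison:
    """Paired DeLong chi² test of AUC equality across k ROC analyses.

    All ROCs must come from the same subjects in the same order.  The test
    statistic is ``(L·a)ᵀ (L·S·Lᵀ)⁻¹ (L·a)`` with contrasts ``L`` of adjacent
    differences, ``a`` the AUC vector and ``S`` its DeLong covariance;
    df = k − 1.  Identical inputs give chi² = 0, p = 1 exactly.
    """
    if len(rocs) < 2:
        raise ValidationError("compare_aucs needs at least two ROC reports")
    ids0, labels0 = rocs[0].subject_ids, rocs[0].labels
    for r in rocs[1:]:
        if r.subject_ids != ids0 or not np.array_equal(r.labels, labels0):
            raise ValidationError("ROC reports are not paired (different subjects/labels)")
    scores = np.vstack([r.scores for r in rocs])
    aucs, cov = _delong_components(scores, labels0)
    k = len(rocs)
    L = np.zeros((k - 1, k))
    for i in range(k - 1):
        L[i, 0] = 1.0
        L[i, i + 1] = -1.0
    d = L @ aucs
    if np.allclose(d, 0.0):
        return AUCComparison(chi2=0.0, p_value=1.0, df=k - 1, aucs=tuple(aucs))
    chi2 = float(d @ np.linalg.pinv(L @ cov @ L.T) @ d)
    p = float(sps.chi2.sf(chi2, k - 1))
    return AUCComparison(chi2=chi2, p_value=p, df=k - 1, aucs=tuple(float(a) for a in aucs))


def interobserver(
    observer_a: pd.DataFrame,
    observer_b: pd.DataFrame,
    metrics: Sequence[str] = ("cnfl", "cnfd", "cnbd"),
) -> InterobserverReport:
    """Agreement between two observers' per-subject metrics.

    Inputs are DataFrames indexed by subject with one column per metric.
    Reports a paired t-test per metric and each observer's coefficient of
    variation (SD/mean × 100%).
    """
    if not observer_a.index.equals(observer_b.index):
        raise ValidationError("observers must rate the same subjects in the same order")
    if len(observer_a) < 2:
        raise ValidationError("interobserver comparison needs ≥ 2 subjects")
    rows = []
    for m in metrics:
        a = observer_a[m].to_numpy(dtype=float)
        b = observer_b[m].to_numpy(dtype=float)
        if np.allclose(a - b, 0.0):
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_rel(a, b)
        cv = lambda x: 0.0 if x.mean() == 0 else 100.0 * x.std(ddof=1) / x.mean()
        rows.append(
            {
                "metric": m,
                "t_statistic": float(t),
                "p_value": float(p),
                "cv_a_percent": float(cv(a)),
                "cv_b_percent": float(cv(b)),
            }
        )
    return InterobserverReport(per_metric=pd.DataFrame(rows).set_index("metric"), n=len(observer_a))
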