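import numpy as np
import pandas as pd
import pytest

from stereoccm.data_model import CCMMetrics, SubjectRecord, ValidationError
from stereoccm.stats import (
    compare_aucs,
    correlate,
    group_compare,
    interobserver,
    paired_methods_test,
    roc_analysis,
)


def _record(subject_id, group, cnfl_adj, cnfl_unadj=None, ienfd=None):
    cnfl_unadj = cnfl_adj / 1.5 if cnfl_unadj is None else cnfl_unadj
    return SubjectRecord(
        subject_id=subject_id,
        group=group,
        metrics_adjusted=CCMMetrics(cnfl_adj, cnfl_adj + 1, cnfl_adj + 2, 0.1, "adjusted"),
        metrics_unadjusted=CCMMetrics(cnfl_unadj, cnfl_unadj + 1, cnfl_unadj + 2, 0.16, "unadjusted"),
        ienfd=ienfd,
    )


def _cohort(values_by_group, ienfd_by_group=None):
    records = []
    for g, values in values_by_group.items():
        for i, v in enumerate(values):
            ienfd = None
            if ienfd_by_group is not None:
                ienfd = ienfd_by_group[g][i]
            records.append(_record(f"{g}{i}", g, float(v), ienfd=ienfd))
    return records


# -- group comparison ---------------------------------------------------------


def test_identical_groups_yield_p_near_one(rng):
    base = rng.normal(10, 1, 12)
    records = _cohort({"control": base, "dspn_minus": base, "dspn_plus": base})
    rep = group_compare(records, "cnfl")
    assert rep.p_value > 0.99
    assert rep.statistic == pytest.approx(0.0, abs=1e-10)


def test_separated_group_detected(rng):
    records = _cohort(
        {
            "control": rng.normal(10, 1, 30),
            "dspn_minus": rng.normal(10, 1, 30),
            "dspn_plus": rng.normal(5, 1, 30),
        }
    )
    rep = group_compare(records, "cnfl")
    assert rep.p_value < 1e-3
    plus_pairs = rep.posthoc[rep.posthoc["pair"].str.contains("dspn_plus")]
    assert (plus_pairs["p_adjusted"] < 0.01).all()


def test_constant_tied_groups_handled():
    records = _cohort({"control": [5.0] * 4, "dspn_plus": [5.0] * 4})
    rep = group_compare(records, "cnfl", force="kruskal")
    assert rep.p_value == 1.0
    assert rep.statistic == 0.0


def test_small_group_rejected():
    records = _cohort({"control": [1.0, 2.0], "dspn_plus": [3.0]})
    with pytest.raises(ValidationError):
        group_compare(records, "cnfl")


def test_normality_screen_switches_test(rng):
    normal = _cohort(
        {"control": rng.normal(10, 1, 25), "dspn_plus": rng.normal(11, 1, 25)}
    )
    skewed = _cohort(
        {"control": rng.lognormal(0, 1.5, 25), "dspn_plus": rng.lognormal(0.3, 1.5, 25)}
    )
    assert group_compare(normal, "cnfl").test == "anova"
    assert group_compare(skewed, "cnfl").test == "kruskal"


# -- paired methods -----------------------------------------------------------


def test_equal_methods_give_zero_difference(rng):
    vals = rng.normal(15, 2, 20)
    records = [_record(f"s{i}", "control", v, cnfl_unadj=v) for i, v in enumerate(vals)]
    rep = paired_methods_test(records, "cnfl")
    assert rep.t_statistic == 0.0
    assert rep.p_value == 1.0
    assert rep.percent_difference == pytest.approx(0.0, abs=1e-12)


def test_twenty_percent_inflation_closed_form(rng):
    """If b = 1.2·a exactly, the percent difference of a vs b is −16.67%."""
    vals = rng.uniform(5, 25, 15)
    records = [_record(f"s{i}", "control", v, cnfl_unadj=1.2 * v) for i, v in enumerate(vals)]
    rep = paired_methods_test(records, "cnfl")
    assert rep.percent_difference == pytest.approx(-100.0 / 6.0, rel=1e-9)


def test_mismatched_lengths_rejected():
    with pytest.raises(ValidationError):
        paired_methods_test([_record("s1", "control", 10.0)], "cnfl")


# -- correlation --------------------------------------------------------------


def test_perfect_linear_correlation(rng):
    x = rng.uniform(0, 10, 20)
    rep = correlate(x, 2 * x)
    assert rep.r == pytest.approx(1.0)
    assert rep.slope == pytest.approx(2.0, rel=1e-9)


def test_anticorrelation_limit(rng):
    x = rng.uniform(0, 10, 30)
    rep = correlate(x, -x + rng.normal(0, 1e-9, 30))
    assert rep.r == pytest.approx(-1.0, abs=1e-6)


def test_zero_variance_rejected():
    with pytest.raises(ValidationError):
        correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_independent_samples_have_small_r(rng):
    hits = 0
    for _ in range(100):
        x = rng.normal(size=88)
        y = rng.normal(size=88)
        if abs(correlate(x, y).r) < 0.3:
            hits += 1
    assert hits >= 97


# -- ROC / AUC ----------------------------------------------------------------


def _brute_force_auc(scores, labels):
    """Concordant-pair fraction with half credit for ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_perfect_separation_gives_auc_one():
    records = _cohort({"control": [10, 11, 12, 13], "dspn_plus": [1, 2, 3, 4]})
    rep = roc_analysis(records, "cnfl")
    assert rep.auc == pytest.approx(1.0)


def test_auc_equals_concordant_pair_fraction(rng):
    """Implementation AUC matches the exhaustive pairwise oracle and sklearn."""
    from sklearn.metrics import roc_auc_score

    for _ in range(20):
        n = int(rng.integers(6, 25))
        values = np.round(rng.normal(10, 3, n), 1)  # rounding forces ties
        groups = rng.choice(["control", "dspn_plus"], n)
        if (groups == "dspn_plus").sum() < 2 or (groups == "control").sum() < 2:
            continue
        records = [
            _record(f"s{i}", g, float(v)) for i, (g, v) in enumerate(zip(groups, values))
        ]
        rep = roc_analysis(records, "cnfl")
        labels = (groups == "dspn_plus").astype(int)
        oracle = _brute_force_auc(-values, labels)
        assert rep.auc == pytest.approx(oracle, abs=1e-12)
        assert rep.auc == pytest.approx(roc_auc_score(labels, -values), abs=1e-12)


def test_null_auc_is_half_on_average(rng):
    aucs = []
    for _ in range(200):
        values = rng.normal(50, 3, 88)
        groups = np.array(["control"] * 71 + ["dspn_plus"] * 17)
        rng.shuffle(groups)
        records = [
            _record(f"s{i}", g, float(v)) for i, (g, v) in enumerate(zip(groups, values))
        ]
        aucs.append(roc_analysis(records, "cnfl").auc)
    assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)


def test_one_class_missing_rejected():
    records = _cohort({"control": [1, 2, 3, 4]})
    with pytest.raises(ValidationError):
        roc_analysis(records, "cnfl")


# -- AUC comparison -----------------------------------------------------------


def test_identical_rocs_give_chi2_zero(rng):
    values = rng.normal(10, 2, 40)
    groups = np.array(["control"] * 30 + ["dspn_plus"] * 10)
    records = [
        _record(f"s{i}", g, float(v), ienfd=float(v))
        for i, (g, v) in enumerate(zip(groups, values))
    ]
    roc_a = roc_analysis(records, "cnfl")
    roc_b = roc_analysis(records, "cnfl")
    rep = compare_aucs(roc_a, roc_b)
    assert rep.chi2 == 0.0
    assert rep.p_value == 1.0


def test_two_sample_comparison_matches_z_squared(rng):
    """k=2 chi² equals the squared paired DeLong z statistic."""
    from stereoccm.stats import _delong_components

    n = 60
    signal = np.concatenate([rng.normal(1.0, 1, 15), rng.normal(0, 1, n - 15)])
    noise = rng.normal(0, 1, n)
    groups = np.array(["dspn_plus"] * 15 + ["control"] * (n - 15))
    records = []
    for i in range(n):
        rec = SubjectRecord(
            subject_id=f"s{i}",
            group=groups[i],
            metrics_adjusted=CCMMetrics(max(signal[i] + 10, 0), 1, 1, 0.1, "adjusted"),
            metrics_unadjusted=CCMMetrics(max(noise[i] + 10, 0), 1, 1, 0.16, "unadjusted"),
        )
        records.append(rec)
    roc_a = roc_analysis(records, "cnfl", mode="adjusted")
    roc_b = roc_analysis(records, "cnfl", mode="unadjusted")
    rep = compare_aucs(roc_a, roc_b)
    scores = np.vstack([roc_a.scores, roc_b.scores])
    aucs, cov = _delong_components(scores, roc_a.labels)
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    z2 = (aucs[0] - aucs[1]) ** 2 / var_diff
    assert rep.chi2 == pytest.approx(z2, rel=1e-9)
    assert rep.df == 1


def test_strong_predictor_rejects_equality(rng):
    """A strong predictor vs two weak ones is detected in most replicates."""
    rejections = 0
    n_rep = 30
    for _ in range(n_rep):
        n1, n0 = 40, 80
        labels_groups = ["dspn_plus"] * n1 + ["control"] * n0
        strong = np.concatenate([rng.normal(2.5, 1, n1), rng.normal(0, 1, n0)])
        weak1 = np.concatenate([rng.normal(0.2, 1, n1), rng.normal(0, 1, n0)])
        records = []
        for i in range(n1 + n0):
            records.append(
                SubjectRecord(
                    subject_id=f"s{i}",
                    group=labels_groups[i],
                    metrics_adjusted=CCMMetrics(strong[i] + 10, 1, 1, 0.1, "adjusted"),
                    metrics_unadjusted=CCMMetrics(weak1[i] + 10, 1, 1, 0.16, "unadjusted"),
                )
            )
        roc_a = roc_analysis(records, "cnfl", mode="adjusted", direction="higher")
        roc_b = roc_analysis(records, "cnfl", mode="unadjusted", direction="higher")
        if compare_aucs(roc_a, roc_b).p_value < 0.05:
            rejections += 1
    assert rejections >= 0.7 * n_rep


def test_unpaired_rocs_rejected(rng):
    values = rng.normal(10, 2, 20)
    groups = np.array(["control"] * 15 + ["dspn_plus"] * 5)
    recs_a = [_record(f"a{i}", g, float(v)) for i, (g, v) in enumerate(zip(groups, values))]
    recs_b = [_record(f"b{i}", g, float(v)) for i, (g, v) in enumerate(zip(groups, values))]
    with pytest.raises(ValidationError):
        compare_aucs(roc_analysis(recs_a, "cnfl"), roc_analysis(recs_b, "cnfl"))


# -- interobserver ------------------------------------------------------------


def test_identical_observers_agree_exactly(rng):
    df = pd.DataFrame(
        {"cnfl": rng.uniform(10, 20, 5), "cnfd": rng.uniform(20, 40, 5), "cnbd": rng.uniform(30, 60, 5)},
        index=[f"s{i}" for i in range(5)],
    )
    rep = interobserver(df, df.copy())
    assert (rep.per_metric["p_value"] == 1.0).all()
    assert (rep.per_metric["t_statistic"] == 0.0).all()
    assert np.allclose(rep.per_metric["cv_a_percent"], rep.per_metric["cv_b_percent"])


def test_constant_shift_detected(rng):
    a = pd.DataFrame(
        {"cnfl": rng.uniform(10, 20, 8), "cnfd": rng.uniform(20, 40, 8), "cnbd": rng.uniform(30, 60, 8)},
        index=[f"s{i}" for i in range(8)],
    )
    b = a + 2.0 + rng.normal(0, 1e-9, a.shape)
    rep = interobserver(a, b)
    assert (rep.per_metric["p_value"] < 1e-6).all()


def test_constant_series_has_zero_cv():
    a = pd.DataFrame({"cnfl": [10.0, 10.0, 10.0]}, index=["s1", "s2", "s3"])
    rep = interobserver(a, a.copy(), metrics=("cnfl",))
    assert rep.per_metric.loc["cnfl", "cv_a_percent"] == 0.0


def test_mismatched_subjects_rejected():
    a = pd.DataFrame({"cnfl": [1.0, 2.0]}, index=["s1", "s2"])
    b = pd.DataFrame({"cnfl": [1.0, 2.0]}, index=["s1", "s3"])
    with pytest.raises(ValidationError):
        interobserver(a, b, metrics=("cnfl",))
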