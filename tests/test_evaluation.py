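"""Fold geometry, ROC/ORP, repeated CV, ranking and Friedman comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nkdetect.ensemble import EnsembleConfig
from nkdetect.evaluation import (
    ConfusionCounts,
    CostSpec,
    confusion_metrics,
    friedman_compare,
    kfold_partitions,
    optimal_roc_point,
    posthoc_bonferroni,
    rank_and_best,
    repeated_cv,
    roc_and_auc,
)


# --- folds ----------------------------------------------------------------

def test_71_into_10_folds_gives_one_8_and_nine_7():
    folds = kfold_partitions(71, 10, seed=0)
    sizes = sorted(len(f) for f in folds)
    assert sizes == [7] * 9 + [8]


def test_20_into_10_folds_gives_ten_2():
    assert [len(f) for f in kfold_partitions(20, 10, seed=1)] == [2] * 10


def test_folds_partition_the_index_set():
    rng = np.random.default_rng(2)
    for _ in range(100):
        n = int(rng.integers(10, 200))
        k = int(rng.integers(2, min(n, 15) + 1))
        folds = kfold_partitions(n, k, seed=int(rng.integers(2**31)))
        allidx = np.concatenate(folds)
        assert len(allidx) == n and len(np.unique(allidx)) == n
        assert max(len(f) for f in folds) - min(len(f) for f in folds) <= 1


def test_stratified_folds_spread_classes():
    y = np.array([1] * 10 + [0] * 40)
    folds = kfold_partitions(50, 10, seed=3, stratify=y)
    assert all(y[f].sum() == 1 for f in folds)


def test_too_many_folds_errors():
    with pytest.raises(ValueError):
        kfold_partitions(5, 10, seed=0)


# --- confusion metrics ----------------------------------------------------

def test_confusion_metrics_hand_arithmetic():
    m = confusion_metrics(ConfusionCounts(tp=3, fn=1, tn=4, fp=1))
    assert m["tpr"] == pytest.approx(0.75)
    assert m["fpr"] == pytest.approx(0.2)
    assert m["accuracy"] == pytest.approx(7 / 9)
    perfect = confusion_metrics(ConfusionCounts(tp=41, tn=30, fp=0, fn=0))
    assert perfect["accuracy"] == 1.0 and perfect["fpr"] == 0.0


def test_confusion_label_swap_symmetry():
    rng = np.random.default_rng(4)
    for _ in range(20):
        tp, tn, fp, fn = rng.integers(1, 50, 4)
        m = confusion_metrics(ConfusionCounts(tp, tn, fp, fn))
        sw = confusion_metrics(ConfusionCounts(tn, tp, fn, fp))
        assert sw["tpr"] == pytest.approx(m["tnr"])
        assert sw["fpr"] == pytest.approx(m["fnr"])


def test_confusion_empty_class_is_nan():
    m = confusion_metrics(ConfusionCounts(tp=0, fn=0, tn=4, fp=1))
    assert np.isnan(m["tpr"]) and np.isnan(m["fnr"])


# --- ROC / AUC / ORP ------------------------------------------------------

def test_auc_extremes():
    y = np.array([0, 0, 1, 1])
    assert roc_and_auc([0.1, 0.2, 0.8, 0.9], y)[2] == 1.0
    assert roc_and_auc([0.5, 0.5, 0.5, 0.5], y)[2] == 0.5


def test_auc_equals_mann_whitney_u_statistic():
    rng = np.random.default_rng(5)
    for _ in range(200):
        n = int(rng.integers(6, 40))
        y = np.zeros(n, int)
        y[rng.choice(n, int(rng.integers(1, n)), replace=False)] = 1
        if y.sum() in (0, n):
            continue
        scores = np.round(rng.random(n), 2)  # induce ties
        _, _, auc = roc_and_auc(scores, y)
        pos, neg = scores[y == 1], scores[y == 0]
        u = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert auc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-10)


def test_single_class_roc_errors():
    with pytest.raises(ValueError):
        roc_and_auc([0.1, 0.9], np.array([1, 1]))


def test_orp_slope_is_one_for_unit_costs_balanced_classes():
    assert CostSpec().slope(10, 10) == 1.0
    assert CostSpec().slope(41, 30) == pytest.approx(30 / 41)


def test_orp_degenerate_costs_error():
    with pytest.raises(ValueError, match="degenerate"):
        CostSpec(cost_fn=0.0).slope(5, 5)


def test_orp_perfect_classifier_is_corner():
    y = np.array([0, 0, 1, 1])
    fpr, tpr, _ = roc_and_auc([0.1, 0.2, 0.8, 0.9], y)
    assert optimal_roc_point(fpr, tpr, CostSpec(), 2, 2) == (0.0, 1.0)


def test_orp_matches_brute_force_argmax():
    rng = np.random.default_rng(6)
    for _ in range(50):
        n = int(rng.integers(8, 60))
        y = (rng.random(n) < 0.5).astype(int)
        if y.sum() in (0, n):
            continue
        scores = rng.random(n)
        fpr, tpr, _ = roc_and_auc(scores, y)
        costs = CostSpec(cost_fn=rng.uniform(0.5, 2), cost_fp=rng.uniform(0.5, 2))
        p, q = int(y.sum()), int((1 - y).sum())
        got = optimal_roc_point(fpr, tpr, costs, p, q)
        s = costs.slope(p, q)
        obj = tpr - s * fpr
        best = obj.max()
        assert got[1] - s * got[0] == pytest.approx(best, abs=1e-12)
        assert (got[0], got[1]) in set(zip(fpr, tpr))  # lies on the curve
        assert got[0] == min(f for f, t in zip(fpr, tpr) if t - s * f >= best - 1e-12)


# --- repeated CV ----------------------------------------------------------

def test_repeated_cv_perfectly_separable():
    from nkdetect.cohort import Cohort

    rng = np.random.default_rng(7)
    n = 40
    y = np.array([0] * 20 + [1] * 20)
    values = rng.uniform(0, 20, (n, 32))
    values[y == 1, 0] += 70  # feature 1 fully separates
    c = Cohort(values, np.full(n, 8.0), y, [f"p{i}" for i in range(n)])
    rep = repeated_cv(c, [1], EnsembleConfig(seed=0), k=10, runs=5, master_seed=0)
    assert rep.means["auc"] == 1.0
    assert rep.stds["auc"] == 0.0
    assert rep.means["accuracy"] == 1.0


def test_repeated_cv_report_shape_and_mean_std(detection_cohort):
    rep = repeated_cv(
        detection_cohort, [2, 20, 27, 28], EnsembleConfig(seed=0),
        k=10, runs=4, master_seed=1, condition="GA",
    )
    assert list(rep.runs.columns) == ["auc", "orp_fpr", "orp_tpr", "accuracy"]
    assert len(rep.runs) == 4
    assert rep.mean_std == pytest.approx(rep.stds.mean())
    assert ((rep.runs >= 0) & (rep.runs <= 1)).all().all()


def test_out_of_fold_scores_cover_each_patient_once(detection_cohort):
    from nkdetect.evaluation import _model_scores

    X = detection_cohort.predictor_matrix([2, 20, 27, 28])
    y = detection_cohort.labels
    folds = kfold_partitions(len(y), 10, seed=0)
    scores = _model_scores(X, y, folds, EnsembleConfig(seed=0), 0)
    assert not np.isnan(scores).any()


def test_per_fold_mode_runs(detection_cohort):
    rep = repeated_cv(
        detection_cohort, [15, 16], EnsembleConfig(seed=0), k=5, runs=2,
        master_seed=0, mode="per-fold", stratify=True,
    )
    assert len(rep.runs) == 2


# --- ranking --------------------------------------------------------------

def _fake_report(name, auc):
    from nkdetect.evaluation import RunReport

    rng = np.random.default_rng(abs(hash(name)) % 2**31)
    runs = pd.DataFrame(
        {
            "auc": auc + rng.normal(0, 1e-4, 10),
            "orp_fpr": 0.2 + rng.normal(0, 1e-4, 10),
            "orp_tpr": 0.8 + rng.normal(0, 1e-4, 10),
            "accuracy": auc + rng.normal(0, 1e-4, 10),
        }
    )
    return RunReport(condition=name, feature_set=[1], runs=runs, k=10)


def test_rank_orders_by_mean_auc():
    agg, best = rank_and_best([_fake_report("A", 0.9), _fake_report("B", 0.7)])
    assert agg.loc[agg.condition == "A", "rank"].item() == 1
    assert agg.loc[agg.condition == "B", "rank"].item() == 2
    assert sorted(agg["rank"]) == [1, 2]
    # best single-run AUC is at least the mean AUC
    for _, row in best.iterrows():
        mean_auc = agg.loc[agg.condition == row.condition, "auc"].item()
        assert row.auc >= mean_auc - 1e-9


def test_rank_is_permutation_for_many_conditions():
    reports = [_fake_report(f"c{i}", 0.5 + 0.05 * i) for i in range(6)]
    agg, best = rank_and_best(reports)
    assert sorted(agg["rank"]) == list(range(1, 7))
    assert sorted(best["rank"]) == list(range(1, 7))


# --- Friedman / post-hoc --------------------------------------------------

def test_friedman_zero_on_identical_conditions():
    C = np.tile(np.random.default_rng(8).random(12)[:, None], (1, 4))
    res = friedman_compare(C)
    assert res.chi_sq == 0.0 and res.p == 1.0


def test_friedman_closed_form_for_fixed_rank_pattern():
    """One condition strictly dominant in all runs of 5 conditions: ranks
    are the same permutation every run, chi2 = n(k-1) * 12/(k(k+1)) * var
    term -> closed form n*(k-1) when ranks are 1..k each run is chi2 =
    n*(k-1)... computed directly from the rank-sum formula."""
    n, k = 30, 5
    rng = np.random.default_rng(9)
    base = rng.random((n, 1))
    C = np.hstack([base + j for j in range(k)])  # strict order every run
    res = friedman_compare(C)
    Rj = np.array([n * (j + 1) for j in range(k)], dtype=float)
    expected = 12.0 / (n * k * (k + 1)) * np.sum(Rj**2) - 3 * n * (k + 1)
    assert res.chi_sq == pytest.approx(expected, abs=1e-9)
    assert res.p < 1e-10
    assert res.mean_ranks[f"cond{k-1}"] == pytest.approx(k)


def test_friedman_matches_scipy_reference():
    rng = np.random.default_rng(10)
    for _ in range(50):
        n = int(rng.integers(5, 20))
        k = int(rng.integers(3, 7))
        C = rng.random((n, k))
        ours = friedman_compare(C)
        ref_chi, ref_p = stats.friedmanchisquare(*(C[:, j] for j in range(k)))
        assert ours.chi_sq == pytest.approx(ref_chi, abs=1e-9)
        assert ours.p == pytest.approx(ref_p, abs=1e-9)


def test_friedman_invariant_under_monotone_transform():
    rng = np.random.default_rng(11)
    C = rng.random((15, 4))
    a = friedman_compare(C).chi_sq
    b = friedman_compare(np.exp(3 * C)).chi_sq
    assert a == pytest.approx(b, abs=1e-9)


def test_posthoc_bonferroni_definition_and_cis():
    rng = np.random.default_rng(12)
    C = rng.random((20, 5))
    post = posthoc_bonferroni(C)
    assert len(post) == 10  # C(5,2)
    res = friedman_compare(C)
    se = np.sqrt(5 * 6 / (6.0 * 20))
    for _, row in post.iterrows():
        diff = res.mean_ranks[row.group_1] - res.mean_ranks[row.group_2]
        assert row["diff"] == pytest.approx(diff)
        assert row.ci_lower <= row["diff"] <= row.ci_upper
        raw = 2 * stats.norm.sf(abs(diff / se))
        assert row.p_adjusted == pytest.approx(min(1.0, raw * 10), abs=1e-12)


def test_posthoc_identical_conditions_all_p_one():
    C = np.tile(np.random.default_rng(13).random(10)[:, None], (1, 4))
    post = posthoc_bonferroni(C)
    assert (post["p_adjusted"] == 1.0).all()
    assert np.allclose(post["diff"], 0.0)
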