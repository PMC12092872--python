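"""Split plan, LASSO selection, and the preliminary loop bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from petrad import (
    SyntheticSpec,
    average_family_metrics,
    feature_frequency,
    lasso_select,
    make_split_plan,
    pick_candidates,
    simulate_feature_table,
    tune_family,
)
from petrad.models import FAMILIES
from petrad.stats import METRICS


def _cohort_labels(n_high=72, n_low=71):
    return np.array(["high"] * n_high + ["low"] * n_low)


# ---------------------------------------------------------------------------
# split plan


def test_split_plan_143_cohort_sizes():
    """A 72/71 cohort at test fraction 0.2 always holds out 15 high + 14 low."""
    y = _cohort_labels()
    plan = make_split_plan(y, reps=5, test_frac=0.2, k=5, seed=0)
    for rep in range(plan.reps):
        test = plan.test[rep]
        assert len(test) == 29
        assert (y[test] == "high").sum() == 15
        assert (y[test] == "low").sum() == 14


def test_split_plan_invariants():
    y = _cohort_labels(40, 35)
    plan = make_split_plan(y, reps=4, test_frac=0.2, k=5, seed=3)
    p_global = (y == "high").mean()
    n = len(y)
    for rep in range(plan.reps):
        tr, te = plan.train[rep], plan.test[rep]
        assert len(np.intersect1d(tr, te)) == 0
        assert len(tr) + len(te) == n
        # stratification within one patient of the global proportion
        assert abs((y[te] == "high").mean() - p_global) <= 1.0 / len(te)
        assert abs((y[tr] == "high").mean() - p_global) <= 1.0 / len(tr)
        # folds partition the training rows
        ids = plan.fold_ids[rep]
        assert sorted(np.unique(ids)) == list(range(plan.k))
        folds = plan.folds(rep)
        covered = np.sort(np.concatenate([va for _, va in folds]))
        assert np.array_equal(covered, np.arange(len(tr)))


def test_split_plan_deterministic_and_checksummed():
    y = _cohort_labels(30, 30)
    p1 = make_split_plan(y, reps=3, seed=9)
    p2 = make_split_plan(y, reps=3, seed=9)
    p3 = make_split_plan(y, reps=3, seed=10)
    assert p1.checksum() == p2.checksum() != p3.checksum()


def test_split_plan_roundtrips_through_json(tmp_path):
    from petrad.preliminary import SplitPlan

    y = _cohort_labels(20, 20)
    plan = make_split_plan(y, reps=2, seed=1)
    plan.to_json(tmp_path / "plan.json")
    loaded = SplitPlan.from_json(tmp_path / "plan.json")
    assert loaded.checksum() == plan.checksum()


def test_split_plan_rejects_single_class():
    with pytest.raises(ValueError, match="single class"):
        make_split_plan(np.array(["high"] * 50))


# ---------------------------------------------------------------------------
# LASSO


def test_lasso_selects_planted_features():
    table, labels, truth = simulate_feature_table(
        SyntheticSpec(n_patients=150, n_features=50, n_informative=5,
                      effect_size=2.0, seed=4)
    )
    selected = lasso_select(table, labels, seed=0)
    assert set(truth.informative_names) <= set(selected)


def test_lasso_never_selects_zero_variance_feature():
    table, labels, _ = simulate_feature_table(
        SyntheticSpec(n_patients=100, n_features=20, n_informative=3,
                      effect_size=2.0, seed=6)
    )
    table = table.copy()
    table["original_firstorder_Flat"] = 1.0
    assert "original_firstorder_Flat" not in lasso_select(table, labels, seed=0)


def test_lasso_rejects_constant_labels():
    table, _, _ = simulate_feature_table(SyntheticSpec(n_patients=40, n_features=10, seed=0))
    with pytest.raises(ValueError, match="constant"):
        lasso_select(table, np.array(["high"] * 40))


def test_lasso_1se_no_weaker_than_min_rule():
    table, labels, _ = simulate_feature_table(
        SyntheticSpec(n_patients=120, n_features=40, n_informative=4,
                      effect_size=1.5, seed=7)
    )
    k_1se = len(lasso_select(table, labels, lambda_rule="1se", seed=1))
    k_min = len(lasso_select(table, labels, lambda_rule="min", seed=1))
    assert k_1se <= k_min


# ---------------------------------------------------------------------------
# tuning


def test_tune_family_perfect_on_separable_toy():
    rng = np.random.default_rng(0)
    n = 60
    X = rng.normal(size=(n, 2))
    y = np.where(X[:, 0] > 0, "high", "low")
    X[:, 0] += np.where(y == "high", 3.0, -3.0)  # wide margin
    plan = make_split_plan(y, reps=1, test_frac=0.2, k=5, seed=0)
    folds = plan.folds(0)
    Xtr, ytr = X[plan.train[0]], y[plan.train[0]]
    for family in FAMILIES:
        tm = tune_family(family, Xtr, ytr, folds, budget=4, seed=0)
        assert tm.cv_error == 0.0, family
        assert tm.validation_auc == 1.0, family
        assert tm.params.keys() == set(tm.params)  # chosen params recorded


# ---------------------------------------------------------------------------
# the loop (shared small_run fixture)


def test_preliminary_cardinalities(small_run):
    _, _, _, plan, result = small_run
    assert len(result.selections) == plan.reps
    assert len(result.metrics) == plan.reps * len(FAMILIES)
    assert set(result.metrics["family"]) == set(FAMILIES)


def test_frequency_lattice_and_bruteforce_oracle(small_run):
    _, _, _, plan, result = small_run
    freq = feature_frequency(result)
    lattice = {100.0 * n / plan.reps for n in range(plan.reps + 1)}
    assert {round(v, 9) for v in freq} <= {round(v, 9) for v in lattice}
    # brute-force recount over the selection log
    for feature in result.feature_names:
        n_sel = sum(feature in sel for sel in result.selections)
        assert freq[feature] == pytest.approx(100.0 * n_sel / plan.reps)


def test_frequency_worked_values():
    log = [["a"]] * 29 + [[]]
    freq = feature_frequency(log, feature_names=["a", "b"])
    assert freq["a"] == pytest.approx(96.67, abs=0.005)
    assert freq["b"] == 0.0
    assert feature_frequency([["a"]] * 30, feature_names=["a"])["a"] == 100.0


def test_planted_features_lead_frequency(small_run):
    _, _, truth, _, result = small_run
    freq = feature_frequency(result)
    informative = list(truth.informative_names)
    nuisance = freq.drop(informative)
    assert freq[informative].min() > np.percentile(nuisance, 90)


def test_average_family_metrics_is_mean_over_reps(small_run):
    _, _, _, _, result = small_run
    means = average_family_metrics(result)
    for family in FAMILIES:
        sub = result.metrics[result.metrics["family"] == family]
        for m in METRICS:
            expected = sub[m].mean()
            assert means.loc[family, m] == pytest.approx(expected, nan_ok=True)


def test_pick_candidates_rules():
    means = pd.DataFrame(
        {"accuracy": [80, 70], "auc": [75, 90]},
        index=["A", "B"],
    )
    assert pick_candidates(means) == {"A", "B"}
    means_single = pd.DataFrame({"accuracy": [80, 70], "auc": [90, 75]}, index=["A", "B"])
    assert pick_candidates(means_single) == {"A"}
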