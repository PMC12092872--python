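"""Majority vote, weighted posterior, ROC/AUC and the fitted ensemble."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petrad import (
    FittedEnsemble,
    fit_ensemble,
    majority_vote,
    reference_spec,
    roc_auc,
    weighted_posterior,
)


# ---------------------------------------------------------------------------
# voting and scoring primitives


@pytest.mark.parametrize(
    "labels, expected",
    [
        (["high", "high", "low", "high", "low"], "high"),
        (["low"] * 5, "low"),
        (["high"], "high"),
    ],
)
def test_majority_vote(labels, expected):
    assert majority_vote(labels) == expected


def test_majority_vote_tie_falls_back_to_score():
    assert majority_vote(["high", "low"], score=0.7) == "high"
    assert majority_vote(["high", "low"], score=0.3) == "low"


def test_majority_vote_rejects_empty():
    with pytest.raises(ValueError):
        majority_vote([])


def test_weighted_posterior_values():
    assert weighted_posterior([0.2, 0.4, 0.6], [1, 1, 1]) == pytest.approx(0.4)
    assert weighted_posterior([0.9, 0.1, 0.5], [1, 0, 0]) == pytest.approx(0.9)


@settings(derandomize=True, max_examples=50)
@given(
    p=st.lists(st.floats(0, 1), min_size=1, max_size=8),
    c=st.floats(0.01, 100),
)
def test_weighted_posterior_scale_invariant(p, c):
    w = np.arange(1.0, len(p) + 1.0)
    assert weighted_posterior(p, w) == pytest.approx(weighted_posterior(p, c * w))


def test_weighted_posterior_rejects_zero_weights():
    with pytest.raises(ValueError, match="zero"):
        weighted_posterior([0.5, 0.5], [0.0, 0.0])


# ---------------------------------------------------------------------------
# AUC


def test_auc_perfect_separation():
    y = np.array(["low"] * 5 + ["high"] * 5)
    s = np.r_[np.zeros(5), np.ones(5)]
    auc, curve = roc_auc(y, s, return_curve=True)
    assert auc == 1.0
    assert tuple(curve[0]) == (0.0, 0.0) and tuple(curve[-1]) == (1.0, 1.0)
    assert np.all(np.diff(curve[:, 0]) >= 0) and np.all(np.diff(curve[:, 1]) >= 0)


def test_auc_equals_pairwise_concordance_oracle():
    """Mann-Whitney AUC equals the O(n^2) concordance count, ties at 1/2."""
    rng = np.random.default_rng(0)
    for trial in range(5):
        n = 200
        y = rng.choice(["high", "low"], size=n)
        if len(set(y)) < 2:
            continue
        s = np.round(rng.normal(size=n), 1)  # rounding forces ties
        pos, neg = s[y == "high"], s[y == "low"]
        pairs = (pos[:, None] > neg[None, :]).sum() + 0.5 * (
            pos[:, None] == neg[None, :]
        ).sum()
        oracle = pairs / (len(pos) * len(neg))
        assert roc_auc(y, s) == pytest.approx(oracle, abs=1e-12)


def test_auc_chance_level_under_null():
    rng = np.random.default_rng(1)
    y = np.array(["high", "low"] * 1000)
    s = rng.normal(size=2000)
    assert roc_auc(y, s) == pytest.approx(0.5, abs=0.04)


def test_auc_rejects_single_class():
    with pytest.raises(ValueError):
        roc_auc(np.array(["high", "high"]), [0.1, 0.9])


# ---------------------------------------------------------------------------
# fitted ensemble


def _separable(n=60, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 3))
    y = np.where(X[:, 0] > 0, "high", "low")
    X[:, 0] += np.where(y == "high", 4.0, -4.0)
    return X, y


def test_reference_spec_has_five_members():
    spec = reference_spec()
    assert len(spec.members) == 5
    kernels = [m.kernel for m in spec.members[:3]]
    assert kernels == ["linear", "diaglinear", "pseudolinear"]
    assert spec.members[3].box_constraint == pytest.approx(984.2237)
    assert spec.members[4].layer_sizes[-1] == 1


def test_ensemble_perfect_on_separable_toy():
    X, y = _separable()
    ens = fit_ensemble(reference_spec(), X, y, seed=0)
    labels, scores = ens.decision(X)
    assert (labels == y).all()
    for member in ens.members:
        assert (member.predict(X) == y).all()
    assert roc_auc(y, scores) == 1.0


def test_fixed_weights_reduce_to_mean_posterior():
    X, y = _separable(seed=2)
    spec = reference_spec()
    spec = type(spec)(members=spec.members, weight_source="fixed")
    ens = fit_ensemble(spec, X, y, seed=0)
    _, posteriors = ens.member_predictions(X[:10])
    assert np.allclose(ens.predict_score(X[:10]), posteriors.mean(axis=1))


def test_scores_invariant_to_weight_rescaling():
    X, y = _separable(seed=3)
    ens = fit_ensemble(reference_spec(), X, y, seed=1)
    scaled = FittedEnsemble(ens.spec, ens.members, 7.5 * ens.weights)
    assert np.allclose(ens.predict_score(X), scaled.predict_score(X))
    assert np.array_equal(ens.predict(X), scaled.predict(X))


def test_identical_members_match_single_member():
    from petrad.ensemble import DAConfig, EnsembleSpec

    X, y = _separable(seed=4)
    cfg = DAConfig("linear", 0.1, 0.0)
    spec = EnsembleSpec(members=(cfg, cfg, cfg), weight_source="fixed")
    ens = fit_ensemble(spec, X, y, seed=0)
    single = cfg.build(0).fit(X, y)
    assert np.array_equal(ens.predict(X), single.predict(X))
    from petrad.models import proba_high

    assert np.allclose(ens.predict_score(X), proba_high(single, X))


def test_fit_ensemble_rejects_single_class():
    X, _ = _separable()
    with pytest.raises(ValueError):
        fit_ensemble(reference_spec(), X, np.array(["high"] * len(X)))


def test_evaluate_over_plan_shapes_and_checksum(small_run):
    from petrad import FeatureSubset, evaluate_over_plan

    table, labels, truth, plan, _ = small_run
    subset = FeatureSubset("planted", {}, tuple(truth.informative_names))
    results = evaluate_over_plan(reference_spec(), [subset], table, labels, plan,
                                 expected_checksum=plan.checksum())
    df = results["planted"]
    assert len(df) == plan.reps
    assert df["auc"].between(0, 100).all()
    with pytest.raises(ValueError, match="plan"):
        evaluate_over_plan(reference_spec(), [subset], table, labels, plan,
                           expected_checksum="not-the-checksum")


def test_evaluate_over_plan_rejects_unknown_feature(small_run):
    from petrad import FeatureSubset, evaluate_over_plan

    table, labels, _, plan, _ = small_run
    bad = FeatureSubset("bad", {}, ("no_such_feature",))
    with pytest.raises(ValueError, match="unknown features"):
        evaluate_over_plan(reference_spec(), [bad], table, labels, plan)
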