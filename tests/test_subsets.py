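"""Frequency-threshold subsets, the PCC redundancy filter and the union."""

import numpy as np
import pandas as pd
import pytest

from petrad import (
    FeatureSubset,
    avg_reference_pcc,
    build_finetuning,
    build_union_subset,
    make_split_plan,
    threshold_subsets,
)


@pytest.fixture()
def worked_freq():
    """Frequency table with one >90% feature and three others >=70%."""
    return pd.Series(
        {
            "wavelet-LHH_firstorder_Skewness": 96.67,
            "wavelet-HHL_glszm_SmallAreaEmphasis": 86.67,
            "wavelet-LHL_gldm_DependenceVariance": 76.67,
            "wavelet-HHL_glszm_SmallAreaLowGrayLevelEmphasis": 73.33,
            "wavelet-HLH_glcm_Idn": 36.67,
            "log-sigma-2-5-mm-3D_glszm_GrayLevelNonUniformity": 43.33,
            "original_firstorder_Mean": 10.0,
            "original_glcm_Contrast": 0.0,
        }
    )


def test_threshold_subsets_worked_example(worked_freq):
    subs = {s.name: s for s in threshold_subsets(worked_freq)}
    assert len(subs) == 11
    assert len(subs["features90"]) == 1
    assert len(subs["features70"]) == 4
    assert set(subs["features70"].members) == {
        "wavelet-LHH_firstorder_Skewness",
        "wavelet-HHL_glszm_SmallAreaEmphasis",
        "wavelet-LHL_gldm_DependenceVariance",
        "wavelet-HHL_glszm_SmallAreaLowGrayLevelEmphasis",
    }
    # features0 keeps every ever-selected feature but not the never-selected
    assert len(subs["features0"]) == 7
    assert "original_glcm_Contrast" not in subs["features0"].members


def test_threshold_subsets_nested(worked_freq):
    subs = threshold_subsets(worked_freq)
    for smaller, larger in zip(subs, subs[1:]):
        assert set(smaller.members) <= set(larger.members)
        assert len(smaller) <= len(larger)


def test_threshold_subsets_empty_table():
    subs = threshold_subsets(pd.Series(dtype=float))
    assert len(subs) == 11
    assert all(len(s) == 0 for s in subs)


# ---------------------------------------------------------------------------
# average reference PCC


def _table_and_plan(seed=0, n=200, p=8):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    names = [f"original_glcm_F{i}" for i in range(p)]
    labels = np.array(["high", "low"] * (n // 2))
    table = pd.DataFrame(X, columns=names)
    plan = make_split_plan(labels, reps=5, test_frac=0.2, k=5, seed=seed)
    return table, plan, names


def test_duplicated_reference_feature_has_pcc_one():
    table, plan, names = _table_and_plan()
    table["copy_of_ref"] = table[names[0]]
    ref = FeatureSubset("features70", {}, tuple(names[:4]))
    pcc = avg_reference_pcc(["copy_of_ref"], ref, table, plan)
    assert pcc["copy_of_ref"] == pytest.approx(1.0)


def test_independent_candidate_has_low_pcc():
    table, plan, names = _table_and_plan(seed=1, n=500)
    ref = FeatureSubset("features70", {}, tuple(names[:4]))
    pcc = avg_reference_pcc([names[5]], ref, table, plan)
    assert pcc[names[5]] < 0.3


def test_avg_pcc_matches_bruteforce_oracle():
    table, plan, names = _table_and_plan(seed=2)
    ref_names = names[:3]
    cands = names[3:6]
    ref = FeatureSubset("features70", {}, tuple(ref_names))
    pcc = avg_reference_pcc(cands, ref, table, plan)
    for cand in cands:
        per_rep = []
        for rep in range(plan.reps):
            rows = plan.train[rep]
            vals = [
                abs(np.corrcoef(table[cand].iloc[rows], table[r].iloc[rows])[0, 1])
                for r in ref_names
            ]
            per_rep.append(max(vals))
        assert pcc[cand] == pytest.approx(np.mean(per_rep), abs=1e-12)


def test_avg_pcc_zero_variance_candidate_warns():
    table, plan, names = _table_and_plan()
    table["flat"] = 1.0
    ref = FeatureSubset("features70", {}, tuple(names[:2]))
    with pytest.warns(UserWarning, match="zero-variance"):
        pcc = avg_reference_pcc(["flat"], ref, table, plan)
    assert pcc["flat"] == 0.0


def test_avg_pcc_rejects_overlap_and_empty_reference():
    table, plan, names = _table_and_plan()
    ref = FeatureSubset("features70", {}, tuple(names[:2]))
    with pytest.raises(ValueError, match="overlap"):
        avg_reference_pcc(names[:3], ref, table, plan)
    with pytest.raises(ValueError, match="empty"):
        avg_reference_pcc(names[:1], FeatureSubset("features70", {}, ()), table, plan)


# ---------------------------------------------------------------------------
# finetuning band and union


def test_finetuning_band_bounds():
    freq = pd.Series({"at30": 30.0, "at70": 70.0, "mid": 50.0, "low": 10.0})
    pcc = pd.Series({"at30": 0.1, "at70": 0.1, "mid": 0.5, "low": 0.1})
    fine = build_finetuning(freq, pcc)
    assert "at30" in fine.members  # 30% included
    assert "at70" not in fine.members  # 70% excluded
    assert "mid" not in fine.members  # filtered by PCC >= 0.3
    assert "low" not in fine.members  # below the band


def test_finetuning_all_correlated_empty():
    freq = pd.Series({"a": 40.0, "b": 50.0})
    pcc = pd.Series({"a": 0.5, "b": 0.5})
    assert len(build_finetuning(freq, pcc)) == 0


def test_finetuning_requires_pcc_coverage():
    freq = pd.Series({"a": 40.0, "b": 50.0})
    with pytest.raises(ValueError, match="missing"):
        build_finetuning(freq, pd.Series({"a": 0.1}))


def test_union_sizes_additive_and_order():
    f70 = FeatureSubset("features70", {}, ("s1", "s2", "s3", "s4"))
    fine = FeatureSubset("finetuning", {}, ("f1", "f2"))
    union = build_union_subset(f70, fine)
    assert union.members == ("s1", "s2", "s3", "s4", "f1", "f2")
    assert len(union) == len(f70) + len(fine)


def test_union_with_empty_finetuning_equals_features70():
    f70 = FeatureSubset("features70", {}, ("s1", "s2"))
    union = build_union_subset(f70, FeatureSubset("finetuning", {}, ()))
    assert union.members == f70.members


def test_union_rejects_overlap():
    f70 = FeatureSubset("features70", {}, ("s1",))
    fine = FeatureSubset("finetuning", {}, ("s1", "f1"))
    with pytest.raises(ValueError, match="overlap"):
        build_union_subset(f70, fine)
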