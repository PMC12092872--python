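"""Metrics, confidence intervals and the Friedman/Dunn-Sidak layer."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from petrad import ci95, compute_metrics, friedman_posthoc, report
from petrad.stats import METRICS


def _labels(tp, fn, fp, tn):
    true = ["high"] * (tp + fn) + ["low"] * (fp + tn)
    pred = ["high"] * tp + ["low"] * fn + ["high"] * fp + ["low"] * tn
    return np.array(true), np.array(pred)


def test_metrics_hand_worked_confusion():
    true, pred = _labels(tp=3, fn=1, fp=2, tn=2)
    scores = (pred == "high").astype(float)
    ms = compute_metrics(true, pred, scores)
    assert ms.sensitivity == pytest.approx(75.0)
    assert ms.specificity == pytest.approx(50.0)
    assert ms.precision == pytest.approx(60.0)
    assert ms.accuracy == pytest.approx(62.5)
    assert ms.fscore == pytest.approx(66.6667, abs=1e-3)


def test_metrics_exhaustive_small_count_oracle():
    """Agreement with the direct confusion-matrix formulas on all small tables."""
    for tp in range(3):
        for fn in range(3):
            for fp in range(3):
                for tn in range(3):
                    if tp + fn == 0 or fp + tn == 0 or tp + fp == 0:
                        continue  # undefined cases covered elsewhere
                    true, pred = _labels(tp, fn, fp, tn)
                    scores = (pred == "high").astype(float)
                    ms = compute_metrics(true, pred, scores)
                    assert ms.accuracy == pytest.approx(100 * (tp + tn) / (tp + fn + fp + tn))
                    assert ms.sensitivity == pytest.approx(100 * tp / (tp + fn))
                    assert ms.specificity == pytest.approx(100 * tn / (tn + fp))
                    assert ms.precision == pytest.approx(100 * tp / (tp + fp))


def test_metrics_perfect_prediction():
    true, pred = _labels(tp=4, fn=0, fp=0, tn=4)
    ms = compute_metrics(true, pred, (pred == "high").astype(float))
    assert all(getattr(ms, m) == 100.0 for m in METRICS)


def test_metrics_undefined_precision_warns_nan():
    true, pred = _labels(tp=0, fn=3, fp=0, tn=3)
    with pytest.warns(UserWarning, match="precision"):
        ms = compute_metrics(true, pred, np.zeros(6))
    assert np.isnan(ms.precision) and np.isnan(ms.fscore)
    assert ms.specificity == 100.0


# ---------------------------------------------------------------------------
# confidence intervals


def test_ci95_constant_samples_zero_width():
    est = ci95([80.0, 80.0, 80.0])
    assert (est.mean, est.lower, est.upper) == (80.0, 80.0, 80.0)


def test_ci95_two_samples_closed_form():
    est = ci95([70.0, 80.0])
    # sd = sqrt(50), se = 5, t_{.975, df=1} = 12.7062
    half = sps.t.ppf(0.975, 1) * 5.0
    assert est.mean == pytest.approx(75.0)
    assert est.lower == pytest.approx(75.0 - half)
    assert est.upper == pytest.approx(75.0 + half)


def test_ci95_width_shrinks_with_sqrt_n():
    rng = np.random.default_rng(0)
    widths = []
    for n in (20, 2000):
        x = rng.normal(70, 5, size=n)
        est = ci95(x)
        widths.append(est.upper - est.lower)
    assert widths[1] < widths[0] / 5  # ~1/sqrt(100) = 1/10, with slack


def test_ci95_bootstrap_option_and_errors():
    est = ci95([60, 70, 80, 90], method="bootstrap", seed=1)
    assert est.lower <= est.mean <= est.upper
    with pytest.raises(ValueError):
        ci95([70.0])


# ---------------------------------------------------------------------------
# Friedman + Dunn-Sidak


def test_friedman_identical_columns():
    M = pd.DataFrame({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
    rep = friedman_posthoc(M)
    assert rep.statistic == 0.0
    assert rep.p_value == 1.0
    assert not rep.significant.to_numpy().any()


def test_friedman_hand_ranked_4x3_oracle():
    """Rank sums 5/8/11 give the hand-computed statistic 4.5."""
    M = pd.DataFrame(
        [[1, 2, 3], [1, 3, 2], [2, 1, 3], [1, 2, 3]], columns=["a", "b", "c"]
    )
    rep = friedman_posthoc(M)
    assert rep.statistic == pytest.approx(4.5)
    assert rep.p_value == pytest.approx(sps.chi2.sf(4.5, df=2))
    assert rep.mean_ranks.tolist() == pytest.approx([5 / 4, 8 / 4, 11 / 4])


def test_friedman_matches_scipy_without_ties():
    rng = np.random.default_rng(3)
    M = pd.DataFrame(rng.normal(size=(12, 4)))
    rep = friedman_posthoc(M)
    ref = sps.friedmanchisquare(*[M[c] for c in M.columns])
    assert rep.statistic == pytest.approx(ref.statistic)
    assert rep.p_value == pytest.approx(ref.pvalue)


def test_sidak_correction_monotone():
    rng = np.random.default_rng(4)
    M = pd.DataFrame(rng.normal(size=(20, 5)))
    rep = friedman_posthoc(M)
    k = M.shape[1]
    m = k * (k - 1) // 2
    se = np.sqrt(k * (k + 1) / (6.0 * len(M)))
    for a in range(k):
        for b in range(a + 1, k):
            z = (rep.mean_ranks.iloc[a] - rep.mean_ranks.iloc[b]) / se
            raw = 2 * sps.norm.sf(abs(z))
            corrected = rep.pairwise_p.iloc[a, b]
            assert corrected >= raw - 1e-12
            assert corrected == pytest.approx(1 - (1 - raw) ** m)
    # symmetry
    P = rep.pairwise_p.to_numpy()
    assert np.allclose(P, P.T)


def test_friedman_type_one_error_calibrated():
    """Null rejection rate at alpha=0.05 stays inside its binomial band."""
    rng = np.random.default_rng(5)
    n_runs = 600
    rejections = 0
    for _ in range(n_runs):
        M = pd.DataFrame(rng.normal(size=(30, 13)))
        rejections += friedman_posthoc(M).p_value < 0.05
    rate = rejections / n_runs
    band = 3 * np.sqrt(0.05 * 0.95 / n_runs)
    assert abs(rate - 0.05) < band


def test_friedman_rejects_missing_cells():
    M = pd.DataFrame({"a": [1.0, np.nan], "b": [2.0, 3.0]})
    with pytest.raises(ValueError, match="missing"):
        friedman_posthoc(M)


# ---------------------------------------------------------------------------
# report files


def test_report_files_deterministic(tmp_path):
    rng = np.random.default_rng(6)
    results = {
        name: pd.DataFrame(
            {m: rng.uniform(50, 90, size=6) for m in METRICS}
        )
        for name in ("features70", "features30", "finetuning")
    }
    mat = pd.DataFrame({k: v["auc"] for k, v in results.items()})
    rep = friedman_posthoc(mat)
    out1 = report(results, rep, tmp_path / "r1")
    report(results, rep, tmp_path / "r2")
    summary = out1["summary"]
    assert summary.shape[0] == 3
    for m in METRICS:
        assert summary[f"{m}_best"].sum() == 1
    b1 = (tmp_path / "r1" / "metrics_summary.csv").read_bytes()
    b2 = (tmp_path / "r2" / "metrics_summary.csv").read_bytes()
    assert b1 == b2
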