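"""Performance metrics, confidence intervals and model comparison.

Six metrics are reported, all as percentages: accuracy, AUC, sensitivity
(recall on the positive/high-risk class), specificity (recall on the
negative class), precision (positive predictive value) and the F1 score.
Repetition-level metric samples are summarized as a mean with a two-sided
95% confidence interval.  Methods are compared across repetitions with the
Friedman rank test followed by pairwise rank-mean post-hoc tests under the
Dunn-Sidak familywise correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import HIGH

__all__ = [
    "METRICS",
    "MetricSet",
    "CIEstimate",
    "roc_auc",
    "compute_metrics",
    "ci95",
    "friedman_posthoc",
    "StatsReport",
    "report",
]

METRICS = ("accuracy", "auc", "sensitivity", "specificity", "precision", "fscore")


@dataclass(frozen=True)
class MetricSet:
    """The six evaluation metrics, each a percent in [0, 100] (NaN = undefined)."""

    accuracy: float
    auc: float
    sensitivity: float
    specificity: float
    precision: float
    fscore: float

    def as_dict(self) -> dict:
        return {m: getattr(self, m) for m in METRICS}


@dataclass(frozen=True)
class CIEstimate:
    mean: float
    lower: float
    upper: float


def roc_auc(true_labels, scores, positive: str = HIGH, return_curve: bool = False):
    """AUC as the probability that a positive score exceeds a negative one.

    Ties count one half (the Mann-Whitney convention).  Optionally also
    returns the ROC curve points (fpr, tpr), monotone from (0,0) to (1,1).
    """
    y = np.asarray(true_labels)
    s = np.asarray(scores, dtype=float)
    pos = y == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes in true_labels")
    ranks = sps.rankdata(s)  # midranks handle ties
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    if not return_curve:
        return float(auc)
    order = np.argsort(-s, kind="stable")
    tps = np.cumsum(pos[order])
    fps = np.cumsum(~pos[order])
    # collapse threshold ties so the curve is well defined
    distinct = np.r_[np.where(np.diff(s[order]))[0], len(s) - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    return float(auc), np.column_stack([fpr, tpr])


def compute_metrics(true_labels, predicted_labels, scores, positive: str = HIGH) -> MetricSet:
    """Confusion-matrix metrics plus AUC, all scaled to percent.

    With zero predicted positives, precision and F1 are undefined and
    reported as NaN with a warning.
    """
    y = np.asarray(true_labels)
    yhat = np.asarray(predicted_labels)
    if len(y) != len(yhat):
        raise ValueError("label vectors differ in length")
    pos = y == positive
    pred_pos = yhat == positive
    tp = int(np.sum(pos & pred_pos))
    fn = int(np.sum(pos & ~pred_pos))
    fp = int(np.sum(~pos & pred_pos))
    tn = int(np.sum(~pos & ~pred_pos))
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both classes must be present in true_labels")

    accuracy = (tp + tn) / len(y)
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    if tp + fp == 0:
        warnings.warn("no predicted positives: precision and F-score undefined", stacklevel=2)
        precision = np.nan
        fscore = np.nan
    else:
        precision = tp / (tp + fp)
        denom = precision + sensitivity
        fscore = 2 * precision * sensitivity / denom if denom > 0 else 0.0
    auc = roc_auc(y, scores, positive=positive)
    return MetricSet(
        accuracy=100 * accuracy,
        auc=100 * auc,
        sensitivity=100 * sensitivity,
        specificity=100 * specificity,
        precision=100 * precision,
        fscore=100 * fscore,
    )


def ci95(samples, method: str = "t", n_boot: int = 2000, seed: int = 0) -> CIEstimate:
    """Mean with a two-sided 95% interval over repetition-level samples.

    ``method='t'`` uses the Student interval with n-1 degrees of freedom;
    ``method='bootstrap'`` the percentile bootstrap.
    """
    x = np.asarray(samples, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        raise ValueError("ci95 needs at least two samples")
    mean = float(x.mean())
    if method == "t":
        se = x.std(ddof=1) / np.sqrt(x.size)
        half = float(sps.t.ppf(0.975, df=x.size - 1) * se)
        return CIEstimate(mean, mean - half, mean + half)
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        means = rng.choice(x, size=(n_boot, x.size), replace=True).mean(axis=1)
        lo, hi = np.percentile(means, [2.5, 97.5])
        return CIEstimate(mean, float(lo), float(hi))
    raise ValueError(f"unknown CI method {method!r}")


@dataclass(frozen=True)
class StatsReport:
    statistic: float
    p_value: float
    mean_ranks: pd.Series
    pairwise_p: pd.DataFrame  # Sidak-corrected, symmetric
    significant: pd.DataFrame  # p < 0.05, double-sided


def friedman_posthoc(metric_matrix: pd.DataFrame, alpha: float = 0.05) -> StatsReport:
    """Friedman test plus Dunn-Sidak-corrected pairwise rank comparisons.

    ``metric_matrix`` is repetitions x methods with no missing cells.  Ranks
    use midranks on ties and the Friedman statistic carries the standard tie
    correction.  Pairwise tests compare mean ranks with the normal
    approximation z = (Ri - Rj) / sqrt(k(k+1)/(6n)); raw two-sided p-values
    are corrected as p' = 1 - (1 - p)^m over the m = k(k-1)/2 pairs.
    """
    M = pd.DataFrame(metric_matrix)
    if M.isna().any().any():
        raise ValueError("metric matrix contains missing cells")
    n, k = M.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 repetitions and 2 methods")

    ranks = np.apply_along_axis(sps.rankdata, 1, M.to_numpy(dtype=float))
    rank_sums = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * np.sum(rank_sums**2) - 3.0 * n * (k + 1)
    # tie correction
    ties = 0.0
    for row in M.to_numpy(dtype=float):
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    correction = 1.0 - ties / (n * k * (k**2 - 1))
    if correction > 0:
        stat /= correction
        p_value = float(sps.chi2.sf(stat, df=k - 1))
    else:  # every row fully tied: no evidence of any difference
        stat, p_value = 0.0, 1.0

    mean_ranks = pd.Series(rank_sums / n, index=M.columns, name="mean_rank")
    m = k * (k - 1) // 2
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    pmat = pd.DataFrame(np.ones((k, k)), index=M.columns, columns=M.columns)
    for a in range(k):
        for b in range(a + 1, k):
            z = (mean_ranks.iloc[a] - mean_ranks.iloc[b]) / se
            raw = 2.0 * sps.norm.sf(abs(z))
            corrected = 1.0 - (1.0 - min(raw, 1.0)) ** m
            pmat.iloc[a, b] = pmat.iloc[b, a] = corrected
    significant = (pmat < alpha) & ~np.eye(k, dtype=bool)
    return StatsReport(float(stat), p_value, mean_ranks, pmat, significant)


def report(per_subset_metrics: dict, stats_report: StatsReport | None, out_dir) -> dict:
    """Write deterministic report files for an evaluation run.

    ``per_subset_metrics`` maps subset name -> DataFrame (repetitions x the
    six metric columns).  Writes a mean/CI summary table (the best value per
    metric flagged), the pairwise-significance grid when stats are supplied,
    and returns the summary DataFrame.
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = {}
    for name, df in per_subset_metrics.items():
        row = {}
        for metric in METRICS:
            est = ci95(df[metric])
            row[metric] = est.mean
            row[f"{metric}_lo"] = est.lower
            row[f"{metric}_hi"] = est.upper
        rows[name] = row
    summary = pd.DataFrame.from_dict(rows, orient="index")
    summary.index.name = "subset"
    for metric in METRICS:
        summary[f"{metric}_best"] = summary[metric] == summary[metric].max()
    summary.to_csv(out_dir / "metrics_summary.csv", float_format="%.6f")

    files = {"summary": out_dir / "metrics_summary.csv"}
    if stats_report is not None:
        stats_report.pairwise_p.to_csv(out_dir / "pairwise_p.csv", float_format="%.6g")
        stats_report.significant.astype(int).to_csv(out_dir / "pairwise_significant.csv")
        pd.Series(
            {"statistic": stats_report.statistic, "p_value": stats_report.p_value}
        ).to_csv(out_dir / "friedman.csv", header=False)
        files["pairwise_p"] = out_dir / "pairwise_p.csv"
    return {"summary": summary, "files": files}
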