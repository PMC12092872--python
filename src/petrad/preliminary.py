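"""The repeated-resampling preliminary analysis.

Each repetition performs a stratified 80/20 train/test split, LASSO feature
selection on the standardized training split, Bayesian hyperparameter tuning
of every classifier family on shared 5-fold assignments of the training
rows, and evaluation of the tuned models on the held-out test rows.  Across
repetitions this yields a per-feature selection frequency (the stability
statistic), per-family averaged metrics and the candidate families for the
final ensemble.

Stratified rounding uses largest-remainder apportionment of the per-class
test counts, so a 143-patient cohort (72/71) at a 0.2 test fraction always
holds out 29 patients (15 of the majority class, 14 of the minority).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

from . import models
from .stats import METRICS, compute_metrics

__all__ = [
    "SplitPlan",
    "make_split_plan",
    "lasso_select",
    "TrainedModel",
    "tune_family",
    "PreliminaryResult",
    "run_preliminary",
    "feature_frequency",
    "average_family_metrics",
    "pick_candidates",
]


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _l1_logistic(c: float) -> LogisticRegression:
    """Pure-L1 logistic regression across scikit-learn API generations."""
    try:
        return LogisticRegression(l1_ratio=1.0, C=c, solver="liblinear", max_iter=1000)
    except TypeError:  # older releases: l1_ratio only valid with elasticnet
        return LogisticRegression(penalty="l1", C=c, solver="liblinear", max_iter=1000)


# ---------------------------------------------------------------------------
# split plan


@dataclass
class SplitPlan:
    """Per-repetition train/test indices plus shared fold assignments.

    ``fold_ids[rep]`` aligns with ``train[rep]``: entry j is the CV fold
    (0..k-1) of training row ``train[rep][j]``.  The same folds are served to
    every classifier family within a repetition.
    """

    reps: int
    test_frac: float
    k: int
    seed: int
    train: list[np.ndarray]
    test: list[np.ndarray]
    fold_ids: list[np.ndarray]

    def folds(self, rep: int) -> list[tuple[np.ndarray, np.ndarray]]:
        """(train_pos, val_pos) pairs, positions into the rep's train rows."""
        ids = self.fold_ids[rep]
        return [
            (np.where(ids != f)[0], np.where(ids == f)[0]) for f in range(self.k)
        ]

    def checksum(self) -> str:
        h = hashlib.sha256()
        for rep in range(self.reps):
            h.update(self.train[rep].tobytes())
            h.update(self.test[rep].tobytes())
            h.update(self.fold_ids[rep].tobytes())
        return h.hexdigest()

    def to_json(self, path) -> None:
        doc = {
            "reps": self.reps,
            "test_frac": self.test_frac,
            "k": self.k,
            "seed": self.seed,
            "train": [t.tolist() for t in self.train],
            "test": [t.tolist() for t in self.test],
            "fold_ids": [f.tolist() for f in self.fold_ids],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "SplitPlan":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            reps=doc["reps"],
            test_frac=doc["test_frac"],
            k=doc["k"],
            seed=doc["seed"],
            train=[np.asarray(t, dtype=np.int64) for t in doc["train"]],
            test=[np.asarray(t, dtype=np.int64) for t in doc["test"]],
            fold_ids=[np.asarray(f, dtype=np.int64) for f in doc["fold_ids"]],
        )


def _apportion_test_counts(class_counts: dict, n_test: int) -> dict:
    """Largest-remainder apportionment of the test slots across classes."""
    total = sum(class_counts.values())
    quotas = {c: n_test * cnt / total for c, cnt in class_counts.items()}
    counts = {c: int(np.floor(q)) for c, q in quotas.items()}
    short = n_test - sum(counts.values())
    # distribute the remainder by largest fractional part; break ties toward
    # the larger class, then by name, so the result is deterministic
    order = sorted(
        class_counts,
        key=lambda c: (-(quotas[c] - counts[c]), -class_counts[c], str(c)),
    )
    for c in order[:short]:
        counts[c] += 1
    return counts


def make_split_plan(
    labels, reps: int = 30, test_frac: float = 0.2, k: int = 5, seed: int = 0
) -> SplitPlan:
    """Build the stratified split plan shared by all downstream stages."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("labels contain a single class; stratification impossible")
    n = len(y)
    n_test = int(round(n * test_frac))
    if n_test < 1 or n - n_test < 2 * k:
        raise ValueError("test fraction leaves too few patients for k-fold CV")
    test_counts = _apportion_test_counts(dict(zip(classes, counts)), n_test)

    root = np.random.SeedSequence(seed)
    rep_seeds = root.spawn(reps)
    train_l, test_l, folds_l = [], [], []
    for rep in range(reps):
        split_ss, fold_ss = rep_seeds[rep].spawn(2)
        rng = np.random.default_rng(split_ss)
        test_idx = []
        for c in classes:
            idx = np.where(y == c)[0]
            rng.shuffle(idx)
            test_idx.append(idx[: test_counts[c]])
        test_idx = np.sort(np.concatenate(test_idx))
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=_seed_int(fold_ss))
        fold_ids = np.empty(len(train_idx), dtype=np.int64)
        for f, (_, va) in enumerate(skf.split(np.zeros(len(train_idx)), y[train_idx])):
            fold_ids[va] = f
        train_l.append(train_idx.astype(np.int64))
        test_l.append(test_idx.astype(np.int64))
        folds_l.append(fold_ids)
    return SplitPlan(reps, test_frac, k, seed, train_l, test_l, folds_l)


# ---------------------------------------------------------------------------
# LASSO selection


def lasso_select(
    train_features,
    labels,
    lambda_rule: str = "1se",
    n_penalties: int = 20,
    cv: int = 5,
    seed: int = 0,
    standardize: bool = True,
):
    """Features with nonzero L1-penalized logistic coefficients.

    The penalty is chosen by internal stratified ``cv``-fold cross-validation
    of the deviance on the training split: ``'min'`` takes the best mean
    deviance, ``'1se'`` (default) the strongest penalty within one standard
    error of it.  Returns the selected feature names (column order
    preserved); an empty selection is possible and returned as such.
    """
    X = pd.DataFrame(train_features)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("labels are constant; LASSO selection undefined")
    names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    if standardize:
        mu, sd = Xv.mean(axis=0), Xv.std(axis=0)
        sd_safe = np.where(sd > 0, sd, 1.0)
        Xv = (Xv - mu) / sd_safe
        Xv[:, sd == 0] = 0.0  # zero-variance features can never be selected

    t = (y == classes[1]).astype(float)
    # null-model penalty bound: C below 1/max|X'(y - ybar)| shrinks all
    # coefficients to zero; scan 3 decades of weaker penalties above it
    grad0 = np.abs(Xv.T @ (t - t.mean())).max()
    c_null = 1.0 / max(grad0, 1e-12)
    cs = c_null * np.logspace(0.0, 3.0, n_penalties)

    skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed % (2**31 - 1))
    dev = np.zeros((cv, len(cs)))
    for f, (tr, va) in enumerate(skf.split(Xv, y)):
        for j, c in enumerate(cs):
            clf = _l1_logistic(c)
            clf.fit(Xv[tr], y[tr])
            p = clf.predict_proba(Xv[va])
            dev[f, j] = log_loss(y[va], p, labels=list(clf.classes_))
    mean_dev = dev.mean(axis=0)
    se_dev = dev.std(axis=0, ddof=1) / np.sqrt(cv)
    j_min = int(np.argmin(mean_dev))
    if lambda_rule == "min":
        j_pick = j_min
    elif lambda_rule == "1se":
        within = np.where(mean_dev <= mean_dev[j_min] + se_dev[j_min])[0]
        j_pick = int(within.min())  # smallest C = strongest penalty
    else:
        raise ValueError(f"unknown lambda_rule {lambda_rule!r}")

    clf = _l1_logistic(cs[j_pick])
    clf.fit(Xv, y)
    nonzero = np.abs(clf.coef_[0]) > 0
    return [names[i] for i in np.where(nonzero)[0]]


# ---------------------------------------------------------------------------
# tuning


@dataclass
class TrainedModel:
    """A tuned and fitted classifier with its fold-validated AUC weight."""

    family: str
    params: dict
    model: object
    validation_auc: float
    cv_error: float


def tune_family(
    family: str,
    train_features,
    labels,
    folds,
    budget: int = 30,
    seed: int = 0,
) -> TrainedModel:
    """Bayesian-optimize one family over shared folds and refit on all rows."""
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(labels)
    space = models.family_space(family)
    objective = models.cv_objective(family, X, y, folds, seed=seed)
    best_params, best_value, _ = models.bayes_minimize(
        objective, space, budget=budget, seed=seed
    )
    # fold-validated AUC of the chosen configuration (same folds)
    from .stats import roc_auc

    aucs = []
    for tr, va in folds:
        m = models.build_estimator(family, best_params, seed=seed)
        m.fit(X[tr], y[tr])
        aucs.append(roc_auc(y[va], models.proba_high(m, X[va])))
    model = models.build_estimator(family, best_params, seed=seed)
    model.fit(X, y)
    return TrainedModel(family, best_params, model, float(np.mean(aucs)), float(best_value))


# ---------------------------------------------------------------------------
# the full loop


@dataclass
class PreliminaryResult:
    """Selection log, per-rep per-family metrics and chosen hyperparameters."""

    feature_names: list[str]
    selections: list[list[str]]  # one selected-feature list per repetition
    metrics: pd.DataFrame  # columns: rep, family, the six metrics
    hyperparams: list[dict]  # per rep: family -> chosen params
    validation_aucs: list[dict]  # per rep: family -> fold-validated AUC
    plan: SplitPlan
    families: tuple[str, ...]


def run_preliminary(
    table: pd.DataFrame,
    labels,
    plan: SplitPlan,
    budget: int = 30,
    families: tuple[str, ...] = models.FAMILIES,
    lambda_rule: str = "1se",
) -> PreliminaryResult:
    """Run the full preliminary loop over the split plan.

    Standardization is fit on each repetition's training rows only and
    applied to its test rows.  A repetition with an empty LASSO selection is
    logged with an empty subset; its models are skipped and their metrics
    recorded as missing.
    """
    X = table.to_numpy(dtype=float)
    y = np.asarray(labels)
    if len(X) != len(y):
        raise ValueError("table row count does not match labels")
    names = list(table.columns)

    root = np.random.SeedSequence((plan.seed, 1))
    rep_seeds = root.spawn(plan.reps)

    selections: list[list[str]] = []
    rows = []
    hp_log, auc_log = [], []
    for rep in range(plan.reps):
        tr_idx, te_idx = plan.train[rep], plan.test[rep]
        mu = X[tr_idx].mean(axis=0)
        sd = X[tr_idx].std(axis=0)
        sd_safe = np.where(sd > 0, sd, 1.0)
        Xtr = (X[tr_idx] - mu) / sd_safe
        Xte = (X[te_idx] - mu) / sd_safe
        ytr, yte = y[tr_idx], y[te_idx]

        lasso_ss, tune_ss = rep_seeds[rep].spawn(2)
        try:
            selected = lasso_select(
                pd.DataFrame(Xtr, columns=names),
                ytr,
                lambda_rule=lambda_rule,
                seed=_seed_int(lasso_ss),
                standardize=False,
            )
        except Exception as err:
            raise RuntimeError(f"repetition {rep}: LASSO selection failed") from err
        selections.append(selected)
        if not selected:
            warnings.warn(f"repetition {rep}: empty LASSO selection; models skipped")
            for family in families:
                rows.append({"rep": rep, "family": family, **{m: np.nan for m in METRICS}})
            hp_log.append({})
            auc_log.append({})
            continue

        cols = [names.index(s) for s in selected]
        folds = plan.folds(rep)
        fam_seeds = tune_ss.spawn(len(families))
        hp_rep, auc_rep = {}, {}
        for fi, family in enumerate(families):
            try:
                tm = tune_family(
                    family,
                    Xtr[:, cols],
                    ytr,
                    folds,
                    budget=budget,
                    seed=_seed_int(fam_seeds[fi]),
                )
                pred = tm.model.predict(Xte[:, cols])
                score = models.proba_high(tm.model, Xte[:, cols])
                ms = compute_metrics(yte, pred, score)
            except Exception as err:
                raise RuntimeError(f"repetition {rep}, family {family} failed") from err
            rows.append({"rep": rep, "family": family, **ms.as_dict()})
            hp_rep[family] = tm.params
            auc_rep[family] = tm.validation_auc
        hp_log.append(hp_rep)
        auc_log.append(auc_rep)

    metrics = pd.DataFrame(rows)
    return PreliminaryResult(
        feature_names=names,
        selections=selections,
        metrics=metrics,
        hyperparams=hp_log,
        validation_aucs=auc_log,
        plan=plan,
        families=tuple(families),
    )


def feature_frequency(result: PreliminaryResult | list, feature_names=None) -> pd.Series:
    """Per-feature selection frequency in percent: 100 * n_selected / reps.

    Accepts a :class:`PreliminaryResult` or a bare selection log (list of
    per-repetition feature-name lists).  Features never selected carry 0.
    """
    if isinstance(result, PreliminaryResult):
        selections = result.selections
        feature_names = result.feature_names
    else:
        selections = list(result)
        if feature_names is None:
            feature_names = sorted({f for sel in selections for f in sel})
    reps = len(selections)
    if reps == 0:
        raise ValueError("no repetitions in the selection log")
    counts = pd.Series(0, index=pd.Index(feature_names, name="feature"), dtype=float)
    for sel in selections:
        counts[list(sel)] += 1
    return (100.0 * counts / reps).rename("frequency")


def average_family_metrics(result: PreliminaryResult) -> pd.DataFrame:
    """Mean of each metric over repetitions, per classifier family.

    Missing cells (skipped repetitions, undefined precision) are excluded
    pairwise from the average.
    """
    return (
        result.metrics.groupby("family")[list(METRICS)]
        .mean()
        .reindex(list(result.families))
    )


def pick_candidates(family_means: pd.DataFrame) -> set:
    """Families achieving the maximum of at least one averaged metric."""
    winners: set = set()
    for metric in family_means.columns:
        col = family_means[metric]
        if col.notna().any():
            top = col.max()
            winners |= set(col.index[col == top])
    return winners
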