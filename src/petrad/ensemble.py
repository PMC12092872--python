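"""The five-member voting ensemble.

The reference ensemble combines three discriminant-analysis members (linear,
diaglinear and pseudolinear kernels with their tuned gamma/delta pairs), one
gaussian-kernel SVM with a large box constraint, and one sigmoid network
whose single fully connected layer has size 1.  The ensemble label is the
majority vote of the member labels (five members: no tie is reachable); the
ensemble score is the AUC-weighted average of the member posterior
probabilities for the high-risk class,

    score = sum_i w_i * p_i / sum_i w_i,

where w_i defaults to member i's 5-fold cross-validated AUC on the training
split (a test-set AUC would leak information into the weights).
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .cohort import HIGH, LOW
from .models import DiscriminantClassifier, SigmoidNetClassifier, proba_high
from .stats import compute_metrics, roc_auc  # noqa: F401  (roc_auc re-exported here)

__all__ = [
    "DAConfig",
    "SVMConfig",
    "NNConfig",
    "EnsembleSpec",
    "reference_spec",
    "FittedEnsemble",
    "fit_ensemble",
    "majority_vote",
    "weighted_posterior",
    "roc_auc",
    "evaluate_over_plan",
]


@dataclass(frozen=True)
class DAConfig:
    kernel: str
    gamma: float
    delta: float

    def build(self, seed: int):
        return DiscriminantClassifier(self.kernel, self.gamma, self.delta)

    @property
    def name(self) -> str:
        return f"DA-{self.kernel}"


@dataclass(frozen=True)
class SVMConfig:
    kernel: str = "gaussian"
    box_constraint: float = 984.2237
    kernel_scale: float | None = None  # None: data-driven heuristic

    def build(self, seed: int):
        if self.box_constraint <= 0:
            raise ValueError("box constraint must be positive")
        gamma = "scale" if self.kernel_scale is None else 1.0 / self.kernel_scale**2
        return SVC(
            C=self.box_constraint,
            kernel="rbf" if self.kernel == "gaussian" else self.kernel,
            gamma=gamma,
            probability=True,  # sigmoid calibration fitted on training folds
            random_state=seed,
        )

    @property
    def name(self) -> str:
        return f"SVM-{self.kernel}"


@dataclass(frozen=True)
class NNConfig:
    layer_sizes: tuple[int, ...] = (1,)  # sizes of the FC layers; last must be 1
    activation: str = "sigmoid"
    seed: int = 0

    def build(self, seed: int):
        if self.layer_sizes[-1] != 1:
            raise ValueError("the final fully connected layer must have size 1")
        if self.activation != "sigmoid":
            raise ValueError("only the sigmoid activation is supported")
        return SigmoidNetClassifier(hidden_sizes=tuple(self.layer_sizes[:-1]), seed=seed)

    @property
    def name(self) -> str:
        return "NN"


@dataclass(frozen=True)
class EnsembleSpec:
    members: tuple  # ordered member configs
    weight_source: str = "cv_auc"  # or "fixed"

    def __post_init__(self) -> None:
        if self.weight_source not in ("cv_auc", "fixed"):
            raise ValueError("weight_source must be 'cv_auc' or 'fixed'")


def reference_spec() -> EnsembleSpec:
    """The reference five-member ensemble (3 DA + 1 SVM + 1 NN)."""
    return EnsembleSpec(
        members=(
            DAConfig("linear", 0.3354, 0.2081),
            DAConfig("diaglinear", 0.4298, 0.1525),
            DAConfig("pseudolinear", 0.3722, 0.2536),
            SVMConfig("gaussian", 984.2237),
            NNConfig((1,)),
        ),
        weight_source="cv_auc",
    )


def majority_vote(member_labels, score: float | None = None):
    """Modal label of the member predictions for one observation.

    With an even split (impossible for five members) the vote falls back to
    the weighted score when given: score >= 0.5 votes high.
    """
    labels = list(member_labels)
    if not labels:
        raise ValueError("no member labels")
    n_high = sum(1 for l in labels if l == HIGH)
    n_low = len(labels) - n_high
    if n_high > n_low:
        return HIGH
    if n_low > n_high:
        return LOW
    if score is not None:
        return HIGH if score >= 0.5 else LOW
    return HIGH  # documented even-split default when no score is available


def weighted_posterior(posteriors, weights) -> float:
    """Weight-normalized average posterior: sum(w p) / sum(w)."""
    p = np.asarray(posteriors, dtype=float)
    w = np.asarray(weights, dtype=float)
    if p.shape != w.shape:
        raise ValueError("posteriors and weights differ in length")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total == 0:
        raise ValueError("all-zero member weights")
    return float(np.sum(w * p) / total)


class FittedEnsemble:
    """Fitted members with their AUC weights; predicts labels and scores."""

    def __init__(self, spec: EnsembleSpec, members, weights, feature_names=None):
        self.spec = spec
        self.members = list(members)
        self.weights = np.asarray(weights, dtype=float)
        self.feature_names = list(feature_names) if feature_names is not None else None

    def member_predictions(self, X):
        labels = np.stack([m.predict(X) for m in self.members], axis=1)
        posteriors = np.stack([proba_high(m, X) for m in self.members], axis=1)
        return labels, posteriors

    def decision(self, X):
        """(labels, scores) for each row of X."""
        member_labels, posteriors = self.member_predictions(X)
        scores = np.array([weighted_posterior(p, self.weights) for p in posteriors])
        labels = np.array(
            [majority_vote(ml, s) for ml, s in zip(member_labels, scores)]
        )
        return labels, scores

    def predict(self, X):
        return self.decision(X)[0]

    def predict_score(self, X):
        return self.decision(X)[1]

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "FittedEnsemble":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def fit_ensemble(
    spec: EnsembleSpec,
    train_features,
    labels,
    seed: int = 0,
    k: int = 5,
    feature_names=None,
) -> FittedEnsemble:
    """Fit every member and derive its weight.

    With ``weight_source='cv_auc'`` each member's weight is its k-fold
    cross-validated AUC on the training split (shared stratified folds);
    with ``'fixed'`` all weights are 1 and the score reduces to the plain
    mean of member posteriors.
    """
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to fit the ensemble")

    members, weights = [], []
    if spec.weight_source == "cv_auc":
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31 - 1))
        folds = list(skf.split(X, y))
    for i, cfg in enumerate(spec.members):
        try:
            model = cfg.build(seed + i)
            model.fit(X, y)
        except Exception as err:
            raise RuntimeError(f"ensemble member {cfg.name} failed to fit") from err
        members.append(model)
        if spec.weight_source == "cv_auc":
            aucs = []
            for tr, va in folds:
                m = cfg.build(seed + i)
                m.fit(X[tr], y[tr])
                aucs.append(roc_auc(y[va], proba_high(m, X[va])))
            weights.append(float(np.mean(aucs)))
        else:
            weights.append(1.0)
    return FittedEnsemble(spec, members, weights, feature_names)


def evaluate_over_plan(
    spec: EnsembleSpec,
    subsets,
    table: pd.DataFrame,
    labels,
    plan,
    expected_checksum: str | None = None,
) -> dict[str, pd.DataFrame]:
    """Evaluate the ensemble per feature subset over the shared split plan.

    The plan must be the one used by the preliminary analysis (verified
    against ``expected_checksum`` when given) so that every model family and
    every subset is measured on identical test partitions.  Features are
    standardized with training-split statistics.  Returns, per subset, a
    repetitions x metrics DataFrame; empty subsets are skipped.
    """
    if expected_checksum is not None and plan.checksum() != expected_checksum:
        raise ValueError("split plan does not match the preliminary analysis plan")
    X = table.to_numpy(dtype=float)
    y = np.asarray(labels)
    columns = list(table.columns)

    results: dict[str, pd.DataFrame] = {}
    for subset in subsets:
        missing = [f for f in subset.members if f not in columns]
        if missing:
            raise ValueError(f"subset {subset.name!r} has unknown features: {missing}")
        if len(subset) == 0:
            continue
        cols = [columns.index(f) for f in subset.members]
        rows = []
        root = np.random.SeedSequence((plan.seed, 2))
        rep_seeds = root.spawn(plan.reps)
        for rep in range(plan.reps):
            tr_idx, te_idx = plan.train[rep], plan.test[rep]
            mu = X[np.ix_(tr_idx, cols)].mean(axis=0)
            sd = X[np.ix_(tr_idx, cols)].std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)
            Xtr = (X[np.ix_(tr_idx, cols)] - mu) / sd
            Xte = (X[np.ix_(te_idx, cols)] - mu) / sd
            ens = fit_ensemble(
                spec,
                Xtr,
                y[tr_idx],
                seed=int(rep_seeds[rep].generate_state(1)[0] % (2**31 - 1)),
                feature_names=list(subset.members),
            )
            pred, score = ens.decision(Xte)
            ms = compute_metrics(y[te_idx], pred, score)
            rows.append({"rep": rep, **ms.as_dict()})
        results[subset.name] = pd.DataFrame(rows).set_index("rep")
    return results
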