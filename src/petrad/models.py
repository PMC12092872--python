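"""Classifier families, their hyperparameter spaces, and Bayesian tuning.

Six families are supported: discriminant analysis (DA), support vector
machines (SVM), k-nearest neighbors (KNN), a small sigmoid neural network
(NN), random forests (RF) and AdaBoost (BOOST).  DA and NN are implemented
here because their required semantics (covariance-shrinkage ``gamma`` and
coefficient-threshold ``delta`` kernels; He-initialized sigmoid layers with
zero biases) are not available off the shelf; the rest wrap scikit-learn.

Hyperparameters are tuned by minimizing cross-validated misclassification
error with a Gaussian-process surrogate and expected-improvement
acquisition over an encoded mixed search space.
"""

from __future__ import annotations

import warnings
from typing import Callable

import numpy as np
from scipy import optimize, special
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

__all__ = [
    "FAMILIES",
    "DiscriminantClassifier",
    "SigmoidNetClassifier",
    "family_space",
    "build_estimator",
    "bayes_minimize",
    "proba_high",
]

FAMILIES = ("DA", "SVM", "KNN", "NN", "RF", "BOOST")

DA_KERNELS = ("linear", "diaglinear", "pseudolinear", "quadratic", "diagquadratic")


def proba_high(model, X, positive: str = "high") -> np.ndarray:
    """Posterior probability of the positive class, whatever the class order."""
    proba = model.predict_proba(X)
    idx = list(model.classes_).index(positive)
    return proba[:, idx]


# ---------------------------------------------------------------------------
# discriminant analysis


class DiscriminantClassifier(BaseEstimator, ClassifierMixin):
    """Gaussian discriminant analysis with shrinkage and coefficient threshold.

    ``gamma`` in [0, 1] shrinks the (pooled or per-class) covariance toward
    its diagonal: Sigma_reg = (1 - gamma) * Sigma + gamma * diag(Sigma).
    ``delta`` zeroes components of the linear-discriminant coefficient vector
    whose magnitude falls below it (linear kernels only).  Kernels:

    * ``linear``       pooled covariance, plain inverse
    * ``diaglinear``   pooled diagonal covariance
    * ``pseudolinear`` pooled covariance, Moore-Penrose pseudoinverse
    * ``quadratic`` / ``diagquadratic``  per-class (diagonal) covariance
    """

    def __init__(self, kernel: str = "linear", gamma: float = 0.0, delta: float = 0.0):
        self.kernel = kernel
        self.gamma = gamma
        self.delta = delta

    def _regularize(self, cov: np.ndarray) -> np.ndarray:
        return (1.0 - self.gamma) * cov + self.gamma * np.diag(np.diag(cov))

    def fit(self, X, y):
        if self.kernel not in DA_KERNELS:
            raise ValueError(f"unknown DA kernel {self.kernel!r}; one of {DA_KERNELS}")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) != 2:
            raise ValueError("DiscriminantClassifier is binary")
        n, p = X.shape
        self.means_ = np.stack([X[y_idx == k].mean(axis=0) for k in range(2)])
        self.priors_ = np.bincount(y_idx, minlength=2) / n

        if self.kernel in ("linear", "diaglinear", "pseudolinear"):
            pooled = np.zeros((p, p))
            for k in range(2):
                Xa = X[y_idx == k] - self.means_[k]
                pooled += Xa.T @ Xa
            pooled /= max(n - 2, 1)
            if self.kernel == "diaglinear":
                pooled = np.diag(np.diag(pooled))
            cov = self._regularize(pooled)
            if self.kernel == "pseudolinear":
                inv = np.linalg.pinv(cov)
            else:
                try:
                    inv = np.linalg.inv(cov)
                except np.linalg.LinAlgError as err:
                    raise np.linalg.LinAlgError(
                        f"singular pooled covariance for kernel {self.kernel!r}; "
                        "use 'pseudolinear' or increase gamma"
                    ) from err
            w = inv @ (self.means_[1] - self.means_[0])
            w = np.where(np.abs(w) >= self.delta, w, 0.0)
            b = (
                -0.5 * w @ (self.means_[0] + self.means_[1])
                + np.log(self.priors_[1] / self.priors_[0])
            )
            self.coef_, self.intercept_ = w, float(b)
        else:  # quadratic family: per-class covariance
            self.covs_inv_, self.logdets_ = [], []
            for k in range(2):
                Xa = X[y_idx == k] - self.means_[k]
                cov = Xa.T @ Xa / max((y_idx == k).sum() - 1, 1)
                if self.kernel == "diagquadratic":
                    cov = np.diag(np.diag(cov))
                cov = self._regularize(cov)
                # eigendecomposition with a floor keeps near-singular classes usable
                vals, vecs = np.linalg.eigh(cov)
                vals = np.clip(vals, 1e-10, None)
                self.covs_inv_.append((vecs / vals) @ vecs.T)
                self.logdets_.append(float(np.sum(np.log(vals))))
        return self

    def _decision(self, X) -> np.ndarray:
        """Log posterior odds of class 1 over class 0."""
        X = np.asarray(X, dtype=float)
        if self.kernel in ("linear", "diaglinear", "pseudolinear"):
            return X @ self.coef_ + self.intercept_
        scores = []
        for k in range(2):
            d = X - self.means_[k]
            maha = np.einsum("ij,jk,ik->i", d, self.covs_inv_[k], d)
            scores.append(-0.5 * (maha + self.logdets_[k]) + np.log(self.priors_[k]))
        return scores[1] - scores[0]

    def predict_proba(self, X) -> np.ndarray:
        p1 = special.expit(self._decision(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return self.classes_[(self._decision(X) > 0).astype(int)]


# ---------------------------------------------------------------------------
# sigmoid network


class SigmoidNetClassifier(BaseEstimator, ClassifierMixin):
    """Fully connected sigmoid network ending in a single output unit.

    ``hidden_sizes`` may be empty (pure logistic unit).  Weights use the He
    scheme (normal with sd sqrt(2 / fan_in)); biases start at zero.  Trained
    by quasi-Newton (L-BFGS) minimization of the cross-entropy with optional
    L2 penalty ``alpha``; deterministic given ``seed``.
    """

    def __init__(
        self,
        hidden_sizes: tuple[int, ...] = (),
        alpha: float = 0.0,
        max_iter: int = 200,
        seed: int = 0,
    ):
        self.hidden_sizes = hidden_sizes
        self.alpha = alpha
        self.max_iter = max_iter
        self.seed = seed

    def _shapes(self, p: int):
        sizes = [p, *self.hidden_sizes, 1]
        return [(sizes[i + 1], sizes[i]) for i in range(len(sizes) - 1)]

    def _unpack(self, theta, shapes):
        Ws, bs, pos = [], [], 0
        for (o, i) in shapes:
            Ws.append(theta[pos : pos + o * i].reshape(o, i))
            pos += o * i
            bs.append(theta[pos : pos + o])
            pos += o
        return Ws, bs

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) != 2:
            raise ValueError("SigmoidNetClassifier is binary")
        t = y_idx.astype(float)  # 1.0 for classes_[1]
        n, p = X.shape
        shapes = self._shapes(p)
        rng = np.random.default_rng(self.seed)
        theta0 = np.concatenate(
            [
                np.concatenate(
                    [rng.normal(0.0, np.sqrt(2.0 / i), size=o * i), np.zeros(o)]
                )
                for (o, i) in shapes
            ]
        )

        def loss_grad(theta):
            Ws, bs = self._unpack(theta, shapes)
            acts = [X]
            for W, b in zip(Ws, bs):
                acts.append(special.expit(acts[-1] @ W.T + b))
            out = acts[-1][:, 0]
            eps = 1e-12
            loss = -np.mean(t * np.log(out + eps) + (1 - t) * np.log(1 - out + eps))
            grads = []
            delta = ((out - t) / n)[:, None]  # dL/dz of the output unit
            for layer in range(len(Ws) - 1, -1, -1):
                a_prev = acts[layer]
                gW = delta.T @ a_prev + self.alpha * Ws[layer]
                gb = delta.sum(axis=0)
                grads.append((gW, gb))
                if layer > 0:
                    delta = (delta @ Ws[layer]) * acts[layer] * (1 - acts[layer])
            grads.reverse()
            loss += 0.5 * self.alpha * sum(float(np.sum(W**2)) for W in Ws)
            g = np.concatenate([np.concatenate([gW.ravel(), gb]) for gW, gb in grads])
            return loss, g

        res = optimize.minimize(
            loss_grad,
            theta0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.max_iter},
        )
        self.theta_, self.shapes_ = res.x, shapes
        return self

    def _forward(self, X) -> np.ndarray:
        Ws, bs = self._unpack(self.theta_, self.shapes_)
        a = np.asarray(X, dtype=float)
        for W, b in zip(Ws, bs):
            a = special.expit(a @ W.T + b)
        return a[:, 0]

    def predict_proba(self, X) -> np.ndarray:
        p1 = self._forward(X)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return self.classes_[(self._forward(X) > 0.5).astype(int)]


# ---------------------------------------------------------------------------
# search spaces

# space entries: ("real", lo, hi, "linear"|"log") | ("int", lo, hi) | ("cat", choices)
_SPACES: dict[str, dict] = {
    "DA": {
        "kernel": ("cat", DA_KERNELS),
        "gamma": ("real", 0.0, 1.0, "linear"),
        "delta": ("real", 0.0, 1.0, "linear"),
    },
    "SVM": {
        # the box-constraint range spans 1e-3..1e3
        "C": ("real", 1e-3, 1e3, "log"),
        "kernel": ("cat", ("gaussian", "linear", "polynomial")),
        "kernel_scale": ("real", 0.1, 100.0, "log"),
    },
    "KNN": {
        "n_neighbors": ("int", 1, 30),
        "weights": ("cat", ("uniform", "distance")),
    },
    "NN": {
        "hidden": ("int", 1, 32),
        "alpha": ("real", 1e-5, 1e-1, "log"),
    },
    "RF": {
        "n_estimators": ("int", 50, 300),
        "max_depth": ("int", 2, 12),
        "max_features": ("cat", ("sqrt", "log2")),
    },
    "BOOST": {
        "n_estimators": ("int", 50, 300),
        "learning_rate": ("real", 0.01, 1.0, "log"),
    },
}


def family_space(family: str) -> dict:
    if family not in FAMILIES:
        raise ValueError(f"unknown classifier family {family!r}; one of {FAMILIES}")
    return dict(_SPACES[family])


def build_estimator(family: str, params: dict, seed: int = 0):
    """Instantiate a classifier of ``family`` with tuned ``params``."""
    if family == "DA":
        return DiscriminantClassifier(**params)
    if family == "SVM":
        kernel = {"gaussian": "rbf", "linear": "linear", "polynomial": "poly"}[
            params["kernel"]
        ]
        gamma = 1.0 / params["kernel_scale"] ** 2 if kernel != "linear" else "scale"
        return SVC(
            C=params["C"],
            kernel=kernel,
            gamma=gamma,
            degree=3,
            probability=True,
            random_state=seed,
        )
    if family == "KNN":
        return KNeighborsClassifier(
            n_neighbors=params["n_neighbors"], weights=params["weights"]
        )
    if family == "NN":
        return SigmoidNetClassifier(
            hidden_sizes=(params["hidden"],), alpha=params["alpha"], seed=seed
        )
    if family == "RF":
        return RandomForestClassifier(
            n_estimators=params["n_estimators"],
            max_depth=params["max_depth"],
            max_features=params["max_features"],
            random_state=seed,
        )
    if family == "BOOST":
        return AdaBoostClassifier(
            n_estimators=params["n_estimators"],
            learning_rate=params["learning_rate"],
            random_state=seed,
        )
    raise ValueError(f"unknown classifier family {family!r}; one of {FAMILIES}")


# ---------------------------------------------------------------------------
# Bayesian optimization over encoded mixed spaces


def _encode(space: dict, params: dict) -> np.ndarray:
    vec = []
    for name, spec in space.items():
        kind = spec[0]
        v = params[name]
        if kind == "real":
            _, lo, hi, scale = spec
            if scale == "log":
                vec.append((np.log(v) - np.log(lo)) / (np.log(hi) - np.log(lo)))
            else:
                vec.append((v - lo) / (hi - lo))
        elif kind == "int":
            _, lo, hi = spec
            vec.append((v - lo) / max(hi - lo, 1))
        else:
            onehot = [1.0 if c == v else 0.0 for c in spec[1]]
            vec.extend(onehot)
    return np.asarray(vec)


def _sample(space: dict, rng: np.random.Generator) -> dict:
    params = {}
    for name, spec in space.items():
        kind = spec[0]
        if kind == "real":
            _, lo, hi, scale = spec
            if scale == "log":
                params[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            else:
                params[name] = float(rng.uniform(lo, hi))
        elif kind == "int":
            _, lo, hi = spec
            params[name] = int(rng.integers(lo, hi + 1))
        else:
            params[name] = spec[1][rng.integers(len(spec[1]))]
    return params


def bayes_minimize(
    objective: Callable[[dict], float],
    space: dict,
    budget: int = 30,
    seed: int = 0,
    n_candidates: int = 256,
) -> tuple[dict, float, list]:
    """Minimize ``objective`` over ``space`` within ``budget`` evaluations.

    A Matern-5/2 Gaussian-process surrogate is fit to the encoded evaluated
    points and the next point maximizes expected improvement over a random
    candidate pool.  Returns (best_params, best_value, history); history is a
    list of (params, value) in evaluation order.  Deterministic given seed.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    history: list[tuple[dict, float]] = []
    n_init = min(budget, max(4, budget // 3))
    for _ in range(n_init):
        params = _sample(space, rng)
        history.append((params, float(objective(params))))

    while len(history) < budget:
        X = np.stack([_encode(space, p) for p, _ in history])
        y = np.asarray([v for _, v in history])
        gp = GaussianProcessRegressor(
            kernel=Matern(
                nu=2.5,
                length_scale=np.full(X.shape[1], 0.5),
                length_scale_bounds=(1e-2, 1e2),
            ),
            alpha=1e-6,
            normalize_y=True,
            n_restarts_optimizer=1,
            random_state=int(rng.integers(2**31 - 1)),
        )
        with warnings.catch_warnings():
            # encoded objectives are often flat along inactive dimensions;
            # a length scale pinned at its bound is expected, not an error
            warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit(X, y)
        cands = [_sample(space, rng) for _ in range(n_candidates)]
        Xc = np.stack([_encode(space, p) for p in cands])
        mu, sd = gp.predict(Xc, return_std=True)
        best = y.min()
        xi = 0.01
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (best - mu - xi) / np.where(sd > 0, sd, 1.0)
            ei = (best - mu - xi) * special.ndtr(z) + sd * np.exp(
                -0.5 * z**2
            ) / np.sqrt(2 * np.pi)
            ei = np.where(sd > 0, ei, 0.0)
        params = cands[int(np.argmax(ei))]
        history.append((params, float(objective(params))))

    best_params, best_value = min(history, key=lambda h: h[1])
    return best_params, best_value, history


def cv_objective(family: str, X, y, folds, seed: int = 0):
    """Cross-validated misclassification objective for one family.

    ``folds`` is a list of (train_idx, val_idx) index pairs into X/y; the
    same folds must be served to every family within a repetition.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)

    def objective(params: dict) -> float:
        errors = []
        for tr, va in folds:
            model = build_estimator(family, params, seed=seed)
            model.fit(X[tr], y[tr])
            errors.append(float(np.mean(model.predict(X[va]) != y[va])))
        return float(np.mean(errors))

    return objective
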