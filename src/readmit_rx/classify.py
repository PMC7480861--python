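"""Predictive readmission models and threshold calibration.

Two linear classifiers are implemented here directly:

* **L2-regularized logistic regression** (L2LR) — convex smooth objective
  solved with L-BFGS; the L2 term guards against data corruption and keeps
  the optimum unique.
* **Sparse linear SVM** (SLSVM) — class-weighted hinge loss with an L1
  penalty, solved exactly as a linear program, then hard-thresholded to the
  ``sparsity`` largest-magnitude weights and refit on that support.  The
  small support is what makes the separating hyperplane readable: the
  variables it retains are the ones that best separate readmitted from
  non-readmitted patients.

Ensemble and neural models (random forest, gradient boosting, multilayer
perceptron) are *adapters* around scikit-learn estimators satisfying the
same ``fit``/``score`` contract; their internals are not re-implemented.

Scores follow one sign convention throughout: larger score = higher
readmission risk.  Because the readmission prevalence is low (~5.5%), the
classification threshold is calibrated so that the predicted readmission
rate on the training set matches the observed rate, rather than using 0.5.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class LinearModel:
    """Affine risk score s(x) = w.x + b0; larger score = higher risk."""

    var_names: list[str]
    weights: np.ndarray
    intercept: float
    regularization: dict = field(default_factory=dict)

    @property
    def support(self) -> list[str]:
        """Variables with a nonzero weight."""
        return [v for v, w in zip(self.var_names, self.weights)
                if abs(w) > 1e-10]

    def score(self, X) -> np.ndarray:
        X = _as_matrix(X, self.var_names)
        return X @ self.weights + self.intercept

    def weight_of(self, var: str) -> float:
        return float(self.weights[self.var_names.index(var)])

    def to_json(self) -> str:
        return json.dumps({
            "var_names": self.var_names,
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "regularization": self.regularization,
        })

    @classmethod
    def from_json(cls, text: str) -> "LinearModel":
        d = json.loads(text)
        return cls(d["var_names"], np.asarray(d["weights"], dtype=float),
                   float(d["intercept"]), d.get("regularization", {}))


@runtime_checkable
class PredictorContract(Protocol):
    """Anything that can be fit on (X, y) and emit real risk scores."""

    def fit(self, X, y) -> "PredictorContract": ...

    def score(self, X) -> np.ndarray: ...


@dataclass(frozen=True)
class ThresholdRule:
    """Decision threshold: predict readmission iff score > threshold."""

    threshold: float
    target_prevalence: float

    def predict(self, scores: np.ndarray) -> np.ndarray:
        return (np.asarray(scores) > self.threshold).astype(int)


def _as_matrix(X, var_names=None) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        if var_names is not None:
            X = X[var_names]
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def _check_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes")
    return y


def _class_weights(y: np.ndarray, class_weight: str | None) -> np.ndarray:
    """Per-sample weights; 'balanced' = inverse-prevalence, mean weight 1."""
    if class_weight is None:
        return np.ones(len(y))
    n = len(y)
    n1 = y.sum()
    w = np.where(y == 1, n / (2 * n1), n / (2 * (n - n1)))
    return w


# ---------------------------------------------------------------------------
# L2 logistic regression
# ---------------------------------------------------------------------------

def train_l2_logistic(
    X,
    y,
    lam2: float = 1e-3,
    seed: int = 0,
    class_weight: str | None = "balanced",
) -> LinearModel:
    """Minimize mean (class-weighted) logistic loss + lam2 * ||w||^2.

    The objective is strictly convex in w, so the optimum is independent of
    the start; the intercept is unpenalized.  ``seed`` is accepted for the
    predictor contract but the solver is deterministic.
    """
    var_names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{j}" for j in range(np.asarray(X).shape[1])]
    Xm = _as_matrix(X)
    y = _check_binary(y)
    ys = 2.0 * y - 1.0  # {-1, +1}
    c = _class_weights(y, class_weight)
    n, p = Xm.shape

    def fg(theta):
        w, b = theta[:p], theta[p]
        z = ys * (Xm @ w + b)
        # log(1+exp(-z)) computed stably
        loss = np.logaddexp(0.0, -z)
        sig = 1.0 / (1.0 + np.exp(np.clip(z, -500, 500)))
        f = float(np.mean(c * loss) + lam2 * w @ w)
        coef = -c * ys * sig / n
        g = np.empty(p + 1)
        g[:p] = Xm.T @ coef + 2 * lam2 * w
        g[p] = coef.sum()
        return f, g

    res = optimize.minimize(
        fg, np.zeros(p + 1), jac=True, method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-9})
    w, b = res.x[:p], float(res.x[p])
    return LinearModel(var_names, w, b,
                       {"l2_strength": lam2, "class_weight": class_weight})


# ---------------------------------------------------------------------------
# sparse linear SVM
# ---------------------------------------------------------------------------

def _hinge_l1_lp(Xm, ys, c, lam1):
    """Exact LP for min (1/n) sum c_i xi_i + lam1 ||w||_1 over (w, b).

    Variables ordered [w (p), b, xi (n), t (p)] with xi >= hinge slack and
    t >= |w| elementwise.
    """
    n, p = Xm.shape
    nv = p + 1 + n + p
    cost = np.zeros(nv)
    cost[p + 1:p + 1 + n] = c / n
    cost[p + 1 + n:] = lam1
    # -ys_i * (x_i . w + b) - xi_i <= -1
    A1 = sparse.hstack([
        sparse.csr_matrix(-ys[:, None] * Xm),
        sparse.csr_matrix(-ys[:, None]),
        -sparse.eye(n, format="csr"),
        sparse.csr_matrix((n, p)),
    ])
    eye_p = sparse.eye(p, format="csr")
    zer = sparse.csr_matrix((p, 1 + n))
    A2 = sparse.hstack([eye_p, zer, -eye_p])   # w - t <= 0
    A3 = sparse.hstack([-eye_p, zer, -eye_p])  # -w - t <= 0
    A = sparse.vstack([A1, A2, A3], format="csr")
    b_ub = np.concatenate([-np.ones(n), np.zeros(2 * p)])
    bounds = ([(None, None)] * (p + 1)) + ([(0, None)] * (n + p))
    res = optimize.linprog(cost, A_ub=A, b_ub=b_ub, bounds=bounds,
                           method="highs")
    if not res.success:
        raise RuntimeError(f"hinge-loss LP failed: {res.message}")
    return res.x[:p].copy(), float(res.x[p])


def train_slsvm(
    X,
    y,
    sparsity: int = 10,
    lam1: float = 0.01,
    seed: int = 0,
    class_weight: str | None = "balanced",
) -> LinearModel:
    """Sparse linear SVM: L1-penalized hinge fit, hard-threshold, refit.

    Stage A solves the class-weighted hinge + L1 problem exactly as an LP.
    Stage B keeps the ``sparsity`` largest-|w| variables and refits the
    hinge loss restricted to that support (with a vanishing L1 term to keep
    the refit bounded on separable data).  The returned support has at most
    ``sparsity`` variables.
    """
    var_names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{j}" for j in range(np.asarray(X).shape[1])]
    Xm = _as_matrix(X)
    y = _check_binary(y)
    ys = 2.0 * np.asarray(y) - 1.0
    c = _class_weights(np.asarray(y), class_weight)
    n, p = Xm.shape
    if sparsity < 1:
        raise ValueError("sparsity must be >= 1")
    if sparsity > p:
        warnings.warn(f"sparsity {sparsity} exceeds {p} variables; clamping")
        sparsity = p

    w_full, _ = _hinge_l1_lp(Xm, ys, c, lam1)
    order = np.argsort(-np.abs(w_full), kind="stable")
    keep = np.sort(order[:sparsity])
    w_sub, b = _hinge_l1_lp(Xm[:, keep], ys, c, lam1=1e-8)
    w = np.zeros(p)
    w[keep] = w_sub
    w[np.abs(w) <= 1e-10] = 0.0
    return LinearModel(var_names, w, b,
                       {"sparsity": sparsity, "l1_strength": lam1,
                        "class_weight": class_weight})


# ---------------------------------------------------------------------------
# metrics and calibration
# ---------------------------------------------------------------------------

def roc_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney AUC: P(random positive outscores random negative), ties 1/2."""
    y = _check_binary(y)
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def calibrate_threshold(train_scores: np.ndarray, train_y: np.ndarray) -> ThresholdRule:
    """Pick the threshold matching the predicted rate to training prevalence.

    With prevalence p, the threshold is the (1-p)-quantile of the training
    scores: round(p*n) patients are predicted positive, up to score ties,
    which are classified negative (strictly-greater rule).
    """
    s = np.asarray(train_scores, dtype=float)
    y = np.asarray(train_y)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("y must be binary 0/1")
    p = float(np.mean(y))
    n = len(s)
    m = int(round(p * n))
    srt = np.sort(s)
    if m >= n:
        tau = srt[0] - 1.0
    elif m <= 0:
        tau = srt[-1]
    else:
        tau = srt[n - m - 1]
    return ThresholdRule(threshold=float(tau), target_prevalence=p)


def confusion_at(rule: ThresholdRule, scores: np.ndarray, y: np.ndarray
                 ) -> tuple[float, float]:
    """(sensitivity, specificity) of the thresholded score."""
    y = np.asarray(y)
    pred = rule.predict(scores)
    pos, neg = y == 1, y == 0
    sens = float(pred[pos].mean()) if pos.any() else float("nan")
    spec = float(1 - pred[neg].mean()) if neg.any() else float("nan")
    return sens, spec


# ---------------------------------------------------------------------------
# adapters for ensemble / neural predictors
# ---------------------------------------------------------------------------

class SklearnProbaAdapter:
    """Wrap a scikit-learn classifier as a risk-score predictor."""

    def __init__(self, estimator):
        self.estimator = estimator

    def fit(self, X, y):
        self.estimator.fit(_as_matrix(X), np.asarray(y))
        return self

    def score(self, X) -> np.ndarray:
        return self.estimator.predict_proba(_as_matrix(X))[:, 1]


class _LinearPredictor:
    """Fit-on-demand wrapper giving LinearModel trainers the contract API."""

    def __init__(self, trainer, **kwargs):
        self._trainer = trainer
        self._kwargs = kwargs
        self.model: LinearModel | None = None

    def fit(self, X, y):
        self.model = self._trainer(X, y, **self._kwargs)
        return self

    def score(self, X) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("predictor not fitted")
        return self.model.score(X)


def make_predictor(name: str, seed: int = 0, **kwargs) -> PredictorContract:
    """Factory for the evaluation ground-truth models.

    ``rf`` uses 500 trees by default; ``nn`` is a small fixed multilayer
    perceptron.  All are deterministic given ``seed``.
    """
    name = name.lower()
    if name == "l2lr":
        return _LinearPredictor(train_l2_logistic, seed=seed, **kwargs)
    if name == "slsvm":
        return _LinearPredictor(train_slsvm, seed=seed, **kwargs)
    if name == "rf":
        kwargs.setdefault("n_estimators", 500)
        return SklearnProbaAdapter(RandomForestClassifier(
            random_state=seed, n_jobs=1, class_weight="balanced", **kwargs))
    if name == "gbm":
        return SklearnProbaAdapter(HistGradientBoostingClassifier(
            random_state=seed, **kwargs))
    if name == "nn":
        kwargs.setdefault("hidden_layer_sizes", (32, 16))
        kwargs.setdefault("max_iter", 300)
        return SklearnProbaAdapter(MLPClassifier(random_state=seed, **kwargs))
    raise ValueError(f"unknown predictor {name!r}")


def cross_val_auc(name: str, X, y, param_grid: list[dict],
                  n_folds: int = 5, seed: int = 0) -> dict:
    """Pick the grid point with the best mean out-of-fold AUC."""
    y = np.asarray(y)
    best, best_auc = None, -np.inf
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    Xm = _as_matrix(X)
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(Xm)
    for params in param_grid:
        aucs = []
        for tr, te in skf.split(Xm, y):
            model = make_predictor(name, seed=seed, **params)
            model.fit(Xdf.iloc[tr], y[tr])
            aucs.append(roc_auc(model.score(Xdf.iloc[te]), y[te]))
        mean_auc = float(np.mean(aucs))
        if mean_auc > best_auc:
            best, best_auc = params, mean_auc
    return {"params": best, "auc": best_auc}
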