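"""Probabilistic multi-class classifiers.

Three classifiers share one contract: ``fit(X, y)`` then
``predict_proba(X)`` returning an (n, K) matrix of class probabilities
aligned with a fixed, ordered label alphabet.  They serve double duty —
as standalone probabilistic predictors and as the taxonomy (category
assigner) inside the Venn machine.

* :class:`GaussianNaiveBayes` — per-feature Gaussian class-conditional
  densities, empirical priors (delegates the density fitting to
  scikit-learn's ``GaussianNB``).
* :class:`SoftmaxRegression` — multinomial logistic regression fit by
  L-BFGS on the cross-entropy objective with an L2 ridge.
* :class:`SVMPlatt` — one-vs-one RBF support vector machines
  (scikit-learn ``SVC``) whose pairwise decision values are mapped to
  pairwise probabilities by a Platt sigmoid and coupled into a single
  distribution by :func:`pairwise_couple`.

The Platt sigmoid fit and the pairwise-coupling quadratic program are
implemented here; both are cross-checked against independent solvers in
the test-suite.
"""

from __future__ import annotations

import math
from abc import ABC, abstractmethod
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB as _SkGaussianNB
from sklearn.svm import SVC

from .datasets import Dataset
from .errors import ConvergenceError, InvalidInputError, NotFittedError

__all__ = [
    "ProbabilisticClassifier",
    "GaussianNaiveBayes",
    "SoftmaxRegression",
    "SVMPlatt",
    "make_classifier",
    "platt_fit_sigmoid",
    "platt_sigmoid",
    "pairwise_couple",
    "tune_svm",
    "DEFAULT_C_GRID",
    "DEFAULT_GAMMA_GRID",
]

#: Hyperparameter search grids for the RBF SVM: C in 2^2 .. 2^14 (step 2^2),
#: gamma in 2^-9 .. 2^-1 (step 2^2).
DEFAULT_C_GRID = tuple(2.0 ** k for k in range(2, 15, 2))
DEFAULT_GAMMA_GRID = tuple(2.0 ** k for k in range(-9, 0, 2))


class ProbabilisticClassifier(ABC):
    """Fit/predict contract over a fixed label alphabet.

    Output distributions are always length K = ``len(self.labels)`` and
    aligned with the alphabet, even when some classes are absent from
    the training data (those classes simply receive probability 0).
    """

    def __init__(self, labels):
        self.labels = tuple(labels)
        self._fitted = False

    @property
    def K(self) -> int:
        return len(self.labels)

    def _check_fitted(self) -> None:
        if not self._fitted:
            raise NotFittedError(f"{type(self).__name__} has not been fitted")

    def _encode(self, y) -> np.ndarray:
        lut = {lab: i for i, lab in enumerate(self.labels)}
        try:
            return np.array([lut[lab] for lab in np.asarray(y).tolist()], dtype=int)
        except KeyError as exc:  # pragma: no cover - guarded upstream
            raise InvalidInputError(f"unknown label {exc.args[0]!r}") from exc

    def fit(self, X, y) -> "ProbabilisticClassifier":
        X = np.asarray(X, dtype=float)
        yi = self._encode(y)
        if X.shape[0] == 0:
            raise InvalidInputError("cannot fit on an empty training set")
        self._present = np.unique(yi)  # alphabet indices seen in training
        if self._present.size == 1:
            # degenerate single-class training set: predict that class
            self._single = int(self._present[0])
        else:
            self._single = None
            self._fit(X, yi)
        self._fitted = True
        return self

    def fit_dataset(self, data: Dataset) -> "ProbabilisticClassifier":
        return self.fit(data.X, data.y)

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self._single is not None:
            out = np.zeros((X.shape[0], self.K))
            out[:, self._single] = 1.0
            return out
        return self._predict_proba(X)

    def predict(self, X) -> np.ndarray:
        """Predicted labels (alphabet values, first index wins ties)."""
        probs = self.predict_proba(X)
        idx = probs.argmax(axis=1)
        return np.array([self.labels[i] for i in idx], dtype=object)

    @abstractmethod
    def _fit(self, X: np.ndarray, yi: np.ndarray) -> None: ...

    @abstractmethod
    def _predict_proba(self, X: np.ndarray) -> np.ndarray: ...


# ---------------------------------------------------------------------------
# Gaussian Naive Bayes
# ---------------------------------------------------------------------------

class GaussianNaiveBayes(ProbabilisticClassifier):
    """Naive Bayes with per-feature Gaussian class-conditional densities.

    The posterior is ``P(y=k|x) ∝ P(y=k) · Π_j N(x_j; μ_kj, σ_kj²)``
    with empirical class priors.  A variance floor (``var_smoothing`` ×
    the largest feature variance) guards against zero-variance features
    in small classes.
    """

    def __init__(self, labels, var_smoothing: float = 1e-9):
        super().__init__(labels)
        self.var_smoothing = var_smoothing

    def _fit(self, X, yi):
        self._model = _SkGaussianNB(var_smoothing=self.var_smoothing)
        self._model.fit(X, yi)

    def _predict_proba(self, X):
        out = np.zeros((X.shape[0], self.K))
        out[:, self._model.classes_] = self._model.predict_proba(X)
        return out

    # fitted parameters, exposed for inspection / JSON round-trip
    def params(self) -> dict:
        self._check_fitted()
        if self._single is not None:
            return {"single_class": self._single}
        return {
            "classes": self._model.classes_.tolist(),
            "priors": self._model.class_prior_.tolist(),
            "means": self._model.theta_.tolist(),
            "variances": self._model.var_.tolist(),
        }


# ---------------------------------------------------------------------------
# Softmax regression
# ---------------------------------------------------------------------------

class SoftmaxRegression(ProbabilisticClassifier):
    """Multinomial logistic (softmax) regression.

    Class scores are linear, ``s_k(x) = θ_k·[1, x]``, and the predicted
    distribution is ``softmax(s)``.  Parameters minimise the summed
    cross-entropy plus an L2 ridge ``l2/2·‖θ‖²`` (intercepts excluded);
    the ridge also pins down the shared-shift degeneracy of the softmax
    parameterisation.  Optimised with L-BFGS using the analytic
    gradient; the objective value at each accepted iterate is recorded
    in ``objective_history_``.
    """

    def __init__(self, labels, l2: float = 1e-4, max_iter: int = 500,
                 gtol: float = 1e-6, seed: int = 0):
        super().__init__(labels)
        if l2 < 0:
            raise InvalidInputError("l2 penalty must be >= 0")
        self.l2 = l2
        self.max_iter = max_iter
        self.gtol = gtol
        self.seed = seed  # kept for the determinism contract; init is zeros

    def _objective(self, theta_flat, X1, Y):
        K, d1 = self.K, X1.shape[1]
        theta = theta_flat.reshape(K, d1)
        S = X1 @ theta.T                       # (n, K) scores
        S -= S.max(axis=1, keepdims=True)
        logZ = np.log(np.exp(S).sum(axis=1))
        loglik = (S[np.arange(X1.shape[0]), Y] - logZ).sum()
        pen = 0.5 * self.l2 * (theta[:, 1:] ** 2).sum()
        J = -loglik + pen
        P = np.exp(S - logZ[:, None])
        G = (P - np.eye(K)[Y]).T @ X1          # (K, d1)
        G[:, 1:] += self.l2 * theta[:, 1:]
        return J, G.ravel()

    def _fit(self, X, yi):
        from scipy.optimize import minimize

        X1 = np.hstack([np.ones((X.shape[0], 1)), X])
        history: list[float] = []
        fun = lambda t: self._objective(t, X1, yi)

        def cb(tk):
            history.append(fun(tk)[0])

        x0 = np.zeros(self.K * X1.shape[1])
        history.append(fun(x0)[0])
        res = minimize(fun, x0, jac=True, method="L-BFGS-B", callback=cb,
                       options={"maxiter": self.max_iter, "gtol": self.gtol})
        gnorm = float(np.max(np.abs(res.jac)))
        if not res.success and gnorm > 1e-3:
            raise ConvergenceError(
                f"softmax optimisation did not converge: {res.message}",
                gradient_norm=gnorm, iterations=res.nit)
        self.theta_ = res.x.reshape(self.K, X1.shape[1])
        self.objective_history_ = history
        self.gradient_norm_ = gnorm

    def _predict_proba(self, X):
        X1 = np.hstack([np.ones((X.shape[0], 1)), X])
        S = X1 @ self.theta_.T
        S -= S.max(axis=1, keepdims=True)
        E = np.exp(S)
        return E / E.sum(axis=1, keepdims=True)

    def params(self) -> dict:
        self._check_fitted()
        if self._single is not None:
            return {"single_class": self._single}
        return {"theta": self.theta_.tolist(), "l2": self.l2}


# ---------------------------------------------------------------------------
# Platt sigmoid
# ---------------------------------------------------------------------------

def platt_sigmoid(f, A: float, B: float) -> np.ndarray:
    """Pairwise probability ``r = 1 / (1 + exp(A·f + B))``, computed stably."""
    z = A * np.asarray(f, dtype=float) + B
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = np.exp(-z[pos]) / (1.0 + np.exp(-z[pos]))
    out[~pos] = 1.0 / (1.0 + np.exp(z[~pos]))
    return out


def platt_fit_sigmoid(f, y, max_iter: int = 100, min_step: float = 1e-10,
                      sigma: float = 1e-12) -> tuple[float, float]:
    """Fit the Platt sigmoid ``r = 1/(1+exp(A·f+B))`` to binary outcomes.

    ``f`` are decision values and ``y`` is True for the positive class
    of the pair.  A and B maximise the regularised log-likelihood with
    prior-smoothed targets ``(N⁺+1)/(N⁺+2)`` and ``1/(N⁻+2)`` (the
    smoothing acts as a Bayesian guard against deterministic outputs),
    using Newton's method with backtracking line search.

    Returns
    -------
    (A, B) : tuple of float

    Raises
    ------
    InvalidInputError
        If only one class is present (the sigmoid is unidentifiable).
    ConvergenceError
        If the line search stalls before reaching the optimum.
    """
    f = np.asarray(f, dtype=float)
    y = np.asarray(y, dtype=bool)
    if f.shape != y.shape or f.ndim != 1:
        raise InvalidInputError("f and y must be matching 1-D arrays")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise InvalidInputError("both pair classes must be represented")

    hi = (n_pos + 1.0) / (n_pos + 2.0)
    lo = 1.0 / (n_neg + 2.0)
    t = np.where(y, hi, lo)

    def nll(A, B):
        z = A * f + B
        # -sum t*log r + (1-t)*log(1-r), stable in both tails
        return float(np.sum(np.where(z >= 0,
                                     t * z + np.log1p(np.exp(-z)),
                                     (t - 1.0) * z + np.log1p(np.exp(z)))))

    A, B = 0.0, math.log((n_neg + 1.0) / (n_pos + 1.0))
    fval = nll(A, B)
    for _ in range(max_iter):
        z = A * f + B
        p = platt_sigmoid(f, A, B)
        d1 = t - p                      # dNLL/dz has sign -(t - p)... see below
        # gradient of NLL wrt (A, B): dNLL/dz = t - p  (r decreasing in z)
        g1 = float(np.dot(f, d1))
        g2 = float(np.sum(d1))
        if abs(g1) < 1e-5 and abs(g2) < 1e-5:
            break
        w = p * (1.0 - p)
        h11 = float(np.dot(f * f, w)) + sigma
        h22 = float(np.sum(w)) + sigma
        h21 = float(np.dot(f, w))
        det = h11 * h22 - h21 * h21
        dA = -(h22 * g1 - h21 * g2) / det
        dB = -(-h21 * g1 + h11 * g2) / det
        gd = g1 * dA + g2 * dB
        step = 1.0
        while step >= min_step:
            newA, newB = A + step * dA, B + step * dB
            newf = nll(newA, newB)
            if newf < fval + 1e-4 * step * gd:
                A, B, fval = newA, newB, newf
                break
            step /= 2.0
        else:
            if max(abs(g1), abs(g2)) < 1e-5:
                break  # at the optimum to floating-point resolution
            raise ConvergenceError("Platt sigmoid line search failed",
                                   gradient_norm=max(abs(g1), abs(g2)))
    return A, B


# ---------------------------------------------------------------------------
# Pairwise coupling
# ---------------------------------------------------------------------------

def pairwise_couple(r: np.ndarray, tol: float = 1e-10,
                    max_iter: int = 5000) -> np.ndarray:
    """Couple pairwise probabilities into one multi-class distribution.

    Given ``r[i, j] ≈ P(y=i | y ∈ {i, j}, x)`` with ``r[i,j]+r[j,i]=1``,
    returns the distribution p minimising

        ½ Σ_i Σ_{j≠i} (r_ji·p_i − r_ij·p_j)²   s.t.  p ≥ 0, Σp = 1.

    Solved by the damped fixed-point sweep on the KKT system
    (coordinate update ``p_t ← (p^T Q p − Σ_{j≠t} Q_tj p_j)/Q_tt`` with
    simplex renormalisation), stopping when the KKT residual
    ``max_t |(Qp)_t − p^T Q p|`` drops below ``tol``.
    """
    r = np.asarray(r, dtype=float)
    K = r.shape[0]
    if r.shape != (K, K) or K < 2:
        raise InvalidInputError("r must be a K×K matrix with K >= 2")
    off = ~np.eye(K, dtype=bool)
    if np.any(r[off] < -1e-12) or np.any(r[off] > 1 + 1e-12):
        raise InvalidInputError("pairwise probabilities must lie in [0, 1]")
    if not np.allclose(r[off] + r.T[off], 1.0, atol=1e-8):
        raise InvalidInputError("pairwise probabilities must satisfy r_ij + r_ji = 1")

    Q = np.zeros((K, K))
    for i in range(K):
        for j in range(K):
            if i == j:
                Q[i, i] = sum(r[j2, i] ** 2 for j2 in range(K) if j2 != i)
            else:
                Q[i, j] = -r[j, i] * r[i, j]

    p = np.full(K, 1.0 / K)
    for it in range(max_iter):
        Qp = Q @ p
        pQp = float(p @ Qp)
        if np.max(np.abs(Qp - pQp)) < tol:
            return p
        for tt in range(K):
            diff = (-Qp[tt] + pQp) / Q[tt, tt]
            p[tt] += diff
            pQp = (pQp + diff * (diff * Q[tt, tt] + 2.0 * Qp[tt])) / (1.0 + diff) ** 2
            Qp = (Qp + diff * Q[:, tt]) / (1.0 + diff)
            p /= 1.0 + diff
    raise ConvergenceError("pairwise coupling did not converge", iterations=max_iter)


# ---------------------------------------------------------------------------
# SVM + Platt
# ---------------------------------------------------------------------------

class SVMPlatt(ProbabilisticClassifier):
    """One-vs-one RBF SVMs with Platt-calibrated, coupled probabilities.

    The margin machines are scikit-learn ``SVC`` classifiers (one per
    class pair); their decision values on the training data feed a
    Platt sigmoid per pair, and at prediction time the pairwise
    probabilities are coupled with :func:`pairwise_couple`.  ``predict``
    uses the coupled distribution; ``predict_label_votes`` exposes raw
    one-vs-one voting (used as the fast Venn taxonomy, where only the
    label is needed and the sigmoid fits would be wasted work).
    """

    def __init__(self, labels, C: float = 10.0, gamma="scale"):
        super().__init__(labels)
        self.C = C
        self.gamma = gamma

    def _fit(self, X, yi):
        self._svc = SVC(C=self.C, gamma=self.gamma, kernel="rbf",
                        decision_function_shape="ovo")
        self._svc.fit(X, yi)
        self._train_X = X
        self._train_yi = yi
        self._platt = None  # fitted lazily

    # -- decision values --------------------------------------------------
    def decision_values(self, X) -> np.ndarray:
        """(n, K, K) antisymmetric matrix of pairwise decision values.

        ``F[:, i, j] = f_ij`` (alphabet indices), positive when the
        example falls on class i's side of the (i, j) margin;
        ``f_ij = -f_ji``.  Pairs involving a class absent from training
        are left at 0.
        """
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self._single is not None:
            raise NotFittedError("decision values undefined for a single-class fit")
        dec = self._svc.decision_function(X)
        if dec.ndim == 1:
            # binary: sklearn returns one column with positive favouring
            # classes_[1]; flip to the multiclass ovo convention
            # (positive favours the first class of the pair)
            dec = -dec[:, None]
        classes = [int(c) for c in self._svc.classes_]
        F = np.zeros((X.shape[0], self.K, self.K))
        for col, (a, b) in enumerate(combinations(range(len(classes)), 2)):
            i, j = classes[a], classes[b]
            # sklearn/libsvm ovo: positive value favours the first class
            F[:, i, j] = dec[:, col]
            F[:, j, i] = -dec[:, col]
        return F

    def _ensure_platt(self):
        if self._platt is not None:
            return
        F = self.decision_values(self._train_X)
        self._platt = {}
        for i, j in combinations([int(c) for c in self._svc.classes_], 2):
            mask = (self._train_yi == i) | (self._train_yi == j)
            f_pair = F[mask, i, j]
            y_pair = self._train_yi[mask] == i
            self._platt[(i, j)] = platt_fit_sigmoid(f_pair, y_pair)

    def pairwise_probabilities(self, X) -> np.ndarray:
        """(n, K, K) matrix of Platt pairwise probabilities r_ij."""
        self._ensure_platt()
        F = self.decision_values(X)
        R = np.full((F.shape[0], self.K, self.K), 0.5)
        for (i, j), (A, B) in self._platt.items():
            rij = platt_sigmoid(F[:, i, j], A, B)
            R[:, i, j] = rij
            R[:, j, i] = 1.0 - rij
        return R

    def _predict_proba(self, X):
        R = self.pairwise_probabilities(X)
        present = [int(c) for c in self._svc.classes_]
        out = np.zeros((X.shape[0], self.K))
        if len(present) == self.K:
            for n in range(X.shape[0]):
                out[n] = pairwise_couple(R[n])
        else:  # couple only over classes seen in training
            sub = np.ix_(present, present)
            for n in range(X.shape[0]):
                out[n][present] = pairwise_couple(R[n][sub])
        return out

    def predict(self, X) -> np.ndarray:
        """Labels by one-vs-one majority vote.

        Voting is the margin machines' native label rule and needs no
        sigmoid calibration, so the Venn taxonomy (which only consumes
        labels) skips the Platt/coupling chain entirely.  Note the
        voted label can occasionally differ from the argmax of
        ``predict_proba``.
        """
        return self.predict_label_votes(X)

    def predict_label_votes(self, X) -> np.ndarray:
        """Labels by one-vs-one majority vote (no sigmoid calibration)."""
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self._single is not None:
            return np.array([self.labels[self._single]] * X.shape[0], dtype=object)
        yi = self._svc.predict(X)
        return np.array([self.labels[int(i)] for i in yi], dtype=object)

    def platt_params(self) -> dict:
        self._ensure_platt()
        return {f"{i},{j}": [A, B] for (i, j), (A, B) in self._platt.items()}


# ---------------------------------------------------------------------------
# Factory & tuning
# ---------------------------------------------------------------------------

def make_classifier(kind: str, labels, seed: int = 0, **hyper) -> ProbabilisticClassifier:
    """Build a classifier by name: ``"nb"``, ``"softmax"`` or ``"svm"``."""
    kind = kind.lower()
    if kind == "nb":
        return GaussianNaiveBayes(labels, **hyper)
    if kind in ("softmax", "sr"):
        return SoftmaxRegression(labels, seed=seed, **hyper)
    if kind == "svm":
        return SVMPlatt(labels, **hyper)
    raise InvalidInputError(f"unknown classifier {kind!r}; expected nb, softmax or svm")


def save_model(clf: ProbabilisticClassifier, path) -> None:
    """Serialise a fitted NB or softmax model to JSON (versioned schema).

    SVM-backed models are excluded on purpose: the support-vector state
    belongs to the backing implementation's own serialisation.
    """
    import json
    from pathlib import Path

    clf._check_fitted()
    if isinstance(clf, GaussianNaiveBayes):
        kind = "nb"
        extra = {"var_smoothing": clf.var_smoothing}
    elif isinstance(clf, SoftmaxRegression):
        kind = "softmax"
        extra = {"max_iter": clf.max_iter, "gtol": clf.gtol, "seed": clf.seed}
    else:
        raise InvalidInputError(
            f"JSON persistence supports nb and softmax models, not "
            f"{type(clf).__name__}")
    payload = {"schema_version": 1, "kind": kind,
               "labels": list(clf.labels), "params": clf.params(), **extra}
    Path(path).write_text(json.dumps(payload, indent=2))


def load_model(path) -> ProbabilisticClassifier:
    """Rebuild a model saved with :func:`save_model`."""
    import json
    from pathlib import Path

    payload = json.loads(Path(path).read_text())
    if payload.get("schema_version") != 1:
        raise InvalidInputError(f"unsupported model schema: {payload.get('schema_version')}")
    labels = tuple(payload["labels"])
    params = payload["params"]
    if payload["kind"] == "nb":
        clf = GaussianNaiveBayes(labels, var_smoothing=payload["var_smoothing"])
        if "single_class" in params:
            clf._single = params["single_class"]
        else:
            clf._single = None
            clf._model = _SkGaussianNB(var_smoothing=clf.var_smoothing)
            clf._model.classes_ = np.asarray(params["classes"])
            clf._model.class_prior_ = np.asarray(params["priors"])
            clf._model.theta_ = np.asarray(params["means"])
            clf._model.var_ = np.asarray(params["variances"])
    elif payload["kind"] == "softmax":
        clf = SoftmaxRegression(labels, l2=params.get("l2", 1e-4),
                                max_iter=payload["max_iter"],
                                gtol=payload["gtol"], seed=payload["seed"])
        if "single_class" in params:
            clf._single = params["single_class"]
        else:
            clf._single = None
            clf.theta_ = np.asarray(params["theta"])
    else:
        raise InvalidInputError(f"unknown model kind {payload['kind']!r}")
    clf._fitted = True
    return clf


@dataclass
class TuningResult:
    C: float
    gamma: float
    cv_accuracy: float
    table: list  # (C, gamma, accuracy) triples in search order


def tune_svm(data: Dataset, c_grid=DEFAULT_C_GRID, gamma_grid=DEFAULT_GAMMA_GRID,
             folds: int = 5, seed: int = 0) -> TuningResult:
    """Grid-search (C, γ) for the RBF SVM by stratified K-fold accuracy.

    Ties are broken toward the smallest C, then the smallest γ.  Raises
    if a class has fewer members than the number of folds (stratified
    splitting would be impossible).
    """
    yi = data.label_indices()
    _, counts = np.unique(yi, return_counts=True)
    if counts.min() < folds:
        raise InvalidInputError(
            f"every class needs at least {folds} examples for {folds}-fold "
            f"stratified tuning (smallest class has {counts.min()})")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(data.X, yi))
    best = None
    table = []
    for C in c_grid:
        for gamma in gamma_grid:
            correct = 0
            for tr, te in splits:
                svc = SVC(C=C, gamma=gamma, kernel="rbf")
                svc.fit(data.X[tr], yi[tr])
                correct += int((svc.predict(data.X[te]) == yi[te]).sum())
            acc = correct / data.n
            table.append((C, gamma, acc))
            if best is None or acc > best[2]:  # strict: earliest grid point wins ties
                best = (C, gamma, acc)
    return TuningResult(C=best[0], gamma=best[1], cv_accuracy=best[2], table=table)
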