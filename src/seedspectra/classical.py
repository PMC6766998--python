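"""Classical spectral classifiers: PLS-DA, logistic regression, RBF-SVM.

All three share a small estimator interface (``fit`` / ``predict``) and a
provenance tag saying which feature space they were trained on (full
spectra, effective wavelengths, or deep features).  Model selection follows
standard chemometric practice: PLS-DA picks its number of latent variables
by leave-one-out cross-validation, the SVM picks (C, gamma) by a 5-fold
stratified grid search, and logistic regression uses an L2-penalized
one-vs-rest fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC


# ------------------------------------------------------------ dummy coding
def encode_plsda_targets(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """One-hot dummy matrix with the bit-string convention that class k has
    its 1 in position ``n_classes - 1 - k``: for 7 classes, class 0 encodes
    as 0000001 and class 6 as 1000000."""
    labels = np.asarray(labels, dtype=int)
    if labels.size and (labels.min() < 0 or labels.max() >= n_classes):
        raise ValueError("labels out of range for the dummy coding")
    dummy = np.zeros((labels.size, n_classes))
    dummy[np.arange(labels.size), n_classes - 1 - labels] = 1.0
    return dummy


def decode_plsda_targets(dummy: np.ndarray) -> np.ndarray:
    """Inverse of :func:`encode_plsda_targets` via argmax."""
    dummy = np.asarray(dummy)
    n_classes = dummy.shape[1]
    return n_classes - 1 - np.argmax(dummy, axis=1)


def _canonical_order(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row permutation that depends only on the multiset of (x, y) pairs,
    making cross-validation results invariant to input row order."""
    keys = [X[:, j] for j in range(X.shape[1] - 1, -1, -1)] + [y]
    return np.lexsort(tuple(keys))


def simpls(X: np.ndarray, Y: np.ndarray, n_components: int
           ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """SIMPLS decomposition of centered multi-response PLS regression.

    Returns ``(x_mean, y_mean, R, Q)`` where the regression coefficients
    using the first ``a`` latent variables are ``R[:, :a] @ Q[:, :a].T``
    (components are nested, so one decomposition serves every LV count).
    For a single response this coincides exactly with NIPALS PLS.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean
    d = X.shape[1]
    S = Xc.T @ Yc
    R = np.zeros((d, n_components))
    Q = np.zeros((Y.shape[1], n_components))
    V = np.zeros((d, n_components))
    for a in range(n_components):
        # dominant left singular vector of the (deflated) cross-covariance
        u, sv, _ = np.linalg.svd(S, full_matrices=False)
        if sv[0] <= np.finfo(float).eps * max(1.0, sv.max(initial=0.0)):
            R, Q = R[:, :a], Q[:, :a]
            break
        r = u[:, 0]
        t = Xc @ r
        norm_t = np.linalg.norm(t)
        if norm_t <= np.finfo(float).eps:
            R, Q = R[:, :a], Q[:, :a]
            break
        t /= norm_t
        r /= norm_t
        p = Xc.T @ t
        q = Yc.T @ t
        v = p - V[:, :a] @ (V[:, :a].T @ p)
        nv = np.linalg.norm(v)
        if nv <= np.finfo(float).eps:
            R, Q = R[:, :a], Q[:, :a]
            break
        v /= nv
        S = S - np.outer(v, v @ S)
        R[:, a], Q[:, a], V[:, a] = r, q, v
    return x_mean, y_mean, R, Q


# -------------------------------------------------------------- estimators
@dataclass
class PLSDAClassifier:
    """PLS regression onto the class dummy matrix, decoded by argmax.

    The number of latent variables (LVs) maximizing leave-one-out CV
    accuracy is selected (smallest count on ties) and the model refit on all
    data; passing ``n_lv`` skips the search and uses that count directly.
    """

    max_lv: int = 30
    n_lv: int | None = None
    kind: str = "PLS-DA"
    provenance: str = "full-spectra"
    n_lv_: int | None = None
    cv_accuracy_: float | None = None

    def _fit_final(self, X: np.ndarray, Y: np.ndarray, n_lv: int) -> None:
        x_mean, y_mean, R, Q = simpls(X, Y, n_lv)
        self._x_mean = x_mean
        self._y_mean = y_mean
        self._coef = R @ Q.T
        self.n_lv_ = R.shape[1]

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PLSDAClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 samples")
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("need at least 2 classes present")
        self.n_classes_ = int(y.max()) + 1
        Y = encode_plsda_targets(y, self.n_classes_)
        n, d = X.shape
        if self.n_lv is not None:
            self._fit_final(X, Y, self.n_lv)
            return self
        max_lv = min(self.max_lv, d, n - 2)
        lvs = np.arange(1, max_lv + 1)
        hits = np.zeros(max_lv + 1, dtype=int)
        for i in range(n):
            keep = np.arange(n) != i
            x_mean, y_mean, R, Q = simpls(X[keep], Y[keep], max_lv)
            xc = X[i] - x_mean
            # nested predictions for every LV count from one decomposition
            contrib = (xc @ R)[:, None] * Q.T          # (A, q) per-LV increments
            preds = y_mean + np.cumsum(contrib, axis=0)
            decoded = decode_plsda_targets(preds)
            hits[1:R.shape[1] + 1] += decoded == y[i]
        best = int(max(lvs, key=lambda a: (hits[a], -a)))
        self.cv_accuracy_ = 100.0 * hits[best] / n
        self._fit_final(X, Y, best)
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self._coef.shape[0]:
            raise ValueError(
                f"expected {self._coef.shape[0]} features, got {X.shape[1]}")
        return (X - self._x_mean) @ self._coef + self._y_mean

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[0] == 0:
            return np.empty(0, dtype=int)
        return decode_plsda_targets(self.decision_function(X))


@dataclass
class LRClassifier:
    """One-vs-rest regularized logistic regression."""

    penalty: str = "l2"
    C: float = 1.0
    max_iter: int = 2000
    kind: str = "LR"
    provenance: str = "full-spectra"

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LRClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if np.unique(y).size < 2:
            raise ValueError("need at least 2 classes present")
        solver = "liblinear" if self.penalty == "l1" else "lbfgs"
        self._ovr = OneVsRestClassifier(LogisticRegression(
            penalty=self.penalty, C=self.C, solver=solver,
            max_iter=self.max_iter))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self._ovr.fit(X, y)
        self.n_features_ = X.shape[1]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[0] == 0:
            return np.empty(0, dtype=int)
        if X.shape[1] != self.n_features_:
            raise ValueError(f"expected {self.n_features_} features, got {X.shape[1]}")
        return self._ovr.predict(X)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self._ovr.predict_proba(X)


def default_svm_grid() -> tuple[np.ndarray, np.ndarray]:
    return (np.logspace(-2, 4, 7), np.logspace(-4, 2, 7))


@dataclass
class SVMClassifier:
    """RBF-kernel SVM with a stratified 5-fold CV grid search over (C, gamma).

    Ties in mean CV accuracy break toward smaller C, then smaller gamma.
    The search is invariant to input row order (rows are canonically sorted
    before fold construction) and the winner is refit on all data.
    """

    C_grid: np.ndarray = field(default_factory=lambda: default_svm_grid()[0])
    gamma_grid: np.ndarray = field(default_factory=lambda: default_svm_grid()[1])
    folds: int = 5
    kind: str = "SVM"
    provenance: str = "full-spectra"
    C_: float | None = None
    gamma_: float | None = None
    cv_accuracy_: float | None = None

    def cv_accuracy_at(self, X: np.ndarray, y: np.ndarray,
                       C: float, gamma: float) -> float:
        """Mean stratified-CV accuracy at one grid point (canonical row
        order), as used by the search."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        order = _canonical_order(X, y)
        Xs, ys = X[order], y[order]
        skf = StratifiedKFold(n_splits=self.folds, shuffle=False)
        accs = []
        for train, test in skf.split(Xs, ys):
            model = SVC(C=C, gamma=gamma, kernel="rbf")
            model.fit(Xs[train], ys[train])
            accs.append(float(np.mean(model.predict(Xs[test]) == ys[test])))
        return float(np.mean(accs))

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SVMClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < self.folds:
            raise ValueError(
                f"every class needs at least {self.folds} members for "
                f"{self.folds}-fold CV (smallest has {counts.min()})")
        best = (-1.0, None, None)
        for C in sorted(self.C_grid):
            for gamma in sorted(self.gamma_grid):
                acc = self.cv_accuracy_at(X, y, C, gamma)
                if acc > best[0]:
                    best = (acc, C, gamma)
        self.cv_accuracy_ = best[0] * 100.0
        self.C_, self.gamma_ = float(best[1]), float(best[2])
        self._svc = SVC(C=self.C_, gamma=self.gamma_, kernel="rbf")
        self._svc.fit(X, y)
        self.n_features_ = X.shape[1]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[0] == 0:
            return np.empty(0, dtype=int)
        if X.shape[1] != self.n_features_:
            raise ValueError(f"expected {self.n_features_} features, got {X.shape[1]}")
        return self._svc.predict(X)


# ------------------------------------------------------ functional surface
def fit_plsda(X, labels, max_lv: int = 30, provenance: str = "full-spectra"):
    return PLSDAClassifier(max_lv=max_lv, provenance=provenance).fit(X, labels)


def fit_lr(X, labels, penalty: str = "l2", C: float = 1.0,
           provenance: str = "full-spectra"):
    return LRClassifier(penalty=penalty, C=C, provenance=provenance).fit(X, labels)


def fit_svm(X, labels, C_grid=None, gamma_grid=None, folds: int = 5,
            provenance: str = "full-spectra"):
    default_C, default_gamma = default_svm_grid()
    return SVMClassifier(
        C_grid=np.asarray(C_grid) if C_grid is not None else default_C,
        gamma_grid=np.asarray(gamma_grid) if gamma_grid is not None else default_gamma,
        folds=folds, provenance=provenance,
    ).fit(X, labels)


def predict(model, X) -> np.ndarray:
    """Uniform prediction entry point for any trained classifier."""
    return model.predict(X)
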