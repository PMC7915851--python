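"""NIPALS PLS2 discriminant analysis with VIP scores, CV diagnostics, and
label-permutation testing.

PLS-DA regresses a column-centered one-hot class matrix Y on the (auto-
scaled) feature matrix X by NIPALS partial least squares and classifies by
argmax of the predicted Y row. Model quality is summarised per component
count A by R2 (fitted Y variance), Q2 = 1 - PRESS/SS_tot (cross-validated),
and out-of-fold accuracy; A is chosen to maximise Q2. Overfitting is probed
with a label-permutation test: the CV statistic is recomputed under B
random relabelings and p = (1 + #{perm >= observed}) / (B + 1).

VIP (variable importance in projection) for feature j:

    VIP_j = sqrt( p * sum_a SSY_a (w_aj / ||w_a||)^2 / sum_a SSY_a )

with SSY_a the Y sum of squares explained by component a; the scores
satisfy sum_j VIP_j^2 = p, so VIP = 1 is the indifference level and the
conventional selection threshold is VIP > 1.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import RepeatedStratifiedKFold, LeaveOneOut
from sklearn.utils.validation import check_array, check_is_fitted


def _one_hot(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    Y = np.zeros((len(y), len(classes)))
    for k, c in enumerate(classes):
        Y[y == c, k] = 1.0
    return Y


class PLSDAClassifier(ClassifierMixin, BaseEstimator):
    """Partial least squares discriminant analysis (NIPALS PLS2).

    Parameters
    ----------
    n_components : int
        Number of latent components A. Truncated (with a warning) if the
        data cannot support that many.
    scale : bool
        Autoscale X columns (mean 0, sd 1, n-1 denominator) using training
        statistics. The one-hot Y is always column-centered.
    max_iter, tol : NIPALS inner-loop controls.

    Attributes
    ----------
    classes_ : ndarray of class labels (sorted).
    x_weights_ : (p, A) NIPALS weights, unit-norm columns.
    x_scores_ : (n, A) score matrix T with mutually orthogonal columns.
    x_loadings_, y_loadings_ : (p, A) and (K, A) loading matrices.
    coef_ : (p, K) regression coefficients mapping scaled X to centered Y.
    explained_y_ss_ : (A,) per-component explained Y sum of squares.
    """

    def __init__(self, n_components: int = 2, scale: bool = True,
                 max_iter: int = 500, tol: float = 1e-10):
        self.n_components = n_components
        self.scale = scale
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        X = check_array(X, dtype=float)
        y = np.asarray(y)
        if len(y) != X.shape[0]:
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        n, p = X.shape
        self.x_mean_ = X.mean(axis=0)
        if self.scale:
            sd = X.std(axis=0, ddof=1)
            if (sd == 0).all():
                raise ValueError("X has zero variance everywhere")
            self.x_std_ = np.where(sd > 0, sd, 1.0)
        else:
            self.x_std_ = np.ones(p)
        Xc = (X - self.x_mean_) / self.x_std_
        if not np.isfinite(Xc).all():
            raise ValueError("non-finite values after scaling")

        Y = _one_hot(y, self.classes_)
        self.y_mean_ = Y.mean(axis=0)
        Yc = Y - self.y_mean_

        A = min(self.n_components, n - 1, p)
        if A < self.n_components:
            warnings.warn(f"n_components truncated to {A} (rank limit)")
        W, T, P, C = [], [], [], []
        Xr, Yr = Xc.copy(), Yc.copy()
        eps = np.finfo(float).eps
        for _ in range(A):
            if np.linalg.norm(Xr) < 1e-12:
                warnings.warn("X residual exhausted; stopping early")
                break
            # start u from the Y-residual column with the largest variance
            u = Yr[:, np.argmax((Yr ** 2).sum(axis=0))].copy()
            if np.linalg.norm(u) < 1e-12:
                break
            t_old = None
            for _ in range(self.max_iter):
                w = Xr.T @ u
                nw = np.linalg.norm(w)
                if nw < eps:
                    break
                w /= nw
                t = Xr @ w
                c = Yr.T @ t / (t @ t)
                u = Yr @ c / max(c @ c, eps)
                if t_old is not None and np.linalg.norm(t - t_old) < self.tol * np.linalg.norm(t):
                    break
                t_old = t
            if np.linalg.norm(t) < 1e-12:
                break
            p_load = Xr.T @ t / (t @ t)
            Xr = Xr - np.outer(t, p_load)
            Yr = Yr - np.outer(t, c)
            W.append(w); T.append(t); P.append(p_load); C.append(c)
        if not W:
            raise ValueError("no usable PLS component (X or Y degenerate)")
        self.n_components_ = len(W)
        self.x_weights_ = np.column_stack(W)
        self.x_scores_ = np.column_stack(T)
        self.x_loadings_ = np.column_stack(P)
        self.y_loadings_ = np.column_stack(C)
        # B = W (P'W)^-1 C'
        pw = self.x_loadings_.T @ self.x_weights_
        self.coef_ = self.x_weights_ @ np.linalg.solve(pw, self.y_loadings_.T)
        tt = (self.x_scores_ ** 2).sum(axis=0)
        self.explained_y_ss_ = tt * (self.y_loadings_ ** 2).sum(axis=0)
        return self

    def decision_function(self, X) -> np.ndarray:
        """Predicted (uncentered) Y rows; one column per class."""
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        if X.shape[1] != len(self.x_mean_):
            raise ValueError("feature count mismatch with training data")
        Xc = (X - self.x_mean_) / self.x_std_
        return Xc @ self.coef_ + self.y_mean_

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        ties = np.isclose(scores, scores.max(axis=1, keepdims=True)).sum(axis=1) > 1
        if ties.any():
            warnings.warn(f"{int(ties.sum())} tied prediction(s); lowest class index taken")
        return self.classes_[np.argmax(scores, axis=1)]


def vip_scores(model: PLSDAClassifier) -> np.ndarray:
    """Per-feature VIP scores of a fitted model; satisfies sum(VIP^2) = p."""
    check_is_fitted(model, "coef_")
    w = model.x_weights_
    wnorm2 = (w ** 2).sum(axis=0)  # = 1 by construction, kept for safety
    ssy = model.explained_y_ss_
    p = w.shape[0]
    contrib = (w ** 2 / wnorm2) @ ssy
    return np.sqrt(p * contrib / ssy.sum())


@dataclass
class CvResult:
    """Per-component-count cross-validation diagnostics."""

    components: np.ndarray
    r2: np.ndarray
    q2: np.ndarray
    accuracy: np.ndarray
    chosen: int
    scheme: str

    @property
    def chosen_index(self) -> int:
        return int(np.flatnonzero(self.components == self.chosen)[0])

    @property
    def chosen_q2(self) -> float:
        return float(self.q2[self.chosen_index])

    @property
    def chosen_r2(self) -> float:
        return float(self.r2[self.chosen_index])

    @property
    def chosen_accuracy(self) -> float:
        return float(self.accuracy[self.chosen_index])


def _cv_splitter(y: np.ndarray, folds: int, repeats: int, seed=None):
    counts = np.unique(y, return_counts=True)[1]
    if counts.min() < folds:
        return LeaveOneOut(), "loo"
    rs = int(seed) if seed is not None else None
    return RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats,
                                   random_state=rs), f"stratified-{folds}fold-x{repeats}"


def cross_validate(X, y, a_max: int = 10, folds: int = 5, repeats: int = 10,
                   seed: int = 0, scale: bool = True) -> CvResult:
    """R2 / Q2 / out-of-fold accuracy per component count.

    Q2(A) = 1 - PRESS(A) / SS_tot(Y), with PRESS pooled over folds (and
    repeats) against the centered one-hot class matrix. Falls back to
    leave-one-out when the smallest class cannot fill the folds. The
    chosen component count maximises Q2.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    Y = _one_hot(y, classes)
    a_max = int(min(a_max, X.shape[0] - 2, X.shape[1]))
    if a_max < 1:
        raise ValueError("no usable component count")
    splitter, scheme = _cv_splitter(y, folds, repeats, seed)

    ss_tot = ((Y - Y.mean(axis=0)) ** 2).sum()
    press = np.zeros(a_max)
    correct = np.zeros(a_max)
    total = 0
    n_splits = 0
    for train, test in splitter.split(X, y):
        if len(np.unique(y[train])) < len(classes):
            continue  # degenerate fold: a class entirely held out
        n_splits += 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            models = {}
            full = PLSDAClassifier(n_components=a_max, scale=scale).fit(X[train], y[train])
        for a in range(1, a_max + 1):
            m = _truncate(full, a)
            yhat = m.decision_function(X[test])
            press[a - 1] += ((Y[test] - yhat) ** 2).sum()
            pred = m.classes_[np.argmax(yhat, axis=1)]
            correct[a - 1] += (pred == y[test]).sum()
        total += len(test)
    if n_splits == 0:
        raise ValueError("no valid CV split")
    # PRESS accumulates over every split; normalise by how often each
    # sample was held out so repeats do not inflate it
    coverage = total / len(y)
    q2 = 1.0 - press / (ss_tot * coverage)
    accuracy = correct / total

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = PLSDAClassifier(n_components=a_max, scale=scale).fit(X, y)
    r2 = np.empty(a_max)
    for a in range(1, a_max + 1):
        yhat = _truncate(full, a).decision_function(X)
        r2[a - 1] = 1.0 - ((Y - yhat) ** 2).sum() / ss_tot

    components = np.arange(1, a_max + 1)
    chosen = int(components[np.argmax(q2)])
    return CvResult(components, r2, q2, accuracy, chosen, scheme)


def _truncate(model: PLSDAClassifier, a: int) -> PLSDAClassifier:
    """View of a fitted model restricted to its first *a* components."""
    if a >= model.n_components_:
        return model
    m = PLSDAClassifier(n_components=a, scale=model.scale)
    m.classes_ = model.classes_
    m.x_mean_, m.x_std_, m.y_mean_ = model.x_mean_, model.x_std_, model.y_mean_
    m.x_weights_ = model.x_weights_[:, :a]
    m.x_scores_ = model.x_scores_[:, :a]
    m.x_loadings_ = model.x_loadings_[:, :a]
    m.y_loadings_ = model.y_loadings_[:, :a]
    m.n_components_ = a
    pw = m.x_loadings_.T @ m.x_weights_
    m.coef_ = m.x_weights_ @ np.linalg.solve(pw, m.y_loadings_.T)
    m.explained_y_ss_ = model.explained_y_ss_[:a]
    return m


@dataclass
class PermutationResult:
    observed: float
    permuted: np.ndarray = field(repr=False)
    p_value: float
    statistic: str


def permutation_test(X, y, statistic: str = "accuracy", n_permutations: int = 1000,
                     seed: int = 0, a_max: int = 10, folds: int = 5,
                     repeats: int = 1) -> PermutationResult:
    """Label-permutation test of the cross-validated model statistic.

    The full CV procedure (including component selection) is re-run on each
    of *n_permutations* random relabelings; p = (1 + #{perm >= obs})/(B + 1).
    """
    if statistic not in ("accuracy", "q2"):
        raise ValueError("statistic must be 'accuracy' or 'q2'")
    if n_permutations < 1:
        raise ValueError("need at least 1 permutation")
    y = np.asarray(y)

    def stat(labels) -> float:
        cv = cross_validate(X, labels, a_max=a_max, folds=folds, repeats=repeats, seed=seed)
        return cv.chosen_accuracy if statistic == "accuracy" else cv.chosen_q2

    observed = stat(y)
    rng = np.random.default_rng(seed)
    permuted = np.empty(n_permutations)
    for b in range(n_permutations):
        permuted[b] = stat(rng.permutation(y))
    p = (1 + int((permuted >= observed - 1e-12).sum())) / (n_permutations + 1)
    return PermutationResult(float(observed), permuted, float(p), statistic)
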