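"""Multivariate clinical validation of connectivity-derived subgroups.

A linear support vector machine predicts each patient's
connectivity-derived subgroup label from either the three PANSS sub-scores
or five a-priori cognitive measures.  Accuracy is estimated by
leave-one-out cross-validation with predictors z-scored *inside* each
training fold (the held-out row is scaled with the training statistics, so
no information leaks).  Significance uses a Monte Carlo permutation test:
the label vector is shuffled m times (1000 by default), the full LOOCV
accuracy is recomputed each time, and

    p = (b + 1) / (m + 1),  b = #{ permuted accuracy >= observed }.

Feature importance is read from the weight vector of the SVM fitted on all
rows; a positive weight pushes the decision toward subgroup 2.

The SVM itself is solved by dual coordinate descent with an augmented
(regularized) bias term.  The solver runs many problems as one batched
numpy computation — every LOOCV fold of every permutation simultaneously —
which is what makes leave-one-out loops inside 1000-permutation tests
affordable on a single core.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .group_stats import ClinicalTable

__all__ = [
    "PREDICTOR_SETS",
    "LinearSVM",
    "PredictionResult",
    "svm_loocv_accuracy",
    "permutation_test",
    "inspect_weights",
    "predict_subgroups",
]

#: A-priori predictor sets: 3 PANSS sub-scores or 5 cognitive measures.
PREDICTOR_SETS: dict[str, tuple[str, ...]] = {
    "panss": ("panss_pos", "panss_neg", "panss_gen"),
    "cognition": (
        "verbal_iq",
        "verbal_memory",
        "verbal_fluency",
        "mental_flexibility",
        "reaction_time",
    ),
}


@dataclass
class PredictionResult:
    predictor_set: str
    accuracy: float
    n_correct: int
    n_total: int
    permutation_p: float | None
    n_permutations: int
    weights: dict[str, float]
    per_fold_predictions: np.ndarray
    n_dropped_missing: int = 0


def _solve_batch(
    Xt: np.ndarray,
    T: np.ndarray,
    Cbox: np.ndarray,
    tol: float = 1e-8,
    max_sweeps: int = 400,
) -> np.ndarray:
    """Batched L1-hinge linear-SVM dual coordinate descent.

    Solves, for every batch member b,

        min_w  0.5 ||w||^2 + sum_i Cbox[b, i] * hinge(T[b, i] * w . Xt[b, i])

    where ``Xt`` already carries the bias column.  ``Xt`` is either
    ``(n, p)`` (shared design) or ``(B, n, p)``; ``T`` in {-1, +1} and the
    per-row box bound ``Cbox`` are ``(B, n)`` (a bound of 0 removes the row,
    which is how held-out LOOCV rows are expressed).  Returns ``w`` of
    shape ``(B, p)``.  Deterministic: fixed cyclic coordinate order.
    """
    shared = Xt.ndim == 2
    B, n = T.shape
    p = Xt.shape[-1]
    out = np.zeros((B, p))
    w = np.zeros((B, p))
    alpha = np.zeros((B, n))
    active = np.arange(B)
    T = np.array(T, dtype=float)
    Cbox = np.array(Cbox, dtype=float)
    if shared:
        q = np.einsum("ip,ip->i", Xt, Xt)  # (n,)
    else:
        Xt = np.array(Xt, dtype=float)
        q = np.einsum("bip,bip->bi", Xt, Xt)  # (B, n)
    for _ in range(max_sweeps):
        step = np.zeros(active.size)
        for i in range(n):
            xi = Xt[i] if shared else Xt[:, i, :]  # (p,) or (B, p)
            qi = q[i] if shared else q[:, i]
            proj = w @ xi if shared else np.einsum("bp,bp->b", w, xi)
            g = T[:, i] * proj - 1.0
            a_new = np.clip(alpha[:, i] - g / np.maximum(qi, 1e-300), 0.0, Cbox[:, i])
            d = (a_new - alpha[:, i]) * T[:, i]
            alpha[:, i] = a_new
            if shared:
                w += d[:, None] * xi[None, :]
            else:
                w += d[:, None] * xi
            np.maximum(step, np.abs(d), out=step)
        done = step < tol
        if done.any():  # retire converged problems from the batch
            out[active[done]] = w[done]
            keep = ~done
            active, w, alpha, T, Cbox = active[keep], w[keep], alpha[keep], T[keep], Cbox[keep]
            if not shared:
                Xt, q = Xt[keep], q[keep]
            if active.size == 0:
                break
    if active.size:
        out[active] = w
    return out


class LinearSVM:
    """Linear soft-margin SVM (hinge loss, L2 penalty, regularized bias).

    A thin single-problem wrapper over the batched dual coordinate-descent
    solver.  The bias enters as an augmented constant feature and is
    therefore (weakly) regularized, as in liblinear; with z-scored
    predictors the difference from an unregularized intercept is
    negligible.
    """

    def __init__(self, C: float = 1.0, tol: float = 1e-8, max_sweeps: int = 400):
        self.C = float(C)
        self.tol = float(tol)
        self.max_sweeps = int(max_sweeps)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LinearSVM":
        X = np.asarray(X, dtype=float)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("LinearSVM is binary")
        self.classes_ = classes
        t = np.where(np.asarray(y) == classes[1], 1.0, -1.0)
        Xt = np.hstack([X, np.ones((X.shape[0], 1))])
        w = _solve_batch(
            Xt, t[None, :], np.full((1, X.shape[0]), self.C), self.tol, self.max_sweeps
        )[0]
        self.coef_ = w[None, :-1]
        self.intercept_ = w[-1:]
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef_[0] + self.intercept_[0]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(X) >= 0, self.classes_[1], self.classes_[0])


def _zscore_train_apply(train: np.ndarray, other: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, (other - mu) / sd


def _fold_designs(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-fold z-scored designs with bias column.

    Returns ``folds`` of shape (n, n, p+1) where ``folds[b]`` is the whole
    data matrix scaled with the statistics of the fold-b *training* rows
    (every row except b), and ``held`` of shape (n, p+1), the held-out row
    of each fold on its own fold's scale.
    """
    n, p = X.shape
    folds = np.empty((n, n, p + 1))
    folds[:, :, p] = 1.0
    for b in range(n):
        mask = np.ones(n, dtype=bool)
        mask[b] = False
        Z_tr, Z_all = _zscore_train_apply(X[mask], X)
        folds[b, :, :p] = Z_all
    held = folds[np.arange(n), np.arange(n), :]
    return folds, held


def _loocv_batch(folds, held, T, C) -> np.ndarray:
    """LOOCV predictions (+1/-1 decision signs) for many label vectors.

    ``T`` is (m, n) in {-1, +1}; problem (perm, fold) is expressed by
    zeroing the held-out row's box bound.  Returns the (m, n) matrix of
    held-out decision signs.
    """
    m, n = T.shape
    p = folds.shape[2]
    # batch index: perm-major, fold-minor
    Xt = np.broadcast_to(folds[None], (m, n, n, p)).reshape(m * n, n, p)
    Tb = np.repeat(T, n, axis=0)  # (m*n, n)
    Cbox = np.full((m * n, n), float(C))
    fold_idx = np.tile(np.arange(n), m)
    Cbox[np.arange(m * n), fold_idx] = 0.0
    w = _solve_batch(Xt, Tb, Cbox)
    dec = np.einsum("bp,bp->b", w, np.tile(held, (m, 1)))
    return np.where(dec >= 0, 1.0, -1.0).reshape(m, n)


def svm_loocv_accuracy(
    X: np.ndarray, y: np.ndarray, C: float = 1.0
) -> tuple[float, np.ndarray]:
    """LOOCV accuracy of the linear SVM with within-fold z-scoring.

    Returns the fraction of correctly predicted held-out rows and the
    per-fold predicted labels.  A training fold that loses one class
    entirely (only possible when a class has a single member) predicts the
    majority class for its held-out row, with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n x p) with one label per row")
    if np.isnan(X).any():
        raise ValueError("X contains missing values; drop incomplete rows first")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.tolist()}")
    t = np.where(y == classes[1], 1.0, -1.0)
    folds, held = _fold_designs(X)
    signs = _loocv_batch(folds, held, t[None, :], C)[0]
    preds = np.where(signs > 0, classes[1], classes[0])
    # folds whose training set lost a class: majority-class fallback
    counts = {c: int(np.sum(y == c)) for c in classes}
    for c, cnt in counts.items():
        if cnt == 1:
            b = int(np.flatnonzero(y == c)[0])
            other = classes[0] if c == classes[1] else classes[1]
            preds[b] = other
            warnings.warn(
                f"fold {b}: training set lost class {c!r}; predicting majority",
                stacklevel=2,
            )
    accuracy = float(np.mean(preds == y))
    return accuracy, preds


def permutation_test(
    X: np.ndarray,
    y: np.ndarray,
    C: float = 1.0,
    n_permutations: int = 1000,
    seed: int = 0,
) -> tuple[float, float, np.ndarray]:
    """Monte Carlo permutation p for the LOOCV accuracy.

    Returns ``(observed_accuracy, p, permuted_accuracies)`` with
    p = (b + 1)/(m + 1), b counting permuted accuracies >= the observed one
    (the conservative add-one estimator; the smallest attainable p is
    1/(m + 1)).  All (permutation, fold) SVM fits run as one batched solve.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    observed, _ = svm_loocv_accuracy(X, y, C)
    classes = np.unique(y)
    t = np.where(y == classes[1], 1.0, -1.0)
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(t) for _ in range(n_permutations)])
    folds, held = _fold_designs(X)
    signs = _loocv_batch(folds, held, perms, C)
    perm_acc = (signs == perms).mean(axis=1)
    p = (np.sum(perm_acc >= observed - 1e-12) + 1.0) / (n_permutations + 1.0)
    return observed, float(p), perm_acc


def inspect_weights(
    X: np.ndarray, y: np.ndarray, C: float = 1.0, feature_names=None
) -> dict[str, float]:
    """Signed weights of the SVM fitted on all rows (z-scored predictors).

    The sign convention follows the sorted class order: a positive weight
    pushes the decision function toward the higher class label (subgroup 2
    when labels are 1/2).
    """
    X = np.asarray(X, dtype=float)
    Z, _ = _zscore_train_apply(X, X)
    clf = LinearSVM(C=C).fit(Z, np.asarray(y))
    w = clf.coef_[0]
    names = list(feature_names) if feature_names is not None else [f"x{j}" for j in range(len(w))]
    return dict(zip(names, map(float, w)))


def predict_subgroups(
    labels: dict[str, int],
    clinical: ClinicalTable,
    predictor_set: str,
    C: float = 1.0,
    n_permutations: int = 1000,
    seed: int = 0,
) -> PredictionResult:
    """Run the full validation for one predictor set against subgroup labels.

    Patients with any missing predictor are dropped listwise (the count is
    recorded on the result).
    """
    if predictor_set not in PREDICTOR_SETS:
        raise ValueError(f"unknown predictor set {predictor_set!r}")
    variables = list(PREDICTOR_SETS[predictor_set])
    table = clinical.data.set_index("participant_id")
    ids = [p for p in labels if p in table.index]
    Xfull = table.loc[ids, variables].to_numpy(dtype=float)
    keep = ~np.isnan(Xfull).any(axis=1)
    n_dropped = int((~keep).sum())
    X = Xfull[keep]
    y = np.asarray([labels[p] for p in ids])[keep]
    observed, p, _ = permutation_test(X, y, C, n_permutations, seed)
    _, preds = svm_loocv_accuracy(X, y, C)
    weights = inspect_weights(X, y, C, feature_names=variables)
    return PredictionResult(
        predictor_set=predictor_set,
        accuracy=observed,
        n_correct=int(np.sum(preds == y)),
        n_total=int(len(y)),
        permutation_p=p,
        n_permutations=n_permutations,
        weights=weights,
        per_fold_predictions=preds,
        n_dropped_missing=n_dropped,
    )
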