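"""Stability-gated Gaussian-mixture subgrouping of patient PC scores.

Patients (never controls) are clustered in the reduced PLI-score space by a
Gaussian mixture model fitted with EM.  Every M-step adds a ridge term
``lambda * I`` to each component covariance, which keeps tiny-sample fits
well conditioned; ``lambda`` and the component count ``K`` are chosen
jointly by leave-one-out cross-validated held-out log-likelihood over a
grid (``K`` = 1..8 by default).  Because EM is initialization-dependent,
the whole selection is repeated (50 times by default) from different
starts; a cluster count is only *reported* when the same ``K`` wins in at
least 90% of the repeats.  A stable solution is then refitted on all
patients and each patient is assigned to the component with the highest
posterior responsibility.  Subgroups are numbered by decreasing size
(ties broken by the lower mean on the first principal component).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "GmmModel",
    "ClusterSolution",
    "GmmDegenerateError",
    "fit_gmm",
    "score_samples",
    "assign_posterior",
    "loocv_score",
    "select_model",
    "summarize_runs",
    "default_lambda_grid",
]

_LOG_2PI = np.log(2.0 * np.pi)


class GmmDegenerateError(RuntimeError):
    """EM collapsed onto a degenerate component (use lambda > 0)."""


@dataclass
class GmmModel:
    """A fitted Gaussian mixture with ridge-regularized covariances."""

    weights: np.ndarray  # (K,)
    means: np.ndarray  # (K, d)
    covariances: np.ndarray  # (K, d, d)
    lam: float
    fit_seed: int
    log_likelihood_path: list[float] = field(default_factory=list)
    converged: bool = True
    n_iter: int = 0

    @property
    def n_components(self) -> int:
        return self.weights.size

    @property
    def n_dims(self) -> int:
        return self.means.shape[1]


@dataclass
class ClusterSolution:
    """Outcome of the repeated LOOCV model selection for one band."""

    band: str
    k_optimal: int
    lam_optimal: float
    stability_fraction: float
    stable: bool
    runs: list[int]  # per-repeat winning K
    labels: np.ndarray | None = None  # 1-based subgroup numbers, size-descending
    posterior: np.ndarray | None = None  # (n_patients, K)
    model: GmmModel | None = None

    @property
    def subgroup_sizes(self) -> list[int] | None:
        if self.labels is None:
            return None
        return [int(np.sum(self.labels == g)) for g in range(1, self.k_optimal + 1)]


def _log_gaussian_prob(x: np.ndarray, means: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """Stacked log N(x | mean_k, cov_k): returns (K, n)."""
    K, d = means.shape
    try:
        chols = np.linalg.cholesky(covs)
    except np.linalg.LinAlgError as err:
        raise GmmDegenerateError(
            "component covariance is not positive-definite; "
            "increase the regularization lambda above 0"
        ) from err
    diff = x[None, :, :] - means[:, None, :]  # (K, n, d)
    sol = np.linalg.solve(chols, diff.transpose(0, 2, 1))  # (K, d, n)
    maha = np.einsum("kdn,kdn->kn", sol, sol)
    logdet = np.log(np.einsum("kii->ki", chols)).sum(axis=1)  # (K,)
    return -0.5 * (d * _LOG_2PI + maha) - logdet[:, None]


def _kmeanspp_centers(x: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    n = x.shape[0]
    centers = [x[rng.integers(n)]]
    for _ in range(1, K):
        d2 = np.min(((x[:, None, :] - np.asarray(centers)[None]) ** 2).sum(-1), axis=1)
        total = d2.sum()
        probs = d2 / total if total > 0 else np.full(n, 1.0 / n)
        centers.append(x[rng.choice(n, p=probs)])
    return np.asarray(centers)


def _m_step(x, resp, lam):
    n, d = x.shape
    nk = resp.sum(axis=1)  # (K,)
    safe_nk = np.maximum(nk, 1e-12)
    weights = nk / n
    means = (resp @ x) / safe_nk[:, None]
    diff = x[None, :, :] - means[:, None, :]
    covs = np.einsum("kn,kni,knj->kij", resp, diff, diff) / safe_nk[:, None, None]
    covs += lam * np.eye(d)[None]
    if lam == 0.0 and (nk < d).any():
        raise GmmDegenerateError(
            f"component responsibility mass {nk.min():.3g} below the dimension {d} "
            "with lambda=0; the covariance collapses — use lambda > 0"
        )
    return weights, means, covs


def fit_gmm(
    scores: np.ndarray,
    K: int,
    lam: float = 0.0,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> GmmModel:
    """EM fit of a K-component full-covariance mixture with ridge lambda*I.

    Initialization assigns hard responsibilities to k-means++-seeded
    centers; EM iterates to a 1e-6 absolute tolerance on the total
    log-likelihood (at most ``max_iter`` iterations).  Deterministic for a
    given seed.
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim != 2:
        raise ValueError("scores must be 2-D (n x k)")
    n, d = x.shape
    if n <= K:
        raise ValueError(f"need more rows than components (n={n}, K={K})")
    if lam < 0:
        raise ValueError("lambda must be non-negative")

    if K == 1:  # closed form: single Gaussian
        mean = x.mean(axis=0)
        cov = (x - mean).T @ (x - mean) / n + lam * np.eye(d)
        model = GmmModel(np.ones(1), mean[None], cov[None], lam, seed)
        model.log_likelihood_path = [float(score_samples(model, x).sum())]
        return model

    rng = np.random.default_rng(seed)
    centers = _kmeanspp_centers(x, K, rng)
    d2 = ((x[:, None, :] - centers[None]) ** 2).sum(-1)
    resp = np.zeros((K, n))
    resp[np.argmin(d2, axis=1), np.arange(n)] = 1.0
    weights, means, covs = _m_step(x, resp, lam)

    path: list[float] = []
    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        log_prob = _log_gaussian_prob(x, means, covs)
        with np.errstate(divide="ignore"):
            weighted = log_prob + np.log(weights)[:, None]
        log_norm = logsumexp(weighted, axis=0)
        ll = float(log_norm.sum())
        path.append(ll)
        resp = np.exp(weighted - log_norm[None, :])
        weights, means, covs = _m_step(x, resp, lam)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) < tol:
            converged = True
            break
        prev_ll = ll
    model = GmmModel(weights, means, covs, lam, seed, path, converged, it)
    return model


def score_samples(model: GmmModel, scores: np.ndarray) -> np.ndarray:
    """Per-row log density under the mixture."""
    x = np.atleast_2d(np.asarray(scores, dtype=float))
    if x.shape[1] != model.n_dims:
        raise ValueError(f"dimension mismatch: scores have {x.shape[1]}, model {model.n_dims}")
    log_prob = _log_gaussian_prob(x, model.means, model.covariances)
    with np.errstate(divide="ignore"):
        weighted = log_prob + np.log(model.weights)[:, None]
    return logsumexp(weighted, axis=0)


def assign_posterior(model: GmmModel, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior responsibilities and hard labels (argmax; ties -> lower index).

    Labels here are 0-based component indices of the model, *not* the
    renumbered subgroup labels of a :class:`ClusterSolution`.
    """
    x = np.atleast_2d(np.asarray(scores, dtype=float))
    if x.shape[1] != model.n_dims:
        raise ValueError(f"dimension mismatch: scores have {x.shape[1]}, model {model.n_dims}")
    log_prob = _log_gaussian_prob(x, model.means, model.covariances)
    with np.errstate(divide="ignore"):
        weighted = log_prob + np.log(model.weights)[:, None]
    log_norm = logsumexp(weighted, axis=0)
    posterior = np.exp(weighted - log_norm[None, :]).T  # (n, K)
    labels = np.argmax(posterior, axis=1)  # argmax takes the lower index on ties
    return labels, posterior


def _batch_m_step(x, resp, lam):
    """Weighted M-step for a batch of problems: resp is (B, K, n), x (n, d)."""
    d = x.shape[1]
    nk = resp.sum(axis=2)  # (B, K)
    safe_nk = np.maximum(nk, 1e-12)
    weights = nk / np.maximum(nk.sum(axis=1, keepdims=True), 1e-12)
    means = np.einsum("bkn,nd->bkd", resp, x) / safe_nk[..., None]
    diff = x[None, None, :, :] - means[:, :, None, :]  # (B, K, n, d)
    covs = np.einsum("bkn,bknd,bkne->bkde", resp, diff, diff) / safe_nk[..., None, None]
    covs = covs + lam[:, None, None, None] * np.eye(d)[None, None]
    degenerate = (lam == 0.0) & (nk < d).any(axis=1)  # (B,)
    return weights, means, covs, degenerate


def _batch_cholesky(covs):
    """Stacked cholesky with per-problem failure isolation.

    Returns (chols, failed) where failed problems get identity factors so
    the batch can proceed (their results are discarded by the caller).
    """
    try:
        return np.linalg.cholesky(covs), np.zeros(covs.shape[0], dtype=bool)
    except np.linalg.LinAlgError:
        B, K, d, _ = covs.shape
        chols = np.empty_like(covs)
        failed = np.zeros(B, dtype=bool)
        for b in range(B):
            try:
                chols[b] = np.linalg.cholesky(covs[b])
            except np.linalg.LinAlgError:
                chols[b] = np.eye(d)[None]
                failed[b] = True
        return chols, failed


def _batch_log_prob(x, means, chols):
    """Stacked log N(x | mean_bk, cov_bk): returns (B, K, n)."""
    d = x.shape[1]
    diff = x[None, None, :, :] - means[:, :, None, :]  # (B, K, n, d)
    sol = np.linalg.solve(chols, diff.transpose(0, 1, 3, 2))  # (B, K, d, n)
    maha = np.einsum("bkdn,bkdn->bkn", sol, sol)
    logdet = np.log(np.einsum("bkii->bki", chols)).sum(axis=2)  # (B, K)
    return -0.5 * (d * _LOG_2PI + maha) - logdet[:, :, None]


def _loocv_scores_batch(
    x: np.ndarray,
    K: int,
    lam_values: Sequence[float],
    repeat_seeds: Sequence[int],
    tol: float = 1e-6,
    max_iter: int = 500,
    n_restarts: int = 1,
) -> np.ndarray:
    """Held-out LOOCV log-likelihoods for a (repeat x lambda) grid at one K.

    Runs every (repeat, lambda, restart, fold) EM fit as one batched
    computation (held-out rows enter with sample weight zero, exactly
    reproducing a fit on the remaining rows).  Initialization per
    (repeat, fold) replicates the single-problem path: hard assignment to
    k-means++ centers seeded by the repeat seed on the fold's training
    rows; additional restarts draw fresh centers and the best restart by
    final training log-likelihood supplies the held-out score.  Converged
    problems retire from the batch individually; degenerate problems score
    -inf.  Returns an array of shape (n_repeats, n_lambdas).
    """
    x = np.asarray(x, dtype=float)
    n, d = x.shape
    L, R, J = len(lam_values), len(repeat_seeds), int(n_restarts)
    lam_values = np.asarray(lam_values, dtype=float)

    if K == 1:  # closed form per fold; independent of the repeat seed
        held = np.empty((L, n))
        mask = np.ones(n, dtype=bool)
        for i in range(n):
            mask[i] = False
            xm = x[mask]
            mean = xm.mean(axis=0)
            base_cov = (xm - mean).T @ (xm - mean) / (n - 1)
            for li, lam in enumerate(lam_values):
                model = GmmModel(np.ones(1), mean[None], (base_cov + lam * np.eye(d))[None], lam, 0)
                held[li, i] = score_samples(model, x[i : i + 1])[0]
            mask[i] = True
        return np.broadcast_to(held.mean(axis=1)[None, :], (R, L)).copy()

    # initial responsibilities per (repeat, restart, fold); shared across
    # lambdas.  Restart 0 uses the plain repeat seed so a single-restart
    # run reproduces the fold-by-fold fit_gmm loop exactly.
    init_resp = np.empty((R, J, n, K, n))
    mask = np.ones(n, dtype=bool)
    for r, seed in enumerate(repeat_seeds):
        for j in range(J):
            for i in range(n):
                rng = np.random.default_rng(int(seed) if j == 0 else (int(seed), j))
                mask[i] = False
                centers = _kmeanspp_centers(x[mask], K, rng)
                mask[i] = True
                d2 = ((x[:, None, :] - centers[None]) ** 2).sum(-1)
                resp = np.zeros((K, n))
                resp[np.argmin(d2, axis=1), np.arange(n)] = 1.0
                init_resp[r, j, i] = resp

    # batch layout: b = ((r * L + l) * J + j) * n + fold
    B = R * L * J * n
    resp = np.broadcast_to(init_resp[:, None], (R, L, J, n, K, n)).reshape(B, K, n).copy()
    w_b = np.ones((R, L, J, n, n))
    w_b[:, :, :, np.arange(n), np.arange(n)] = 0.0  # held-out row has weight 0
    w_b = w_b.reshape(B, n)
    resp *= w_b[:, None, :]
    lam_b = np.broadcast_to(lam_values[None, :, None, None], (R, L, J, n)).reshape(B).copy()

    held_out = np.full(B, -np.inf)
    train_ll = np.full(B, -np.inf)
    final: dict[int, tuple] = {}
    weights, means, covs, degen = _batch_m_step(x, resp, lam_b)
    active = np.arange(B)
    prev_ll = np.full(B, -np.inf)

    def compact(drop, save_mask):
        """Retire problems: save params for ``save_mask``, drop the rest silently."""
        nonlocal active, weights, means, covs, lam_b, w_b, prev_ll
        for j in np.flatnonzero(save_mask):
            final[int(active[j])] = (weights[j], means[j], covs[j])
            train_ll[int(active[j])] = prev_ll[j]
        keep = ~drop
        active, lam_b, w_b, prev_ll = active[keep], lam_b[keep], w_b[keep], prev_ll[keep]
        weights, means, covs = weights[keep], means[keep], covs[keep]

    if degen.any():
        compact(degen, np.zeros_like(degen))  # degenerate at init: stays -inf

    for _ in range(max_iter):
        if active.size == 0:
            break
        chols, failed = _batch_cholesky(covs)
        log_prob = _batch_log_prob(x, means, chols)
        with np.errstate(divide="ignore"):
            weighted = log_prob + np.log(np.maximum(weights, 1e-300))[:, :, None]
        log_norm = logsumexp(weighted, axis=1)  # (B', n)
        ll = (log_norm * w_b).sum(axis=1)
        resp = np.exp(weighted - log_norm[:, None, :]) * w_b[:, None, :]
        new_w, new_m, new_c, degen = _batch_m_step(x, resp, lam_b)
        weights, means, covs = new_w, new_m, new_c  # post-M-step params, as in fit_gmm
        done = (np.abs(ll - prev_ll) < tol) & np.isfinite(ll)
        prev_ll = ll
        drop = done | failed | degen
        if drop.any():
            compact(drop, done & ~(failed | degen))

    for j in range(active.size):  # max_iter reached: use current params
        final[int(active[j])] = (weights[j], means[j], covs[j])
        train_ll[int(active[j])] = prev_ll[j]

    for b, (wt, mu, cv) in final.items():
        model = GmmModel(wt, mu, cv, 0.0, 0)
        i = b % n
        try:
            held_out[b] = score_samples(model, x[i : i + 1])[0]
        except (GmmDegenerateError, np.linalg.LinAlgError):
            held_out[b] = -np.inf

    held = held_out.reshape(R, L, J, n)
    if J > 1:  # best restart per fold, judged by final training likelihood
        best = np.argmax(train_ll.reshape(R, L, J, n), axis=2)
        held = np.take_along_axis(held, best[:, :, None, :], axis=2)[:, :, 0, :]
    else:
        held = held[:, :, 0, :]
    return held.mean(axis=2)


def loocv_score(scores: np.ndarray, K: int, lam: float, seed: int = 0) -> float:
    """Mean held-out log-likelihood over leave-one-out folds.

    Each row is held out once; the mixture is refitted on the remaining
    rows (same init seed per fold) and the held-out log density recorded.
    A fold whose fit degenerates contributes -inf, so fragile (K, lambda)
    pairs lose the model selection instead of crashing it.  Internally the
    folds run as one batched EM; the result matches an explicit
    fold-by-fold loop over :func:`fit_gmm`.
    """
    x = np.asarray(scores, dtype=float)
    n = x.shape[0]
    if n < K + 2:
        raise ValueError(f"need at least K+2 rows for LOOCV (n={n}, K={K})")
    return float(_loocv_scores_batch(x, K, [lam], [seed])[0, 0])


def default_lambda_grid(scores: np.ndarray) -> np.ndarray:
    """{1e-5, 1e-4, 1e-3, 1e-2} x mean per-dimension variance of the scores.

    The reference scale is the *total* per-dimension variance, which for
    clustered data includes the between-cluster separation; the grid
    therefore stays well below it.  A ridge of order 10% of the total
    variance is large enough to let over-clustered solutions imitate (and
    beat) the true components on held-out likelihood, so the grid stops at
    1%.
    """
    base = float(np.asarray(scores, dtype=float).var(axis=0).mean())
    return base * np.array([1e-5, 1e-4, 1e-3, 1e-2])


def summarize_runs(runs: Sequence[int], stability_threshold: float = 0.9) -> tuple[int, float, bool]:
    """Modal K, its frequency among the runs, and the stability verdict."""
    runs = list(runs)
    if not runs:
        raise ValueError("no runs to summarize")
    values, counts = np.unique(runs, return_counts=True)
    modal_k = int(values[np.argmax(counts)])  # ties -> smaller K (values ascend)
    fraction = float(counts.max() / len(runs))
    return modal_k, fraction, fraction >= stability_threshold


def select_model(
    scores: np.ndarray,
    K_grid: Sequence[int] = tuple(range(1, 9)),
    lam_grid: Sequence[float] | None = None,
    n_repeats: int = 50,
    stability_threshold: float = 0.9,
    seed: int = 0,
    band: str = "",
    n_restarts: int = 1,
) -> ClusterSolution:
    """Repeated LOOCV selection of (K, lambda) with the 90% stability gate.

    Per repeat r (seeded ``seed + r``) the LOOCV held-out log-likelihood is
    computed for every (K, lambda) on the grid — each individual fit taking
    the best of ``n_restarts`` EM initializations by training likelihood,
    so that repeat-to-repeat disagreement reflects the data rather than
    local optima — and the winning K recorded (ties -> smaller K, then
    larger lambda).  The modal K must win at least
    ``stability_threshold`` of the repeats; only then is the mixture
    refitted on all rows at (modal K, modal winning lambda) and labels /
    posteriors emitted.  An unstable outcome carries no labels.
    """
    x = np.asarray(scores, dtype=float)
    K_grid = sorted(set(int(k) for k in K_grid))
    if not K_grid:
        raise ValueError("K_grid is empty")
    if lam_grid is None:
        lam_grid = default_lambda_grid(x)
    lam_grid = sorted(float(l) for l in lam_grid)
    if not lam_grid:
        raise ValueError("lam_grid is empty")

    repeat_seeds = [int(seed + r) for r in range(n_repeats)]
    grid_scores = {
        K: _loocv_scores_batch(x, K, lam_grid, repeat_seeds, n_restarts=n_restarts)
        for K in K_grid
    }  # each (n_repeats, n_lambdas)
    runs: list[int] = []
    best_lams: list[float] = []
    for r in range(n_repeats):
        best = (-np.inf, None, None)
        for K in K_grid:
            row = grid_scores[K][r]
            for li in range(len(lam_grid) - 1, -1, -1):  # larger lambda first: wins exact ties
                if row[li] > best[0]:
                    best = (float(row[li]), K, lam_grid[li])
        runs.append(int(best[1]))
        best_lams.append(float(best[2]))

    k_modal, fraction, stable = summarize_runs(runs, stability_threshold)
    lam_candidates = [l for k, l in zip(runs, best_lams) if k == k_modal]
    values, counts = np.unique(lam_candidates, return_counts=True)
    # modal winning lambda among modal-K repeats; ties -> larger lambda
    order = np.lexsort((-values, -counts))
    lam_optimal = float(values[order[0]])

    if not stable:
        return ClusterSolution(band, k_modal, lam_optimal, fraction, False, runs)

    candidates = [fit_gmm(x, k_modal, lam_optimal, seed=int(seed) + 104729 * j)
                  for j in range(max(1, n_restarts))]
    model = max(candidates, key=lambda m: m.log_likelihood_path[-1])
    raw_labels, posterior = assign_posterior(model, x)
    labels, posterior, model = _renumber(raw_labels, posterior, model, x)
    return ClusterSolution(band, k_modal, lam_optimal, fraction, True, runs, labels, posterior, model)


def _renumber(raw_labels, posterior, model, x):
    """Renumber components size-descending (ties: lower mean on PC1 first)."""
    K = model.n_components
    sizes = np.array([(raw_labels == k).sum() for k in range(K)])
    pc1_means = np.array(
        [x[raw_labels == k, 0].mean() if sizes[k] else np.inf for k in range(K)]
    )
    order = np.lexsort((pc1_means, -sizes))
    labels = np.empty_like(raw_labels)
    for new, old in enumerate(order):
        labels[raw_labels == old] = new + 1  # 1-based subgroup numbers
    reordered = GmmModel(
        model.weights[order],
        model.means[order],
        model.covariances[order],
        model.lam,
        model.fit_seed,
        model.log_likelihood_path,
        model.converged,
        model.n_iter,
    )
    return labels, posterior[:, order], reordered
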