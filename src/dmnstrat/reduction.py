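"""Per-band PCA with AIC-based choice of the component count.

The 15 PLI features per band are reduced by a mean-centered PCA fitted on
the *entire* cohort (patients and controls together); only the patient
rows' scores are later clustered.  The component count k is chosen by
minimizing an AIC built on the probabilistic-PCA (PPCA) likelihood: for
rank k with isotropic residual variance, the maximized log-likelihood has
the closed form

    LL(k) = -n/2 * [ d ln(2 pi) + sum_{i<=k} ln l_i + (d-k) ln s2_k + d ]

where l_i are the sample-covariance eigenvalues (descending) and
s2_k = mean(l_{k+1..d}) is the ML residual variance, and the free-parameter
count is  d*k - k(k-1)/2 + 1 + d  (loadings modulo rotation, the residual
variance, and the mean).  AIC(k) = -2 LL(k) + 2 * n_params(k).

By default the small-sample–corrected criterion (AICc) is used:
AICc = AIC + 2 p (p + 1) / (n - p - 1).  With 15 features the parameter
count approaches the cohort size (p(k=14) = 135 vs n = 134), where the
uncorrected AIC is ill-posed; the correction also suppresses the
well-known tendency of plain AIC to over-select the rank.  Ranks whose
parameter count leaves no residual degrees of freedom are excluded.

Because clustering n samples supports at most log2(n) variables (the
2^d-samples rule of thumb for mixture models), ``formann_max_dims`` caps
the number of scores handed to the clustering stage (5 for n = 37).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PcaModel",
    "fit_pca",
    "aic_select_components",
    "ppca_log_likelihood",
    "project",
    "reconstruct",
    "formann_max_dims",
]


def formann_max_dims(n_samples: int) -> int:
    """Largest d with 2**d <= n_samples (sample-size rule for clustering)."""
    if n_samples < 2:
        return 0
    return int(np.floor(np.log2(n_samples)))


@dataclass
class PcaModel:
    """A fitted full-rank PCA with its AIC model-selection curve.

    ``loadings`` columns are the orthonormal principal axes ordered by
    decreasing explained variance; ``aic_curve[k-1]`` is the AIC of the
    rank-k PPCA model and ``k_selected`` its argmin (smallest k on ties).
    """

    mean: np.ndarray
    loadings: np.ndarray  # (n_features, rank)
    explained_variance: np.ndarray
    k_selected: int
    aic_curve: np.ndarray
    band: str = ""
    n_samples: int = 0
    standardized: bool = False
    scale: np.ndarray | None = None

    @property
    def rank(self) -> int:
        return self.loadings.shape[1]


def _center(features: np.ndarray, standardize: bool):
    x = np.asarray(features, dtype=float)
    if x.ndim != 2:
        raise ValueError("features must be a 2-D matrix (participants x features)")
    variances = x.var(axis=0)
    dead = np.flatnonzero(np.ptp(x, axis=0) == 0)
    if dead.size:
        raise ValueError(f"zero-variance feature column(s) {dead.tolist()}; PCA is rank-deficient")
    mean = x.mean(axis=0)
    scale = np.sqrt(variances) if standardize else None
    xc = (x - mean) / scale if standardize else x - mean
    return xc, mean, scale


def ppca_log_likelihood(eigenvalues: np.ndarray, n: int, k: int) -> float:
    """Maximized PPCA log-likelihood at rank ``k`` from ML covariance eigenvalues."""
    l = np.asarray(eigenvalues, dtype=float)
    d = l.size
    if not 0 < k < d:
        raise ValueError(f"need 0 < k < n_features, got k={k}, d={d}")
    s2 = l[k:].mean()
    if s2 <= 0:
        raise ValueError(f"residual variance is zero at rank {k}; likelihood unbounded")
    return float(-0.5 * n * (d * np.log(2 * np.pi) + np.log(l[:k]).sum() + (d - k) * np.log(s2) + d))


def ppca_n_params(d: int, k: int) -> int:
    """Free parameters of the rank-k PPCA: loadings mod rotation + noise + mean."""
    return d * k - k * (k - 1) // 2 + 1 + d


def aic_select_components(
    features: np.ndarray,
    k_max: int | None = None,
    standardize: bool = False,
    small_sample_correction: bool = True,
) -> tuple[int, np.ndarray]:
    """Scan candidate ranks 1..k_max and return (argmin-AIC rank, AIC curve).

    ``k_max`` defaults to d-1 and is reduced (with a warning) when the
    sample size cannot support the requested rank (the PPCA residual
    variance needs at least one strictly positive discarded eigenvalue).
    With ``small_sample_correction`` (the default) the AICc form is used
    and ranks with ``n - n_params - 1 <= 0`` receive an infinite score.
    """
    xc, _, _ = _center(features, standardize)
    n, d = xc.shape
    if k_max is None:
        k_max = d - 1
    if not 1 <= k_max < d:
        raise ValueError(f"k_max must satisfy 1 <= k_max < {d}, got {k_max}")
    # ML covariance spectrum; rank limited by n-1 centered samples
    l = np.linalg.eigvalsh(xc.T @ xc / n)[::-1]
    l = np.clip(l, 0.0, None)
    supported = max(1, min(k_max, min(n - 1, d) - 1))
    if supported < k_max:
        warnings.warn(
            f"k_max reduced from {k_max} to {supported}: only {n} samples", stacklevel=2
        )
        k_max = supported
    aic = np.empty(k_max)
    for k in range(1, k_max + 1):
        p = ppca_n_params(d, k)
        value = -2.0 * ppca_log_likelihood(l, n, k) + 2.0 * p
        if small_sample_correction:
            value = value + 2.0 * p * (p + 1) / (n - p - 1) if n - p - 1 > 0 else np.inf
        aic[k - 1] = value
    if not np.isfinite(aic).any():
        raise ValueError(f"no candidate rank is supported by {n} samples")
    k_selected = int(np.argmin(aic)) + 1  # argmin takes the first (smallest k) on ties
    return k_selected, aic


def fit_pca(
    features: np.ndarray,
    band: str = "",
    k_max: int | None = None,
    standardize: bool = False,
    min_ratio: float = 5.0,
) -> PcaModel:
    """Fit a full-rank mean-centered PCA and select k by the PPCA AIC.

    Warns when the sample count is below ``min_ratio`` times the feature
    count (the usual sample-size rule of thumb for PCA).
    """
    xc, mean, scale = _center(features, standardize)
    n, d = xc.shape
    if n < d:
        raise ValueError(f"need at least {d} rows to fit a full-rank PCA, got {n}")
    if n < min_ratio * d:
        warnings.warn(
            f"sample size {n} is below {min_ratio}x the {d} features; "
            "PCA loadings may be unstable",
            stacklevel=2,
        )
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    explained = s**2 / n
    if d == 1:  # single feature: nothing to select
        k_selected, aic = 1, np.empty(0)
    else:
        k_selected, aic = aic_select_components(
            features, k_max=min(k_max, d - 1) if k_max is not None else None,
            standardize=standardize,
        )
    return PcaModel(
        mean=mean,
        loadings=vt.T,
        explained_variance=explained,
        k_selected=k_selected,
        aic_curve=aic,
        band=band,
        n_samples=n,
        standardized=standardize,
        scale=scale,
    )


def project(model: PcaModel, features: np.ndarray, k: int | None = None) -> np.ndarray:
    """Centered projection of ``features`` onto the first ``k`` loadings."""
    if k is None:
        k = model.k_selected
    if not 1 <= k <= model.rank:
        raise ValueError(f"k={k} exceeds the fitted rank {model.rank}")
    x = np.asarray(features, dtype=float)
    if x.shape[-1] != model.mean.size:
        raise ValueError(
            f"feature dimension {x.shape[-1]} does not match the model ({model.mean.size})"
        )
    xc = x - model.mean
    if model.standardized:
        xc = xc / model.scale
    return xc @ model.loadings[:, :k]


def reconstruct(model: PcaModel, scores: np.ndarray) -> np.ndarray:
    """Map score rows back to feature space (inverse of :func:`project`)."""
    scores = np.asarray(scores, dtype=float)
    k = scores.shape[-1]
    x = scores @ model.loadings[:, :k].T
    if model.standardized:
        x = x * model.scale
    return x + model.mean
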