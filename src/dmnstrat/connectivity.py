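"""Phase-lag-index (PLI) connectivity features for ROI-level EEG.

The functional-connectivity substrate of the whole pipeline: each
participant's six default-mode-network (DMN) region time series are
band-pass filtered into the canonical delta/theta/alpha/beta bands,
cut into fixed-length epochs, and the epoch-averaged PLI is computed
for every region pair.  The PLI between two narrowband signals is

    PLI = | < sign( sin(phi_i(t) - phi_j(t)) ) >_t |

where ``phi`` is the instantaneous (analytic-signal) phase.  A PLI of 0
means no consistently lagged coupling, 1 means a perfectly consistent
nonzero lag.  Because zero-lag phase differences contribute sign(0)=0,
the index is insensitive to instantaneously mixed (volume-conducted)
common sources.

Also provided is ``pca_flip_aggregate``, the standard utility that
collapses many within-ROI source signals into a single representative
series (first principal component, sign-anchored to the mean signal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

__all__ = [
    "DMN_ROIS",
    "BandDefinition",
    "BANDS",
    "RoiRecording",
    "EpochArray",
    "ConnectivityFeatures",
    "pair_indices",
    "pair_names",
    "matrix_to_vector",
    "vector_to_matrix",
    "pca_flip_aggregate",
    "bandpass",
    "epoch",
    "instantaneous_phase",
    "pli_pair",
    "pli_matrix",
]

#: Canonical DMN ROI order: left lateral parietal, left medial prefrontal,
#: left precuneus, then the right-hemisphere homologues.  Pair enumeration
#: is row-major over the strict upper triangle of this order, so feature
#: columns line up with the usual "L LP vs L MPFC, L LP vs L PCC, ..." layout.
DMN_ROIS: tuple[str, ...] = ("LP_L", "MPFC_L", "PCC_L", "LP_R", "MPFC_R", "PCC_R")


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with edges in Hz."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError(
                f"band {self.name!r}: need 0 < low_hz < high_hz, "
                f"got ({self.low_hz}, {self.high_hz})"
            )


#: Canonical analysis bands.  Gamma is deliberately absent: EEG gamma is too
#: easily contaminated by scalp-muscle activity to be trusted in this design.
BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", 1.5, 4.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 12.0),
    "beta": BandDefinition("beta", 12.0, 30.0),
}


@dataclass
class RoiRecording:
    """One participant's multichannel ROI time series.

    Parameters
    ----------
    series
        Real array of shape ``(n_samples, n_rois)``.
    sampling_rate
        Sampling frequency in Hz.
    roi_order
        ROI names, one per column of ``series``.
    participant_id
        Identifier carried through to feature tables.
    """

    series: np.ndarray
    sampling_rate: float
    roi_order: tuple[str, ...] = DMN_ROIS
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 2:
            raise ValueError("series must be 2-D (n_samples, n_rois)")
        if not np.isfinite(self.series).all():
            raise ValueError("series contains NaN or infinite values")
        self.roi_order = tuple(self.roi_order)
        if len(self.roi_order) != self.series.shape[1]:
            raise ValueError(
                f"roi_order has {len(self.roi_order)} names but series has "
                f"{self.series.shape[1]} columns"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.series.shape[0]

    @property
    def n_rois(self) -> int:
        return self.series.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class EpochArray:
    """Consecutive, non-overlapping epochs cut from the start of a recording."""

    epochs: np.ndarray  # (n_epochs, n_samples_per_epoch, n_rois)
    epoch_length_s: float
    sampling_rate: float
    roi_order: tuple[str, ...] = DMN_ROIS
    participant_id: str = ""

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_samples_per_epoch(self) -> int:
        return self.epochs.shape[1]


def pair_indices(n_rois: int) -> list[tuple[int, int]]:
    """Row-major strict upper-triangle pair order: (0,1), (0,2), ..."""
    return [(i, j) for i in range(n_rois) for j in range(i + 1, n_rois)]


def pair_names(roi_order: tuple[str, ...] = DMN_ROIS, sep: str = "--") -> list[str]:
    """Feature-column names ``"<ROI_i><sep><ROI_j>"`` in canonical pair order."""
    return [f"{roi_order[i]}{sep}{roi_order[j]}" for i, j in pair_indices(len(roi_order))]


def matrix_to_vector(matrix: np.ndarray) -> np.ndarray:
    """Flatten a symmetric connectivity matrix to its strict upper triangle."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("connectivity matrix must be square")
    iu = np.triu_indices(matrix.shape[0], k=1)
    return matrix[iu]


def vector_to_matrix(vector: np.ndarray) -> np.ndarray:
    """Inverse of :func:`matrix_to_vector`; zero diagonal, symmetric output."""
    vector = np.asarray(vector, dtype=float)
    m = vector.size
    n = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
    if n * (n - 1) // 2 != m:
        raise ValueError(f"vector length {m} is not a triangular number")
    out = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    out[iu] = vector
    return out + out.T


@dataclass
class ConnectivityFeatures:
    """Per-band epoch-averaged PLI for one participant.

    ``matrix`` is the symmetric ``n_rois x n_rois`` PLI matrix with zero
    diagonal; ``vector`` is its strict upper triangle in canonical pair
    order (length ``n_rois*(n_rois-1)/2``, i.e. 15 for the 6-ROI DMN set).
    """

    band: BandDefinition
    matrix: np.ndarray
    participant_id: str = ""
    roi_order: tuple[str, ...] = DMN_ROIS

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ValueError("matrix must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("PLI matrix must be symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("PLI matrix must have zero diagonal")
        if self.matrix.min() < -1e-12 or self.matrix.max() > 1 + 1e-12:
            raise ValueError("PLI values must lie in [0, 1]")

    @property
    def vector(self) -> np.ndarray:
        return matrix_to_vector(self.matrix)

    @property
    def feature_names(self) -> list[str]:
        return pair_names(self.roi_order)


def pca_flip_aggregate(vertex_signals: np.ndarray) -> np.ndarray:
    """Collapse within-ROI vertex signals to one representative series.

    Returns the first principal-component score series of the (internally
    mean-centered) vertex signals.  The sign is fixed so the output
    correlates non-negatively with the across-vertex mean signal; if that
    correlation is exactly zero (e.g. two vertices carrying ``s`` and
    ``-s``), the largest-magnitude loading is made positive instead.
    """
    x = np.asarray(vertex_signals, dtype=float)
    if x.ndim != 2:
        raise ValueError("vertex_signals must be 2-D (n_samples, n_vertices)")
    n_samples, n_vertices = x.shape
    if n_samples < 2 or n_vertices < 2:
        raise ValueError("need at least 2 samples and 2 vertices")
    xc = x - x.mean(axis=0, keepdims=True)
    if not np.any(xc):
        raise ValueError("vertex signals are constant; principal component undefined")
    # economical SVD: scores of the first right-singular direction
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    scores = u[:, 0] * s[0]
    loading = vt[0]
    mean_signal = xc.mean(axis=1)
    corr = float(scores @ mean_signal)
    if corr < 0:
        scores, loading = -scores, -loading
    elif corr == 0 and loading[np.argmax(np.abs(loading))] < 0:
        scores = -scores
    return scores


def _design_bandpass(band: BandDefinition, sampling_rate: float, order: int = 8) -> np.ndarray:
    nyq = sampling_rate / 2.0
    if band.high_hz >= nyq:
        raise ValueError(
            f"band {band.name!r} upper edge {band.high_hz} Hz requires a sampling "
            f"rate above {2 * band.high_hz} Hz (got {sampling_rate} Hz)"
        )
    return sp_signal.butter(
        order, [band.low_hz, band.high_hz], btype="bandpass", fs=sampling_rate, output="sos"
    )


def bandpass_array(series: np.ndarray, sampling_rate: float, band: BandDefinition, order: int = 8) -> np.ndarray:
    """Zero-phase Butterworth band-pass along axis 0 (length preserved)."""
    sos = _design_bandpass(band, sampling_rate, order)
    return sp_signal.sosfiltfilt(sos, np.asarray(series, dtype=float), axis=0)


def bandpass(recording: RoiRecording, band: BandDefinition, order: int = 8) -> RoiRecording:
    """Band-pass every ROI channel of a recording (zero-phase, forward-backward).

    The filter is an order-``order``-per-edge Butterworth applied forward and
    backward, which preserves pass-band tone amplitude to within a few
    percent mid-band and attenuates by far more than 30 dB one octave
    outside the edges.
    """
    return RoiRecording(
        series=bandpass_array(recording.series, recording.sampling_rate, band, order),
        sampling_rate=recording.sampling_rate,
        roi_order=recording.roi_order,
        participant_id=recording.participant_id,
    )


def epoch(recording: RoiRecording, epoch_length_s: float = 8.0, n_epochs: int = 40) -> EpochArray:
    """Cut the first ``n_epochs`` consecutive non-overlapping epochs.

    Epoching always starts at sample 0 and trailing samples are discarded;
    every participant therefore contributes the same amount of data to the
    PLI estimate, which keeps the estimator bias comparable across
    participants.
    """
    spe = epoch_length_s * recording.sampling_rate
    n_per = int(round(spe))
    if abs(spe - n_per) > 1e-9:
        raise ValueError("epoch_length_s x sampling_rate must be an integer sample count")
    needed = n_per * n_epochs
    if recording.n_samples < needed:
        raise ValueError(
            f"recording too short for {n_epochs} epochs of {epoch_length_s} s: "
            f"requires {needed} samples, got {recording.n_samples}"
        )
    cut = recording.series[:needed].reshape(n_epochs, n_per, recording.n_rois)
    return EpochArray(
        epochs=cut,
        epoch_length_s=epoch_length_s,
        sampling_rate=recording.sampling_rate,
        roi_order=recording.roi_order,
        participant_id=recording.participant_id,
    )


def instantaneous_phase(epochs: np.ndarray | EpochArray) -> np.ndarray:
    """Analytic-signal phase, computed per epoch independently.

    Accepts either an :class:`EpochArray` or a raw array whose first axis is
    the epoch axis and second axis is time.  Returns phases in (-pi, pi].
    """
    arr = epochs.epochs if isinstance(epochs, EpochArray) else np.asarray(epochs, dtype=float)
    if arr.ndim < 2:
        raise ValueError("expected at least (n_epochs, n_samples)")
    flat = np.all(arr == 0, axis=tuple(range(1, arr.ndim)))
    if np.any(flat):
        raise ValueError(f"phase undefined for all-zero epoch(s) {np.flatnonzero(flat).tolist()}")
    analytic = sp_signal.hilbert(arr, axis=1)
    return np.angle(analytic)


def pli_pair(phase_i: np.ndarray, phase_j: np.ndarray, edge_fraction: float = 0.0) -> float:
    """Epoch-averaged phase lag index between two phase series.

    ``phase_i``/``phase_j`` are ``(n_epochs, n_samples)`` (a 1-D input is
    treated as a single epoch).  Per epoch the PLI is the absolute mean of
    ``sign(sin(phase_i - phase_j))``; sign(0) contributes 0, so exactly
    zero-lag samples do not count as coupling.  The returned value is the
    plain mean of the per-epoch PLIs.  ``edge_fraction`` trims that fraction
    of samples at both ends of every epoch before averaging (analytic-signal
    phase estimates are least reliable at epoch edges).
    """
    pi_arr = np.atleast_2d(np.asarray(phase_i, dtype=float))
    pj_arr = np.atleast_2d(np.asarray(phase_j, dtype=float))
    if pi_arr.shape != pj_arr.shape:
        raise ValueError(f"phase series shapes differ: {pi_arr.shape} vs {pj_arr.shape}")
    n = pi_arr.shape[1]
    k = int(np.floor(edge_fraction * n))
    if k > 0:
        pi_arr = pi_arr[:, k : n - k]
        pj_arr = pj_arr[:, k : n - k]
    signs = np.sign(np.sin(pi_arr - pj_arr))
    per_epoch = np.abs(signs.mean(axis=1))
    return float(per_epoch.mean())


def pli_matrix(
    recording: RoiRecording,
    band: BandDefinition,
    epoch_length_s: float = 8.0,
    n_epochs: int = 40,
    edge_fraction: float = 0.05,
    filter_order: int = 8,
) -> ConnectivityFeatures:
    """Full per-band PLI pipeline: bandpass -> epoch -> phase -> pairwise PLI.

    Returns a :class:`ConnectivityFeatures` whose vector is the strict
    upper triangle in canonical pair order.
    """
    filtered = bandpass(recording, band, order=filter_order)
    epochs = epoch(filtered, epoch_length_s=epoch_length_s, n_epochs=n_epochs)
    phases = instantaneous_phase(epochs)  # (n_epochs, n_samples, n_rois)
    n_rois = recording.n_rois
    mat = np.zeros((n_rois, n_rois))
    for i, j in pair_indices(n_rois):
        v = pli_pair(phases[:, :, i], phases[:, :, j], edge_fraction=edge_fraction)
        mat[i, j] = mat[j, i] = v
    return ConnectivityFeatures(
        band=band,
        matrix=mat,
        participant_id=recording.participant_id,
        roi_order=recording.roi_order,
    )
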