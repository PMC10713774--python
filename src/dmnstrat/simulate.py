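"""Synthetic cohorts with planted phase-lag coupling and subgroup structure.

Because clinical EEG recordings of this kind cannot be shared, every stage
of the pipeline is exercised on simulated data that reproduces the
statistical structure the analysis assumes:

* band-limited coupled-oscillator ROI signals whose pairwise phase-lag
  coupling is controlled per band, per ROI pair and per cohort group
  (coupling strength ``kappa`` in [0, 1], phase lag ``delta`` in (-pi, pi));
* a planted two-subgroup partition of the patients (default sizes 19/18 in
  a 37-patient, 97-control cohort);
* clinical scores (PANSS sub-scores, five cognitive measures) whose group
  means shift with the planted subgroup label by configurable standardized
  effects.

The signal model: per band, a shared latent narrowband Gaussian process is
generated for each coupled ROI pair; ROI ``i`` receives
``kappa * latent + (1 - kappa) * independent narrowband noise`` and ROI
``j`` the same with the latent's analytic signal rotated by ``e^{i delta}``.
Expected PLI of the pair grows monotonically with ``kappa`` and stays at
the estimator's noise floor when ``kappa = 0`` or when ``delta`` is 0 or pi
(the PLI discards zero-lag coupling by construction).  All randomness
derives from a single seed; identical configurations give bit-identical
cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .connectivity import BANDS, DMN_ROIS, RoiRecording, bandpass_array, pair_names
from .group_stats import CLINICAL_VARIABLES, ClinicalTable

__all__ = [
    "PairCoupling",
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_coupled_sources",
    "simulate_feature_cohort",
    "simulate_clinical",
    "default_coupling_spec",
    "default_clinical_effects",
]

#: Cohort-group keys used in per-group coupling overrides.
GROUP_KEYS = ("sz1", "sz2", "hc")


@dataclass(frozen=True)
class PairCoupling:
    """Phase-lag coupling of one ROI pair within one band.

    ``kappa`` is either a scalar (same strength for every cohort group) or a
    mapping over group keys ``sz1``/``sz2``/``hc``; missing keys default
    to 0 (no coupling).  ``delta`` is the imposed phase lag of ``roi_j``
    relative to ``roi_i`` in radians.
    """

    roi_i: str
    roi_j: str
    delta: float = math.pi / 2
    kappa: float | Mapping[str, float] = 0.0

    def __post_init__(self) -> None:
        if not (-math.pi < self.delta < math.pi):
            raise ValueError(f"phase lag delta must lie in (-pi, pi), got {self.delta}")
        for k in self._kappas():
            if not (0.0 <= k <= 1.0):
                raise ValueError(f"coupling strength kappa must lie in [0, 1], got {k}")
        if isinstance(self.kappa, Mapping):
            unknown = set(self.kappa) - set(GROUP_KEYS)
            if unknown:
                raise ValueError(f"unknown group keys in kappa mapping: {sorted(unknown)}")

    def _kappas(self) -> list[float]:
        if isinstance(self.kappa, Mapping):
            return [float(v) for v in self.kappa.values()]
        return [float(self.kappa)]

    def kappa_for(self, group_key: str) -> float:
        if isinstance(self.kappa, Mapping):
            return float(self.kappa.get(group_key, 0.0))
        return float(self.kappa)


def default_coupling_spec() -> dict[str, tuple[PairCoupling, ...]]:
    """The default planted structure, mirroring the qualitative band outcome.

    Theta and beta carry a two-subgroup split (subgroup 1 hyper-coupled and
    subgroup 2 hypo-coupled relative to controls on a handful of pairs, with
    one pair reversed per band, so the subgroups differ in the coupling
    *pattern*, not just the overall level); delta and alpha have
    group-independent coupling only, so clustering should find no subgroups
    there.  The kappa gap is calibrated so the planted subgroups sit a few
    SDs apart in the PCA score space the clustering actually sees, after
    the per-participant coupling-variability factor has contributed the
    dominant (subgroup-independent) variance axis — a recoverable but not
    degenerate regime; the strengths are illustrative, not fitted to any
    real cohort.
    """
    split = {"sz1": 0.38, "sz2": 0.22, "hc": 0.30}
    reversed_split = {"sz1": 0.22, "sz2": 0.38, "hc": 0.30}
    q = math.pi / 2
    return {
        "delta": (PairCoupling("LP_L", "MPFC_L", q, 0.30),),
        "theta": (
            PairCoupling("LP_L", "PCC_L", q, split),
            PairCoupling("LP_L", "PCC_R", q, split),
            PairCoupling("LP_R", "MPFC_R", q, reversed_split),
        ),
        "alpha": (PairCoupling("PCC_L", "PCC_R", q, 0.30),),
        "beta": (
            PairCoupling("LP_L", "PCC_L", q, split),
            PairCoupling("MPFC_L", "PCC_L", q, split),
            PairCoupling("PCC_L", "MPFC_R", q, split),
            PairCoupling("MPFC_R", "PCC_R", q, reversed_split),
        ),
    }


def default_clinical_effects() -> dict[str, float]:
    """Standardized subgroup-1 minus subgroup-2 mean differences.

    Directions follow the planted narrative: subgroup 1 shows more negative
    and fewer positive symptoms; subgroup 2 is slower, makes more
    set-shifting errors, but has higher verbal IQ.  Magnitudes are
    illustrative.
    """
    return {
        "panss_neg": 1.0,
        "panss_pos": -0.5,
        "panss_gen": 0.4,
        "verbal_iq": -0.4,
        "mental_flexibility": -0.8,
        "reaction_time": -0.6,
    }


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort generator (defaults = study design)."""

    n_patients: int = 37
    n_controls: int = 97
    subgroup_sizes: tuple[int, ...] = (19, 18)
    n_rois: int = 6
    roi_order: tuple[str, ...] = DMN_ROIS
    sampling_rate: float = 256.0
    duration: float = 336.0
    epoch_length_s: float = 8.0
    n_epochs: int = 40
    bands: tuple[str, ...] = tuple(BANDS)
    coupling_spec: dict[str, tuple[PairCoupling, ...]] = field(default_factory=default_coupling_spec)
    coupling_variability: float = 0.02
    coupling_jitter: float = 0.03
    noise_sd: float = 1.0
    clinical_effects: dict[str, float] = field(default_factory=default_clinical_effects)
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.subgroup_sizes) != self.n_patients:
            raise ValueError(
                f"subgroup_sizes {self.subgroup_sizes} must sum to n_patients {self.n_patients}"
            )
        self.roi_order = tuple(self.roi_order)[: self.n_rois]
        if len(self.roi_order) != self.n_rois:
            raise ValueError("roi_order must provide a name for every ROI")
        self.bands = tuple(self.bands)
        for b in self.bands:
            if b not in BANDS:
                raise ValueError(f"unknown band {b!r} in bands")
        for band_name, couplings in self.coupling_spec.items():
            if band_name not in BANDS:
                raise ValueError(f"unknown band {band_name!r} in coupling_spec")
            if band_name not in self.bands:
                continue
            for c in couplings:
                for roi in (c.roi_i, c.roi_j):
                    if roi not in self.roi_order:
                        raise ValueError(f"coupling references unknown ROI {roi!r}")
        for var in self.clinical_effects:
            if var not in CLINICAL_VARIABLES:
                raise ValueError(f"unknown clinical variable {var!r} in clinical_effects")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    @property
    def min_duration(self) -> float:
        return self.n_epochs * self.epoch_length_s

    def group_key(self, index: int) -> str:
        """Cohort-group key for participant ``index`` (patients first)."""
        if index >= self.n_patients:
            return "hc"
        edge = 0
        for g, size in enumerate(self.subgroup_sizes, start=1):
            edge += size
            if index < edge:
                return f"sz{g}"
        raise IndexError(index)


@dataclass
class SyntheticCohort:
    """A fully simulated cohort: signals, group labels, truth, clinical table."""

    recordings: list[RoiRecording]
    group_labels: dict[str, str]  # participant_id -> "patient" | "control"
    true_subgroup: dict[str, int | None]  # None for controls
    clinical: ClinicalTable
    config: SimulationConfig

    @property
    def participant_ids(self) -> list[str]:
        return [r.participant_id for r in self.recordings]

    @property
    def patient_ids(self) -> list[str]:
        return [p for p, g in self.group_labels.items() if g == "patient"]

    @property
    def control_ids(self) -> list[str]:
        return [p for p, g in self.group_labels.items() if g == "control"]


def _narrowband(rng: np.random.Generator, n: int, fs: float, band) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise."""
    x = bandpass_array(rng.standard_normal(n), fs, band)
    sd = x.std()
    return x / sd if sd > 0 else x


def _rotate_phase(x: np.ndarray, delta: float) -> np.ndarray:
    """Advance the instantaneous phase of a narrowband signal by ``delta``."""
    return np.real(sp_signal.hilbert(x) * np.exp(1j * delta))


def _participant_signal(
    rng: np.random.Generator, config: SimulationConfig, group_key: str
) -> np.ndarray:
    n, fs = config.n_samples, config.sampling_rate
    roi_index = {name: k for k, name in enumerate(config.roi_order)}
    out = np.zeros((n, config.n_rois))
    # inter-individual variability, additive on the kappa scale: a shared
    # offset (globally more- or less-synchronized individuals — the dominant
    # subgroup-independent covariance axis of real connectivity data) plus
    # independent per-connection jitter
    global_offset = config.coupling_variability * rng.standard_normal()
    for band in (BANDS[b] for b in config.bands):
        component = np.zeros((n, config.n_rois))
        touched = np.zeros(config.n_rois, dtype=bool)
        for coupling in config.coupling_spec.get(band.name, ()):
            kappa = coupling.kappa_for(group_key)
            if kappa > 0:
                kappa += global_offset + config.coupling_jitter * rng.standard_normal()
            kappa = float(np.clip(kappa, 0.0, 1.0))
            latent = _narrowband(rng, n, fs, band)
            i, j = roi_index[coupling.roi_i], roi_index[coupling.roi_j]
            component[:, i] += kappa * latent + (1 - kappa) * _narrowband(rng, n, fs, band)
            component[:, j] += kappa * _rotate_phase(latent, coupling.delta) + (
                1 - kappa
            ) * _narrowband(rng, n, fs, band)
            touched[[i, j]] = True
        for k in np.flatnonzero(~touched):
            component[:, k] = _narrowband(rng, n, fs, band)
        out += component
    if config.noise_sd > 0:
        out += rng.normal(0.0, config.noise_sd, size=out.shape)
    return out


def _participant_ids(config: SimulationConfig) -> list[str]:
    return [f"sz{i + 1:03d}" for i in range(config.n_patients)] + [
        f"hc{i + 1:03d}" for i in range(config.n_controls)
    ]


def simulate_coupled_sources(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full cohort of coupled-oscillator ROI recordings.

    Deterministic given ``config.seed``: all per-participant noise streams
    and the clinical scores are spawned from one seed sequence.
    """
    if config.duration < config.min_duration:
        raise ValueError(
            f"duration {config.duration} s too short for {config.n_epochs} epochs of "
            f"{config.epoch_length_s} s; need at least {config.min_duration} s"
        )
    ids = _participant_ids(config)
    n_total = len(ids)
    children = np.random.SeedSequence(config.seed).spawn(n_total + 1)
    clinical_seed = int(children[0].generate_state(1)[0] % (2**31))

    recordings: list[RoiRecording] = []
    group_labels: dict[str, str] = {}
    true_subgroup: dict[str, int | None] = {}
    for idx, (pid, child) in enumerate(zip(ids, children[1:])):
        gkey = config.group_key(idx)
        rng = np.random.default_rng(child)
        series = _participant_signal(rng, config, gkey)
        recordings.append(
            RoiRecording(series, config.sampling_rate, config.roi_order, participant_id=pid)
        )
        group_labels[pid] = "control" if gkey == "hc" else "patient"
        true_subgroup[pid] = None if gkey == "hc" else int(gkey[2:])

    clinical = simulate_clinical(
        true_subgroup, config.clinical_effects, seed=clinical_seed, participant_ids=ids
    )
    return SyntheticCohort(recordings, group_labels, true_subgroup, clinical, config)


def simulate_clinical(
    true_subgroup: Mapping[str, int | None] | Sequence[int | None],
    clinical_effects: Mapping[str, float] | None = None,
    seed: int = 0,
    participant_ids: Sequence[str] | None = None,
) -> ClinicalTable:
    """Clinical scores whose means shift with the planted subgroup label.

    Each variable is Gaussian around its patient reference mean; a
    standardized effect ``d`` for a variable moves subgroup 1 by ``+d/2``
    and subgroup 2 by ``-d/2`` reference SDs.  Controls draw from the
    control reference mean; variables without a control reference (the
    PANSS sub-scores) are NaN for controls.  Labels of ``None`` (or the
    string ``"none"``) mark controls.
    """
    if isinstance(true_subgroup, Mapping):
        ids = list(true_subgroup.keys())
        labels = [true_subgroup[p] for p in ids]
    else:
        labels = list(true_subgroup)
        ids = list(participant_ids) if participant_ids is not None else [
            f"p{i + 1:03d}" for i in range(len(labels))
        ]
    labels = [None if (l is None or l == "none") else int(l) for l in labels]
    effects = dict(clinical_effects or {})
    for var in effects:
        if var not in CLINICAL_VARIABLES:
            raise ValueError(f"unknown clinical variable {var!r} in clinical_effects")

    rng = np.random.default_rng(seed)
    cols: dict[str, list] = {"participant_id": ids, "group": []}
    for label in labels:
        cols["group"].append("control" if label is None else "patient")
    for var, (_, patient_mean, control_mean, sd) in CLINICAL_VARIABLES.items():
        d = effects.get(var, 0.0)
        values = []
        for label in labels:
            if label is None:
                if np.isnan(control_mean):
                    values.append(np.nan)
                else:
                    values.append(control_mean + sd * rng.standard_normal())
            else:
                shift = {1: +0.5, 2: -0.5}.get(label, 0.0) * d * sd
                values.append(patient_mean + shift + sd * rng.standard_normal())
        cols[var] = values
    return ClinicalTable(pd.DataFrame(cols))


def simulate_feature_cohort(
    config: SimulationConfig,
    mixture_means: np.ndarray,
    mixture_covs: np.ndarray,
    control_mean: np.ndarray | None = None,
    control_cov: np.ndarray | None = None,
    band: str = "theta",
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict[str, int | None]]:
    """Fast path: draw per-band PLI feature rows directly from a mixture.

    Patient rows come from the specified Gaussian mixture (one component per
    planted subgroup, component sizes = ``config.subgroup_sizes``); control
    rows from a separate single Gaussian (defaults: mean of the component
    means, first component covariance).  Values are clipped to the valid PLI
    range [0, 1].  Returns a feature table (participant_id, group, one
    column per ROI pair) and the true subgroup labels.
    """
    means = np.atleast_2d(np.asarray(mixture_means, dtype=float))
    covs = np.asarray(mixture_covs, dtype=float)
    if covs.ndim == 2:
        covs = np.repeat(covs[None], means.shape[0], axis=0)
    if means.shape[0] != len(config.subgroup_sizes):
        raise ValueError(
            f"{means.shape[0]} mixture components but {len(config.subgroup_sizes)} subgroups"
        )
    n_feat = means.shape[1]
    for c in covs:
        try:
            np.linalg.cholesky(c)
        except np.linalg.LinAlgError as err:
            raise ValueError("mixture covariance is not positive-definite") from err
    if control_mean is None:
        control_mean = means.mean(axis=0)
    if control_cov is None:
        control_cov = covs[0]
    np.linalg.cholesky(np.asarray(control_cov, dtype=float))

    rng = np.random.default_rng(config.seed if seed is None else seed)
    ids = _participant_ids(config)
    rows, groups, truth = [], [], {}
    i = 0
    for g, size in enumerate(config.subgroup_sizes, start=1):
        draws = rng.multivariate_normal(means[g - 1], covs[g - 1], size=size)
        for d in draws:
            rows.append(d)
            groups.append("patient")
            truth[ids[i]] = g
            i += 1
    draws = rng.multivariate_normal(np.asarray(control_mean, float), np.asarray(control_cov, float),
                                    size=config.n_controls)
    for d in draws:
        rows.append(d)
        groups.append("control")
        truth[ids[i]] = None
        i += 1
    feats = np.clip(np.array(rows), 0.0, 1.0)
    if n_feat == len(pair_names(config.roi_order)):
        columns = pair_names(config.roi_order)
    else:
        columns = [f"f{j + 1}" for j in range(n_feat)]
    df = pd.DataFrame(feats, columns=columns)
    df.insert(0, "group", groups)
    df.insert(0, "participant_id", ids)
    return df, truth
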