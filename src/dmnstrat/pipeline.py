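"""End-to-end orchestration: features -> PCA -> clustering -> validation.

One :class:`RunConfig` holds every stage parameter (the defaults are the
study design: 8-s epochs, first 40 epochs, K = 1..8 clusters, 50 selection
repeats, 90% stability, 1000 permutations, alpha = 0.05) plus the single
master seed from which all per-band and per-test seeds are derived.  A run
processes each band independently: bands whose cluster solution is not
stable — or stabilizes at a single cluster — are reported as having no
subgroups and skip the statistical and predictive validation; an error in
one band aborts only that band.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .connectivity import BANDS, pli_matrix
from .group_stats import ClinicalTable, results_to_frame, subgroup_comparison_suite
from .prediction import PREDICTOR_SETS, predict_subgroups
from .reduction import fit_pca, formann_max_dims, project
from .simulate import PairCoupling, SimulationConfig, SyntheticCohort, simulate_coupled_sources
from .subgrouping import ClusterSolution, select_model

logger = logging.getLogger("dmnstrat")

__all__ = ["RunConfig", "RunReport", "run_pipeline", "compute_band_features"]


@dataclass
class RunConfig:
    """All parameters of one pipeline run (serializable, hashable)."""

    input_dir: str | None = None  # None -> simulate a cohort
    bands: tuple[str, ...] = ("delta", "theta", "alpha", "beta")
    epoch_length_s: float = 8.0
    n_epochs: int = 40
    standardize_features: bool = False
    k_max: int = 14
    cap_cluster_dims: bool = True  # apply the 2^d sample-size bound
    K_grid: tuple[int, ...] = tuple(range(1, 9))
    lam_grid: tuple[float, ...] | None = None
    n_repeats: int = 50
    stability_threshold: float = 0.9
    n_restarts: int = 1
    svm_C: float = 1.0
    n_permutations: int = 1000
    alpha: float = 0.05
    seed: int = 0
    simulation: SimulationConfig | None = None

    def __post_init__(self) -> None:
        self.bands = tuple(self.bands)
        for b in self.bands:
            if b not in BANDS:
                raise ValueError(f"unknown band {b!r}")
        self.K_grid = tuple(int(k) for k in self.K_grid)
        if self.lam_grid is not None:
            self.lam_grid = tuple(float(x) for x in self.lam_grid)
        if self.input_dir is None and self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dio.to_jsonable(self)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        sim = d.pop("simulation", None)
        cfg_sim = None
        if sim is not None:
            sim = dict(sim)
            spec = sim.pop("coupling_spec", None)
            if spec is not None:
                sim["coupling_spec"] = {
                    band: tuple(
                        PairCoupling(
                            c["roi_i"], c["roi_j"], c.get("delta", np.pi / 2), c.get("kappa", 0.0)
                        )
                        for c in couplings
                    )
                    for band, couplings in spec.items()
                }
            for key in ("subgroup_sizes", "roi_order", "bands"):
                if key in sim and sim[key] is not None:
                    sim[key] = tuple(sim[key])
            cfg_sim = SimulationConfig(**sim)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(simulation=cfg_sim, **{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()})

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _derived_seed(master: int, *key: str) -> int:
    digest = hashlib.sha256(("/".join(map(str, (master, *key)))).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunReport:
    """Machine-parseable outcome of one pipeline run."""

    config: dict
    config_hash: str
    seed: int
    n_patients: int
    n_controls: int
    bands: dict = field(default_factory=dict)
    elapsed_s: float = 0.0

    def to_json(self, path: str | Path) -> Path:
        return dio.dump_json(self, path)

    def summary(self) -> str:
        lines = [
            f"dmnstrat run {self.config_hash} (seed {self.seed}): "
            f"{self.n_patients} patients, {self.n_controls} controls"
        ]
        for band, entry in self.bands.items():
            if "error" in entry:
                lines.append(f"  {band}: FAILED ({entry['error']})")
                continue
            cl = entry["cluster"]
            if entry["has_subgroups"]:
                sizes = "/".join(map(str, cl["subgroup_sizes"]))
                lines.append(
                    f"  {band}: K*={cl['k_optimal']} stable "
                    f"({100 * cl['stability_fraction']:.0f}% of runs), sizes {sizes}"
                )
                for name, pred in entry.get("predictions", {}).items():
                    lines.append(
                        f"    {name}: LOOCV accuracy {100 * pred['accuracy']:.1f}% "
                        f"(p = {pred['permutation_p']:.4g})"
                    )
            else:
                reason = "stable at K*=1" if cl["stable"] else (
                    f"not stable (modal K in {100 * cl['stability_fraction']:.0f}% of runs)"
                )
                lines.append(f"  {band}: no stable subgroups ({reason})")
        return "\n".join(lines)


def compute_band_features(
    recordings: Sequence, band_name: str, config: RunConfig, group_labels: dict[str, str]
) -> pd.DataFrame:
    """Per-participant PLI feature table for one band."""
    feats = [
        pli_matrix(
            rec,
            BANDS[band_name],
            epoch_length_s=config.epoch_length_s,
            n_epochs=config.n_epochs,
        )
        for rec in recordings
    ]
    return dio.features_to_frame(feats, group_labels)


def _analyze_band(
    band: str,
    features: pd.DataFrame,
    clinical: ClinicalTable | None,
    config: RunConfig,
) -> dict:
    feature_cols = [c for c in features.columns if c not in ("participant_id", "group")]
    x_all = features[feature_cols].to_numpy(dtype=float)
    is_patient = (features["group"] == "patient").to_numpy()
    n_patients = int(is_patient.sum())

    model = fit_pca(x_all, band=band, k_max=config.k_max, standardize=config.standardize_features)
    k_aic = model.k_selected
    cap = formann_max_dims(n_patients)
    k_used = min(k_aic, cap) if config.cap_cluster_dims else k_aic
    if k_used < k_aic:
        logger.info("%s: AIC chose k=%d, capped to %d by the 2^d bound", band, k_aic, k_used)

    patient_ids = features.loc[is_patient, "participant_id"].tolist()
    scores = project(model, x_all[is_patient], k=k_used)
    solution = select_model(
        scores,
        K_grid=config.K_grid,
        lam_grid=config.lam_grid,
        n_repeats=config.n_repeats,
        stability_threshold=config.stability_threshold,
        seed=_derived_seed(config.seed, band, "cluster"),
        band=band,
        n_restarts=config.n_restarts,
    )
    has_subgroups = bool(solution.stable and solution.k_optimal >= 2)
    entry: dict = {
        "n_features": len(feature_cols),
        "k_aic": k_aic,
        "k_used": k_used,
        "aic_curve": model.aic_curve.tolist(),
        "cluster": {
            "k_optimal": solution.k_optimal,
            "lam_optimal": solution.lam_optimal,
            "stability_fraction": solution.stability_fraction,
            "stable": solution.stable,
            "runs": solution.runs,
            "subgroup_sizes": solution.subgroup_sizes,
        },
        "has_subgroups": has_subgroups,
    }
    if not has_subgroups:
        entry["note"] = "no stable subgroups"
        return entry

    labels = {p: int(l) for p, l in zip(patient_ids, solution.labels)}
    entry["labels"] = labels
    entry["max_posterior"] = {
        p: float(solution.posterior[i].max()) for i, p in enumerate(patient_ids)
    }
    if clinical is not None and solution.k_optimal == 2:
        results = subgroup_comparison_suite(labels, clinical, features)
        entry["group_tests"] = dio.to_jsonable(results_to_frame(results))
        entry["n_significant_fdr"] = int(
            sum(1 for r in results if r.p_fdr is not None and r.p_fdr < config.alpha)
        )
        entry["predictions"] = {}
        for pred_set in PREDICTOR_SETS:
            res = predict_subgroups(
                labels,
                clinical,
                pred_set,
                C=config.svm_C,
                n_permutations=config.n_permutations,
                seed=_derived_seed(config.seed, band, "perm", pred_set),
            )
            entry["predictions"][pred_set] = {
                "accuracy": res.accuracy,
                "permutation_p": res.permutation_p,
                "n_correct": res.n_correct,
                "n_total": res.n_total,
                "n_dropped_missing": res.n_dropped_missing,
                "weights": res.weights,
            }
    return entry


def run_pipeline(
    config: RunConfig,
    cohort: SyntheticCohort | None = None,
    features_by_band: Mapping[str, pd.DataFrame] | None = None,
    clinical: ClinicalTable | None = None,
    out_dir: str | Path | None = None,
) -> RunReport:
    """Execute the full per-band pipeline and return the run report.

    Inputs can come from three places: a provided ``cohort`` (or one
    simulated from ``config.simulation`` when ``config.input_dir`` is None),
    a cohort directory on disk, or precomputed per-band feature tables
    (``features_by_band`` with ``clinical``), which skips signal processing.
    """
    t0 = time.time()
    logger.info("run start: hash %s seed %s", config.config_hash, config.seed)

    truth: dict[str, int | None] | None = None
    if features_by_band is None:
        if cohort is None:
            if config.input_dir is not None:
                recordings, group_labels, truth, clinical = dio.read_cohort(config.input_dir)
            else:
                cohort = simulate_coupled_sources(config.simulation)
        if cohort is not None:
            recordings = cohort.recordings
            group_labels = cohort.group_labels
            truth = cohort.true_subgroup
            clinical = cohort.clinical
    else:
        group_labels = None

    report = RunReport(
        config=config.to_dict(),
        config_hash=config.config_hash,
        seed=config.seed,
        n_patients=0,
        n_controls=0,
    )

    for band in config.bands:
        try:
            if features_by_band is not None:
                features = features_by_band[band]
            else:
                features = compute_band_features(recordings, band, config, group_labels)
            report.n_patients = int((features["group"] == "patient").sum())
            report.n_controls = int((features["group"] == "control").sum())
            entry = _analyze_band(band, features, clinical, config)
            if truth is not None and entry.get("labels"):
                entry["ari_vs_truth"] = _ari_against_truth(entry["labels"], truth)
            report.bands[band] = entry
            if out_dir is not None:
                dio.write_features(features, Path(out_dir) / f"features_{band}.csv")
        except Exception as err:  # keep other bands alive
            logger.exception("band %s failed", band)
            report.bands[band] = {"error": f"{type(err).__name__}: {err}"}
    report.elapsed_s = round(time.time() - t0, 3)

    if out_dir is not None:
        out_dir = Path(out_dir)
        report.to_json(out_dir / "report.json")
        (out_dir / "report.txt").write_text(report.summary() + "\n")
    logger.info("run done in %.1f s", report.elapsed_s)
    return report


def _ari_against_truth(labels: Mapping[str, int], truth: Mapping[str, int | None]) -> float:
    from sklearn.metrics import adjusted_rand_score

    common = [p for p in labels if truth.get(p) is not None]
    if len(common) < 2:
        return float("nan")
    return float(
        adjusted_rand_score([truth[p] for p in common], [labels[p] for p in common])
    )
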