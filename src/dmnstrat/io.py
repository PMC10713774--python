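"""File formats: delimited-text recordings with JSON sidecars, CSV tables.

Everything the pipeline reads or writes is plain text so runs are
inspectable and diffable: per-participant ROI series as a headerless
delimited matrix (one row per sample, one column per ROI) next to a JSON
sidecar with the sampling metadata; per-band feature tables, clinical
scores and subgroup labels as CSV; models and reports as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .connectivity import ConnectivityFeatures, RoiRecording, pair_names
from .group_stats import ClinicalTable

__all__ = [
    "write_recording",
    "read_recording",
    "write_cohort",
    "read_cohort",
    "features_to_frame",
    "write_features",
    "read_features",
    "write_clinical",
    "read_clinical",
    "to_jsonable",
    "dump_json",
]


def write_recording(directory: str | Path, recording: RoiRecording, group: str = "") -> Path:
    """Write ``<pid>.csv`` (samples x ROIs, no header) and ``<pid>.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pid = recording.participant_id or "participant"
    np.savetxt(directory / f"{pid}.csv", recording.series, delimiter=",", fmt="%.8g")
    sidecar = {
        "participant_id": pid,
        "group": group,
        "sampling_rate": recording.sampling_rate,
        "roi_order": list(recording.roi_order),
    }
    (directory / f"{pid}.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return directory / f"{pid}.csv"


def read_recording(directory: str | Path, participant_id: str) -> tuple[RoiRecording, str]:
    """Read one recording and its cohort group from a sidecar pair."""
    directory = Path(directory)
    meta = json.loads((directory / f"{participant_id}.json").read_text())
    series = np.loadtxt(directory / f"{participant_id}.csv", delimiter=",", ndmin=2)
    rec = RoiRecording(
        series=series,
        sampling_rate=float(meta["sampling_rate"]),
        roi_order=tuple(meta["roi_order"]),
        participant_id=meta.get("participant_id", participant_id),
    )
    return rec, meta.get("group", "")


def write_cohort(cohort, directory: str | Path) -> Path:
    """Write every recording, a manifest CSV and the clinical CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort.recordings:
        pid = rec.participant_id
        write_recording(directory, rec, group=cohort.group_labels[pid])
        sub = cohort.true_subgroup.get(pid)
        rows.append(
            {
                "participant_id": pid,
                "group": cohort.group_labels[pid],
                "true_subgroup": "" if sub is None else sub,
            }
        )
    pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)
    write_clinical(cohort.clinical, directory / "clinical.csv")
    return directory


def read_cohort(directory: str | Path):
    """Load a cohort directory written by :func:`write_cohort`.

    Returns ``(recordings, group_labels, true_subgroup, clinical)`` where
    ``clinical`` is None when no clinical.csv is present.
    """
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv", dtype={"participant_id": str})
    recordings, group_labels, true_subgroup = [], {}, {}
    for _, row in manifest.iterrows():
        rec, group = read_recording(directory, row["participant_id"])
        recordings.append(rec)
        group_labels[rec.participant_id] = group or row["group"]
        raw = row.get("true_subgroup", "")
        true_subgroup[rec.participant_id] = None if pd.isna(raw) or raw == "" else int(raw)
    clinical = None
    if (directory / "clinical.csv").exists():
        clinical = read_clinical(directory / "clinical.csv")
    return recordings, group_labels, true_subgroup, clinical


def features_to_frame(
    features: Iterable[ConnectivityFeatures], group_labels: dict[str, str] | None = None
) -> pd.DataFrame:
    """Stack per-participant feature vectors into a tidy per-band table."""
    rows = []
    for f in features:
        row = {"participant_id": f.participant_id}
        if group_labels is not None:
            row["group"] = group_labels.get(f.participant_id, "")
        row.update(zip(f.feature_names, f.vector))
        rows.append(row)
    return pd.DataFrame(rows)


def write_features(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    return path


def read_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"participant_id": str})


def write_clinical(clinical: ClinicalTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    clinical.data.to_csv(path, index=False)
    return path


def read_clinical(path: str | Path) -> ClinicalTable:
    return ClinicalTable(pd.read_csv(path, dtype={"participant_id": str}))


def to_jsonable(obj):
    """Recursively convert dataclasses / numpy / pandas objects for JSON."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: to_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return to_jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.DataFrame):
        return to_jsonable(obj.to_dict(orient="records"))
    return obj


def dump_json(obj, path: str | Path) -> Path:
    """Deterministic JSON dump (sorted keys, fixed layout)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(to_jsonable(obj), indent=2, sort_keys=True) + "\n")
    return path
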