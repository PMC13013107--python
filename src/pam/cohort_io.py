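"""Cohort data model and delimited-text I/O.

The study data are three CSV tables: a patient table (demographics,
severity scores, event status/day, outcome scores), a sample table
(patient link, collection day post-index-event) and a samples x features
intensity matrix of raw positive peak areas.  This module defines the
in-memory records for those tables, validates them (including referential
integrity between samples and patients), and reads/writes them as UTF-8
comma-separated text.

Conventions
-----------
* ``day_post_index`` counts calendar days since the index event (aSAH
  diagnosis), 0-based; an optional ``hour_post_index`` gives sub-day
  resolution and is preferred downstream when present.
* Intensities are raw peak areas until :func:`log2_transform` is applied;
  the transform may be applied at most once (tracked by a state flag).
* Zero intensities are replaced by a configurable floor (default: half
  the smallest positive value of that feature) before taking logs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DataError, IntegrityError, SchemaError, StateError

__all__ = [
    "PatientRecord",
    "SampleRecord",
    "FeatureMatrix",
    "load_cohort",
    "load_feature_matrix",
    "log2_transform",
    "write_results",
    "write_cohort",
    "write_feature_matrix",
    "PATIENT_COLUMNS",
    "SAMPLE_COLUMNS",
]

#: Required / optional columns of patients.csv (in stable output order).
PATIENT_COLUMNS = [
    "patient_id", "age", "sex", "aneurysm_location", "hunt_hess", "mfisher",
    "event_status", "event_day",
    "gos_discharge", "gos_1w", "gos_1m", "gos_12m", "mrs_12m",
]
_PATIENT_REQUIRED = PATIENT_COLUMNS[:8]
_OUTCOME_FIELDS = ["gos_discharge", "gos_1w", "gos_1m", "gos_12m", "mrs_12m"]

SAMPLE_COLUMNS = ["sample_id", "patient_id", "day_post_index", "hour_post_index"]
_SAMPLE_REQUIRED = SAMPLE_COLUMNS[:3]


@dataclass(frozen=True)
class PatientRecord:
    """One subject: matching covariates, event status/day and outcomes.

    ``event_day`` is the integer day post-index-event on which the clinical
    event (DCI) was diagnosed; it is present iff ``event_status`` is true.
    Outcome scores (GOS 1-5, mRS 0-6) are optional: not every patient has
    follow-up at every horizon.
    """

    patient_id: str
    age: float
    sex: str                      # "F" / "M"
    aneurysm_location: str        # "anterior" / "posterior"
    hunt_hess: int                # 1-5
    mfisher: int                  # 0-4
    event_status: bool
    event_day: int | None = None
    gos_discharge: int | None = None
    gos_1w: int | None = None
    gos_1m: int | None = None
    gos_12m: int | None = None
    mrs_12m: int | None = None

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise DataError(f"patient {self.patient_id}: age must be positive")
        if self.sex not in ("F", "M"):
            raise DataError(f"patient {self.patient_id}: sex must be F or M")
        if self.aneurysm_location not in ("anterior", "posterior"):
            raise DataError(
                f"patient {self.patient_id}: aneurysm_location must be "
                "anterior or posterior"
            )
        if not 1 <= self.hunt_hess <= 5:
            raise DataError(f"patient {self.patient_id}: hunt_hess out of 1-5")
        if not 0 <= self.mfisher <= 4:
            raise DataError(f"patient {self.patient_id}: mfisher out of 0-4")
        if self.event_status:
            if self.event_day is None:
                raise IntegrityError(
                    f"patient {self.patient_id}: event_status true but no event_day"
                )
            if self.event_day < 1:
                raise DataError(f"patient {self.patient_id}: event_day must be >= 1")
        elif self.event_day is not None:
            raise IntegrityError(
                f"patient {self.patient_id}: event_day present but event_status false"
            )
        for name in ("gos_discharge", "gos_1w", "gos_1m", "gos_12m"):
            v = getattr(self, name)
            if v is not None and not 1 <= v <= 5:
                raise DataError(f"patient {self.patient_id}: {name} out of 1-5")
        if self.mrs_12m is not None and not 0 <= self.mrs_12m <= 6:
            raise DataError(f"patient {self.patient_id}: mrs_12m out of 0-6")


@dataclass(frozen=True)
class SampleRecord:
    """One plasma draw: patient link and collection time post-index-event."""

    sample_id: str
    patient_id: str
    day_post_index: int
    hour_post_index: float | None = None

    def __post_init__(self) -> None:
        if self.day_post_index < 0:
            raise DataError(f"sample {self.sample_id}: day_post_index must be >= 0")


@dataclass
class FeatureMatrix:
    """Samples x features intensity table with raw and log2 views.

    ``data`` has one row per sample (index = sample_id) and one column per
    feature.  ``annotated`` flags which features carry a metabolite
    annotation (vs unknown m/z features).  ``log_transformed`` records
    whether :func:`log2_transform` has been applied; it may be applied at
    most once.
    """

    data: pd.DataFrame
    annotated: pd.Series | None = None
    log_transformed: bool = False
    feature_names: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise IntegrityError(f"duplicate sample_id {dup!r} in feature matrix")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise IntegrityError(f"duplicate feature_id {dup!r} in feature matrix")
        if self.annotated is None:
            self.annotated = pd.Series(True, index=self.data.columns)
        else:
            self.annotated = self.annotated.reindex(self.data.columns, fill_value=False)
        if not self.log_transformed:
            vals = self.data.to_numpy()
            if np.any(vals < 0):
                i, j = np.argwhere(vals < 0)[0]
                raise DataError(
                    f"negative intensity at sample {self.data.index[i]!r}, "
                    f"feature {self.data.columns[j]!r}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def feature_scope(self, scope: str) -> list[str]:
        """Feature ids for a discovery scope (``annotated_only`` | ``all_features``)."""
        if scope == "all_features":
            return self.feature_ids
        if scope == "annotated_only":
            return list(self.data.columns[self.annotated.to_numpy(dtype=bool)])
        raise DataError(f"unknown feature scope {scope!r}")


def log2_transform(matrix: FeatureMatrix, zero_floor: str | float | None = "half_min") -> FeatureMatrix:
    """Return a log2 view of a raw-state matrix.

    Zeros are replaced per ``zero_floor``: ``"half_min"`` (default) uses
    half the smallest positive value of the feature, a float is used as-is,
    and ``None`` makes any zero a :class:`DataError`.  The transform may be
    applied at most once.
    """
    if matrix.log_transformed:
        raise StateError("matrix is already log2-transformed")
    values = matrix.data.to_numpy(dtype=float).copy()
    zero_mask = values == 0
    if zero_mask.any():
        if zero_floor is None:
            i, j = np.argwhere(zero_mask)[0]
            raise DataError(
                f"zero intensity at sample {matrix.data.index[i]!r}, feature "
                f"{matrix.data.columns[j]!r} and no zero floor configured"
            )
        if zero_floor == "half_min":
            with np.errstate(invalid="ignore"):
                pos = np.where(values > 0, values, np.nan)
                col_floor = np.nanmin(pos, axis=0) / 2.0
            if np.isnan(col_floor[zero_mask.any(axis=0)]).any():
                bad = matrix.data.columns[np.isnan(col_floor) & zero_mask.any(axis=0)][0]
                raise DataError(f"feature {bad!r} is identically zero; no floor derivable")
            values = np.where(zero_mask, np.broadcast_to(col_floor, values.shape), values)
        else:
            values = np.where(zero_mask, float(zero_floor), values)
    out = pd.DataFrame(np.log2(values), index=matrix.data.index, columns=matrix.data.columns)
    return FeatureMatrix(out, annotated=matrix.annotated.copy(), log_transformed=True,
                         feature_names=matrix.feature_names)


# ---------------------------------------------------------------------------
# readers


def _opt_int(v) -> int | None:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return int(v)


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def load_cohort(patient_path, sample_path, study_days: int = 7,
                ) -> tuple[dict[str, PatientRecord], dict[str, SampleRecord]]:
    """Read and validate patients.csv and samples.csv.

    Returns dicts keyed by id.  Referential integrity (every sample's
    patient exists) and the per-record invariants are enforced here, so
    downstream stages can assume a valid cohort.
    """
    pdf = pd.read_csv(patient_path, dtype={"patient_id": str})
    _require_columns(pdf, _PATIENT_REQUIRED, patient_path)
    patients: dict[str, PatientRecord] = {}
    for row in pdf.to_dict("records"):
        rec = PatientRecord(
            patient_id=str(row["patient_id"]),
            age=float(row["age"]),
            sex=str(row["sex"]),
            aneurysm_location=str(row["aneurysm_location"]),
            hunt_hess=int(row["hunt_hess"]),
            mfisher=int(row["mfisher"]),
            event_status=bool(int(row["event_status"])),
            event_day=_opt_int(row.get("event_day")),
            **{f: _opt_int(row.get(f)) for f in _OUTCOME_FIELDS},
        )
        if rec.patient_id in patients:
            raise IntegrityError(f"duplicate patient_id {rec.patient_id!r}")
        patients[rec.patient_id] = rec

    sdf = pd.read_csv(sample_path, dtype={"sample_id": str, "patient_id": str})
    _require_columns(sdf, _SAMPLE_REQUIRED, sample_path)
    samples: dict[str, SampleRecord] = {}
    for row in sdf.to_dict("records"):
        hour = row.get("hour_post_index")
        if hour is not None and isinstance(hour, float) and math.isnan(hour):
            hour = None
        rec = SampleRecord(
            sample_id=str(row["sample_id"]),
            patient_id=str(row["patient_id"]),
            day_post_index=int(row["day_post_index"]),
            hour_post_index=None if hour is None else float(hour),
        )
        if rec.patient_id not in patients:
            raise IntegrityError(
                f"sample {rec.sample_id!r} references unknown patient {rec.patient_id!r}"
            )
        if rec.day_post_index > study_days:
            raise DataError(
                f"sample {rec.sample_id!r}: day_post_index {rec.day_post_index} "
                f"exceeds study window of {study_days} days"
            )
        if rec.sample_id in samples:
            raise IntegrityError(f"duplicate sample_id {rec.sample_id!r}")
        samples[rec.sample_id] = rec
    return patients, samples


def load_feature_matrix(path, annotations_path=None, orientation: str = "samples",
                        ) -> FeatureMatrix:
    """Read a raw intensity matrix from CSV.

    ``orientation="samples"`` (default) expects samples as rows with a
    leading ``sample_id`` column; ``orientation="features"`` expects the
    transposed layout with a leading ``feature_id`` column.  An optional
    companion table (feature_id, annotated[, name]) supplies annotation
    flags; without it all features count as annotated.
    """
    df = pd.read_csv(path)
    if orientation == "features":
        df = df.set_index(df.columns[0]).T.reset_index(names="sample_id")
    elif orientation != "samples":
        raise DataError(f"unknown orientation {orientation!r}")
    id_col = df.columns[0]
    df[id_col] = df[id_col].astype(str)
    if df[id_col].duplicated().any():
        dup = df[id_col][df[id_col].duplicated()].iloc[0]
        raise IntegrityError(f"duplicate sample_id {dup!r} in {path}")
    data = df.set_index(id_col)
    data.index.name = "sample_id"
    data = data.astype(float)
    vals = data.to_numpy()
    if np.any(vals < 0):
        i, j = np.argwhere(vals < 0)[0]
        raise DataError(
            f"{path}: negative value at row {data.index[i]!r}, column {data.columns[j]!r}"
        )
    annotated = None
    names = None
    if annotations_path is not None:
        ann = pd.read_csv(annotations_path, dtype={"feature_id": str})
        _require_columns(ann, ["feature_id", "annotated"], annotations_path)
        ann = ann.set_index("feature_id")
        annotated = ann["annotated"].astype(bool)
        if "name" in ann.columns:
            names = ann["name"]
    return FeatureMatrix(data, annotated=annotated, feature_names=names)


# ---------------------------------------------------------------------------
# writers


def _patients_frame(patients: Mapping[str, PatientRecord]) -> pd.DataFrame:
    rows = []
    for pid in sorted(patients):
        p = patients[pid]
        rows.append({
            "patient_id": p.patient_id, "age": p.age, "sex": p.sex,
            "aneurysm_location": p.aneurysm_location, "hunt_hess": p.hunt_hess,
            "mfisher": p.mfisher, "event_status": int(p.event_status),
            "event_day": p.event_day,
            **{f: getattr(p, f) for f in _OUTCOME_FIELDS},
        })
    return pd.DataFrame(rows, columns=PATIENT_COLUMNS)


def _samples_frame(samples: Mapping[str, SampleRecord]) -> pd.DataFrame:
    rows = []
    for sid in sorted(samples):
        s = samples[sid]
        rows.append({"sample_id": s.sample_id, "patient_id": s.patient_id,
                     "day_post_index": s.day_post_index,
                     "hour_post_index": s.hour_post_index})
    return pd.DataFrame(rows, columns=SAMPLE_COLUMNS)


def write_cohort(patients: Mapping[str, PatientRecord],
                 samples: Mapping[str, SampleRecord], out_dir) -> dict[str, Path]:
    """Write patients.csv and samples.csv; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"patients": out_dir / "patients.csv", "samples": out_dir / "samples.csv"}
    _patients_frame(patients).to_csv(paths["patients"], index=False)
    _samples_frame(samples).to_csv(paths["samples"], index=False)
    return paths


def write_feature_matrix(matrix: FeatureMatrix, out_dir) -> dict[str, Path]:
    """Write features.csv (full float precision) + feature_annotations.csv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fpath = out_dir / "features.csv"
    matrix.data.to_csv(fpath, index_label="sample_id")
    ann = pd.DataFrame({
        "feature_id": matrix.feature_ids,
        "annotated": matrix.annotated.astype(int).to_numpy(),
    })
    if matrix.feature_names is not None:
        ann["name"] = matrix.feature_names.reindex(matrix.feature_ids).to_numpy()
    apath = out_dir / "feature_annotations.csv"
    ann.to_csv(apath, index=False)
    return {"features": fpath, "feature_annotations": apath}


def write_results(tables: Mapping[str, pd.DataFrame], out_dir,
                  float_format: str = "%.6g") -> dict[str, Path]:
    """Write result tables as CSV with stable column order and fixed precision.

    ``tables`` maps a bare table name to a DataFrame; files are written as
    ``<name>.csv``.  Deterministic: same tables -> byte-identical files.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - environment dependent
        raise IOError(f"cannot create output directory {out_dir}: {exc}") from exc
    paths = {}
    for name, df in tables.items():
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False, float_format=float_format)
        paths[name] = path
    return paths
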