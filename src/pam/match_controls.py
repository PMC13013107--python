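"""Covariate-matched control selection.

Each case sample (a pre-event window sample from an event patient) gets
``k`` control samples from non-event patients, matched on collection day
post-index-event plus clinical covariates (age, sex, aneurysm location,
Hunt-Hess, modified Fisher).  The covariate metric is a Gower-style
weighted sum:

    |d_age| / IQR_age  +  1[sex differs]  +  1[location differs]
    +  |d_HuntHess| / 4  +  |d_mFisher| / 4

each term multiplied by its configured weight.  Day matching starts
exact (same day) and auto-widens to +/-1 day when a case's pool is
exhausted.  Ties break deterministically by (distance, control
patient_id, control sample_id).  A control sample may serve several
cases (the study drew 2 controls per case from a smaller distinct pool),
controlled by ``reuse_policy``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .align_stratify import WindowStratum
from .cohort_io import PatientRecord, SampleRecord
from .errors import ConfigError, MatchError

__all__ = ["MatchConfig", "MatchSet", "covariate_distance",
           "select_matched_controls", "cohort_age_iqr",
           "matches_frame", "balance_table"]

_COVARIATES = ("age", "sex", "aneurysm_location", "hunt_hess", "mfisher")


@dataclass
class MatchConfig:
    """Knobs of the matching stage (all defaults logged in run manifests)."""

    k: int = 2
    day_tolerance: int = 0
    max_day_tolerance: int = 1      # auto-widening cap on pool exhaustion
    weights: dict[str, float] = field(
        default_factory=lambda: {c: 1.0 for c in _COVARIATES})
    reuse_policy: str = "per_case_unique"   # or "globally_unique"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        if self.day_tolerance < 0:
            raise ConfigError("day_tolerance must be >= 0")
        if self.reuse_policy not in ("per_case_unique", "globally_unique"):
            raise ConfigError(f"unknown reuse_policy {self.reuse_policy!r}")


@dataclass
class MatchSet:
    """One case sample plus its selected controls (parallel distances)."""

    case_sample_id: str
    control_sample_ids: list[str]
    distances: list[float]
    day_gap_used: int


def cohort_age_iqr(patients: Mapping[str, PatientRecord]) -> float:
    ages = np.array([p.age for p in patients.values()], dtype=float)
    q75, q25 = np.percentile(ages, [75, 25])
    iqr = float(q75 - q25)
    return iqr if iqr > 0 else 1.0


def covariate_distance(case: PatientRecord, control: PatientRecord,
                       weights: Mapping[str, float] | None = None,
                       age_iqr: float = 1.0) -> float:
    """Gower-style covariate distance between two patients.

    Age is scaled by the cohort age IQR, ordinal grades by their range,
    binary covariates contribute 0/1.
    """
    w = {c: 1.0 for c in _COVARIATES}
    if weights:
        w.update(weights)
    for rec in (case, control):
        for c in _COVARIATES:
            if getattr(rec, c) is None:
                raise MatchError(f"patient {rec.patient_id!r}: missing covariate {c!r}")
    d = w["age"] * abs(case.age - control.age) / age_iqr
    d += w["sex"] * (case.sex != control.sex)
    d += w["aneurysm_location"] * (case.aneurysm_location != control.aneurysm_location)
    d += w["hunt_hess"] * abs(case.hunt_hess - control.hunt_hess) / 4.0
    d += w["mfisher"] * abs(case.mfisher - control.mfisher) / 4.0
    return float(d)


def select_matched_controls(stratum: WindowStratum,
                            patients: Mapping[str, PatientRecord],
                            samples: Mapping[str, SampleRecord],
                            config: MatchConfig | None = None,
                            rng: np.random.Generator | None = None,
                            ) -> list[MatchSet]:
    """Pick the k lowest-distance day-eligible controls per case sample.

    Day eligibility starts at ``day_tolerance`` and widens one day at a
    time up to ``max_day_tolerance`` whenever a case's pool holds fewer
    than k controls.  Selection is deterministic (``rng`` is accepted for
    interface symmetry but unused: ties break lexicographically).  Under
    ``globally_unique`` a control sample is consumed once across the
    whole stratum (greedy, cases in sorted order).
    """
    del rng  # deterministic tie-breaks; no randomness needed
    config = config or MatchConfig()
    if stratum.is_empty:
        return []
    age_iqr = cohort_age_iqr(patients)
    used_globally: set[str] = set()
    out: list[MatchSet] = []
    for case_sid in sorted(stratum.case_samples):
        case_patient = patients[samples[case_sid].patient_id]
        case_day = samples[case_sid].day_post_index
        chosen: list[tuple[float, str, str]] = []
        gap_used = config.day_tolerance
        for gap in range(config.day_tolerance, config.max_day_tolerance + 1):
            pool = []
            for ctrl_sid, ctrl_day in stratum.control_pool:
                if abs(ctrl_day - case_day) > gap:
                    continue
                if ctrl_sid in used_globally:
                    continue
                cp = patients[samples[ctrl_sid].patient_id]
                dist = covariate_distance(case_patient, cp,
                                          config.weights, age_iqr)
                pool.append((dist, cp.patient_id, ctrl_sid))
            gap_used = gap
            if len(pool) >= config.k:
                break
        pool.sort()
        chosen = pool[:config.k]
        if len(chosen) < config.k:
            warnings.warn(
                f"case {case_sid}: only {len(chosen)} control(s) within "
                f"+/-{gap_used} day(s); partial match set", stacklevel=2)
        if config.reuse_policy == "globally_unique":
            used_globally.update(sid for _, _, sid in chosen)
        out.append(MatchSet(
            case_sample_id=case_sid,
            control_sample_ids=[sid for _, _, sid in chosen],
            distances=[d for d, _, _ in chosen],
            day_gap_used=gap_used,
        ))
    return out


def matches_frame(match_sets: list[MatchSet]) -> pd.DataFrame:
    rows = [
        {"case_sample_id": m.case_sample_id, "control_sample_id": sid,
         "distance": dist, "day_gap_used": m.day_gap_used}
        for m in match_sets
        for sid, dist in zip(m.control_sample_ids, m.distances)
    ]
    return pd.DataFrame(rows, columns=["case_sample_id", "control_sample_id",
                                       "distance", "day_gap_used"])


def _covariate_values(patient: PatientRecord) -> dict[str, float]:
    return {
        "age": patient.age,
        "sex_female": 1.0 * (patient.sex == "F"),
        "anterior": 1.0 * (patient.aneurysm_location == "anterior"),
        "hunt_hess": float(patient.hunt_hess),
        "mfisher": float(patient.mfisher),
    }


def _smd(case_vals: np.ndarray, ctrl_vals: np.ndarray) -> float:
    """Standardized mean difference with pooled SD (0 when both constant)."""
    v1 = case_vals.var(ddof=1) if len(case_vals) > 1 else 0.0
    v0 = ctrl_vals.var(ddof=1) if len(ctrl_vals) > 1 else 0.0
    pooled = np.sqrt((v1 + v0) / 2.0)
    if pooled == 0:
        return 0.0
    return float((case_vals.mean() - ctrl_vals.mean()) / pooled)


def balance_table(stratum: WindowStratum, match_sets: list[MatchSet],
                  patients: Mapping[str, PatientRecord],
                  samples: Mapping[str, SampleRecord]) -> pd.DataFrame:
    """Per-covariate standardized mean difference before/after matching.

    "Before" contrasts case samples against the whole control pool;
    "after" against the selected controls (with multiplicity, mirroring
    their weight in the analysis).
    """
    def values(sids):
        return pd.DataFrame(
            [_covariate_values(patients[samples[sid].patient_id]) for sid in sids])

    case_df = values(stratum.case_samples)
    pool_df = values([sid for sid, _ in stratum.control_pool])
    matched_ids = [sid for m in match_sets for sid in m.control_sample_ids]
    matched_df = values(matched_ids) if matched_ids else pool_df.iloc[:0]
    rows = []
    for cov in case_df.columns:
        rows.append({
            "covariate": cov,
            "smd_before": _smd(case_df[cov].to_numpy(), pool_df[cov].to_numpy()),
            "smd_after": (_smd(case_df[cov].to_numpy(), matched_df[cov].to_numpy())
                          if len(matched_df) else np.nan),
        })
    return pd.DataFrame(rows, columns=["covariate", "smd_before", "smd_after"])
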