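"""Event-time alignment and pre-event window stratification (the PAM core).

Fixed-timepoint designs sample at predetermined calendar days, so a
"day 5" sample may be 12 h pre-event for one patient and 72 h for
another.  Alignment instead computes each sample's temporal relation to
its own patient's event and buckets case samples into pre-event windows:

* ``W24_48`` = [24, 48) hours pre-event
* ``W48_72`` = [48, 72) hours pre-event

Boundaries are half-open; at day resolution this maps a 1-day gap to
W24_48 and a 2-day gap to W48_72.  Samples 0-24 h pre-event are excluded
by design (high expected volatility close to onset), as are samples at
or after the event.  Control samples (patients without an event) carry no
alignment and feed the day-matched control pools instead.

The fixed-timepoint comparator stratification is also provided so the
two designs can be contrasted on the same cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .cohort_io import PatientRecord, SampleRecord
from .errors import IntegrityError, ValidationError

__all__ = [
    "W24_48", "W48_72", "NO_WINDOW", "WINDOWS",
    "AlignedSample", "WindowStratum", "StrataResult",
    "window_for_hours", "align_to_event", "build_strata",
    "fixed_timepoint_strata", "aligned_frame",
]

W24_48 = "W24_48"
W48_72 = "W48_72"
NO_WINDOW = "none"
WINDOWS = (W24_48, W48_72)


def window_for_hours(hours_pre_event: float | None) -> str:
    """Window label for a pre-event lag in hours (half-open boundaries)."""
    if hours_pre_event is None:
        return NO_WINDOW
    if 24.0 <= hours_pre_event < 48.0:
        return W24_48
    if 48.0 <= hours_pre_event < 72.0:
        return W48_72
    return NO_WINDOW


@dataclass(frozen=True)
class AlignedSample:
    """A sample's temporal relation to its patient's event."""

    sample_id: str
    patient_id: str
    day_post_index: int
    hours_pre_event: float | None   # None for control patients
    window: str


@dataclass
class WindowStratum:
    """Case samples of one pre-event window plus the candidate control pool.

    ``control_pool`` lists every sample from non-event patients together
    with its collection day; day-based eligibility is applied later by the
    matching stage.
    """

    window: str
    case_samples: list[str] = field(default_factory=list)
    control_pool: list[tuple[str, int]] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return not self.case_samples


@dataclass
class StrataResult:
    strata: dict[str, WindowStratum]
    n_dual_window_patients: int
    warnings: list[str] = field(default_factory=list)

    def __getitem__(self, window: str) -> WindowStratum:
        return self.strata[window]


def align_to_event(patients: Mapping[str, PatientRecord],
                   samples: Mapping[str, SampleRecord],
                   prefer_hours: bool = True) -> dict[str, AlignedSample]:
    """Compute each sample's pre-event lag and window.

    For event patients the lag is ``(event_day - day_post_index) * 24``
    hours, or the exact hour difference when ``hour_post_index`` is
    present (and ``prefer_hours``).  Samples at or after the event get a
    non-positive lag and no window.  Control samples get no lag.
    """
    aligned: dict[str, AlignedSample] = {}
    for sid, s in samples.items():
        p = patients.get(s.patient_id)
        if p is None:
            raise IntegrityError(f"sample {sid!r} references unknown patient")
        if not p.event_status:
            aligned[sid] = AlignedSample(sid, p.patient_id, s.day_post_index,
                                         None, NO_WINDOW)
            continue
        if p.event_day is None:  # unreachable after cohort validation
            raise IntegrityError(f"event patient {p.patient_id!r} has no event_day")
        if prefer_hours and s.hour_post_index is not None:
            hours = p.event_day * 24.0 - s.hour_post_index
        else:
            hours = (p.event_day - s.day_post_index) * 24.0
        aligned[sid] = AlignedSample(sid, p.patient_id, s.day_post_index,
                                     hours, window_for_hours(hours))
    return aligned


def build_strata(aligned: Mapping[str, AlignedSample],
                 patients: Mapping[str, PatientRecord],
                 samples: Mapping[str, SampleRecord]) -> StrataResult:
    """Bucket aligned case samples per window and attach the control pool.

    Window assignment is a partition: a sample lands in at most one
    window.  Also counts event patients contributing to both windows
    (clinical every-other-day schedules make this the minority).
    """
    strata = {w: WindowStratum(window=w) for w in WINDOWS}
    control_pool = sorted(
        (sid, samples[sid].day_post_index)
        for sid, a in aligned.items()
        if not patients[a.patient_id].event_status
    )
    per_window_patients: dict[str, set[str]] = {w: set() for w in WINDOWS}
    for sid in sorted(aligned):
        a = aligned[sid]
        if a.window in WINDOWS:
            strata[a.window].case_samples.append(sid)
            per_window_patients[a.window].add(a.patient_id)
    notes = []
    for w in WINDOWS:
        strata[w].control_pool = list(control_pool)
        if strata[w].is_empty:
            msg = f"window {w}: no case samples; stratum emitted empty"
            notes.append(msg)
            warnings.warn(msg, stacklevel=2)
    dual = len(per_window_patients[W24_48] & per_window_patients[W48_72])
    return StrataResult(strata=strata, n_dual_window_patients=dual, warnings=notes)


def fixed_timepoint_strata(patients: Mapping[str, PatientRecord],
                           samples: Mapping[str, SampleRecord],
                           day: int, study_days: int = 7,
                           ) -> tuple[list[str], list[str]]:
    """Comparator design: split samples on one calendar day by event status.

    Ignores individual event timing entirely, so the "case" group mixes
    samples collected anywhere from imminently pre-event to post-event.
    Returns (case_sample_ids, control_sample_ids), sorted.
    """
    if not 0 <= day <= study_days:
        raise ValidationError(f"day {day} outside study window 0-{study_days}")
    case, control = [], []
    for sid in sorted(samples):
        s = samples[sid]
        if s.day_post_index != day:
            continue
        (case if patients[s.patient_id].event_status else control).append(sid)
    if not case and not control:
        warnings.warn(f"no samples collected on day {day}", stacklevel=2)
    return case, control


def aligned_frame(aligned: Mapping[str, AlignedSample]) -> pd.DataFrame:
    """Tabular view of alignment results (for aligned_samples.csv)."""
    rows = [{
        "sample_id": a.sample_id, "patient_id": a.patient_id,
        "day_post_index": a.day_post_index,
        "hours_pre_event": a.hours_pre_event, "window": a.window,
    } for _, a in sorted(aligned.items())]
    return pd.DataFrame(rows, columns=["sample_id", "patient_id", "day_post_index",
                                       "hours_pre_event", "window"])
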