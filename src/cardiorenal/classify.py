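"""RIFLE / AKIN / KDIGO serum-creatinine rule engines.

Detection runs on the first 7 days (168 h) of the admission:

* RIFLE fires when some measurement reaches >= 1.5x the baseline.
* AKIN fires when some ordered measurement pair less than 48 h apart shows an
  absolute rise >= 26.5 µmol/L or a relative rise to >= 1.5x the earlier
  value (the "rolling pair" reading; a baseline-referenced variant is
  available via ``relative_reference="baseline"``).
* KDIGO is the disjunction of AKIN's absolute 48-h clause and RIFLE's 7-day
  relative clause, which is what makes it detect every RIFLE or AKIN case on
  series that do not dip below their baseline.

Staging uses the ratio of the peak creatinine over the whole stay to the
baseline (1: >=1.5x or absolute-rise entry, 2: >=2x, 3: >=3x), with the
absolute high-creatinine tier at 354 µmol/L and, for AKIN and KDIGO only,
automatic stage 3 when renal replacement therapy was started. All threshold
comparisons are inclusive (>=). Onset is the earliest time a qualifying
clause fires; when several clauses fire at the same time the trigger label
follows the fixed precedence absolute_48h > relative_48h > relative_7d.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .baseline import BaselineEstimate
from .cohort import Cohort, DETECTION_WINDOW_HOURS, IntegrityError

__all__ = [
    "CRITERIA",
    "ABSOLUTE_RISE_UMOL",
    "RELATIVE_RISE_FACTOR",
    "HIGH_SCR_TIER_UMOL",
    "RIFLE_TIER_RISE_UMOL",
    "PAIR_WINDOW_HOURS",
    "AKIClassification",
    "ClassificationRow",
    "ClassificationTable",
    "detect_rifle",
    "detect_akin",
    "detect_kdigo",
    "stage_classification",
    "classify_patient",
    "classify_cohort",
]

CRITERIA = ("RIFLE", "AKIN", "KDIGO")

#: Absolute 48-h rise threshold, 0.3 mg/dL expressed in µmol/L.
ABSOLUTE_RISE_UMOL = 26.5
#: Relative rise threshold shared by all three criteria.
RELATIVE_RISE_FACTOR = 1.5
#: Absolute creatinine tier that escalates to the top stage.
HIGH_SCR_TIER_UMOL = 354.0
#: Acute-rise requirement attached to RIFLE's 354 µmol/L tier.
RIFLE_TIER_RISE_UMOL = 44.0
#: AKIN/KDIGO pair window.
PAIR_WINDOW_HOURS = 48.0

_TRIGGER_PRECEDENCE = {"absolute_48h": 0, "relative_48h": 1, "relative_7d": 2}


@dataclass(frozen=True)
class AKIClassification:
    """Detection flag, stage and onset for one patient under one criterion."""

    criterion: str
    detected: bool
    stage: int
    onset_hours: Optional[float] = None
    trigger: Optional[str] = None

    def __post_init__(self) -> None:
        if self.criterion not in CRITERIA:
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if self.detected != (self.stage >= 1):
            raise ValueError("detected must be equivalent to stage >= 1")
        if self.detected and self.onset_hours is None:
            raise ValueError("detected classifications need an onset time")
        if not self.detected and self.onset_hours is not None:
            raise ValueError("undetected classifications cannot carry an onset")


def _pair_matrix(t: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Masks of ordered in-window pairs and their rises/ratios."""
    dt = t[None, :] - t[:, None]  # dt[i, j] = t_j - t_i
    ordered = (dt > 0) & (dt <= PAIR_WINDOW_HOURS)
    rise = v[None, :] - v[:, None]
    ratio = v[None, :] / v[:, None]
    return ordered, rise, ratio


def detect_rifle(
    times: np.ndarray,
    values: np.ndarray,
    baseline: float,
    window_hours: float = DETECTION_WINDOW_HOURS,
) -> tuple[bool, Optional[float]]:
    """RIFLE detection: any measurement >= 1.5x baseline within the window."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    mask = (t >= 0) & (t <= window_hours)
    hit = mask & (v >= RELATIVE_RISE_FACTOR * baseline)
    if not hit.any():
        return False, None
    return True, float(t[hit].min())


def detect_akin(
    times: np.ndarray,
    values: np.ndarray,
    window_hours: float = PAIR_WINDOW_HOURS,
    horizon_hours: float = DETECTION_WINDOW_HOURS,
    relative_reference: str = "pair",
    baseline: Optional[float] = None,
) -> tuple[bool, Optional[float], Optional[str]]:
    """AKIN detection over ordered measurement pairs within 48 h.

    With ``relative_reference="pair"`` (default) the relative clause compares
    the later pair member to the earlier one; with ``"baseline"`` it requires
    a rise within the pair window to a value >= 1.5x the supplied baseline.
    """
    if relative_reference not in ("pair", "baseline"):
        raise ValueError(f"unknown relative_reference {relative_reference!r}")
    if relative_reference == "baseline" and baseline is None:
        raise ValueError("baseline reference requires a baseline value")
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    keep = (t >= 0) & (t <= horizon_hours)
    t, v = t[keep], v[keep]
    if t.size < 2:
        return False, None, None
    ordered, rise, ratio = _pair_matrix(t, v)
    abs_hit = ordered & (rise >= ABSOLUTE_RISE_UMOL)
    if relative_reference == "pair":
        rel_hit = ordered & (ratio >= RELATIVE_RISE_FACTOR)
    else:
        later_high = v[None, :] >= RELATIVE_RISE_FACTOR * baseline
        rel_hit = ordered & later_high & (rise > 0)
    return _earliest_pair_hit(t, abs_hit, rel_hit, "relative_48h")


def _earliest_pair_hit(
    t: np.ndarray,
    abs_hit: np.ndarray,
    rel_hit: np.ndarray,
    rel_label: str,
) -> tuple[bool, Optional[float], Optional[str]]:
    abs_times = t[abs_hit.any(axis=0)]
    rel_times = t[rel_hit.any(axis=0)]
    t_abs = abs_times.min() if abs_times.size else np.inf
    t_rel = rel_times.min() if rel_times.size else np.inf
    if not np.isfinite(min(t_abs, t_rel)):
        return False, None, None
    if t_abs <= t_rel:  # absolute clause wins ties
        return True, float(t_abs), "absolute_48h"
    return True, float(t_rel), rel_label


def detect_kdigo(
    times: np.ndarray,
    values: np.ndarray,
    baseline: float,
    window_hours: float = DETECTION_WINDOW_HOURS,
) -> tuple[bool, Optional[float], Optional[str]]:
    """KDIGO detection: 48-h absolute pair clause OR 7-day relative clause."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    keep = (t >= 0) & (t <= window_hours)
    t, v = t[keep], v[keep]
    if t.size == 0:
        return False, None, None
    if t.size >= 2:
        ordered, rise, _ = _pair_matrix(t, v)
        abs_hit = ordered & (rise >= ABSOLUTE_RISE_UMOL)
        abs_times = t[abs_hit.any(axis=0)]
    else:
        abs_times = np.array([])
    rel_times = t[v >= RELATIVE_RISE_FACTOR * baseline]
    t_abs = abs_times.min() if abs_times.size else np.inf
    t_rel = rel_times.min() if rel_times.size else np.inf
    if not np.isfinite(min(t_abs, t_rel)):
        return False, None, None
    if t_abs <= t_rel:
        return True, float(t_abs), "absolute_48h"
    return True, float(t_rel), "relative_7d"


def _peak_and_prior_min(
    times: np.ndarray, values: np.ndarray
) -> tuple[float, Optional[float]]:
    """Stay peak and the minimum value measured strictly before the peak."""
    i_peak = int(np.argmax(values))
    peak_time = times[i_peak]
    earlier = values[times < peak_time]
    prior_min = float(earlier.min()) if earlier.size else None
    return float(values[i_peak]), prior_min


def stage_classification(
    criterion: str,
    times_stay: np.ndarray,
    values_stay: np.ndarray,
    baseline: float,
    detected: bool,
    onset_hours: Optional[float],
    trigger: Optional[str],
    rrt_started: bool = False,
) -> AKIClassification:
    """Assign a stage given a detection result.

    ``times_stay``/``values_stay`` must cover the whole hospitalization
    (detection itself is restricted to the first 7 days); the stage ratio is
    peak over baseline. The 354 µmol/L tier additionally requires an acute
    rise for RIFLE (>= 44 µmol/L above the minimum earlier in-stay value) and
    AKIN (>= 26.5 µmol/L); for KDIGO reaching the tier suffices. RRT forces
    stage 3 under AKIN and KDIGO but not RIFLE.
    """
    if criterion not in CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}")
    if not detected:
        return AKIClassification(criterion, False, 0)
    t = np.asarray(times_stay, dtype=float)
    v = np.asarray(values_stay, dtype=float)
    if t.size == 0:
        raise IntegrityError("detected AKI but empty in-stay series")
    peak, prior_min = _peak_and_prior_min(t, v)
    ratio = peak / baseline
    rise_to_peak = peak - prior_min if prior_min is not None else 0.0

    if criterion == "RIFLE":
        tier = peak >= HIGH_SCR_TIER_UMOL and rise_to_peak >= RIFLE_TIER_RISE_UMOL
        stage3 = ratio >= 3 or tier
    elif criterion == "AKIN":
        tier = peak >= HIGH_SCR_TIER_UMOL and rise_to_peak >= ABSOLUTE_RISE_UMOL
        stage3 = ratio >= 3 or tier or rrt_started
    else:  # KDIGO
        stage3 = ratio >= 3 or peak >= HIGH_SCR_TIER_UMOL or rrt_started
    if stage3:
        stage = 3
    elif ratio >= 2:
        stage = 2
    else:
        stage = 1
    return AKIClassification(criterion, True, stage, onset_hours, trigger)


@dataclass(frozen=True)
class ClassificationRow:
    baseline: BaselineEstimate
    rifle: AKIClassification
    akin: AKIClassification
    kdigo: AKIClassification

    def get(self, criterion: str) -> AKIClassification:
        return {"RIFLE": self.rifle, "AKIN": self.akin, "KDIGO": self.kdigo}[criterion]


@dataclass
class ClassificationTable:
    """Per-patient classifications under all three criteria."""

    rows: dict[str, ClassificationRow]

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        """Flat table mirroring ``classifications.csv``."""
        records = []
        for pid, row in self.rows.items():
            rec = {
                "patient_id": pid,
                "baseline_umol": row.baseline.value_umol,
                "baseline_source": row.baseline.source,
            }
            for name, cls in (("rifle", row.rifle), ("akin", row.akin), ("kdigo", row.kdigo)):
                rec[f"{name}_stage"] = cls.stage
                rec[f"onset_hours_{name}"] = cls.onset_hours
                rec[f"trigger_{name}"] = cls.trigger
            records.append(rec)
        return pd.DataFrame.from_records(records)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def classify_patient(
    record,
    baseline: BaselineEstimate | float,
    relative_reference: str = "pair",
    detection_window_hours: float = DETECTION_WINDOW_HOURS,
) -> ClassificationRow:
    """Run all three criteria for one patient."""
    if isinstance(baseline, BaselineEstimate):
        estimate = baseline
    else:
        estimate = BaselineEstimate(float(baseline), "admission")
    b = estimate.value_umol
    t7, v7 = record.series_arrays(0.0, detection_window_hours)
    if t7.size == 0:
        raise IntegrityError(
            f"patient {record.patient_id}: no measurement within the detection window"
        )
    t_stay, v_stay = record.series_arrays(0.0, record.outcome_time_hours)
    if t_stay.size == 0:
        # a patient measured only inside the window but after the recorded
        # outcome would be inconsistent; fall back to the window series
        t_stay, v_stay = t7, v7

    r_det, r_onset = detect_rifle(t7, v7, b, detection_window_hours)
    a_det, a_onset, a_trig = detect_akin(
        t7, v7, horizon_hours=detection_window_hours,
        relative_reference=relative_reference, baseline=b,
    )
    k_det, k_onset, k_trig = detect_kdigo(t7, v7, b, detection_window_hours)

    rifle = stage_classification(
        "RIFLE", t_stay, v_stay, b, r_det, r_onset,
        "relative_7d" if r_det else None, record.rrt_started,
    )
    akin = stage_classification(
        "AKIN", t_stay, v_stay, b, a_det, a_onset, a_trig, record.rrt_started
    )
    kdigo = stage_classification(
        "KDIGO", t_stay, v_stay, b, k_det, k_onset, k_trig, record.rrt_started
    )
    return ClassificationRow(estimate, rifle, akin, kdigo)


def classify_cohort(
    cohort: Cohort,
    baselines: dict[str, BaselineEstimate],
    relative_reference: str = "pair",
    detection_window_hours: float = DETECTION_WINDOW_HOURS,
) -> ClassificationTable:
    """Classify every patient; deterministic given its inputs."""
    rows = {}
    for p in cohort:
        if p.patient_id not in baselines:
            raise IntegrityError(f"no baseline estimate for patient {p.patient_id}")
        rows[p.patient_id] = classify_patient(
            p, baselines[p.patient_id], relative_reference, detection_window_hours
        )
    return ClassificationTable(rows=rows)
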