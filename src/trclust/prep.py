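"""Serial depression-rating preparation.

Turns raw HAM-D visit records into complete, ln-transformed weekly
trajectories.  Scores are transformed as ln(score + 0.5); interior missing
visits are linearly interpolated on the raw scale between the nearest
observed neighbours, and the series is truncated at the last observed week
(no extrapolation).  Weeks are 0-based with baseline = week 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: Scheduled visit weeks per study design.  MARS rates weekly to week 6 then
#: bi-weekly to week 16 (21-item HAM-D, max 63); GENDEP rates weekly to
#: week 12 (17-item HAM-D, max 52).
DESIGN_WEEKS = {
    "MARS": (0, 1, 2, 3, 4, 5, 6, 8, 10, 12, 14, 16),
    "GENDEP": tuple(range(13)),
}
DESIGN_MAX_RAW = {"MARS": 63, "GENDEP": 52}

ELIGIBILITY_MIN_BASELINE = 14  # patients with baseline HAM-D < 14 are excluded
REMISSION_THRESHOLD = 10       # HAM-D < 10 at discharge


def transform_score(raw) -> float:
    """ln(raw + 0.5) for a non-negative HAM-D total (scalar or array)."""
    arr = np.asarray(raw, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ValueError("HAM-D scores must be non-negative")
    out = np.log(arr + 0.5)
    return float(out) if np.isscalar(raw) or arr.ndim == 0 else out


def inverse_transform(lnval, max_raw: int = 63):
    """Back-transform: round(exp(y) - 0.5), clipped to [0, max_raw]."""
    raw = np.round(np.exp(np.asarray(lnval, dtype=float)) - 0.5)
    raw = np.clip(raw, 0, max_raw)
    return float(raw) if np.isscalar(lnval) else raw


@dataclass
class RatingSeries:
    """One patient's visit grid.

    ``raw`` is float with NaN marking missing scores; ``lnvals`` is populated
    by :func:`regularize_grid` on the complete weekly grid 0..last_week.
    """

    patient_id: str
    weeks: np.ndarray
    raw: np.ndarray
    lnvals: Optional[np.ndarray] = None

    def __post_init__(self):
        self.weeks = np.asarray(self.weeks, dtype=int)
        self.raw = np.asarray(self.raw, dtype=float)
        if self.weeks.shape != self.raw.shape:
            raise ValueError("weeks and raw must have equal length")
        if len(self.weeks) == 0:
            raise ValueError("empty rating series")
        if np.any(np.diff(self.weeks) <= 0):
            raise ValueError("weeks must be strictly increasing")
        if self.lnvals is not None:
            self.lnvals = np.asarray(self.lnvals, dtype=float)

    @property
    def last_week(self) -> int:
        return int(self.weeks[-1])

    @property
    def baseline_raw(self) -> float:
        """Raw score at week 0 (NaN if week 0 absent or missing)."""
        if self.weeks[0] != 0:
            return float("nan")
        return float(self.raw[0])

    @property
    def n_observed(self) -> int:
        return int(np.sum(~np.isnan(self.raw)))

    @property
    def usable(self) -> bool:
        """At least two observed visits (needed for any slope information)."""
        return self.n_observed >= 2


@dataclass
class Cohort:
    series: list
    design: str = "MARS"

    def __post_init__(self):
        if self.design not in DESIGN_WEEKS:
            raise ValueError(f"unknown design {self.design!r}")
        ids = [s.patient_id for s in self.series]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate patient_ids in cohort")

    def __len__(self) -> int:
        return len(self.series)

    @property
    def patient_ids(self):
        return [s.patient_id for s in self.series]


@dataclass
class Exclusion:
    patient_id: str
    reason: str


def filter_eligible(cohort: Cohort):
    """Retain patients with an observed baseline raw score >= 14.

    Returns (filtered cohort, exclusion report).  Patients without a week-0
    record (or with a missing baseline score) are excluded with reason
    "no baseline".
    """
    kept, report = [], []
    for s in cohort.series:
        b = s.baseline_raw
        if np.isnan(b):
            report.append(Exclusion(s.patient_id, "no baseline"))
        elif b < ELIGIBILITY_MIN_BASELINE:
            report.append(Exclusion(s.patient_id, f"baseline {int(b)} < {ELIGIBILITY_MIN_BASELINE}"))
        else:
            kept.append(s)
    return Cohort(kept, cohort.design), report


def regularize_grid(series: RatingSeries) -> RatingSeries:
    """Complete a series on the integer weekly grid 0..last observed week.

    Missing interior values (skipped bi-weekly visits, accidental gaps) are
    linearly interpolated on the raw scale between the nearest observed
    neighbours, then ln-transformed.  Trailing missing values truncate the
    series at the last observed week; observed values are never altered.
    """
    obs = ~np.isnan(series.raw)
    if series.weeks[0] != 0 or not obs[0]:
        raise ValueError(f"patient {series.patient_id}: baseline (week 0) must be observed")
    if not np.any(obs):
        raise ValueError(f"patient {series.patient_id}: no observed visits")
    ow = series.weeks[obs].astype(float)
    ov = series.raw[obs]
    last = int(ow[-1])
    grid = np.arange(last + 1)
    raw_full = np.interp(grid, ow, ov)
    return RatingSeries(
        patient_id=series.patient_id,
        weeks=grid,
        raw=raw_full,
        lnvals=np.log(raw_full + 0.5),
    )


def regularize_cohort(cohort: Cohort) -> Cohort:
    return Cohort([regularize_grid(s) for s in cohort.series], cohort.design)
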