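"""Diagnostic-procedure classification and diagnosis dating.

The date of first treatment is the earliest of the index surgery and any
neoadjuvant course start.  The diagnosis date is then fixed by precedence:
earliest core biopsy in the year before first treatment; failing that the
earliest fine-needle cytology in the same window; failing that a backward
walk through breast imaging procedures separated by at most a month; and
finally the first-treatment date itself when no diagnostic procedure was
recorded.  Ages are rounded whole-year differences on a 365.25-day year.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

from .treatment_engine import SETTING_BOTH, SETTING_NEO, SETTING_NEO_THEN_ADJ, TreatmentCourse

_NEO_SETTINGS = (SETTING_NEO, SETTING_BOTH, SETTING_NEO_THEN_ADJ)


def first_treatment_date(courses: Iterable[TreatmentCourse], index_day: int) -> int:
    """Minimum of the index surgery day and the start days of courses with a
    neoadjuvant component."""
    candidates = [index_day]
    for c in courses:
        if c.received and c.setting in _NEO_SETTINGS and c.start_day is not None:
            candidates.append(c.start_day)
    return min(candidates)


def diagnosis_date(
    biopsy_days: Sequence[int],
    cytology_days: Sequence[int],
    imaging_days: Sequence[int],
    first_treatment_day: int,
    window_days: int = 365,
    month_days: int = 30,
):
    """Return ``(mode, day)`` with mode in {biopsy, cytology, imaging_only,
    none}.

    Biopsy/cytology windows are closed: [first treatment - window_days,
    first treatment].  The imaging chain anchors at the imaging event closest
    to (and not after) first treatment and walks backward while consecutive
    gaps are at most *month_days*, returning the earliest event reached.
    """
    lo = first_treatment_day - window_days
    for mode, days in (("biopsy", biopsy_days), ("cytology", cytology_days)):
        in_win = [d for d in days if lo <= d <= first_treatment_day]
        if in_win:
            return mode, min(in_win)
    anchors = sorted(d for d in imaging_days if d <= first_treatment_day)
    if anchors:
        current = anchors[-1]
        for prev in reversed(anchors[:-1]):
            if current - prev > month_days:
                break
            current = prev
        return "imaging_only", current
    return "none", first_treatment_day


def age_in_years(birth_day: int, later_day: int) -> int:
    """Rounded (half-up) difference in years on a 365.25-day year."""
    days = later_day - birth_day
    if days < 0:
        raise ValueError("date precedes birth date")
    return int(math.floor(days / 365.25 + 0.5))


def age_at_diagnosis(birth_day: int, diagnosis_day: int) -> int:
    return age_in_years(birth_day, diagnosis_day)
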