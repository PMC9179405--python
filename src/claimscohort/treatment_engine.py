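"""Temporal treatment detection around the index surgery.

Every modality is detected inside a fixed day window relative to the index
surgery date (radiotherapy [-150, +365]; chemotherapy, anti-HER2 targeted
therapy and nodal-status codes [-250, +180]; windows are closed on both
ends).  Sessions strictly before the index date form the neoadjuvant
component, sessions on or after it the adjuvant component.  All functions
here work on plain integer day offsets (days since an arbitrary epoch) so
they are trivially unit-testable; the pipeline converts calendar dates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

SURGERY_CATEGORIES = (
    "mastectomy_with_axillary",
    "mastectomy_without_axillary",
    "partial_with_axillary",
    "partial_without_axillary",
    "axillary_only",
)

#: Categories that can define the index surgery (axillary-only cannot).
BREAST_SURGERY_CATEGORIES = SURGERY_CATEGORIES[:4]

SETTING_NEO = "neoadjuvant"
SETTING_ADJ = "adjuvant"
SETTING_BOTH = "both"
SETTING_NEO_THEN_ADJ = "neoadjuvant_then_adjuvant"
SETTING_NONE = "none"

CT_REGIMENS = (
    "anthracyclines",
    "anthracyclines/docetaxel",
    "anthracyclines/paclitaxel",
    "docetaxel",
    "paclitaxel",
    "other",
    "unknown",
)

ET_REGIMENS = (
    "tamoxifen",
    "tamoxifen_with_gnrh",
    "tamoxifen_then_ai",
    "ai",
    "ai_with_gnrh",
    "ai_then_tamoxifen",
    "others",
)

TT_REGIMENS = ("trastuzumab", "pertuzumab±trastuzumab")

TT_COMBINATIONS = (
    "anthracyclines/docetaxel-TT",
    "anthracyclines/paclitaxel-TT",
    "docetaxel-TT",
    "paclitaxel-TT(Tolaney)",
    "TT-ET",
    "other",
)


@dataclass(frozen=True)
class TreatmentWindows:
    """Closed day windows relative to index surgery, (lower, upper)."""

    rt: tuple = (-150, 365)
    ct: tuple = (-250, 180)
    tt: tuple = (-250, 180)
    node: tuple = (-250, 180)

    def __post_init__(self):
        for name in ("rt", "ct", "tt", "node"):
            lo, hi = getattr(self, name)
            if not (lo < 0 < hi):
                raise ValueError(f"window {name} must straddle the index date: {(lo, hi)}")


@dataclass(frozen=True)
class SurgeryEvent:
    day: int
    category: str

    def __post_init__(self):
        if self.category not in SURGERY_CATEGORIES:
            raise ValueError(f"unknown surgery category {self.category!r}")


@dataclass
class TreatmentCourse:
    """One modality's detected course."""

    modality: str
    received: bool = False
    setting: str = SETTING_NONE
    start_day: int | None = None
    end_day: int | None = None
    regimen: str | None = None
    n_cycles_by_setting: dict = field(default_factory=dict)


class NoIndexSurgeryError(ValueError):
    """No qualifying breast surgery: the patient should have been filtered."""


def _mastectomy(cat: str) -> bool:
    return cat.startswith("mastectomy")


def _axillary(cat: str) -> bool:
    return cat.endswith("with_axillary") or cat == "axillary_only"


def find_index_surgery(
    surgeries: Iterable[SurgeryEvent],
    inclusion_day: int,
    inclusion_year_start_day: int,
    lookahead_days: int = 365,
):
    """Index surgery = earliest breast-surgery event (axillary-only excluded)
    between the start of the inclusion year and inclusion + *lookahead_days*.

    Returns ``(index_day, in_window_surgeries)`` where the second element
    contains every surgery event (all five categories) falling in the same
    window, for patient-level type binning.
    """
    surgeries = sorted(surgeries, key=lambda s: s.day)
    lo, hi = inclusion_year_start_day, inclusion_day + lookahead_days
    in_window = [s for s in surgeries if lo <= s.day <= hi]
    qualifying = [s for s in in_window if s.category in BREAST_SURGERY_CATEGORIES]
    if not qualifying:
        raise NoIndexSurgeryError("no breast surgery in the index window")
    return qualifying[0].day, in_window


def bin_surgery(surgeries: Sequence[SurgeryEvent]):
    """Patient-level binning over all index-window surgery events: the most
    extensive procedure wins (any mastectomy => mastectomy; any axillary
    component => axillary surgery yes)."""
    if not surgeries:
        raise ValueError("bin_surgery needs at least one surgery event")
    breast = "mastectomy" if any(_mastectomy(s.category) for s in surgeries) else "partial"
    axillary = any(_axillary(s.category) for s in surgeries)
    return breast, axillary


def assign_setting(session_days: Sequence[int], index_day: int, modality: str) -> str:
    """Sessions strictly before the index day form the neoadjuvant component,
    on/after it the adjuvant component.  RT/CT use {neoadjuvant, adjuvant,
    both}; ET/TT use {neoadjuvant_then_adjuvant, adjuvant}."""
    days = np.asarray(list(session_days))
    if days.size == 0:
        raise ValueError("assign_setting needs at least one session")
    has_neo = bool((days < index_day).any())
    has_adj = bool((days >= index_day).any())
    if modality in ("ET", "TT"):
        return SETTING_NEO_THEN_ADJ if has_neo else SETTING_ADJ
    if has_neo and has_adj:
        return SETTING_BOTH
    return SETTING_NEO if has_neo else SETTING_ADJ


def detect_windowed_modality(
    session_days: Sequence[int],
    index_day: int,
    window: tuple,
    modality: str,
) -> TreatmentCourse:
    """Detect RT, CT or TT: received iff at least one session falls in the
    closed window around index surgery; start/end are the first/last
    in-window sessions."""
    days = np.sort(np.asarray(list(session_days), dtype=int))
    lo, hi = window
    offs = days - index_day
    in_win = days[(offs >= lo) & (offs <= hi)]
    if in_win.size == 0:
        return TreatmentCourse(modality=modality)
    return TreatmentCourse(
        modality=modality,
        received=True,
        setting=assign_setting(in_win, index_day, modality),
        start_day=int(in_win[0]),
        end_day=int(in_win[-1]),
    )


def classify_ct_regimen(molecule_classes: Iterable[str]) -> str:
    """Seven-way chemotherapy regimen from the molecule classes observed on
    in-window sessions.

    ``molecule_classes`` holds labels among {"anthracycline", "docetaxel",
    "paclitaxel", "other"}.  No molecule codes at all => "unknown" (sessions
    coded without an identifiable molecule); any combination outside the five
    named taxane/anthracycline patterns => "other".
    """
    classes = set(molecule_classes)
    if not classes:
        return "unknown"
    a = "anthracycline" in classes
    d = "docetaxel" in classes
    p = "paclitaxel" in classes
    o = "other" in classes
    if o:
        return "other"
    if p and d:
        return "other"
    if p and a:
        return "anthracyclines/paclitaxel"
    if p:
        return "paclitaxel"
    if d and a:
        return "anthracyclines/docetaxel"
    if d:
        return "docetaxel"
    return "anthracyclines"


def count_cycles(
    session_days: Sequence[int], index_day: int, merge_gap: int = 7
) -> dict:
    """Merge sessions into cycles separately within each setting component: a
    session starts a new cycle iff it falls at least *merge_gap* days after
    the previous session (spill-over administrations merge)."""
    days = np.sort(np.asarray(list(session_days), dtype=int))
    out = {}
    for setting, part in (
        (SETTING_NEO, days[days < index_day]),
        (SETTING_ADJ, days[days >= index_day]),
    ):
        if part.size == 0:
            continue
        out[setting] = 1 + int((np.diff(part) >= merge_gap).sum())
    return out


def detect_endocrine_therapy(
    dispensings: Sequence[tuple],
    index_day: int,
    observation_end_day: int,
    ct_start_day: int | None = None,
    lookback_days: int = 250,
    pack_days: int = 30,
    fertility_window_days: int = 30,
) -> TreatmentCourse:
    """Detect endocrine therapy from outpatient (day, molecule) dispensings,
    with molecule in {"tamoxifen", "ai", "gnrh"}.

    Received iff at least one dispensing lies in [index - lookback_days,
    observation end], after discarding deliveries attributable to fertility
    preservation: GnRH-agonist deliveries in the *fertility_window_days* days
    before chemotherapy start, for patients with no tamoxifen/AI delivery
    ever.  The course end is the last dispensing plus one pack (*pack_days*).
    """
    disp = sorted(dispensings)
    has_tam_or_ai = any(m in ("tamoxifen", "ai") for _, m in disp)
    if not has_tam_or_ai and ct_start_day is not None:
        disp = [
            (d, m)
            for d, m in disp
            if not (
                m == "gnrh" and ct_start_day - fertility_window_days <= d < ct_start_day
            )
        ]
    days = [d for d, _ in disp if index_day - lookback_days <= d <= observation_end_day]
    if not days:
        return TreatmentCourse(modality="ET")
    return TreatmentCourse(
        modality="ET",
        received=True,
        setting=assign_setting(days, index_day, "ET"),
        start_day=min(days),
        end_day=max(days) + pack_days,
    )


def classify_et_regimen(dispensings: Sequence[tuple]) -> str:
    """Seven-way endocrine-therapy regimen over the whole study period.

    "Followed by" requires a single switch: every delivery of the first
    molecule precedes every delivery of the second.  GnRH-agonists alone,
    three-molecule patterns, and interleaved tamoxifen/AI sequences fall in
    "others".
    """
    tam = [d for d, m in dispensings if m == "tamoxifen"]
    ai = [d for d, m in dispensings if m == "ai"]
    gnrh = [d for d, m in dispensings if m == "gnrh"]
    if tam and not ai and not gnrh:
        return "tamoxifen"
    if ai and not tam and not gnrh:
        return "ai"
    if tam and gnrh and not ai:
        return "tamoxifen_with_gnrh"
    if ai and gnrh and not tam:
        return "ai_with_gnrh"
    if tam and ai and not gnrh:
        if max(tam) < min(ai):
            return "tamoxifen_then_ai"
        if max(ai) < min(tam):
            return "ai_then_tamoxifen"
    return "others"


def classify_tt(molecules: Iterable[str]) -> str:
    """Two-way targeted-therapy regimen: any pertuzumab delivery (with or
    without trastuzumab) forms its own class."""
    return "pertuzumab±trastuzumab" if "pertuzumab" in set(molecules) else "trastuzumab"


def _overlap(a: TreatmentCourse, b: TreatmentCourse) -> bool:
    """Date-range overlap of at least one day between two courses."""
    if not (a.received and b.received):
        return False
    return a.start_day <= b.end_day and b.start_day <= a.end_day


def classify_tt_combination(
    tt_course: TreatmentCourse,
    ct_course: TreatmentCourse,
    et_course: TreatmentCourse,
) -> str:
    """Six-way classification of TT combined with systemic treatment:
    anthracycline phase then concurrent docetaxel/paclitaxel + TT (classes 1
    and 2), docetaxel + TT throughout (3), paclitaxel + TT without
    anthracyclines (4, the Tolaney regimen), TT with ET and no chemotherapy
    (5), residual combinations (6, "other")."""
    if not tt_course.received:
        raise ValueError("TT combination requires a received TT course")
    if not ct_course.received:
        return "TT-ET" if et_course.received else "other"
    if not _overlap(tt_course, ct_course):
        return "other"
    regimen = ct_course.regimen
    if regimen == "anthracyclines/docetaxel":
        return "anthracyclines/docetaxel-TT"
    if regimen == "anthracyclines/paclitaxel":
        return "anthracyclines/paclitaxel-TT"
    if regimen == "docetaxel":
        return "docetaxel-TT"
    if regimen == "paclitaxel":
        return "paclitaxel-TT(Tolaney)"
    return "other"
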