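"""Treatment-based subtype inference, nodal status, and care pathways.

Claims carry no tumor histology, so the molecular subtype is inferred from
the specificity of the treatments received: anti-HER2 targeted therapy marks
HER2+ disease (split by endocrine therapy into HR+ and HR-), endocrine
therapy without TT marks luminal disease, chemotherapy alone marks
triple-negative disease, and patients treated by surgery with or without
radiotherapy only remain of undefined subtype.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np

from .treatment_engine import (
    SETTING_ADJ,
    SETTING_BOTH,
    SETTING_NEO,
    SETTING_NEO_THEN_ADJ,
    TreatmentCourse,
)

SUBTYPES = ("luminal", "TNBC", "HER2+/HR+", "HER2+/HR-", "undefined")

MAIN_PATHWAYS = ("surgery_no_CT", "surgery_then_CT", "NAC", "NRT", "NET")

#: Table-style age bins: right-open except the last.
AGE_CLASS_EDGES = (0, 30, 40, 50, 60, 70, 80)
AGE_CLASSES = ("(0-30)", "(30-40)", "(40-50)", "(50-60)", "(60-70)", "(70-80)", "80+")

#: Canonical 9-slot order used to display treatment sequences.
SEQUENCE_SLOTS = (
    "NAC",
    "NTT",
    "NRT",
    "NET",
    "surgery",
    "adjCT",
    "adjTT",
    "adjRT",
    "adjET",
)


def infer_subtype(ct: bool, et: bool, tt: bool) -> str:
    """Total function on the 8-cell (ct, et, tt) truth table."""
    if tt:
        return "HER2+/HR+" if et else "HER2+/HR-"
    if et:
        return "luminal"
    if ct:
        return "TNBC"
    return "undefined"


def nodal_status(node_code_days: Iterable[int], index_day: int, window=(-250, 180)) -> bool:
    """Node-positive iff at least one node-disease diagnosis code falls in the
    closed window around index surgery."""
    lo, hi = window
    return any(lo <= d - index_day <= hi for d in node_code_days)


def age_class(age: int) -> str:
    if age < 0:
        raise ValueError("negative age")
    for label, hi in zip(AGE_CLASSES[:-1], AGE_CLASS_EDGES[1:]):
        if age < hi:
            return label
    return AGE_CLASSES[-1]


def _has_neo(course: TreatmentCourse) -> bool:
    return course.received and course.setting in (
        SETTING_NEO,
        SETTING_BOTH,
        SETTING_NEO_THEN_ADJ,
    )


def _has_adj(course: TreatmentCourse) -> bool:
    # Continuation of a neoadjuvant ET/TT course after surgery does not
    # constitute adjuvant therapy; only RT/CT can be "both".
    return course.received and course.setting in (SETTING_ADJ, SETTING_BOTH)


def assign_main_pathway(courses: Mapping[str, TreatmentCourse]) -> str:
    """Main care pathway with precedence NAC > NRT > NET; patients with no
    neoadjuvant therapy split on adjuvant chemotherapy.

    NAC absorbs any NRT/NET status; NRT+NET counts as NRT (a rare fifth
    class, reported separately from the four main pathways).
    """
    ct, rt, et = courses["CT"], courses["RT"], courses["ET"]
    if _has_neo(ct):
        return "NAC"
    if _has_neo(rt):
        return "NRT"
    if _has_neo(et):
        return "NET"
    return "surgery_then_CT" if _has_adj(ct) else "surgery_no_CT"


def derive_sequence(courses: Mapping[str, TreatmentCourse]) -> list:
    """Canonical ordered treatment-sequence labels over the 9 display slots.

    A neoadjuvant-then-adjuvant ET/TT course fills only its neoadjuvant slot
    (post-surgery continuation is not adjuvant therapy); a both-setting RT/CT
    course fills both of its slots.
    """
    ct, rt, et, tt = courses["CT"], courses["RT"], courses["ET"], courses["TT"]
    present = {
        "NAC": _has_neo(ct),
        "NTT": _has_neo(tt),
        "NRT": _has_neo(rt),
        "NET": _has_neo(et),
        "surgery": True,
        "adjCT": _has_adj(ct),
        "adjTT": _has_adj(tt),
        "adjRT": _has_adj(rt),
        "adjET": _has_adj(et),
    }
    return [slot for slot in SEQUENCE_SLOTS if present[slot]]
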