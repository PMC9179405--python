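"""Windowed detection, setting assignment, regimen classifiers, cycles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from claimscohort.treatment_engine import (
    CT_REGIMENS,
    ET_REGIMENS,
    NoIndexSurgeryError,
    SurgeryEvent,
    TreatmentCourse,
    TreatmentWindows,
    assign_setting,
    bin_surgery,
    classify_ct_regimen,
    classify_et_regimen,
    classify_tt,
    classify_tt_combination,
    count_cycles,
    detect_endocrine_therapy,
    detect_windowed_modality,
    find_index_surgery,
)

W = TreatmentWindows()


# --- index surgery and binning ---------------------------------------------


def test_index_is_earliest_qualifying_breast_surgery():
    surgeries = [SurgeryEvent(0, "partial_without_axillary"),
                 SurgeryEvent(40, "mastectomy_with_axillary")]
    index, _ = find_index_surgery(surgeries, inclusion_day=-30, inclusion_year_start_day=-60)
    assert index == 0


def test_axillary_only_never_defines_the_index():
    surgeries = [SurgeryEvent(-10, "axillary_only"),
                 SurgeryEvent(5, "partial_with_axillary")]
    index, in_window = find_index_surgery(surgeries, -30, -60)
    assert index == 5
    assert len(in_window) == 2  # but it still participates in binning


def test_same_day_partial_and_total_bins_to_mastectomy():
    surgeries = [SurgeryEvent(10, "partial_without_axillary"),
                 SurgeryEvent(10, "mastectomy_without_axillary")]
    index, in_window = find_index_surgery(surgeries, 0, -30)
    assert index == 10
    assert bin_surgery(in_window) == ("mastectomy", False)


def test_no_qualifying_surgery_signals_ineligibility():
    with pytest.raises(NoIndexSurgeryError):
        find_index_surgery([SurgeryEvent(5, "axillary_only")], 0, -30)


def _brute_force_bin(categories):
    breast = "partial"
    axillary = False
    for c in categories:
        if c in ("mastectomy_with_axillary", "mastectomy_without_axillary"):
            breast = "mastectomy"
        if c in ("mastectomy_with_axillary", "partial_with_axillary", "axillary_only"):
            axillary = True
    return breast, axillary


@pytest.mark.parametrize("r", range(1, 4))
def test_binning_matches_decision_table_on_all_category_subsets(r):
    from claimscohort.treatment_engine import SURGERY_CATEGORIES

    for combo in itertools.combinations(SURGERY_CATEGORIES, r):
        events = [SurgeryEvent(i, c) for i, c in enumerate(combo)]
        assert bin_surgery(events) == _brute_force_bin(combo)


def test_binning_examples():
    assert bin_surgery([SurgeryEvent(0, "partial_without_axillary")]) == ("partial", False)
    assert bin_surgery([SurgeryEvent(0, "partial_with_axillary"),
                        SurgeryEvent(3, "mastectomy_without_axillary")]) == ("mastectomy", True)
    assert bin_surgery([SurgeryEvent(0, "partial_without_axillary"),
                        SurgeryEvent(3, "axillary_only")]) == ("partial", True)


# --- windowed detection and settings ---------------------------------------


@pytest.mark.parametrize(
    "days, window, modality, received, setting",
    [
        ([366], W.rt, "RT", False, None),              # just past the RT window
        ([365], W.rt, "RT", True, "adjuvant"),         # closed upper endpoint
        ([-150], W.rt, "RT", True, "neoadjuvant"),     # closed lower endpoint
        ([-250, 180], W.ct, "CT", True, "both"),       # CT window endpoints
        ([-251], W.ct, "CT", False, None),
        ([-300], W.tt, "TT", False, None),
        ([-30, 60], W.tt, "TT", True, "neoadjuvant_then_adjuvant"),
        ([0], W.ct, "CT", True, "adjuvant"),           # index-day session is adjuvant
    ],
)
def test_window_membership_and_setting(days, window, modality, received, setting):
    course = detect_windowed_modality(days, index_day=0, window=window, modality=modality)
    assert course.received is received
    if received:
        assert course.setting == setting
        assert course.start_day == min(days)
        assert course.end_day == max(days)


def test_assign_setting_examples():
    assert assign_setting([-90, -60, -30], 0, "CT") == "neoadjuvant"
    assert assign_setting([-90, 30], 0, "CT") == "both"
    assert assign_setting([-30, 60], 0, "TT") == "neoadjuvant_then_adjuvant"
    assert assign_setting([60], 0, "ET") == "adjuvant"


@settings(max_examples=100, derandomize=True)
@given(
    st.lists(st.integers(-400, 500), min_size=1, max_size=20),
    st.integers(-1000, 1000),
)
def test_classification_is_shift_invariant(days, shift):
    base = detect_windowed_modality(days, 0, W.ct, "CT")
    moved = detect_windowed_modality([d + shift for d in days], shift, W.ct, "CT")
    assert base.received == moved.received
    assert base.setting == moved.setting
    if base.received:
        assert moved.start_day - base.start_day == shift
        assert count_cycles(days, 0) == count_cycles([d + shift for d in days], shift)


@settings(max_examples=100, derandomize=True)
@given(st.lists(st.integers(-260, 190), min_size=1, max_size=30, unique=True))
def test_every_in_window_session_counted_in_exactly_one_setting(days):
    cycles = count_cycles(days, 0, merge_gap=1)  # gap 1: every session is a cycle
    n_neo = cycles.get("neoadjuvant", 0)
    n_adj = cycles.get("adjuvant", 0)
    assert n_neo + n_adj == len(days)


# --- chemotherapy regimen and cycles ---------------------------------------


def _brute_force_ct_regimen(classes):
    table = {
        frozenset(): "unknown",
        frozenset({"anthracycline"}): "anthracyclines",
        frozenset({"docetaxel"}): "docetaxel",
        frozenset({"paclitaxel"}): "paclitaxel",
        frozenset({"anthracycline", "docetaxel"}): "anthracyclines/docetaxel",
        frozenset({"anthracycline", "paclitaxel"}): "anthracyclines/paclitaxel",
    }
    return table.get(frozenset(classes), "other")


def test_ct_regimen_examples():
    assert classify_ct_regimen({"paclitaxel", "anthracycline"}) == "anthracyclines/paclitaxel"
    assert classify_ct_regimen(set()) == "unknown"
    assert classify_ct_regimen({"other"}) == "other"  # e.g. platinum-only coding


def test_ct_regimen_total_on_all_molecule_subsets():
    universe = ["anthracycline", "docetaxel", "paclitaxel", "other"]
    for r in range(len(universe) + 1):
        for combo in itertools.combinations(universe, r):
            result = classify_ct_regimen(set(combo))
            assert result in CT_REGIMENS
            assert result == _brute_force_ct_regimen(combo)


def test_cycle_counting_with_gap_merge():
    adj = [21 * k + 10 for k in range(6)]
    assert count_cycles(adj, 0) == {"adjuvant": 6}
    assert count_cycles([10, 12], 0) == {"adjuvant": 1}  # infusion spill-over
    both = [-63, -42, -21, 10, 31, 52]
    assert count_cycles(both, 0) == {"neoadjuvant": 3, "adjuvant": 3}


def _linear_scan_cycles(days, gap):
    days = sorted(days)
    n = 1
    for prev, cur in zip(days, days[1:]):
        if cur - prev >= gap:
            n += 1
    return n


@settings(max_examples=100, derandomize=True)
@given(st.lists(st.integers(1, 200), min_size=1, max_size=25), st.integers(2, 30))
def test_cycle_merge_matches_linear_scan(days, gap):
    assert count_cycles(days, 0, merge_gap=gap) == {"adjuvant": _linear_scan_cycles(days, gap)}


# --- endocrine therapy ------------------------------------------------------


def test_et_monthly_tamoxifen_is_adjuvant():
    disp = [(60 + 30 * k, "tamoxifen") for k in range(12)]
    course = detect_endocrine_therapy(disp, 0, 2000)
    assert course.received and course.setting == "adjuvant"
    assert course.end_day == disp[-1][0] + 30


def test_fertility_preservation_gnrh_discarded():
    # single GnRH delivery 10 days before chemotherapy start, no tamoxifen/AI ever
    course = detect_endocrine_therapy([(-130, "gnrh")], 0, 2000, ct_start_day=-120)
    assert not course.received
    # same delivery but with later tamoxifen: kept
    course = detect_endocrine_therapy(
        [(-130, "gnrh"), (60, "tamoxifen")], 0, 2000, ct_start_day=-120
    )
    assert course.received


def test_et_starting_before_surgery_is_neoadjuvant_then_adjuvant():
    disp = [(-60 + 30 * k, "ai") for k in range(10)]
    course = detect_endocrine_therapy(disp, 0, 2000)
    assert course.setting == "neoadjuvant_then_adjuvant"


def test_et_outside_lookback_not_received():
    course = detect_endocrine_therapy([(-260, "tamoxifen")], 0, 2000)
    assert not course.received


@pytest.mark.parametrize(
    "disp, expected",
    [
        ([(0, "tamoxifen"), (30, "tamoxifen")], "tamoxifen"),
        ([(0, "ai")], "ai"),
        ([(k * 30, "tamoxifen") for k in range(24)]
         + [(720 + k * 30, "ai") for k in range(36)], "tamoxifen_then_ai"),
        ([(0, "ai"), (30, "tamoxifen")], "ai_then_tamoxifen"),
        ([(0, "tamoxifen"), (30, "ai"), (60, "tamoxifen")], "others"),  # multi-switch
        ([(0, "tamoxifen"), (0, "gnrh")], "tamoxifen_with_gnrh"),
        ([(0, "ai"), (84, "gnrh")], "ai_with_gnrh"),
        ([(0, "gnrh")], "others"),  # GnRH agonists alone
        ([(0, "tamoxifen"), (30, "ai"), (60, "gnrh")], "others"),  # three molecules
        ([(0, "tamoxifen"), (15, "ai"), (30, "tamoxifen"), (45, "ai")], "others"),
    ],
)
def test_et_regimen_seven_way_classification(disp, expected):
    assert classify_et_regimen(disp) == expected


@settings(max_examples=200, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 500),
                          st.sampled_from(["tamoxifen", "ai", "gnrh"])),
                min_size=1, max_size=15))
def test_et_regimen_is_total(disp):
    assert classify_et_regimen(disp) in ET_REGIMENS


# --- targeted therapy -------------------------------------------------------


def test_tt_regimen_two_way():
    assert classify_tt({"trastuzumab"}) == "trastuzumab"
    assert classify_tt({"trastuzumab", "pertuzumab"}) == "pertuzumab±trastuzumab"
    assert classify_tt({"pertuzumab"}) == "pertuzumab±trastuzumab"


def _course(modality, received=True, start=0, end=100, regimen=None):
    return TreatmentCourse(modality=modality, received=received,
                           start_day=start if received else None,
                           end_day=end if received else None, regimen=regimen)


@pytest.mark.parametrize(
    "ct, et, expected",
    [
        (_course("CT", received=False), _course("ET"), "TT-ET"),
        (_course("CT", regimen="paclitaxel"), _course("ET", received=False),
         "paclitaxel-TT(Tolaney)"),
        (_course("CT", regimen="anthracyclines/docetaxel"), _course("ET"),
         "anthracyclines/docetaxel-TT"),
        (_course("CT", regimen="anthracyclines/paclitaxel"), _course("ET"),
         "anthracyclines/paclitaxel-TT"),
        (_course("CT", regimen="docetaxel"), _course("ET"), "docetaxel-TT"),
        (_course("CT", regimen="unknown"), _course("ET"), "other"),
        (_course("CT", received=False), _course("ET", received=False), "other"),
        # CT present but not overlapping the TT course dates
        (_course("CT", start=300, end=400, regimen="paclitaxel"), _course("ET"), "other"),
    ],
)
def test_tt_combination_six_way(ct, et, expected):
    tt = _course("TT", start=0, end=150)
    assert classify_tt_combination(tt, ct, et) == expected
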