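"""Summary denominators, rounding, suppression, modality test, survival."""

import numpy as np
import pandas as pd
import pytest

from claimscohort.stats_reporting import (
    km_analysis,
    km_curve,
    locate_modes,
    modality_test,
    percent,
    suppress_small_strata,
    summarize_cohort,
    summary_block,
)


# --- percentages and summary blocks ----------------------------------------


def test_percent_half_up_rounding():
    assert percent(1, 8) == 12.5
    assert percent(21605, 91938) == 23.5   # 23.4995... rounds up
    assert percent(1686, 90252) == 1.9
    assert percent(205, 1000) == 20.5      # exact .5 rounds half-up
    with pytest.raises(ZeroDivisionError):
        percent(1, 0)


def test_summary_block_percents_sum_to_100():
    rows = summary_block("x", {"a": 333, "b": 333, "c": 334})
    assert abs(sum(r[3] for r in rows) - 100.0) <= 0.1


def _records(n_ct_both=1, n_ct_adj=2, n_ct_neo=1, n_plain=6):
    rows = []
    i = 0
    for setting, count in (("both", n_ct_both), ("adjuvant", n_ct_adj),
                           ("neoadjuvant", n_ct_neo), (None, n_plain)):
        for _ in range(count):
            i += 1
            rows.append({
                "patient_id": f"P{i}", "age": 60, "age_class": "(50-60)",
                "subtype": "TNBC" if setting else "undefined",
                "node_positive": False, "surgery_type": "partial",
                "axillary_surgery": True, "main_pathway": "surgery_then_CT",
                "ct_received": setting is not None, "ct_setting": setting,
                "ct_regimen": "unknown" if setting else None,
                "tt_received": False, "tt_setting": None, "tt_regimen": None,
                "rt_received": False, "rt_setting": None,
                "et_received": False, "et_setting": None, "et_regimen": None,
                "survival_months": 50.0, "event": False,
            })
    return pd.DataFrame(rows)


def test_ct_regimen_denominator_counts_both_setting_patients_twice():
    table = summarize_cohort(_records())
    regimen = table[table.variable == "ct_regimen"]
    # 4 chemotherapy patients, one in both settings -> 5 setting instances
    assert (regimen.denominator == 5).all()
    assert regimen["count"].sum() == 5
    settings = table[table.variable == "ct_setting"]
    assert (settings.denominator == 4).all()  # settings shares are per patient
    yes = table[(table.variable == "chemotherapy") & (table["class"] == "yes")]
    assert yes.iloc[0]["count"] == 4
    assert yes.iloc[0].denominator == 10


def test_summary_counts_additive_over_disjoint_subsets():
    full = _records(n_plain=6)
    a, b = full.iloc[:5], full.iloc[5:]
    t_full = summarize_cohort(full)
    t_a, t_b = summarize_cohort(a), summarize_cohort(b)

    def count_of(t, variable, cls):
        sel = t[(t.variable == variable) & (t["class"] == cls)]
        return int(sel["count"].iloc[0]) if len(sel) else 0

    for var, cls in (("chemotherapy", "yes"), ("subtype", "undefined")):
        assert count_of(t_full, var, cls) == count_of(t_a, var, cls) + count_of(t_b, var, cls)


def test_empty_cohort_gives_empty_table():
    table = summarize_cohort(pd.DataFrame(columns=_records().columns))
    assert len(table) == 0


def test_suppress_small_strata():
    counts = pd.Series({"a": 49, "b": 50, "c": 200})
    kept = suppress_small_strata(counts)
    assert list(kept.index) == ["b", "c"]
    intact = pd.Series({"b": 50, "c": 200})
    pd.testing.assert_series_equal(suppress_small_strata(intact), intact)
    with pytest.warns(UserWarning):
        out = suppress_small_strata(pd.Series({"a": 10}))
    assert len(out) == 0


# --- multimodality ----------------------------------------------------------


def test_constant_sample_is_unimodal_by_convention():
    res = modality_test(np.full(50, 3.0), reps=100, seed=0)
    assert res.p_value == 1.0
    assert res.n_modes == 1
    assert res.mode_locations == [3.0]


def test_modality_test_input_validation():
    with pytest.raises(ValueError):
        modality_test(np.arange(10), reps=100, seed=0)
    with pytest.warns(UserWarning):
        modality_test(np.random.default_rng(0).normal(size=50), reps=50, seed=0)


def test_p_value_invariant_to_affine_rescaling():
    x = np.random.default_rng(4).normal(0, 1, 400)
    r1 = modality_test(x, reps=200, seed=3)
    r2 = modality_test(2.5 * x + 100.0, reps=200, seed=3)
    assert r1.p_value == r2.p_value


def test_unimodal_sample_not_rejected():
    x = np.random.default_rng(8).normal(60, 8, 2000)
    res = modality_test(x, reps=200, seed=8)
    assert res.p_value >= 0.05
    assert res.n_modes == 1


def test_locate_modes_on_well_separated_mixture():
    rng = np.random.default_rng(10)
    x = np.concatenate([rng.normal(-10, 1, 1000), rng.normal(10, 1, 1000)])
    locs, _ = locate_modes(x, 2)
    assert abs(locs[0] + 10) < 0.5 and abs(locs[1] - 10) < 0.5


# --- survival ---------------------------------------------------------------


def brute_force_product_limit(durations, events, times):
    """Independent product-limit: S(t) = prod over event times u <= t of
    (1 - d_u / n_u)."""
    out = []
    for t in times:
        s = 1.0
        for u in sorted(set(durations[events])):
            if u > t:
                break
            d = np.sum((durations == u) & events)
            n_at_risk = np.sum(durations >= u)
            s *= 1.0 - d / n_at_risk
        out.append(s)
    return np.array(out)


def test_km_equals_empirical_survival_without_censoring():
    durations = np.array([1.0, 3.0, 5.0, 7.0, 9.0])
    events = np.ones(5, dtype=bool)
    curve = km_curve(durations, events)
    for t, s in zip(curve.time, curve.survival):
        assert s == pytest.approx(np.mean(durations > t), abs=1e-12)


def test_km_matches_brute_force_on_random_data():
    rng = np.random.default_rng(0)
    for _ in range(20):
        n = int(rng.integers(3, 30))
        durations = rng.integers(1, 15, n).astype(float)
        events = rng.random(n) < 0.7
        curve = km_curve(durations, events)
        expected = brute_force_product_limit(durations, events, curve.time.values)
        np.testing.assert_allclose(curve.survival.values, expected, atol=1e-12)


def _surv_records(durations, events, group=None):
    df = pd.DataFrame({"survival_months": durations, "event": events})
    df["age_class"] = group if group is not None else "(50-60)"
    df["subtype"] = "luminal"
    df["node_positive"] = False
    return df


def test_reverse_km_median_equals_closed_form_with_no_deaths():
    durations = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
    res = km_analysis(_surv_records(durations, np.zeros(5, dtype=bool)))
    assert res.median_followup_months == 30.0
    assert res.n_events == 0
    assert res.logrank["age_class"] is None  # zero events: not applicable


def test_logrank_zero_for_identical_groups():
    durations = np.tile([5.0, 10.0, 15.0, 20.0], 2)
    events = np.tile([True, False, True, True], 2)
    groups = ["a"] * 4 + ["b"] * 4
    res = km_analysis(_surv_records(durations, events, group=groups))
    stat, p = res.logrank["age_class"]
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0, abs=1e-12)
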