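"""Reader/writer contract: round trips, validation, load reporting."""

import numpy as np
import pandas as pd
import pytest

from claimscohort.claims_model import (
    ClaimsBundle,
    CodeDictionary,
    ReferentialIntegrityError,
    SchemaError,
    default_dictionary,
    read_claims,
    write_claims,
)
from claimscohort.synthetic_claims import SimulationConfig, simulate

from conftest import make_event, make_patient


def small_bundle():
    patients = pd.DataFrame([
        make_patient("P1"),
        make_patient("P2", vital="dead", death="2016-02-01"),
    ])
    events = pd.DataFrame([
        make_event("P1", "2013-03-10", "ICD10", "C50"),
        make_event("P2", "2013-05-01", "CCAM", "SURG_PM_AX"),
    ])
    return ClaimsBundle(patients=patients, events=events)


def test_round_trip_identity_on_simulator_output(tmp_path, dictionary):
    bundle, _ = simulate(SimulationConfig(n_patients=100, seed=3))
    write_claims(bundle, tmp_path)
    back, report = read_claims(tmp_path, dictionary)
    pd.testing.assert_frame_equal(bundle.patients, back.patients)
    pd.testing.assert_frame_equal(bundle.sorted_events().reset_index(drop=True),
                                  back.sorted_events().reset_index(drop=True))
    assert report.unknown_codes == []
    assert report.n_malformed_rows == 0


def test_parquet_round_trip(tmp_path, dictionary):
    bundle, _ = simulate(SimulationConfig(n_patients=30, seed=4))
    paths = write_claims(bundle, tmp_path, fmt="parquet")
    back, _ = read_claims(paths, dictionary)
    pd.testing.assert_frame_equal(bundle.patients, back.patients)


def test_absent_death_date_written_as_empty_field(tmp_path):
    write_claims(small_bundle(), tmp_path)
    raw = (tmp_path / "patients.csv").read_text().splitlines()
    assert raw[1].split(",")[5] == ""  # alive patient: empty, not a sentinel
    assert raw[2].split(",")[5] == "2016-02-01"


def test_empty_bundle_writes_header_only_files(tmp_path):
    from claimscohort.claims_model import EVENT_COLUMNS, PATIENT_COLUMNS

    empty = ClaimsBundle(
        patients=pd.DataFrame(columns=list(PATIENT_COLUMNS)),
        events=pd.DataFrame(columns=list(EVENT_COLUMNS)),
    )
    write_claims(empty, tmp_path)
    assert (tmp_path / "patients.csv").read_text().count("\n") == 1
    assert (tmp_path / "events.csv").read_text().count("\n") == 1


def test_unknown_code_flagged_not_dropped(tmp_path, dictionary):
    bundle = small_bundle()
    bundle.events.loc[len(bundle.events)] = make_event("P1", "2013-04-01", "ATC", "X99XX99")
    write_claims(bundle, tmp_path)
    back, report = read_claims(tmp_path, dictionary)
    assert report.unknown_codes == ["ATC:X99XX99"]
    assert len(back.events) == 3


def test_orphan_event_raises_naming_the_id(tmp_path):
    bundle = small_bundle()
    bundle.events.loc[len(bundle.events)] = make_event("GHOST", "2013-04-01", "ICD10", "C50")
    write_claims(bundle, tmp_path)
    with pytest.raises(ReferentialIntegrityError, match="GHOST"):
        read_claims(tmp_path)


def test_missing_column_raises_naming_the_column(tmp_path):
    write_claims(small_bundle(), tmp_path)
    events = pd.read_csv(tmp_path / "events.csv").drop(columns=["care_context"])
    events.to_csv(tmp_path / "events.csv", index=False)
    with pytest.raises(SchemaError, match="care_context"):
        read_claims(tmp_path)


def test_malformed_date_counted_with_line_number(tmp_path):
    write_claims(small_bundle(), tmp_path)
    path = tmp_path / "events.csv"
    lines = path.read_text().splitlines()
    lines[1] = lines[1].replace("2013-03-10", "not-a-date")
    path.write_text("\n".join(lines) + "\n")
    back, report = read_claims(tmp_path)
    assert report.n_malformed_rows == 1
    assert any("line 2" in err for err in report.row_errors)
    assert len(back.events) == 1  # counted and reported, not silently kept


def test_death_date_iff_dead_enforced(tmp_path):
    bundle = small_bundle()
    bundle.patients.loc[0, "vital_status"] = "dead"  # dead but no death_date
    write_claims(bundle, tmp_path)
    with pytest.raises(SchemaError, match="death_date"):
        read_claims(tmp_path)


def test_event_row_order_is_irrelevant(tmp_path, dictionary):
    bundle, _ = simulate(SimulationConfig(n_patients=50, seed=5))
    shuffled = ClaimsBundle(
        patients=bundle.patients,
        events=bundle.events.sample(frac=1, random_state=0),
    )
    assert_sorted_equal = pd.testing.assert_frame_equal
    assert_sorted_equal(
        bundle.sorted_events().reset_index(drop=True),
        shuffled.sorted_events().reset_index(drop=True),
    )


def test_dictionary_rejects_overlapping_surgery_sets():
    sets = dict(default_dictionary().sets)
    sets["surgery_partial_with_axillary"] = sets["surgery_total_with_axillary"]
    with pytest.raises(SchemaError, match="overlap"):
        CodeDictionary(sets)


def test_dictionary_rejects_empty_set():
    sets = dict(default_dictionary().sets)
    sets["metastasis"] = frozenset()
    with pytest.raises(SchemaError, match="empty"):
        CodeDictionary(sets)


def test_dictionary_json_round_trip(tmp_path):
    d = default_dictionary()
    d.to_json(tmp_path / "codes.json")
    back = CodeDictionary.from_json(tmp_path / "codes.json")
    assert back.sets == dict(d.sets)
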