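import dataclasses

import pandas as pd
import pytest

from claimscohort import build_cohort, default_dictionary
from claimscohort.synthetic_claims import SimulationConfig, preset, simulate


@pytest.fixture(scope="session")
def dictionary():
    return default_dictionary()


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free 2,000-patient simulation and its full pipeline output."""
    cfg = SimulationConfig(n_patients=2000, seed=1)
    bundle, truth = simulate(cfg)
    records, courses, report = build_cohort(bundle)
    return {"bundle": bundle, "truth": truth, "records": records,
            "courses": courses, "report": report}


@pytest.fixture(scope="session")
def contaminated_sim():
    """Contaminated preset (5,000 patients, every exclusion reason injected)."""
    cfg = dataclasses.replace(preset("contaminated"), seed=2)
    bundle, truth = simulate(cfg)
    records, courses, report = build_cohort(bundle)
    return {"bundle": bundle, "truth": truth, "records": records,
            "courses": courses, "report": report}


def make_patient(pid="P1", sex="female", birth="1955-06-15", plan="general",
                 vital="alive", death=None, inclusion="2013-03-01"):
    return {
        "patient_id": pid, "sex": sex, "birth_date": pd.Timestamp(birth),
        "insurance_plan": plan, "vital_status": vital,
        "death_date": pd.Timestamp(death) if death else pd.NaT,
        "inclusion_date": pd.Timestamp(inclusion),
    }


def make_event(pid, date, system, code, context="hospital"):
    return {"patient_id": pid, "event_date": pd.Timestamp(date),
            "code_system": system, "code": code, "care_context": context}
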