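"""Ordered inclusion/exclusion filters and attrition reporting.

Ten filters are applied in a fixed order; a patient failing several is
attributed to the first applicable one, so the attrition report chains
exactly (each stage's input count equals the previous stage's output).

Order: (1) at least one breast-cancer diagnosis code; (2) inclusion date in
the incidence window; (3) female sex; (4) age 18+ at inclusion; (5) general
insurance plan; (6) breast surgery within a year of inclusion; (7) no other
concomitant cancer; (8) no breast-cancer code in the lookback year (prior
disease); (9) no metastasis code in the diagnosis-era window (stage IV
suspicion); (10) internally consistent record (no events after death or
before birth).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .claims_model import ClaimsBundle, CodeDictionary, SURGERY_SETS
from .diagnosis_dating import age_in_years

FILTER_NAMES = (
    "bc_diagnosis",
    "incidence_window",
    "female",
    "adult",
    "general_plan",
    "surgery_within_year",
    "no_other_cancer",
    "no_prior_bc",
    "non_metastatic",
    "data_quality",
)


@dataclass(frozen=True)
class SelectionConfig:
    incidence_start: str = "2011-01-01"
    incidence_end: str = "2017-12-31"
    surgery_lookahead_days: int = 365
    prior_bc_lookback_days: int = 365
    metastasis_lookback_days: int = 365
    metastasis_lookahead_days: int = 180
    quality_rules: bool = True

    def __post_init__(self):
        if self.surgery_lookahead_days <= 0:
            raise ValueError("surgery_lookahead_days must be positive")
        if pd.Timestamp(self.incidence_start) >= pd.Timestamp(self.incidence_end):
            raise ValueError("incidence window start must precede its end")


@dataclass
class FilterReport:
    """Ordered attrition counts; complete even when a filter excludes nobody."""

    rows: list = field(default_factory=list)  # (name, n_before, n_excluded, n_after)
    excluded_ids: dict = field(default_factory=dict)  # name -> frozenset of ids

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["filter_name", "n_before", "n_excluded", "n_after"]
        )

    @property
    def n_included(self) -> int:
        return self.rows[-1][3] if self.rows else 0


def _days(series) -> np.ndarray:
    return series.values.astype("datetime64[D]").astype(int)


def apply_filters(
    bundle: ClaimsBundle,
    config: SelectionConfig = SelectionConfig(),
    dictionary: CodeDictionary | None = None,
):
    """Apply the ten filters in order.

    Returns ``(included_ids, FilterReport)``.  ``included_ids`` is a list in
    the patient-table order (event-row order never matters).
    """
    if dictionary is None:
        from .claims_model import default_dictionary

        dictionary = default_dictionary()

    patients = bundle.patients
    report = FilterReport()
    if len(patients) == 0:
        return [], report

    events = bundle.events
    tags = dictionary.tag(events)
    ev_pid = events["patient_id"].values
    ev_day = _days(events["event_date"])

    pid = patients["patient_id"].values
    pid_index = pd.Index(pid)
    incl_day = _days(patients["inclusion_date"])
    birth_day = _days(patients["birth_date"])
    death_day = np.where(
        patients["death_date"].notna(), _days(patients["death_date"]), np.iinfo(np.int64).max
    )

    def per_patient_any(event_mask) -> np.ndarray:
        """Boolean per patient: any event satisfying event_mask."""
        out = np.zeros(len(pid), dtype=bool)
        if event_mask.any():
            hit = pid_index.get_indexer(pd.unique(ev_pid[event_mask]))
            out[hit[hit >= 0]] = True
        return out

    ev_incl = incl_day[pid_index.get_indexer(ev_pid)]

    bc_mask = tags["bc_diagnosis"].values
    surgery_mask = np.zeros(len(events), dtype=bool)
    for name in SURGERY_SETS[:4]:  # axillary-only does not qualify
        surgery_mask |= tags[name].values

    # Index surgery day per patient (first qualifying breast surgery from the
    # start of the inclusion year to inclusion + lookahead), for filter 9.
    year_start = patients["inclusion_date"].values.astype("datetime64[Y]").astype("datetime64[D]").astype(int)
    ev_year_start = year_start[pid_index.get_indexer(ev_pid)]
    idx_candidates = surgery_mask & (ev_day >= ev_year_start) & (
        ev_day <= ev_incl + config.surgery_lookahead_days
    )
    index_day = np.full(len(pid), np.iinfo(np.int64).max)
    if idx_candidates.any():
        grp = (
            pd.Series(ev_day[idx_candidates])
            .groupby(pd.Index(ev_pid[idx_candidates]))
            .min()
        )
        loc = pid_index.get_indexer(grp.index)
        index_day[loc] = grp.values

    win_start = pd.Timestamp(config.incidence_start).to_datetime64().astype("datetime64[D]").astype(int)
    win_end = pd.Timestamp(config.incidence_end).to_datetime64().astype("datetime64[D]").astype(int)
    ages = np.array([age_in_years(b, i) for b, i in zip(birth_day, incl_day)])

    fail = {}
    fail["bc_diagnosis"] = ~per_patient_any(bc_mask)
    fail["incidence_window"] = ~((incl_day >= win_start) & (incl_day <= win_end))
    fail["female"] = patients["sex"].values != "female"
    fail["adult"] = ages < 18
    fail["general_plan"] = patients["insurance_plan"].values != "general"
    fail["surgery_within_year"] = ~per_patient_any(
        surgery_mask & (ev_day >= ev_incl) & (ev_day <= ev_incl + config.surgery_lookahead_days)
    )
    fail["no_other_cancer"] = per_patient_any(tags["other_cancer"].values)
    fail["no_prior_bc"] = per_patient_any(
        bc_mask
        & (ev_day >= ev_incl - config.prior_bc_lookback_days)
        & (ev_day <= ev_incl - 1)
    )
    ev_index_day = index_day[pid_index.get_indexer(ev_pid)]
    meta_hi = np.where(
        ev_index_day == np.iinfo(np.int64).max,
        ev_incl + config.surgery_lookahead_days + config.metastasis_lookahead_days,
        ev_index_day + config.metastasis_lookahead_days,
    )
    fail["non_metastatic"] = per_patient_any(
        tags["metastasis"].values
        & (ev_day >= ev_incl - config.metastasis_lookback_days)
        & (ev_day <= meta_hi)
    )
    if config.quality_rules:
        ev_death = death_day[pid_index.get_indexer(ev_pid)]
        ev_birth = birth_day[pid_index.get_indexer(ev_pid)]
        fail["data_quality"] = per_patient_any(
            (ev_day > ev_death) | (ev_day < ev_birth)
        )
    else:
        fail["data_quality"] = np.zeros(len(pid), dtype=bool)

    alive = np.ones(len(pid), dtype=bool)
    for name in FILTER_NAMES:
        n_before = int(alive.sum())
        excluded = alive & fail[name]
        n_excl = int(excluded.sum())
        alive &= ~excluded
        report.rows.append((name, n_before, n_excl, n_before - n_excl))
        report.excluded_ids[name] = frozenset(pid[excluded])

    return list(pid[alive]), report
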