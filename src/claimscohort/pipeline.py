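"""End-to-end cohort construction: select -> phenotype -> summarize.

``build_cohort`` turns a claims bundle into one record per included patient
(derived dates, treatment courses, subtype, nodal status, care pathway,
survival fields) plus a long per-modality course table and the attrition
report.  ``run`` wraps simulate/read + build + summarize into a single
reproducible artifact set driven by a JSON-serialisable RunConfig.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic_claims
from .claims_model import ClaimsBundle, CodeDictionary, default_dictionary, read_claims, write_claims
from .cohort_selection import FilterReport, SelectionConfig, apply_filters
from .diagnosis_dating import age_at_diagnosis, diagnosis_date, first_treatment_date
from .phenotyping import (
    age_class,
    assign_main_pathway,
    derive_sequence,
    infer_subtype,
    nodal_status,
)
from .stats_reporting import DAYS_PER_MONTH, km_analysis, modality_test, summarize_cohort
from .treatment_engine import (
    SurgeryEvent,
    TreatmentWindows,
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

logger = logging.getLogger(__name__)

_SURGERY_SET_TO_CATEGORY = {
    "surgery_partial_with_axillary": "partial_with_axillary",
    "surgery_partial_without_axillary": "partial_without_axillary",
    "surgery_total_with_axillary": "mastectomy_with_axillary",
    "surgery_total_without_axillary": "mastectomy_without_axillary",
    "axillary_only": "axillary_only",
}

_CT_SET_TO_CLASS = {
    "anthracycline": "anthracycline",
    "docetaxel": "docetaxel",
    "paclitaxel": "paclitaxel",
    "other_ct_molecule": "other",
}

_ET_SET_TO_CLASS = {"tamoxifen": "tamoxifen", "aromatase_inhibitor": "ai", "gnrh_agonist": "gnrh"}


def _days(series) -> np.ndarray:
    return series.values.astype("datetime64[D]").astype(int)


def _to_date(day) -> pd.Timestamp:
    if day is None:
        return pd.NaT
    return pd.Timestamp(np.datetime64("1970-01-01", "D") + int(day))


def build_cohort(
    bundle: ClaimsBundle,
    dictionary: CodeDictionary | None = None,
    selection: SelectionConfig = SelectionConfig(),
    windows: TreatmentWindows = TreatmentWindows(),
    month_days: int = 30,
    merge_gap: int = 7,
    et_pack_days: int = 30,
    cutoff_date: str = "2019-03-01",
):
    """Apply selection filters then derive the full phenotype per patient.

    Returns ``(records, courses, report)``: the per-patient cohort table, the
    per-(patient, modality) course table, and the attrition FilterReport.
    """
    if dictionary is None:
        dictionary = default_dictionary()
    included, report = apply_filters(bundle, selection, dictionary)
    cutoff_day = int(np.datetime64(cutoff_date, "D").astype(int))

    events = bundle.events
    tags = dictionary.tag(events)
    ev_day = _days(events["event_date"])

    patients = bundle.patients.set_index("patient_id")
    birth_day = pd.Series(_days(bundle.patients["birth_date"]), index=bundle.patients["patient_id"])
    incl_day = pd.Series(_days(bundle.patients["inclusion_date"]), index=bundle.patients["patient_id"])
    death_day = pd.Series(
        np.where(
            bundle.patients["death_date"].notna(),
            bundle.patients["death_date"].values.astype("datetime64[D]").astype("float64"),
            np.nan,
        ),
        index=bundle.patients["patient_id"],
    )

    groups = {pid: idx.to_numpy() for pid, idx in events.groupby("patient_id").groups.items()}
    tag_arrays = {name: tags[name].to_numpy() for name in tags.columns}

    record_rows = []
    course_rows = []
    for pid in included:
        idx = groups.get(pid, np.array([], dtype=int))
        day = ev_day[idx]

        def days_of(*set_names) -> np.ndarray:
            mask = np.zeros(len(idx), dtype=bool)
            for name in set_names:
                mask |= tag_arrays[name][idx]
            return day[mask]

        incl = int(incl_day[pid])
        year_start = int(
            np.datetime64(np.datetime64("1970-01-01", "D") + incl, "Y").astype("datetime64[D]").astype(int)
        )

        surgeries = []
        for set_name, category in _SURGERY_SET_TO_CATEGORY.items():
            for d in days_of(set_name):
                surgeries.append(SurgeryEvent(int(d), category))
        index_day, in_window_surgeries = find_index_surgery(
            surgeries, incl, year_start, selection.surgery_lookahead_days
        )
        surgery_type, axillary = bin_surgery(in_window_surgeries)

        rt = detect_windowed_modality(days_of("radiotherapy"), index_day, windows.rt, "RT")

        ct_days = days_of("ct_session")
        ct = detect_windowed_modality(ct_days, index_day, windows.ct, "CT")
        if ct.received:
            lo, hi = windows.ct
            in_win = ct_days[(ct_days - index_day >= lo) & (ct_days - index_day <= hi)]
            session_set = set(int(d) for d in in_win)
            molecule_classes = set()
            for set_name, cls in _CT_SET_TO_CLASS.items():
                if any(int(d) in session_set for d in days_of(set_name)):
                    molecule_classes.add(cls)
            ct.regimen = classify_ct_regimen(molecule_classes)
            ct.n_cycles_by_setting = count_cycles(in_win, index_day, merge_gap)

        tt_days = days_of("trastuzumab", "pertuzumab")
        tt = detect_windowed_modality(tt_days, index_day, windows.tt, "TT")
        if tt.received:
            lo, hi = windows.tt
            tt_molecules = set()
            for set_name in ("trastuzumab", "pertuzumab"):
                d = days_of(set_name)
                if ((d - index_day >= lo) & (d - index_day <= hi)).any():
                    tt_molecules.add(set_name)
            tt.regimen = classify_tt(tt_molecules)

        dispensings = []
        for set_name, cls in _ET_SET_TO_CLASS.items():
            for d in days_of(set_name):
                dispensings.append((int(d), cls))
        et = detect_endocrine_therapy(
            dispensings,
            index_day,
            cutoff_day,
            ct_start_day=ct.start_day if ct.received else None,
            pack_days=et_pack_days,
        )
        if et.received:
            et.regimen = classify_et_regimen(dispensings)

        tt_combination = classify_tt_combination(tt, ct, et) if tt.received else None

        ft_day = first_treatment_date([rt, ct, et, tt], index_day)
        diag_mode, diag_day = diagnosis_date(
            days_of("breast_biopsy"),
            days_of("breast_cytology"),
            days_of("breast_imaging"),
            ft_day,
            month_days=month_days,
        )
        age = age_at_diagnosis(int(birth_day[pid]), diag_day)
        subtype = infer_subtype(ct.received, et.received, tt.received)
        node = nodal_status(days_of("node_disease"), index_day, windows.node)
        courses = {"RT": rt, "CT": ct, "ET": et, "TT": tt}
        pathway = assign_main_pathway(courses)
        sequence = derive_sequence(courses)

        d_day = death_day[pid]
        dead = not np.isnan(d_day) and d_day <= cutoff_day
        end_day = min(d_day, cutoff_day) if dead else cutoff_day
        survival_months = max(0.0, (end_day - index_day) / DAYS_PER_MONTH)

        record_rows.append(
            {
                "patient_id": pid,
                "age": age,
                "age_class": age_class(age),
                "subtype": subtype,
                "node_positive": node,
                "surgery_type": surgery_type,
                "axillary_surgery": axillary,
                "index_surgery_date": _to_date(index_day),
                "first_treatment_date": _to_date(ft_day),
                "diagnosis_mode": diag_mode,
                "diagnosis_date": _to_date(diag_day),
                "main_pathway": pathway,
                "sequence": "|".join(sequence),
                "rt_received": rt.received,
                "rt_setting": rt.setting if rt.received else None,
                "ct_received": ct.received,
                "ct_setting": ct.setting if ct.received else None,
                "ct_regimen": ct.regimen,
                "ct_cycles_neoadjuvant": ct.n_cycles_by_setting.get("neoadjuvant"),
                "ct_cycles_adjuvant": ct.n_cycles_by_setting.get("adjuvant"),
                "et_received": et.received,
                "et_setting": et.setting if et.received else None,
                "et_regimen": et.regimen,
                "tt_received": tt.received,
                "tt_setting": tt.setting if tt.received else None,
                "tt_regimen": tt.regimen,
                "tt_combination": tt_combination,
                "survival_months": round(survival_months, 6),
                "event": dead,
            }
        )
        for modality, course in courses.items():
            course_rows.append(
                {
                    "patient_id": pid,
                    "modality": modality,
                    "received": course.received,
                    "setting": course.setting,
                    "start_date": _to_date(course.start_day),
                    "end_date": _to_date(course.end_day),
                    "regimen": course.regimen,
                    "cycles_neoadjuvant": course.n_cycles_by_setting.get("neoadjuvant"),
                    "cycles_adjuvant": course.n_cycles_by_setting.get("adjuvant"),
                }
            )

    records = pd.DataFrame(record_rows)
    courses_df = pd.DataFrame(course_rows)
    return records, courses_df, report


@dataclass
class RunConfig:
    """Everything a run needs; serialised verbatim into the run manifest."""

    preset: str | None = "clean_small"
    input_dir: str | None = None
    dictionary_path: str | None = None
    n_patients: int | None = None
    seed: int = 0
    outdir: str = "results/run"
    month_days: int = 30
    merge_gap: int = 7
    et_pack_days: int = 30
    cutoff_date: str = "2019-03-01"
    modality_reps: int = 200
    selection: dict = field(default_factory=dict)
    windows: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # annotate failures with the stage name
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run(config: RunConfig) -> dict:
    """Execute simulate/read -> build-cohort -> summarize, writing attrition,
    treatments, cohort, summary table, survival curve, modality test, run
    manifest and log under ``config.outdir``.  Returns the artifact paths."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("claimscohort")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        dictionary = (
            CodeDictionary.from_json(config.dictionary_path)
            if config.dictionary_path
            else default_dictionary()
        )

        truth = None
        if config.input_dir:
            bundle, load_report = _stage("read")(read_claims)(config.input_dir, dictionary)
            logger.info("read %d patients, %d events", load_report.n_patients, load_report.n_events)
        else:
            sim = synthetic_claims.preset(config.preset or "clean_small")
            sim = dataclasses.replace(
                sim,
                seed=config.seed,
                cutoff_date=config.cutoff_date,
                **({"n_patients": config.n_patients} if config.n_patients else {}),
            )
            bundle, truth = _stage("simulate")(synthetic_claims.simulate)(sim, dictionary)
            logger.info("simulated %d patients (%d events)", len(bundle.patients), len(bundle.events))

        selection = SelectionConfig(**config.selection)
        windows = TreatmentWindows(**{k: tuple(v) for k, v in config.windows.items()})
        records, courses, report = _stage("build-cohort")(build_cohort)(
            bundle,
            dictionary,
            selection,
            windows,
            month_days=config.month_days,
            merge_gap=config.merge_gap,
            et_pack_days=config.et_pack_days,
            cutoff_date=config.cutoff_date,
        )
        logger.info("included %d of %d patients", len(records), len(bundle.patients))

        table1 = _stage("summarize")(summarize_cohort)(records, courses)
        artifacts = {}

        def save(name, frame):
            path = outdir / name
            frame.to_csv(path, index=False)
            artifacts[name] = path

        save("attrition.csv", report.to_frame())
        save("cohort.csv", records)
        save("treatments.csv", courses)
        save("table1.csv", table1)
        if truth is not None:
            save("ground_truth.csv", truth)

        if len(records):
            surv = _stage("survival")(km_analysis)(records)
            save("survival.csv", surv.curve)
            mod = _stage("modality")(modality_test)(
                records["age"].to_numpy(float), reps=config.modality_reps, seed=config.seed
            )
            with open(outdir / "modality.json", "w") as fh:
                json.dump(
                    {
                        "p_value": mod.p_value,
                        "n_modes": mod.n_modes,
                        "mode_locations": mod.mode_locations,
                        "critical_bandwidth": mod.critical_bandwidth,
                        "reps": mod.reps,
                        "seed": mod.seed,
                        "median_followup_months": surv.median_followup_months,
                        "followup_iqr_months": list(surv.followup_iqr_months),
                        "n_events": surv.n_events,
                    },
                    fh,
                    indent=1,
                )
            artifacts["modality.json"] = outdir / "modality.json"

        config.to_json(outdir / "manifest.json")
        artifacts["manifest.json"] = outdir / "manifest.json"
        return artifacts
    finally:
        root.removeHandler(handler)
        handler.close()
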