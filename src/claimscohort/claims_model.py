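"""Claims data model: patients, coded events, code dictionary, readers/writers.

The pipeline consumes longitudinal reimbursement-claims tables: one patient
table (demographics, insurance plan, vital status) and one event table of
dated, code-system-tagged claim lines (ICD-10 diagnoses, CCAM procedures,
ATC drug deliveries, long-term-illness ICD-10 records).  Drug codes are
assumed to have been normalised to ATC upstream; the pipeline reasons only
in ATC.  All dates are calendar dates and all date arithmetic is in whole
days.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CODE_SYSTEMS = ("ICD10", "CCAM", "ATC", "LTI_ICD10")

#: Named code sets every downstream stage resolves codes through.
SET_NAMES = (
    "bc_diagnosis",
    "node_disease",
    "metastasis",
    "other_cancer",
    "surgery_partial_with_axillary",
    "surgery_partial_without_axillary",
    "surgery_total_with_axillary",
    "surgery_total_without_axillary",
    "axillary_only",
    "radiotherapy",
    "ct_session",
    "anthracycline",
    "docetaxel",
    "paclitaxel",
    "other_ct_molecule",
    "tamoxifen",
    "aromatase_inhibitor",
    "gnrh_agonist",
    "trastuzumab",
    "pertuzumab",
    "breast_biopsy",
    "breast_cytology",
    "breast_imaging",
)

SURGERY_SETS = (
    "surgery_partial_with_axillary",
    "surgery_partial_without_axillary",
    "surgery_total_with_axillary",
    "surgery_total_without_axillary",
    "axillary_only",
)

ET_MOLECULE_SETS = ("tamoxifen", "aromatase_inhibitor", "gnrh_agonist")

PATIENT_COLUMNS = (
    "patient_id",
    "sex",
    "birth_date",
    "insurance_plan",
    "vital_status",
    "death_date",
    "inclusion_date",
)

EVENT_COLUMNS = ("patient_id", "event_date", "code_system", "code", "care_context")


class SchemaError(ValueError):
    """A mandatory column is missing or a field violates the schema."""


class ReferentialIntegrityError(ValueError):
    """An event references a patient_id absent from the patient table."""


@dataclass(frozen=True)
class CodeDictionary:
    """Named sets of (code_system, code) pairs.

    Stands in for the national appendix code lists: the shipped default uses
    real ATC codes where unambiguous and synthetic CCAM/ICD-10 placeholders
    elsewhere; real code lists can be supplied via ``codes.json`` without any
    code change.
    """

    sets: Mapping[str, frozenset]

    def __post_init__(self):
        missing = [name for name in SET_NAMES if name not in self.sets]
        if missing:
            raise SchemaError(f"code dictionary missing sets: {missing}")
        for name in SET_NAMES:
            if not self.sets[name]:
                raise SchemaError(f"code set {name!r} is empty")
        for group in (SURGERY_SETS, ET_MOLECULE_SETS):
            for i, a in enumerate(group):
                for b in group[i + 1 :]:
                    overlap = self.sets[a] & self.sets[b]
                    if overlap:
                        raise SchemaError(
                            f"code sets {a!r} and {b!r} overlap: {sorted(overlap)}"
                        )

    def __getitem__(self, name: str) -> frozenset:
        return self.sets[name]

    def all_codes(self) -> frozenset:
        out = set()
        for s in self.sets.values():
            out |= s
        return frozenset(out)

    def tag(self, events: pd.DataFrame) -> pd.DataFrame:
        """Return a boolean DataFrame (same index as events) with one column
        per named set, True where the event's (code_system, code) belongs."""
        keys = list(zip(events["code_system"], events["code"]))
        out = {}
        for name in SET_NAMES:
            s = self.sets[name]
            out[name] = np.fromiter((k in s for k in keys), dtype=bool, count=len(keys))
        return pd.DataFrame(out, index=events.index)

    @classmethod
    def from_json(cls, path) -> "CodeDictionary":
        with open(path) as fh:
            raw = json.load(fh)
        sets = {}
        for name, codes in raw.items():
            pairs = set()
            for item in codes:
                system, _, code = item.partition(":")
                if system not in CODE_SYSTEMS or not code:
                    raise SchemaError(f"malformed code entry {item!r} in set {name!r}")
                pairs.add((system, code))
            sets[name] = frozenset(pairs)
        return cls(sets)

    def to_json(self, path) -> None:
        raw = {
            name: sorted(f"{sys}:{code}" for sys, code in self.sets[name])
            for name in SET_NAMES
        }
        with open(path, "w") as fh:
            json.dump(raw, fh, indent=1)


def default_dictionary() -> CodeDictionary:
    """Default placeholder dictionary.

    ATC molecule codes are the real WHO codes; diagnosis and procedure codes
    are documented placeholders (``CCAM:SURG_PM_AX`` etc.) because the exact
    national code lists are configuration, not logic.
    """
    d = {
        "bc_diagnosis": {("ICD10", "C50"), ("LTI_ICD10", "C50")},
        "node_disease": {("ICD10", "C773")},
        "metastasis": {("ICD10", "C780"), ("ICD10", "C792"), ("ICD10", "C793")},
        "other_cancer": {("ICD10", "C18"), ("ICD10", "C34"), ("ICD10", "C61")},
        "surgery_partial_with_axillary": {("CCAM", "SURG_PM_AX")},
        "surgery_partial_without_axillary": {("CCAM", "SURG_PM")},
        "surgery_total_with_axillary": {("CCAM", "SURG_TM_AX")},
        "surgery_total_without_axillary": {("CCAM", "SURG_TM")},
        "axillary_only": {("CCAM", "SURG_AX")},
        "radiotherapy": {("CCAM", "RT_SESSION"), ("ICD10", "Z510")},
        "ct_session": {("CCAM", "CT_SESSION"), ("ICD10", "Z511")},
        "anthracycline": {("ATC", "L01DB01"), ("ATC", "L01DB03")},
        "docetaxel": {("ATC", "L01CD02")},
        "paclitaxel": {("ATC", "L01CD01")},
        "other_ct_molecule": {("ATC", "L01XA01"), ("ATC", "L01XA02"), ("ATC", "L01AA01")},
        "tamoxifen": {("ATC", "L02BA01")},
        "aromatase_inhibitor": {("ATC", "L02BG03"), ("ATC", "L02BG04"), ("ATC", "L02BG06")},
        "gnrh_agonist": {("ATC", "L02AE02"), ("ATC", "L02AE03")},
        "trastuzumab": {("ATC", "L01XC03")},
        "pertuzumab": {("ATC", "L01XC13")},
        "breast_biopsy": {("CCAM", "BX_BREAST")},
        "breast_cytology": {("CCAM", "CYTO_BREAST")},
        "breast_imaging": {("CCAM", "IMG_MAMMO"), ("CCAM", "IMG_US"), ("CCAM", "IMG_MRI")},
    }
    return CodeDictionary({k: frozenset(v) for k, v in d.items()})


@dataclass
class LoadReport:
    n_patients: int = 0
    n_events: int = 0
    unknown_codes: list = field(default_factory=list)
    n_malformed_rows: int = 0
    row_errors: list = field(default_factory=list)


@dataclass
class ClaimsBundle:
    """A patient table plus an event table; the pipeline's input contract."""

    patients: pd.DataFrame
    events: pd.DataFrame

    def __post_init__(self):
        self.patients = self.patients.reset_index(drop=True)
        self.events = self.events.reset_index(drop=True)

    def events_for(self, patient_id: str) -> pd.DataFrame:
        sub = self.events[self.events["patient_id"] == patient_id]
        return sub.sort_values("event_date")

    def sorted_events(self) -> pd.DataFrame:
        """Canonically ordered events (all columns as tie-breakers), for
        order-insensitive comparisons."""
        return self.events.sort_values(list(EVENT_COLUMNS), kind="mergesort")


def _validate_patients(patients: pd.DataFrame) -> None:
    dead = patients["vital_status"] == "dead"
    has_death = patients["death_date"].notna()
    if (dead != has_death).any():
        bad = patients.loc[dead != has_death, "patient_id"].tolist()
        raise SchemaError(
            f"death_date must be present iff vital_status is 'dead'; violated for {bad[:5]}"
        )
    bad = patients.loc[has_death & (patients["death_date"] < patients["birth_date"])]
    if len(bad):
        raise SchemaError(
            f"death_date precedes birth_date for {bad['patient_id'].tolist()[:5]}"
        )


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".parquet":
        return pd.read_parquet(path)
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def _parse_dates(df, columns, required, report, table_name):
    """Parse ISO-8601 date columns in place; rows with an unparseable required
    date are counted as malformed (with their line number) and dropped."""
    bad_rows = np.zeros(len(df), dtype=bool)
    for col, is_required in zip(columns, required):
        raw = df[col].astype(str).replace("", None) if df[col].dtype == object else df[col]
        parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
        invalid = parsed.isna() & raw.notna() if hasattr(raw, "notna") else parsed.isna()
        if is_required:
            invalid = invalid | parsed.isna()
        for idx in df.index[np.asarray(invalid)]:
            # +2: header line plus 1-based indexing
            report.row_errors.append(
                f"{table_name} line {idx + 2}: unparseable date in column {col!r}"
            )
        bad_rows |= np.asarray(invalid)
        df[col] = parsed
    report.n_malformed_rows += int(bad_rows.sum())
    return df.loc[~bad_rows].reset_index(drop=True)


def read_claims(paths, dictionary: CodeDictionary | None = None):
    """Read a claims bundle from ``{"patients": ..., "events": ...}`` paths or
    a directory containing ``patients.csv`` and ``events.csv``.

    Returns ``(ClaimsBundle, LoadReport)``.  Unknown codes are retained in the
    bundle but listed in the load report; malformed rows are counted and
    reported, never silently dropped.
    """
    if isinstance(paths, (str, Path)):
        base = Path(paths)
        paths = {"patients": base / "patients.csv", "events": base / "events.csv"}
    report = LoadReport()

    patients = _read_table(paths["patients"])
    missing = [c for c in PATIENT_COLUMNS if c not in patients.columns]
    if missing:
        raise SchemaError(f"patients table missing column(s): {missing}")
    patients = patients.loc[:, list(PATIENT_COLUMNS)]
    patients = _parse_dates(
        patients,
        ["birth_date", "death_date", "inclusion_date"],
        [True, False, True],
        report,
        "patients",
    )
    _validate_patients(patients)

    events = _read_table(paths["events"])
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise SchemaError(f"events table missing column(s): {missing}")
    events = events.loc[:, list(EVENT_COLUMNS)]
    events = _parse_dates(events, ["event_date"], [True], report, "events")
    if (events["code"].astype(str) == "").any():
        raise SchemaError("event rows with empty code")

    known_ids = set(patients["patient_id"])
    orphans = [pid for pid in events["patient_id"].unique() if pid not in known_ids]
    if orphans:
        raise ReferentialIntegrityError(
            f"events reference unknown patient_id(s): {orphans[:5]}"
        )

    if dictionary is not None:
        known = dictionary.all_codes()
        pairs = set(zip(events["code_system"], events["code"]))
        report.unknown_codes = sorted(f"{s}:{c}" for s, c in pairs - known)

    report.n_patients = len(patients)
    report.n_events = len(events)
    return ClaimsBundle(patients=patients, events=events), report


def write_claims(bundle: ClaimsBundle, outdir, fmt: str = "csv"):
    """Write ``patients`` and ``events`` tables under *outdir*.

    Absent optional dates are written as empty fields.  The inverse of
    :func:`read_claims` field-for-field.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    patients = bundle.patients.copy()
    events = bundle.events.copy()
    written = {}
    if fmt == "parquet":
        written["patients"] = outdir / "patients.parquet"
        written["events"] = outdir / "events.parquet"
        patients.to_parquet(written["patients"], index=False)
        events.to_parquet(written["events"], index=False)
        return written
    for col in ("birth_date", "death_date", "inclusion_date"):
        patients[col] = pd.to_datetime(patients[col]).dt.strftime("%Y-%m-%d").fillna("")
    events["event_date"] = pd.to_datetime(events["event_date"]).dt.strftime("%Y-%m-%d")
    written["patients"] = outdir / "patients.csv"
    written["events"] = outdir / "events.csv"
    patients.to_csv(written["patients"], index=False)
    events.to_csv(written["events"], index=False)
    return written
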