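"""Ground-truth-labeled synthetic claims generator.

The national claims database this pipeline targets is access-restricted, so
every downstream stage is exercised on simulated reimbursement timelines
with known generative labels.  The generator works backwards from the
phenotype: it draws a subtype and a care pathway, lays out surgery,
radiotherapy/chemotherapy sessions, drug deliveries and diagnostic
procedures on a day grid consistent with those labels (the exact inverse of
the pipeline's inference maps, so noise-free recovery is well-defined), and
then optionally injects contaminant patients carrying the claim pattern
that triggers each exclusion filter.

Default parameters emulate the published cohort's marginals: a bimodal
age-at-diagnosis mixture peaking near 50.3 and 65.0 years, subtype shares
of 65.1 / 7.7 / 5.3 / 3.0 / 18.9 percent (luminal / TNBC / HER2+HR+ /
HER2+HR- / undefined), and conditional pathway probabilities whose implied
marginals match the printed pathway, setting, and treatment rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .claims_model import ClaimsBundle, CodeDictionary, default_dictionary
from .treatment_engine import classify_et_regimen

EPOCH = np.datetime64("1970-01-01", "D")

SUBTYPES = ("luminal", "TNBC", "HER2+/HR+", "HER2+/HR-", "undefined")
PATHWAYS = ("surgery_no_CT", "surgery_then_CT", "NAC", "NRT", "NET")
EXCLUSION_REASONS = (
    "male",
    "under_18",
    "non_general_plan",
    "no_surgery",
    "other_cancer",
    "prior_bc",
    "metastatic",
    "corrupt",
)

#: exclusion reason -> selection filter expected to catch it
REASON_TO_FILTER = {
    "male": "female",
    "under_18": "adult",
    "non_general_plan": "general_plan",
    "no_surgery": "surgery_within_year",
    "other_cancer": "no_other_cancer",
    "prior_bc": "no_prior_bc",
    "metastatic": "non_metastatic",
    "corrupt": "data_quality",
}


def _day(datestr: str) -> int:
    return int(np.datetime64(datestr, "D").astype(int))


def _date(day: int) -> np.datetime64:
    return EPOCH + int(day)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class TimingConfig:
    """Uniform day-offset ranges (inclusive) for event layout."""

    first_treatment_lag: tuple = (5, 30)  # inclusion -> first treatment
    nac_gap_to_surgery: tuple = (14, 40)  # last neoadjuvant CT cycle -> surgery
    adj_ct_start: tuple = (14, 30)  # surgery -> adjuvant CT start
    ct_cycle_days: int = 21
    adj_rt_start: tuple = (45, 110)
    rt_sessions: int = 15
    rt_session_gap: int = 2
    nrt_start_before_surgery: tuple = (50, 70)
    adj_et_start: tuple = (30, 120)
    net_surgery_gap: tuple = (120, 200)  # NET start -> surgery
    et_dispense_days: int = 30
    gnrh_dispense_days: int = 84
    tt_cycle_days: int = 21
    adj_tt_start: tuple = (21, 35)
    tt_last_session_cap: int = 170  # last TT session <= surgery + cap
    biopsy_lag: tuple = (10, 60)  # before first treatment
    imaging_chain_gap: tuple = (5, 29)
    death_min_days: int = 420  # earliest death after surgery


def _default_pathway_probs() -> dict:
    return {
        "luminal": {"surgery_no_CT": 0.634, "surgery_then_CT": 0.310, "NAC": 0.042, "NRT": 0.0, "NET": 0.014},
        "TNBC": {"surgery_no_CT": 0.0, "surgery_then_CT": 0.65, "NAC": 0.35, "NRT": 0.0, "NET": 0.0},
        "HER2+/HR+": {"surgery_no_CT": 0.10, "surgery_then_CT": 0.72, "NAC": 0.18, "NRT": 0.0, "NET": 0.0},
        "HER2+/HR-": {"surgery_no_CT": 0.0, "surgery_then_CT": 0.72, "NAC": 0.28, "NRT": 0.0, "NET": 0.0},
        "undefined": {"surgery_no_CT": 1.0, "surgery_then_CT": 0.0, "NAC": 0.0, "NRT": 0.0, "NET": 0.0},
    }


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int = 1000
    seed: int = 0
    #: (weight, mean, sd) Gaussian components of age at diagnosis, years.
    #: SDs chosen so the mixture density truly peaks at the component means
    #: (wider components shift overlapping modes inward).
    age_mixture: tuple = ((0.45, 50.3, 4.0), (0.55, 65.0, 4.5))
    subtype_probs: dict = field(
        default_factory=lambda: {
            "luminal": 0.651,
            "TNBC": 0.077,
            "HER2+/HR+": 0.053,
            "HER2+/HR-": 0.030,
            "undefined": 0.189,
        }
    )
    pathway_probs: dict = field(default_factory=_default_pathway_probs)
    contamination_rates: dict = field(default_factory=dict)
    timing: TimingConfig = TimingConfig()
    annual_death_hazard: dict = field(
        default_factory=lambda: {
            "luminal": 0.014,
            "TNBC": 0.037,
            "HER2+/HR+": 0.020,
            "HER2+/HR-": 0.032,
            "undefined": 0.023,
        }
    )
    incidence_start: str = "2011-01-01"
    incidence_end: str = "2017-12-31"
    cutoff_date: str = "2019-03-01"
    rt_prob: float = 0.853
    ct_both_prob: float = 0.10  # share of NAC patients also given adjuvant CT
    node_positive_probs: dict = field(
        default_factory=lambda: {
            "luminal": 0.215,
            "TNBC": 0.25,
            "HER2+/HR+": 0.27,
            "HER2+/HR-": 0.301,
            "undefined": 0.03,
        }
    )
    mastectomy_prob: float = 0.264
    axillary_prob: float = 0.838
    ct_cycles_probs: dict = field(default_factory=lambda: {4: 0.15, 6: 0.62, 8: 0.23})
    ct_regimen_probs: dict = field(
        default_factory=lambda: {
            "anthracyclines": 0.008,
            "anthracyclines/docetaxel": 0.151,
            "anthracyclines/paclitaxel": 0.235,
            "docetaxel": 0.054,
            "paclitaxel": 0.031,
            "other": 0.070,
            "unknown": 0.451,
        }
    )
    #: HER2+ patients get taxane-rich, mostly identifiable regimens.
    ct_regimen_probs_her2: dict = field(
        default_factory=lambda: {
            "anthracyclines": 0.0,
            "anthracyclines/docetaxel": 0.45,
            "anthracyclines/paclitaxel": 0.25,
            "docetaxel": 0.12,
            "paclitaxel": 0.08,
            "other": 0.05,
            "unknown": 0.05,
        }
    )
    et_regimen_probs: dict = field(
        default_factory=lambda: {
            "ai": 0.620,
            "tamoxifen": 0.212,
            "tamoxifen_then_ai": 0.062,
            "ai_then_tamoxifen": 0.048,
            "tamoxifen_with_gnrh": 0.006,
            "ai_with_gnrh": 0.004,
            "others": 0.048,
        }
    )
    tt_pertuzumab_prob: float = 0.022
    diagnostic_mode_probs: dict = field(
        default_factory=lambda: {
            "biopsy": 0.913,
            "cytology": 0.020,
            "imaging_only": 0.056,
            "none": 0.011,
        }
    )
    et_duration_months: int = 24
    #: log-linear age effect on the death hazard (per year above/below 60).
    death_age_log_hazard_per_year: float = 0.04
    #: hazard ratio for node-positive disease.
    node_positive_hazard_ratio: float = 1.6
    #: optional noise: probability that an ET-indicated patient refuses ET
    #: (breaks exact subtype recovery; default off).
    et_refusal_prob: float = 0.0

    def validate(self) -> None:
        def check_probs(name, probs):
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1, got {total}")
            if any(p < 0 for p in probs.values()):
                raise ConfigError(f"{name} has negative entries")

        if self.n_patients <= 0:
            raise ConfigError("n_patients must be positive")
        check_probs("subtype_probs", self.subtype_probs)
        check_probs("diagnostic_mode_probs", self.diagnostic_mode_probs)
        check_probs("ct_cycles_probs", self.ct_cycles_probs)
        check_probs("ct_regimen_probs", self.ct_regimen_probs)
        check_probs("ct_regimen_probs_her2", self.ct_regimen_probs_her2)
        check_probs("et_regimen_probs", self.et_regimen_probs)
        if abs(sum(w for w, _, _ in self.age_mixture) - 1.0) > 1e-9:
            raise ConfigError("age mixture weights must sum to 1")
        for st in SUBTYPES:
            if st not in self.subtype_probs:
                raise ConfigError(f"subtype_probs missing {st!r}")
            check_probs(f"pathway_probs[{st!r}]", self.pathway_probs[st])
        for reason, rate in self.contamination_rates.items():
            if reason not in EXCLUSION_REASONS:
                raise ConfigError(f"unknown contamination reason {reason!r}")
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"contamination rate for {reason!r} outside [0, 1]")
        if sum(self.contamination_rates.values()) > 1.0:
            raise ConfigError("contamination rates sum above 1")
        # pathway consistency with the inference maps
        for st in ("TNBC", "HER2+/HR-"):
            if self.pathway_probs[st].get("surgery_no_CT", 0) or self.pathway_probs[st].get("NET", 0):
                raise ConfigError(f"{st} requires chemotherapy-bearing pathways only")
        if any(self.pathway_probs["undefined"].get(p, 0) for p in ("surgery_then_CT", "NAC", "NET")):
            raise ConfigError("undefined subtype admits only surgery_no_CT (or NRT)")


def _choice(rng, probs: dict):
    keys = list(probs)
    return keys[rng.choice(len(keys), p=np.array([probs[k] for k in keys]))]


def _code(dictionary: CodeDictionary, set_name: str) -> tuple:
    return sorted(dictionary[set_name])[0]


_SURGERY_SET_FOR = {
    ("partial", False): "surgery_partial_without_axillary",
    ("partial", True): "surgery_partial_with_axillary",
    ("mastectomy", False): "surgery_total_without_axillary",
    ("mastectomy", True): "surgery_total_with_axillary",
}

_ET_CLASS_TO_SET = {"tamoxifen": "tamoxifen", "ai": "aromatase_inhibitor", "gnrh": "gnrh_agonist"}
_CT_CLASS_TO_SET = {
    "anthracycline": "anthracycline",
    "docetaxel": "docetaxel",
    "paclitaxel": "paclitaxel",
    "other": "other_ct_molecule",
}


def _ct_molecule_plan(regimen: str, n_sessions: int):
    """Molecule class per session index; None for uncoded sessions.
    Returns (per-session classes, taxane start index or 0)."""
    half = n_sessions // 2
    if regimen == "anthracyclines":
        return ["anthracycline"] * n_sessions, 0
    if regimen == "anthracyclines/docetaxel":
        return ["anthracycline"] * half + ["docetaxel"] * (n_sessions - half), half
    if regimen == "anthracyclines/paclitaxel":
        return ["anthracycline"] * half + ["paclitaxel"] * (n_sessions - half), half
    if regimen == "docetaxel":
        return ["docetaxel"] * n_sessions, 0
    if regimen == "paclitaxel":
        return ["paclitaxel"] * n_sessions, 0
    if regimen == "other":
        return ["other"] * n_sessions, 0
    return [None] * n_sessions, 0  # unknown: sessions carry no molecule code


def _et_molecule_plan(regimen: str, days: list, timing: TimingConfig):
    """Return list of (day, molecule class) dispensings for an ET regimen laid
    over monthly *days* (GnRH agonists are 12-weekly depot deliveries)."""
    n = len(days)
    half = max(1, n // 2)
    gnrh_days = days[:: max(1, timing.gnrh_dispense_days // timing.et_dispense_days)]
    if regimen == "tamoxifen":
        return [(d, "tamoxifen") for d in days]
    if regimen == "ai":
        return [(d, "ai") for d in days]
    if regimen == "tamoxifen_then_ai":
        return [(d, "tamoxifen") for d in days[:half]] + [(d, "ai") for d in days[half:]]
    if regimen == "ai_then_tamoxifen":
        return [(d, "ai") for d in days[:half]] + [(d, "tamoxifen") for d in days[half:]]
    if regimen == "tamoxifen_with_gnrh":
        return [(d, "tamoxifen") for d in days] + [(d, "gnrh") for d in gnrh_days]
    if regimen == "ai_with_gnrh":
        return [(d, "ai") for d in days] + [(d, "gnrh") for d in gnrh_days]
    return [(d, "gnrh") for d in gnrh_days]  # "others": GnRH agonists alone


def _rand_int(rng, bounds) -> int:
    lo, hi = bounds
    return int(rng.integers(lo, hi + 1))


def simulate(config: SimulationConfig, dictionary: CodeDictionary | None = None):
    """Generate ``(ClaimsBundle, ground_truth DataFrame)``.

    The same ``config`` (including its seed) always yields bit-identical
    output; different seeds yield disjoint patient ids.
    """
    config.validate()
    if dictionary is None:
        dictionary = default_dictionary()
    rng = np.random.default_rng(config.seed)
    t = config.timing

    win_lo, win_hi = _day(config.incidence_start), _day(config.incidence_end)
    cutoff = _day(config.cutoff_date)

    reasons = list(config.contamination_rates.keys())
    reason_p = np.array([config.contamination_rates[r] for r in reasons])
    p_vec = np.concatenate([reason_p, [1.0 - reason_p.sum()]])

    weights = np.array([w for w, _, _ in config.age_mixture])

    patients_rows = []
    event_rows = []
    truth_rows = []

    for i in range(config.n_patients):
        pid = f"P{config.seed}-{i:06d}"
        reason = (reasons + ["included"])[rng.choice(len(reasons) + 1, p=p_vec)]

        incl = int(rng.integers(win_lo, win_hi + 1))
        comp = int(rng.choice(len(weights), p=weights))
        _, mean, sd = config.age_mixture[comp]
        age = float(np.clip(rng.normal(mean, sd), 19.0, 99.0))
        subtype = _choice(rng, config.subtype_probs)
        pathway = _choice(rng, config.pathway_probs[subtype])

        ft = incl + _rand_int(rng, t.first_treatment_lag)
        birth = ft - int(round(age * 365.25))

        ct = pathway in ("surgery_then_CT", "NAC")
        et = subtype in ("luminal", "HER2+/HR+")
        if et and config.et_refusal_prob and rng.random() < config.et_refusal_prob:
            et = False
        tt = subtype.startswith("HER2")
        rt = rng.random() < config.rt_prob or pathway == "NRT"

        events = []  # (day, system, code, context)

        def add(day, set_name, context):
            sys_, code = _code(dictionary, set_name)
            events.append((int(day), sys_, code, context))

        # --- chemotherapy sessions and surgery date -------------------------
        ct_sessions: list = []
        n_neo = n_adj = 0
        if pathway == "NAC":
            n_neo = int(_choice(rng, config.ct_cycles_probs))
            ct_start = ft
            neo_days = [ct_start + t.ct_cycle_days * k for k in range(n_neo)]
            surgery = neo_days[-1] + _rand_int(rng, t.nac_gap_to_surgery)
            ct_sessions += neo_days
            if rng.random() < config.ct_both_prob:
                n_adj = 3
                adj_start = surgery + _rand_int(rng, t.adj_ct_start)
                ct_sessions += [adj_start + t.ct_cycle_days * k for k in range(n_adj)]
        elif pathway == "NET":
            surgery = ft + _rand_int(rng, t.net_surgery_gap)
        else:
            surgery = ft
        if pathway == "surgery_then_CT":
            n_adj = int(_choice(rng, config.ct_cycles_probs))
            adj_start = surgery + _rand_int(rng, t.adj_ct_start)
            ct_sessions = [adj_start + t.ct_cycle_days * k for k in range(n_adj)]
        ct_sessions.sort()

        # --- surgery --------------------------------------------------------
        breast = "mastectomy" if rng.random() < config.mastectomy_prob else "partial"
        axillary = bool(rng.random() < config.axillary_prob)
        add(surgery, _SURGERY_SET_FOR[(breast, axillary)], "hospital")
        add(incl, "bc_diagnosis", "hospital")
        add(surgery, "bc_diagnosis", "hospital")

        taxane_start = None
        ct_regimen = None
        if ct:
            regimen_probs = config.ct_regimen_probs_her2 if tt else config.ct_regimen_probs
            ct_regimen = _choice(rng, regimen_probs)
            molecules, tax_idx = _ct_molecule_plan(ct_regimen, len(ct_sessions))
            taxane_start = ct_sessions[tax_idx]
            for day, mol in zip(ct_sessions, molecules):
                add(day, "ct_session", "hospital")
                if mol is not None:
                    add(day, _CT_CLASS_TO_SET[mol], "hospital")

        # --- radiotherapy ---------------------------------------------------
        rt_days: list = []
        if rt:
            if pathway == "NRT":
                start = surgery - _rand_int(rng, t.nrt_start_before_surgery)
            else:
                start = surgery + _rand_int(rng, t.adj_rt_start)
            rt_days = [start + t.rt_session_gap * k for k in range(t.rt_sessions)]
            for day in rt_days:
                add(day, "radiotherapy", "hospital")

        # --- targeted therapy -------------------------------------------------
        tt_days: list = []
        tt_regimen = None
        if tt:
            tt_start = (
                taxane_start
                if ct
                else surgery + _rand_int(rng, t.adj_tt_start)
            )
            day = tt_start
            while day <= surgery + t.tt_last_session_cap:
                tt_days.append(day)
                day += t.tt_cycle_days
            tt_regimen = (
                "pertuzumab±trastuzumab"
                if rng.random() < config.tt_pertuzumab_prob
                else "trastuzumab"
            )
            for day in tt_days:
                add(day, "trastuzumab", "hospital")
                if tt_regimen == "pertuzumab±trastuzumab":
                    add(day, "pertuzumab", "hospital")

        # --- endocrine therapy ------------------------------------------------
        et_disp: list = []
        et_regimen = None
        if et:
            et_regimen = _choice(rng, config.et_regimen_probs)
            et_start = ft if pathway == "NET" else surgery + _rand_int(rng, t.adj_et_start)
            monthly = [
                et_start + t.et_dispense_days * k
                for k in range(config.et_duration_months)
            ]
            et_disp = sorted(_et_molecule_plan(et_regimen, monthly, t))
            for day, mol in et_disp:
                add(day, _ET_CLASS_TO_SET[mol], "outpatient")

        # --- nodal status and diagnostics ------------------------------------
        node_positive = bool(rng.random() < config.node_positive_probs[subtype])
        if node_positive:
            add(surgery, "node_disease", "hospital")

        diag_mode = _choice(rng, config.diagnostic_mode_probs)
        if diag_mode == "biopsy":
            diag_day = ft - _rand_int(rng, t.biopsy_lag)
            add(diag_day, "breast_biopsy", "outpatient")
            add(diag_day - _rand_int(rng, t.imaging_chain_gap), "breast_imaging", "outpatient")
        elif diag_mode == "cytology":
            diag_day = ft - _rand_int(rng, t.biopsy_lag)
            add(diag_day, "breast_cytology", "outpatient")
        elif diag_mode == "imaging_only":
            anchor = ft - _rand_int(rng, (5, 20))
            diag_day = anchor - _rand_int(rng, t.imaging_chain_gap)
            add(anchor, "breast_imaging", "outpatient")
            add(diag_day, "breast_imaging", "outpatient")
        else:
            diag_day = ft

        # --- vital status -----------------------------------------------------
        hazard = config.annual_death_hazard[subtype] * math.exp(
            config.death_age_log_hazard_per_year * (age - 60.0)
        )
        if node_positive:
            hazard *= config.node_positive_hazard_ratio
        if hazard > 0:
            death_day = surgery + t.death_min_days + int(rng.exponential(365.25 / hazard))
        else:
            death_day = cutoff + 10**6
        dead = death_day <= cutoff
        horizon = min(death_day, cutoff) if dead else cutoff
        events = [e for e in events if e[0] <= horizon]
        if et:
            # the observable regimen is defined by the dispensings that fit
            # inside the observation horizon
            et_disp = [(d, m) for d, m in et_disp if d <= horizon]
            et_regimen = classify_et_regimen(et_disp)

        sex, plan = "female", "general"
        # --- contaminant defects ---------------------------------------------
        if reason == "male":
            sex = "male"
        elif reason == "under_18":
            minor_age = float(rng.uniform(8.0, 17.4))
            birth = incl - int(round(minor_age * 365.25))
        elif reason == "non_general_plan":
            plan = "other"
        elif reason == "no_surgery":
            surgery_codes = {
                _code(dictionary, s)
                for s in _SURGERY_SET_FOR.values()
            } | {_code(dictionary, "axillary_only")}
            events = [e for e in events if (e[1], e[2]) not in surgery_codes]
        elif reason == "other_cancer":
            events.append(
                (surgery + _rand_int(rng, (-100, 100)), *_code(dictionary, "other_cancer"), "hospital")
            )
        elif reason == "prior_bc":
            events.append(
                (incl - _rand_int(rng, (30, 300)), *_code(dictionary, "bc_diagnosis"), "hospital")
            )
        elif reason == "metastatic":
            events.append(
                (surgery + _rand_int(rng, (-50, 100)), *_code(dictionary, "metastasis"), "hospital")
            )
        elif reason == "corrupt":
            dead, death_day = True, surgery - 1

        patients_rows.append(
            {
                "patient_id": pid,
                "sex": sex,
                "birth_date": _date(birth),
                "insurance_plan": plan,
                "vital_status": "dead" if dead else "alive",
                "death_date": _date(death_day) if dead else pd.NaT,
                "inclusion_date": _date(incl),
            }
        )
        for day, sys_, code, context in events:
            event_rows.append((pid, _date(day), sys_, code, context))

        # Ground truth reflects the timeline actually generated.
        tt_setting = None
        if tt:
            tt_setting = (
                "neoadjuvant_then_adjuvant" if min(tt_days) < surgery else "adjuvant"
            )
        ct_setting = None
        if ct:
            ct_setting = "both" if (n_neo and n_adj) else ("neoadjuvant" if n_neo else "adjuvant")
        tt_combination = None
        if tt:
            if not ct:
                tt_combination = "TT-ET"
            elif ct_regimen in (
                "anthracyclines/docetaxel",
                "anthracyclines/paclitaxel",
            ):
                tt_combination = f"{ct_regimen}-TT"
            elif ct_regimen == "docetaxel":
                tt_combination = "docetaxel-TT"
            elif ct_regimen == "paclitaxel":
                tt_combination = "paclitaxel-TT(Tolaney)"
            else:
                tt_combination = "other"
        truth_rows.append(
            {
                "patient_id": pid,
                "exclusion_reason": reason,
                "true_subtype": subtype,
                "true_pathway": pathway,
                "index_surgery_date": _date(surgery),
                "surgery_type": breast,
                "axillary_surgery": axillary,
                "rt_received": rt,
                "rt_setting": ("neoadjuvant" if pathway == "NRT" else "adjuvant") if rt else None,
                "ct_received": ct,
                "ct_setting": ct_setting,
                "ct_regimen": ct_regimen,
                "ct_cycles_neoadjuvant": n_neo or None,
                "ct_cycles_adjuvant": n_adj or None,
                "et_received": et,
                "et_setting": ("neoadjuvant_then_adjuvant" if pathway == "NET" else "adjuvant") if et else None,
                "et_regimen": et_regimen,
                "tt_received": tt,
                "tt_setting": tt_setting,
                "tt_regimen": tt_regimen,
                "tt_combination": tt_combination,
                "node_positive": node_positive,
                "diagnosis_mode": diag_mode,
                "diagnosis_date": _date(diag_day),
                "dead": dead,
                "death_date": _date(death_day) if dead else pd.NaT,
            }
        )

    patients = pd.DataFrame(patients_rows)
    patients["birth_date"] = pd.to_datetime(patients["birth_date"])
    patients["death_date"] = pd.to_datetime(patients["death_date"])
    patients["inclusion_date"] = pd.to_datetime(patients["inclusion_date"])
    events = pd.DataFrame(
        event_rows, columns=["patient_id", "event_date", "code_system", "code", "care_context"]
    )
    events["event_date"] = pd.to_datetime(events["event_date"])
    truth = pd.DataFrame(truth_rows)
    truth["index_surgery_date"] = pd.to_datetime(truth["index_surgery_date"])
    truth["diagnosis_date"] = pd.to_datetime(truth["diagnosis_date"])
    truth["death_date"] = pd.to_datetime(truth["death_date"])
    return ClaimsBundle(patients=patients, events=events), truth


PRESET_NAMES = ("clean_small", "fresh_like", "contaminated", "survival_demo")


def preset(name: str) -> SimulationConfig:
    """Documented fixed configurations.

    - ``clean_small``: 200 patients, zero contamination; fast fixture.
    - ``fresh_like``: 20,000 patients with the published-marginal defaults and
      a 4.5% metastatic contamination rate (the only exclusion the published
      attrition quantifies as a share of an otherwise eligible population).
    - ``contaminated``: 5,000 patients exercising every exclusion filter.
    - ``survival_demo``: 3,000 patients, elevated death hazards.
    """
    if name == "clean_small":
        return SimulationConfig(n_patients=200, seed=0)
    if name == "fresh_like":
        return SimulationConfig(
            n_patients=20_000, seed=0, contamination_rates={"metastatic": 0.045}
        )
    if name == "contaminated":
        return SimulationConfig(
            n_patients=5_000,
            seed=0,
            contamination_rates={
                "male": 0.010,
                "under_18": 0.005,
                "non_general_plan": 0.060,
                "no_surgery": 0.030,
                "other_cancer": 0.020,
                "prior_bc": 0.020,
                "metastatic": 0.045,
                "corrupt": 0.010,
            },
        )
    if name == "survival_demo":
        return SimulationConfig(
            n_patients=3_000,
            seed=0,
            annual_death_hazard={
                "luminal": 0.045,
                "TNBC": 0.12,
                "HER2+/HR+": 0.066,
                "HER2+/HR-": 0.105,
                "undefined": 0.075,
            },
        )
    raise ConfigError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
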