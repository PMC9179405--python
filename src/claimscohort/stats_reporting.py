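"""Descriptive and survival statistics over the constructed cohort.

Covers the summary-table logic (each block carries its own denominator: the
whole cohort for treatment yes/no flags and subtype shares, the treated
subset for settings, and — for chemotherapy regimens — the number of
chemotherapy *settings*, in which a both-setting patient counts twice),
small-stratum suppression for trend outputs, a Silverman-type critical-
bandwidth multimodality test with kernel-density mode location, and
Kaplan-Meier / reverse Kaplan-Meier / log-rank survival summaries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from statsmodels.nonparametric.kde import KDEUnivariate

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = ("variable", "class", "count", "percent", "denominator_name", "denominator")

DAYS_PER_MONTH = 30.4375


def percent(count, denominator) -> float:
    """Display percentage with 1-decimal half-up rounding (exact decimal
    arithmetic so e.g. 23.4995... rounds up to 23.5)."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    value = Decimal(int(count)) * Decimal(100) / Decimal(int(denominator))
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summary_block(variable, counts: dict, denominator=None, denominator_name="cohort"):
    """Rows of (variable, class, count, percent, denominator_name,
    denominator) for one summary block.  The denominator defaults to the sum
    of the counts."""
    if denominator is None:
        denominator = int(sum(counts.values()))
    rows = []
    for cls, count in counts.items():
        rows.append(
            (variable, cls, int(count), percent(count, denominator), denominator_name, denominator)
        )
    return rows


def _value_counts(series, order=None) -> dict:
    counts = series.value_counts()
    if order is None:
        order = sorted(counts.index)
    return {k: int(counts.get(k, 0)) for k in order}


def summarize_cohort(records: pd.DataFrame, courses: pd.DataFrame | None = None) -> pd.DataFrame:
    """Build the baseline summary table from the cohort record table.

    ``records`` is the one-row-per-included-patient table produced by the
    pipeline (the ``courses`` long table is accepted for symmetry but every
    needed field is carried on ``records``).  Percent denominators follow the
    block logic documented in the module docstring.
    """
    if len(records) == 0:
        return pd.DataFrame(columns=list(SUMMARY_COLUMNS))
    n = len(records)
    rows = []
    rows += summary_block("age_class", _value_counts(records["age_class"]))

    rows += summary_block("subtype", _value_counts(records["subtype"]))
    defined = records[records["subtype"] != "undefined"]
    if len(defined):
        rows += summary_block(
            "subtype_defined",
            _value_counts(defined["subtype"]),
            denominator_name="defined_subtype",
        )

    rows += summary_block(
        "nodal_status",
        {
            "node_negative": int((~records["node_positive"]).sum()),
            "node_positive": int(records["node_positive"].sum()),
        },
    )
    rows += summary_block("surgery_type", _value_counts(records["surgery_type"]))
    rows += summary_block(
        "axillary_surgery",
        {
            "no": int((~records["axillary_surgery"]).sum()),
            "yes": int(records["axillary_surgery"].sum()),
        },
    )

    for modality, flag in (
        ("chemotherapy", "ct_received"),
        ("targeted_therapy", "tt_received"),
        ("radiotherapy", "rt_received"),
        ("endocrine_therapy", "et_received"),
        ("surgery", None),
    ):
        received = records[flag] if flag else pd.Series(True, index=records.index)
        rows += summary_block(
            modality, {"no": int((~received).sum()), "yes": int(received.sum())}
        )

    for prefix, label in (("ct", "ct"), ("tt", "tt"), ("rt", "rt"), ("et", "et")):
        treated = records[records[f"{prefix}_received"]]
        if not len(treated):
            continue
        rows += summary_block(
            f"{label}_setting",
            _value_counts(treated[f"{prefix}_setting"]),
            denominator_name=f"{label}_treated",
        )

    ct = records[records["ct_received"]]
    if len(ct):
        # a both-setting patient contributes her regimen once per setting
        weights = np.where(ct["ct_setting"] == "both", 2, 1)
        counts = (
            pd.Series(weights, index=ct.index).groupby(ct["ct_regimen"]).sum().astype(int)
        )
        rows += summary_block(
            "ct_regimen",
            {k: int(counts.get(k, 0)) for k in sorted(counts.index)},
            denominator=int(weights.sum()),
            denominator_name="ct_settings",
        )
    for prefix in ("tt", "et"):
        treated = records[records[f"{prefix}_received"]]
        if len(treated):
            rows += summary_block(
                f"{prefix}_regimen",
                _value_counts(treated[f"{prefix}_regimen"]),
                denominator_name=f"{prefix}_treated",
            )

    rows += summary_block("main_pathway", _value_counts(records["main_pathway"]))
    table = pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))
    return table


def suppress_small_strata(counts: pd.Series, min_n: int = 50) -> pd.Series:
    """Drop strata with fewer than *min_n* patients from trend outputs;
    removals are logged (an edge-effect guard for continuous-axis figures)."""
    small = counts[counts < min_n]
    if len(small):
        logger.warning(
            "suppressing %d strata below n=%d: %s",
            len(small),
            min_n,
            list(small.index),
        )
    kept = counts[counts >= min_n]
    if not len(kept):
        warnings.warn(f"all strata below n={min_n}; output is empty")
    return kept


# --- Silverman-type multimodality test ------------------------------------


@dataclass
class ModalityResult:
    p_value: float
    n_modes: int
    mode_locations: list
    critical_bandwidth: float
    mode_bandwidth: float | None
    reps: int
    seed: int | None


def _kde_grid(x: np.ndarray, bw: float, gridsize: int = 512):
    kde = KDEUnivariate(x)
    kde.fit(kernel="gau", bw=bw, fft=True, gridsize=gridsize, cut=3)
    return np.asarray(kde.support), np.asarray(kde.density)


def _mode_indices(d: np.ndarray) -> np.ndarray:
    """Interior local maxima of a gridded density, ignoring numerically
    negligible bumps (FFT evaluation ripples in the far tails)."""
    idx = np.where((d[1:-1] > d[:-2]) & (d[1:-1] > d[2:]))[0] + 1
    return idx[d[idx] > 1e-6 * d.max()]


def count_kde_modes(x: np.ndarray, bw: float, gridsize: int = 512) -> int:
    """Number of local maxima of the Gaussian KDE of *x* at bandwidth *bw*."""
    _, d = _kde_grid(x, bw, gridsize)
    return int(len(_mode_indices(d)))


def critical_bandwidth(
    x: np.ndarray, k: int = 1, rel_tol: float = 1e-3, gridsize: int = 512
) -> float:
    """Smallest Gaussian-kernel bandwidth at which the KDE of *x* has at most
    *k* modes (geometric bisection; mode count is non-increasing in the
    bandwidth for Gaussian kernels)."""
    x = np.asarray(x, dtype=float)
    scale = x.std()
    if scale == 0:
        return 0.0
    hi = scale
    while count_kde_modes(x, hi, gridsize) > k:
        hi *= 2.0
    lo = hi / 1024.0
    while count_kde_modes(x, lo, gridsize) <= k:
        lo /= 2.0
        if lo < hi * 1e-8:
            return lo
    while hi / lo > 1.0 + rel_tol:
        mid = float(np.sqrt(lo * hi))
        if count_kde_modes(x, mid, gridsize) <= k:
            hi = mid
        else:
            lo = mid
    return hi


def locate_modes(x, n_modes: int, gridsize: int = 512):
    """Positions of the *n_modes* local maxima of the Gaussian KDE of *x*,
    evaluated at the critical bandwidth for *n_modes* (the least smoothing at
    which the KDE shows at most that many modes — the usual kernel-density
    mode-location convention).

    Returns ``(sorted locations, bandwidth)``.
    """
    x = np.asarray(x, dtype=float)
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    if x.std() == 0:
        return [float(x[0])], 0.0
    if n_modes == 1:
        scott = 1.06 * x.std() * x.size ** (-0.2)
        h = max(scott, critical_bandwidth(x, 1, gridsize=gridsize))
    else:
        # midpoint (geometric) of the bandwidth range showing exactly
        # n_modes: stable against both sampling jitter and merge bias
        h_min = critical_bandwidth(x, n_modes, gridsize=gridsize)
        h_max = critical_bandwidth(x, n_modes - 1, gridsize=gridsize)
        h = float(np.sqrt(h_min * h_max))
        while count_kde_modes(x, h, gridsize) < n_modes and h > h_min:
            h *= 0.97
        while count_kde_modes(x, h, gridsize) > n_modes:
            h *= 1.03
    support, density = _kde_grid(x, h, gridsize)
    peaks = sorted(_mode_indices(density), key=lambda i: density[i], reverse=True)[:n_modes]
    return sorted(float(support[i]) for i in peaks), float(h)


def modality_test(
    values,
    null_modes: int = 1,
    reps: int = 500,
    seed: int | None = None,
    alpha: float = 0.05,
    assessed_modes: int | None = None,
    gridsize: int = 512,
) -> ModalityResult:
    """Silverman-type critical-bandwidth test of the null of at most
    *null_modes* modes.

    The p-value is the fraction of smoothed bootstrap resamples (rescaled to
    preserve the sample variance) whose KDE at the critical bandwidth shows
    more than *null_modes* modes.  When the null is rejected, mode positions
    are located at the maximal bandwidth compatible with *assessed_modes*
    (default ``null_modes + 1`` — the "graphically assessed" count is a
    parameter, not automated).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 20:
        raise ValueError("modality test requires at least 20 observations")
    if reps < 100:
        warnings.warn("fewer than 100 bootstrap replicates: p-value is unstable")
    if x.std() == 0:
        return ModalityResult(1.0, 1, [float(x[0])], 0.0, None, reps, seed)

    h_crit = critical_bandwidth(x, null_modes, gridsize=gridsize)
    rng = np.random.default_rng(seed)
    n = x.size
    var = x.var()
    shrink = 1.0 / np.sqrt(1.0 + h_crit**2 / var)
    exceed = 0
    for _ in range(reps):
        z = x[rng.integers(0, n, n)] + h_crit * rng.standard_normal(n)
        y = z.mean() + (z - z.mean()) * shrink
        if count_kde_modes(y, h_crit, gridsize) > null_modes:
            exceed += 1
    p = exceed / reps

    if p < alpha:
        k = assessed_modes if assessed_modes is not None else null_modes + 1
        locations, h_mode = locate_modes(x, k, gridsize=gridsize)
        return ModalityResult(p, k, locations, h_crit, h_mode, reps, seed)
    locations, h_mode = locate_modes(x, null_modes, gridsize=gridsize)
    return ModalityResult(p, null_modes, locations, h_crit, h_mode, reps, seed)


# --- survival ---------------------------------------------------------------


@dataclass
class SurvivalResult:
    n: int
    n_events: int
    curve: pd.DataFrame  # time (months), survival, at_risk
    median_followup_months: float
    followup_iqr_months: tuple
    logrank: dict = field(default_factory=dict)  # grouping -> (statistic, p)


def km_curve(durations, events) -> pd.DataFrame:
    """Product-limit curve as a tidy frame (time, survival, at_risk)."""
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    out = kmf.survival_function_.reset_index()
    out.columns = ["time", "survival"]
    at_risk = kmf.event_table["at_risk"].reindex(out["time"]).values
    out["at_risk"] = at_risk
    return out


def _followup_quantile(kmf: KaplanMeierFitter, q: float) -> float:
    """Follow-up quantile q from the reverse-KM censoring curve: the first
    time at which the censoring-survival drops to 1 - q."""
    from lifelines.utils import qth_survival_times

    return float(qth_survival_times(1.0 - q, kmf.survival_function_))


def km_analysis(
    records: pd.DataFrame,
    groupings=("age_class", "subtype", "node_positive"),
) -> SurvivalResult:
    """Overall-survival analysis of the cohort record table.

    Uses the precomputed ``survival_months`` (index surgery to death or
    administrative cutoff) and ``event`` columns; median follow-up and its
    IQR come from the reverse Kaplan-Meier estimator (censoring treated as
    the event); log-rank tests compare survival across each grouping.
    """
    durations = records["survival_months"].to_numpy(dtype=float)
    events = records["event"].to_numpy(dtype=bool)
    curve = km_curve(durations, events)

    rkm = KaplanMeierFitter()
    rkm.fit(durations, event_observed=~events)
    median_fu = _followup_quantile(rkm, 0.5)
    iqr = (_followup_quantile(rkm, 0.25), _followup_quantile(rkm, 0.75))

    logrank = {}
    for grouping in groupings:
        if grouping not in records.columns:
            continue
        if not events.any() or records[grouping].nunique() < 2:
            logrank[grouping] = None  # not applicable
            continue
        res = multivariate_logrank_test(durations, records[grouping], events)
        logrank[grouping] = (float(res.test_statistic), float(res.p_value))

    return SurvivalResult(
        n=len(records),
        n_events=int(events.sum()),
        curve=curve,
        median_followup_months=median_fu,
        followup_iqr_months=iqr,
        logrank=logrank,
    )
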