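# Methods

## Setting and rationale

Claims databases record reimbursements, not diagnoses of record: a breast
cancer cohort must therefore be *constructed* from coded traces — hospital
stay diagnoses (ICD-10), procedures (CCAM), outpatient drug deliveries and
in-hospital costly-drug administrations (both normalised to ATC), and
long-term-illness records. This package implements that construction and
validates every stage on simulated claims with known generative labels,
because the real national database cannot be redistributed.

All dates are calendar dates; all arithmetic is in whole days. A "month" is
30 days and a year 365 days wherever a coded rule needs a constant (both
configurable); ages are rounded half-up on a 365.25-day year.

## Selection filters

Ten filters run in a fixed order; a patient failing several is attributed
to the first, which makes the attrition report chain exactly. Order:
breast-cancer code present; inclusion date in the 2011–2017 incidence
window; female; age ≥ 18 at inclusion; general insurance plan; breast
surgery within 365 days of inclusion (fixes the index surgery and screens
out relapses of earlier disease); no other-cancer code in the observation
window; no breast-cancer code in the 365 days before inclusion; no
metastasis code in [inclusion − 365 d, index surgery + 180 d] (stage IV
suspicion); record quality. The quality filter rejects impossible
chronologies — events after death or before birth. (A further rule for
conflicting duplicate surgeries across hospitals is not implementable here:
the data model carries no hospital identifier.)

## Treatment detection

The **index surgery** is the earliest breast operation (axillary-only
surgery never qualifies) between the start of the inclusion year and
inclusion + 365 d. Patient-level surgery binning is "most extensive wins":
any total mastectomy ⇒ mastectomy; any axillary component ⇒ axillary
surgery. Same-day code ties resolve the same way.

Windows are closed on both ends: RT [−150, +365]; CT, TT and nodal-status
codes [−250, +180] days from the index surgery. Sessions strictly before
the index day are neoadjuvant; sessions on or after it (including the index
day itself — same-day administration is post-operative) are adjuvant. RT
and CT settings are {neoadjuvant, adjuvant, both}; ET and TT, which
continue across surgery rather than restart, use {neoadjuvant-then-adjuvant,
adjuvant}.

Chemotherapy **cycles** merge sessions closer than 7 days (the shortest
standard inter-cycle interval, weekly paclitaxel), separately per setting.
The 7-way CT regimen uses the molecule classes coded on in-window sessions;
sessions without any molecule code are "unknown" (anthracycline- and
docetaxel-only regimens are typically invisible in hospital coding), and
any combination outside the five named anthracycline/taxane patterns is
"other".

**Endocrine therapy** is detected from outpatient deliveries of tamoxifen,
aromatase inhibitors or GnRH agonists from 250 days before the index
surgery onward. GnRH-agonist deliveries in the 30 days before chemotherapy
start, in patients with no tamoxifen/AI delivery ever, are treated as
fertility preservation and discarded. A course ends one 30-day pack after
the last delivery. The 7-way ET regimen follows the molecules over the
whole study period; "followed by" demands a single switch (every delivery
of the first molecule precedes every delivery of the second), and GnRH
alone, three-molecule patterns and interleaved sequences fall into
"others".

**Targeted therapy** is trastuzumab/pertuzumab; any pertuzumab delivery
forms the "pertuzumab ± trastuzumab" class. TT–systemic combinations are
classified from the CT regimen when the TT and CT course date ranges
overlap by at least one day; TT with ET and no CT is the TT-ET class;
everything else is "other".

## Diagnosis dating and phenotype

The first-treatment date is the minimum of the index surgery and any
neoadjuvant course start. Diagnosis precedence: earliest core biopsy within
365 days before first treatment; else earliest cytology in that window;
else a backward walk from the imaging procedure closest to (not after)
first treatment through imaging events separated by ≤ 30 days, taking the
earliest reached; else the first-treatment date itself.

Subtype is inferred from treatment specificity — TT ⇒ HER2+ (ET splits
HR+/HR−), ET without TT ⇒ luminal, CT alone ⇒ TNBC, neither ⇒ undefined —
a total function on the (CT, ET, TT) truth table. The main care pathway
applies precedence NAC > NRT > NET, then splits surgery-first patients on
adjuvant CT. The canonical treatment sequence has nine slots (NAC, NTT,
NRT, NET, surgery, adjuvant CT/TT/RT/ET); a neoadjuvant-then-adjuvant
ET/TT course fills only its neoadjuvant slot, because continuation after
surgery is not new adjuvant therapy.

## Statistics

Summary tables carry an explicit denominator per block: the whole cohort
for treatment yes/no, subtype, nodal status and pathways; the treated
subset for settings and ET/TT regimens; and, for CT regimens, the number of
*setting instances*, in which a both-setting patient counts twice.
Percentages are displayed with one decimal, rounded half-up with exact
decimal arithmetic. Trend outputs drop strata under 50 patients.

The multimodality test is Silverman-type: the critical bandwidth h* is the
smallest Gaussian-KDE bandwidth with at most k modes (geometric bisection,
relative tolerance 1e-3; mode counts are non-increasing in the bandwidth);
the p-value is the fraction of 500 smoothed bootstrap resamples (variance-
rescaled) whose KDE at h* shows more than k modes. KDE evaluation uses
statsmodels' FFT path on a 512-point grid; local maxima below 1e-6 of the
peak density are ignored (FFT ripple in the far tails). The assessed mode
count after rejection is a parameter (default k + 1), not automated; mode
positions are read at the geometric midpoint of the bandwidth range showing
exactly that many modes, which is stable against both sampling jitter and
merge bias. Constant samples are unimodal with p = 1 by convention.

Overall survival runs from the index surgery to death or the 2019-03-01
administrative cutoff, in months of 30.4375 days. Kaplan-Meier, reverse
Kaplan-Meier (censoring as the event; follow-up quantiles read off the
censoring-survival curve) and log-rank tests come from lifelines; tests are
reported as not applicable when there are no events or a single group.

## The synthetic-data generator

The generator works phenotype-first: it draws age at diagnosis from a
two-component Gaussian mixture, a subtype, and a care pathway conditional
on subtype, then lays the implied events on a day grid — surgery, 21-day
chemotherapy cycles (with molecule codes per regimen, or none for
"unknown"), radiotherapy session blocks, monthly ET deliveries (12-weekly
for GnRH depots), 21-day TT administrations aligned with the taxane phase
when chemotherapy is present, node-disease codes, and a diagnostic work-up
(biopsy / cytology / imaging chain / none). Contaminant patients are
generated clean and then given exactly the defect their exclusion filter
targets. Treatments are the *inverse* of the subtype-inference map, so on
noise-free data the pipeline must recover subtype, pathway and every
setting label exactly — the pipeline-recovery test asserts the identity
confusion matrix. An optional ET-refusal probability (default 0) breaks
this identity deliberately.

Default parameters are the published cohort's marginals: subtype shares
65.1 / 7.7 / 5.3 / 3.0 / 18.9% (luminal / TNBC / HER2+HR+ / HER2+HR− /
undefined); age mixture 0.45·N(50.3, 4.0²) + 0.55·N(65.0, 4.5²) — the SDs
are set so the mixture *density* truly peaks at the component means, since
wider overlapping components pull modes inward; conditional pathway
probabilities solved so the implied marginals reproduce the printed
pathway (60.8 / 30.9 / 7.4 / 0.9%), treatment (RT 85.3, ET 70.4, CT 38.3,
TT 8.4%) and setting splits; per-subtype node-positive rates (21.5% luminal
… 30.1% HER2+HR−, overall ≈ 18.8%); regimen mixes from the printed
distributions. Death is a shifted exponential: no deaths within ~14 months
of surgery (so generated treatment timelines never collide with the death
date except for the deliberate "corrupt" contaminant), with per-subtype
baseline hazards scaled log-linearly in age (4%/year around 60) and by 1.6
for node-positive disease, calibrated so ~6.6% die before the cutoff and
the median reverse-KM follow-up is ≈ 55 months. The `fresh_like` preset
adds a 4.5% metastatic contamination rate, the one exclusion quantified as
a share of the otherwise-eligible population.

What the generator does **not** emulate: age–subtype–pathway dependence
beyond independence given subtype (no joint distribution is published);
comorbidity and non-oncologic claims noise; hospital identifiers; coding
errors and inter-center coding drift; calendar trends in practice. Passing
recovery tests therefore demonstrates the *logic* of the construction, not
its operating characteristics on real claims, where code-list quality and
coding noise dominate.

## Numerical and design choices

- Windows closed at both endpoints ("between X before and up to Y after"
  reads inclusive); index-day sessions count as adjuvant.
- Cycle merge gap 7 d, ET pack 30 d, fertility window 30 d, imaging chain
  gap 30 d — all configurable constants serialised into the run manifest.
- The biopsy/cytology window is closed at the treatment date itself.
- Re-initiated adjuvant ET after a neoadjuvant course is treated as
  continuation (fills only the neoadjuvant slot), matching the sequence
  display rule.
- NRT-only patients form an explicit rare fifth pathway class rather than
  being folded into "other".
- Problem sizes: the default test suite simulates 2,000 (clean) and 5,000
  (contaminated) patients; the acceptance script 20,000 — sizes at which
  every stochastic marginal is stable to well under a percentage point
  while the whole suite runs in seconds.

## Known limitations

Subtype is a treatment proxy: HR+ patients who refuse ET and HER2+ patients
never given TT are misclassified by construction, and nothing in claims can
recover them. CT regimens are only partially identifiable from coding, so
"unknown" is a large, structural class. The ten filters' operational
definitions (metastasis code list, quality rules, multi-surgery handling)
are configuration standing in for unavailable national code lists; swapping
in real lists via `codes.json` changes no logic. The death model is
minimal — adequate to exercise survival code, not a clinical survival
model.
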