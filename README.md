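# claimscohort

Construction of an early breast cancer cohort from longitudinal
reimbursement-claims data — the kind of national medico-administrative
database (ICD-10 hospital diagnoses, CCAM procedures, ATC drug deliveries,
long-term-illness records) in which no tumor histology is recorded and every
clinical fact must be *inferred* from reimbursement traces.

The package is aimed at epidemiologists and biostatisticians who build
claims-based phenotypes. It implements, as a tested pipeline:

1. **Selection** — ten ordered inclusion/exclusion filters (breast-cancer
   code, incidence window 2011–2017, female, adult, general insurance plan,
   surgery within a year of inclusion, no concomitant other cancer, no prior
   breast cancer in the lookback year, no metastasis suspicion, internally
   consistent record) with a chained attrition report.
2. **Treatment detection** — each modality is detected in a closed day
   window around the *index surgery* (the first curative breast operation):
   radiotherapy in [−150, +365], chemotherapy / anti-HER2 targeted therapy
   in [−250, +180]. Sessions strictly before the index date form the
   neoadjuvant component, on/after it the adjuvant component. Regimens are
   classified 7-way for chemotherapy (anthracyclines / taxanes / other /
   unknown), 7-way for endocrine therapy (tamoxifen, aromatase inhibitors,
   GnRH agonists and their sequences), 2-way for targeted therapy, and 6-way
   for TT–systemic-treatment combinations (including the
   paclitaxel–trastuzumab Tolaney regimen). Chemotherapy cycles are counted
   per setting with a gap-merge rule.
3. **Diagnosis dating** — core biopsy ≻ fine-needle cytology ≻ backward
   chain of breast imaging procedures separated by ≤ 1 month ≻ first
   treatment date; age at diagnosis is the rounded year difference.
4. **Phenotyping** — subtype inferred from treatment specificity
   (TT ⇒ HER2+, split by ET into HR+/HR−; ET without TT ⇒ luminal; CT alone
   ⇒ TNBC; surgery ± RT only ⇒ undefined), nodal status from node-disease
   codes in [−250, +180], and the main care pathway with precedence
   NAC > NRT > NET over surgery-first pathways.
5. **Statistics** — block-denominator summary tables (a both-setting
   chemotherapy patient counts twice in the regimen denominator),
   small-stratum suppression (n < 50), a Silverman-type critical-bandwidth
   multimodality test with KDE mode location, and Kaplan-Meier /
   reverse-Kaplan-Meier / log-rank survival summaries.

Because the real national claims database is access-restricted, the package
ships a **ground-truth-labeled synthetic claims generator**
(`claimscohort.synthetic_claims`) that lays out reimbursement timelines by
inverting the pipeline's own inference maps, and injects contaminant
patients that exercise every exclusion filter. Every downstream stage is
validated against the generator's labels.

## Worked example

```python
import dataclasses
from claimscohort import build_cohort
from claimscohort.synthetic_claims import preset, simulate
from claimscohort.stats_reporting import km_analysis, modality_test

cfg = dataclasses.replace(preset("contaminated"), seed=42)
bundle, truth = simulate(cfg)                    # 5,000 synthetic patients
records, courses, report = build_cohort(bundle)  # filters + phenotyping
print(report.to_frame().to_string(index=False))
```

```
        filter_name  n_before  n_excluded  n_after
       bc_diagnosis      5000           0     5000
   incidence_window      5000           0     5000
             female      5000          56     4944
              adult      4944          18     4926
       general_plan      4926         270     4656
surgery_within_year      4656         157     4499
    no_other_cancer      4499          87     4412
        no_prior_bc      4412          82     4330
     non_metastatic      4330         224     4106
       data_quality      4106          51     4055
```

Each row is one filter applied in order: 5,000 simulated patients enter,
945 injected contaminants are removed each at its intended stage, and 4,055
patients form the cohort. Continuing:

```python
m = records.merge(truth, on="patient_id", suffixes=("", "_true"))
print("subtype recovery:", (m.subtype == m.true_subtype).mean())
mod = modality_test(records["age"].to_numpy(float), reps=500, seed=42)
print(f"age bimodality p = {mod.p_value:.3f}; modes at "
      + ", ".join(f"{x:.1f}" for x in mod.mode_locations))
surv = km_analysis(records)
print(f"median follow-up {surv.median_followup_months:.1f} months, "
      f"{surv.n_events} deaths ({100*surv.n_events/surv.n:.1f}%)")
```

```
subtype recovery: 1.0
age bimodality p = 0.000; modes at 50.4, 65.1
median follow-up 54.8 months, 261 deaths (6.4%)
```

On noise-free synthetic data the treatment-based subtype is recovered
exactly; the age-at-diagnosis distribution is detected as bimodal with
incidence peaks near 50 and 65 years; follow-up is summarised by the
reverse Kaplan-Meier estimator.

The same chain is scripted step by step under `analysis/`
(`01_simulate.py` → `02_build_cohort.py` → `03_describe.py` →
`04_survival.py`; summary tables land in `results/`, row-level data in
`scratch/`), and is available as a CLI:

```bash
claimscohort simulate --preset fresh_like --seed 1 --out scratch/claims
claimscohort build-cohort --input scratch/claims --out scratch/cohort
claimscohort summarize --cohort scratch/cohort/cohort.csv --out results
claimscohort run --preset clean_small --seed 1 --out results/run
```

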