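#!/usr/bin/env python
"""Overall survival: Kaplan-Meier curve, reverse-KM follow-up, log-rank.

Overall survival runs from the index surgery to death or the administrative
cutoff; median follow-up and its IQR come from the reverse Kaplan-Meier
estimator; log-rank tests compare survival across age class, inferred
subtype and nodal status.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from claimscohort.stats_reporting import km_analysis


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("scratch/cohort/cohort.csv"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    records = pd.read_csv(args.cohort)
    surv = km_analysis(records)
    args.results.mkdir(parents=True, exist_ok=True)
    surv.curve.to_csv(args.results / "survival.csv", index=False)
    summary = {
        "n": surv.n,
        "n_events": surv.n_events,
        "median_followup_months": surv.median_followup_months,
        "followup_iqr_months": list(surv.followup_iqr_months),
        "logrank": {k: (list(v) if v else None) for k, v in surv.logrank.items()},
    }
    with open(args.results / "survival_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)

    print(f"n = {surv.n}, deaths = {surv.n_events} "
          f"({100 * surv.n_events / surv.n:.1f}%)")
    print(f"median follow-up {surv.median_followup_months:.1f} months "
          f"(IQR {surv.followup_iqr_months[0]:.1f}-{surv.followup_iqr_months[1]:.1f})")
    for grouping, res in surv.logrank.items():
        if res is None:
            print(f"log-rank {grouping}: not applicable")
        else:
            print(f"log-rank {grouping}: chi2 = {res[0]:.1f}, p = {res[1]:.2e}")


if __name__ == "__main__":
    main()
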