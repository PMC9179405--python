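#!/usr/bin/env python
"""Generate the synthetic claims database used by the downstream analyses.

Draws a population from the published-marginal preset (bimodal age mixture,
subtype and pathway mix, 4.5% metastatic contamination), writes the claims
tables plus the generative ground truth, and prints what was generated.
Bulky row-level outputs go under scratch/ by default.
"""

import argparse
import dataclasses
from pathlib import Path

from claimscohort.claims_model import write_claims
from claimscohort.synthetic_claims import preset, simulate


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n", type=int, default=20_000)
    ap.add_argument("--out", type=Path, default=Path("scratch/claims"))
    args = ap.parse_args()

    cfg = dataclasses.replace(preset("fresh_like"), seed=args.seed, n_patients=args.n)
    bundle, truth = simulate(cfg)
    write_claims(bundle, args.out)
    truth.to_csv(args.out / "ground_truth.csv", index=False)

    print(f"wrote {len(bundle.patients)} patients / {len(bundle.events)} events to {args.out}")
    print("exclusion reasons injected:")
    print(truth.exclusion_reason.value_counts().to_string())


if __name__ == "__main__":
    main()
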