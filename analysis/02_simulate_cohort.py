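"""Simulate the study cohort: 35 Rescorla-Wagner agents plus ratings.

Each agent plays both phases of the frozen schedule with its own learning
rates, inverse temperatures and initial stimulus values; subjective
pleasantness ratings come from the additive cell-means model (no-loss
rated above loss, positive imagery above neutral, no interaction).  The
bundle (per-subject choice CSVs, condition table, ground truth) is written
for the downstream fitting and inference stages.
"""

import argparse
from pathlib import Path

from conflictval.cohort import CohortSpec, sample_cohort, write_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-subjects", type=int, default=35)
    ap.add_argument("--out", type=Path, default=Path("results/cohort"))
    args = ap.parse_args()

    spec = CohortSpec(n_subjects=args.n_subjects, seed=args.seed)
    cohort = sample_cohort(spec)
    write_cohort(cohort, args.out)
    rates = [
        cd.responded.mean() for per in cohort.choices.values() for cd in per.values()
    ]
    print(
        f"cohort of {spec.n_subjects} subjects (seed {args.seed}) written to {args.out}; "
        f"mean response rate {100 * sum(rates) / len(rates):.1f}%"
    )


if __name__ == "__main__":
    main()
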