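"""Fit the choice model to every simulated agent and test learning rates.

Runs the exhaustive grid search per subject and phase (6-point-per-axis
grid over the six parameters), then the per-phase learning-rate tests:
each stimulus's alpha against zero, chair vs plane, and deemed-high vs
deemed-low inherent value, with JZS BF01 for the paired nulls.
"""

import argparse
from pathlib import Path

from conflictval import study
from conflictval.cohort import read_cohort
from conflictval.rl import GridSpec


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--grid", choices=["coarse", "default"], default="coarse")
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    _, choices = read_cohort(args.cohort)
    grid = GridSpec.coarse() if args.grid == "coarse" else GridSpec.default()
    fits = study.fit_cohort(choices, grid)
    fits.to_csv(args.out / "fits.tsv", sep="\t", index=False, lineterminator="\n")
    tests = study.learning_rate_tests(fits, choices)
    tests.to_csv(args.out / "learning_rates.tsv", sep="\t", index=False, lineterminator="\n")
    print(f"fit {len(fits)} subject-phases on a {grid.n_points}-point grid")
    for row in tests.itertuples():
        bf = f", BF01 {row.bf01:.3f}" if row.bf01 == row.bf01 else ""
        print(f"  {row.test_id}: t({int(row.df1)}) = {row.statistic:.3f}, p = {row.p:.3f}{bf}")


if __name__ == "__main__":
    main()
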