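"""Choice proportions against chance and the 2x2 ratings ANOVA.

Per phase: chair/plane choice percentages and loss-following percentages
tested against 50% (the choices should be unbiased and the predetermined
outcomes uninformative), then the within-subject Emotion x Loss ANOVA on
the ratings with the contrast-based interaction BF01.
"""

import argparse
from pathlib import Path

import pandas as pd

from conflictval import study
from conflictval.cohort import read_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    conditions, choices = read_cohort(args.cohort)
    frames = [study.choice_tests(choices)]
    for measure in sorted(conditions["measure"].unique()):
        frames.append(study.ratings_anova(conditions, measure))
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(args.out / "behavior.tsv", sep="\t", index=False, lineterminator="\n")
    for row in table.itertuples():
        if row.method == "F":
            print(f"  {row.test_id}: F(1,{int(row.df2)}) = {row.statistic:.2f}, p = {row.p:.4f}")
        elif row.method == "interaction_contrast":
            print(
                f"  {row.test_id}: F(1,{int(row.df2)}) = {row.statistic:.2f}, "
                f"p = {row.p:.4f}, BF01 = {row.bf01:.2f}"
            )
        elif row.method == "mean":
            print(f"  {row.test_id}: {row.estimate:.1f}%")
        else:
            print(f"  {row.test_id}: t({int(row.df1)}) = {row.statistic:.2f}, p = {row.p:.3f}")


if __name__ == "__main__":
    main()
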