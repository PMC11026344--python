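"""Cohort-level analyses over fitted agents and condition tables.

These routines reproduce the shape of the study's behavioral result tables
on any cohort: choice proportions tested against chance, per-phase
learning-rate tests (against zero, chair vs plane, deemed high vs low
inherent value) with default-prior Bayes factors for the null results, and
the 2x2 ratings ANOVA.  All return tidy frames with one test per row:
``test_id, statistic, df1, df2, p, estimate, bf01, method, prior_scale``.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

from .rl import ChoiceData, FitResult, GridSpec, fit_phases
from .stats import (
    choice_summary,
    classify_inherent_value,
    interaction_bf01,
    jzs_bf01_t,
    one_sample_t,
    paired_t,
    rm_anova_2x2,
)

__all__ = [
    "fit_cohort",
    "choice_tests",
    "learning_rate_tests",
    "ratings_anova",
    "RESULT_COLUMNS",
]

RESULT_COLUMNS = [
    "test_id",
    "statistic",
    "df1",
    "df2",
    "p",
    "estimate",
    "bf01",
    "method",
    "prior_scale",
]


def fit_cohort(
    choices: Mapping[int, Mapping[int, ChoiceData]],
    grid: GridSpec,
    reward_coding: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Grid-fit every subject and phase; one row per subject x phase."""
    rows = []
    for subject in sorted(choices):
        fits = fit_phases(choices[subject], grid, reward_coding)
        for phase, res in sorted(fits.results.items()):
            p = res.params
            rows.append(
                {
                    "subject": subject,
                    "phase": phase,
                    "alpha_chair": p.alpha_chair,
                    "alpha_plane": p.alpha_plane,
                    "beta_chair": p.beta_chair,
                    "beta_plane": p.beta_plane,
                    "v0_chair": p.v0_chair,
                    "v0_plane": p.v0_plane,
                    "mse": res.mse,
                    "n_trials_used": res.n_trials_used,
                }
            )
        for phase, err in sorted(fits.errors.items()):
            rows.append({"subject": subject, "phase": phase, "error": err})
    return pd.DataFrame(rows)


def _row(test_id, test, bf=None):
    df1 = test.df[0] if len(test.df) >= 1 else math.nan
    df2 = test.df[1] if len(test.df) >= 2 else math.nan
    return {
        "test_id": test_id,
        "statistic": test.statistic,
        "df1": df1,
        "df2": df2,
        "p": test.p,
        "estimate": test.estimate,
        "bf01": bf.bf01 if bf is not None else math.nan,
        "method": bf.method if bf is not None else "t",
        "prior_scale": bf.prior_scale if bf is not None else math.nan,
    }


def choice_tests(
    choices: Mapping[int, Mapping[int, ChoiceData]], r_scale: float = 0.707
) -> pd.DataFrame:
    """Per-phase one-sample t tests of choice percentages against chance (50),
    exactly on raw percentages, plus the cohort response rate."""
    per_subject = {s: choice_summary(cd) for s, cd in choices.items()}
    summary = pd.concat(
        [df.assign(subject=s) for s, df in per_subject.items()], ignore_index=True
    )
    rows = []
    for phase, grp in summary.groupby("phase", sort=True):
        for metric in ("prop_chair", "prop_plane", "loss_after_chair", "loss_after_plane"):
            vals = grp[metric].dropna().to_numpy() * 100.0
            test = one_sample_t(vals, 50.0)
            bf = jzs_bf01_t(test.statistic, test.n, r_scale)
            rows.append(_row(f"phase{phase}_{metric}_vs_50", test, bf))
        rows.append(
            {
                "test_id": f"phase{phase}_response_rate",
                "statistic": math.nan,
                "df1": math.nan,
                "df2": math.nan,
                "p": math.nan,
                "estimate": float(grp["response_rate"].mean() * 100.0),
                "bf01": math.nan,
                "method": "mean",
                "prior_scale": math.nan,
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def learning_rate_tests(
    fits: pd.DataFrame,
    choices: Mapping[int, Mapping[int, ChoiceData]],
    r_scale: float = 0.707,
) -> pd.DataFrame:
    """Per-phase learning-rate inference on a cohort fit table.

    Tests each stimulus's fitted alpha against zero, chair vs plane paired,
    and deemed-high vs deemed-low inherent value paired (ties excluded);
    every paired test carries its JZS BF01.
    """
    rows = []
    labels = {s: classify_inherent_value(cd) for s, cd in choices.items()}
    for phase, grp in fits.groupby("phase", sort=True):
        grp = grp.sort_values("subject")
        a_chair = grp["alpha_chair"].to_numpy()
        a_plane = grp["alpha_plane"].to_numpy()
        for name, vals in (("alpha_chair", a_chair), ("alpha_plane", a_plane)):
            test = one_sample_t(vals, 0.0)
            rows.append(_row(f"phase{phase}_{name}_vs_0", test))
        test = paired_t(a_chair, a_plane)
        rows.append(
            _row(f"phase{phase}_alpha_chair_vs_plane", test, jzs_bf01_t(test.statistic, test.n, r_scale))
        )
        high, low = [], []
        for subject, row in zip(grp["subject"], grp.itertuples()):
            lab = labels[subject][phase]
            if lab["tie"]:
                continue
            if lab["high"] == "chair":
                high.append(row.alpha_chair)
                low.append(row.alpha_plane)
            else:
                high.append(row.alpha_plane)
                low.append(row.alpha_chair)
        if len(high) >= 2 and np.std(np.subtract(high, low), ddof=1) > 0:
            test = paired_t(high, low)
            rows.append(
                _row(
                    f"phase{phase}_alpha_high_vs_low",
                    test,
                    jzs_bf01_t(test.statistic, test.n, r_scale),
                )
            )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def ratings_anova(
    conditions: pd.DataFrame, measure: str = "rating", r_scale: float = 0.707
) -> pd.DataFrame:
    """2x2 within-subject ANOVA on a condition measure, plus the
    contrast-based interaction BF01."""
    anova = rm_anova_2x2(conditions, measure)
    bf = interaction_bf01(conditions, r_scale=r_scale, measure=measure)
    rows = []
    for effect, F, p, est in (
        ("emotion", anova.F_emotion, anova.p_emotion, anova.contrast_emotion),
        ("loss", anova.F_loss, anova.p_loss, anova.contrast_loss),
        ("interaction", anova.F_interaction, anova.p_interaction, anova.contrast_interaction),
    ):
        rows.append(
            {
                "test_id": f"{measure}_anova_{effect}",
                "statistic": F,
                "df1": anova.df[0],
                "df2": anova.df[1],
                "p": p,
                "estimate": est,
                "bf01": bf.bf01 if effect == "interaction" else math.nan,
                "method": bf.method if effect == "interaction" else "F",
                "prior_scale": bf.prior_scale if effect == "interaction" else math.nan,
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)
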