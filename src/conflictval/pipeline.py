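"""Measure-level factorial inference: indices, conjunction, adjudication.

Operates on a finite list of measures (ROI estimates or ratings) rather
than voxel maps: per measure it runs the within-subject 2x2 ANOVA, computes
per-subject main-effect indices, correlates them across subjects with
Bonferroni control and a default-prior correlation Bayes factor, intersects
the two main-effect significance masks (the conjunction), and adjudicates
each measure as additive, interactive, partial or indeterminate.

The adjudication rule is an explicit operationalization (recorded in the
output): a significant interaction is "interactive"; both main effects
significant with a non-significant interaction and BF01 at or above the
null-evidence threshold is "additive"; both mains significant without that
null evidence is "partial"; anything else is "indeterminate".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import (
    AnovaResult2x2,
    BayesFactorResult,
    TestResult,
    bonferroni,
    cell_matrix,
    interaction_bf01,
    jeffreys_bf01_corr,
    pearson_corr,
    rm_anova_2x2,
)

__all__ = [
    "EffectIndices",
    "MeasureReport",
    "compute_indices",
    "correlate_indices",
    "conjunction",
    "adjudicate",
    "analyze_measures",
]


@dataclass
class EffectIndices:
    """Per-subject main-effect indices for one measure.

    emotion_index = (PL + PNL) - (NL + NNL); loss_index = (PL + NL) - (PNL + NNL),
    raw sums with no scaling.
    """

    measure: str
    subjects: np.ndarray
    emotion_index: np.ndarray
    loss_index: np.ndarray


@dataclass
class MeasureReport:
    measure: str
    anova: AnovaResult2x2
    emotion_significant: bool
    loss_significant: bool
    conjunction: bool
    interaction_significant: bool
    bf01_interaction: float
    adjudication: str
    alpha: float
    bf_null_threshold: float


def compute_indices(table: pd.DataFrame, measure: str | None = None) -> EffectIndices:
    """Exact {+1, -1} linear combinations of the four cells, per subject."""
    df = table
    if measure is not None and "measure" in df.columns:
        df = df[df["measure"] == measure]
    cells = cell_matrix(df)
    subjects = np.sort(df["subject"].unique()) if "subject" in df.columns else np.arange(
        1, cells.shape[0] + 1
    )
    pl, pnl, nl, nnl = cells.T
    return EffectIndices(
        measure=measure if measure is not None else "measure",
        subjects=subjects,
        emotion_index=(pl + pnl) - (nl + nnl),
        loss_index=(pl + nl) - (pnl + nnl),
    )


def correlate_indices(
    indices: EffectIndices | Sequence[EffectIndices],
    k_measures: int | None = None,
    alpha_family: float = 0.05,
    kappa: float = 1.0,
) -> pd.DataFrame:
    """Cross-subject Pearson correlation between the emotion and loss
    indices, per measure, thresholded at the Bonferroni-corrected level and
    accompanied by the default correlation Bayes factor."""
    items = [indices] if isinstance(indices, EffectIndices) else list(indices)
    k = k_measures if k_measures is not None else len(items)
    threshold = bonferroni(alpha_family, k)
    rows = []
    for idx in items:
        if np.std(idx.emotion_index, ddof=1) == 0 or np.std(idx.loss_index, ddof=1) == 0:
            raise ValueError(f"zero variance in an effect index for measure {idx.measure!r}")
        test: TestResult = pearson_corr(idx.emotion_index, idx.loss_index)
        bf: BayesFactorResult = jeffreys_bf01_corr(test.estimate, test.n, kappa)
        rows.append(
            {
                "measure": idx.measure,
                "r": test.estimate,
                "t": test.statistic,
                "df": test.df[0],
                "p": test.p,
                "alpha_per_test": threshold,
                "significant": test.p < threshold,
                "bf01": bf.bf01,
                "prior_kappa": bf.prior_scale,
                "n": test.n,
            }
        )
    return pd.DataFrame(rows)


def conjunction(
    emotion_flags: Sequence[bool], loss_flags: Sequence[bool]
) -> list[bool]:
    """Logical intersection of the two main-effect significance masks."""
    if len(emotion_flags) != len(loss_flags):
        raise ValueError("flag lists must be aligned")
    return [bool(e) and bool(l) for e, l in zip(emotion_flags, loss_flags)]


def adjudicate(
    anova: AnovaResult2x2,
    bf_interaction: BayesFactorResult | float,
    alpha: float = 0.05,
    bf_null_threshold: float = 3.0,
) -> str:
    """Label a measure's integration pattern; see module docstring for the rule."""
    bf01 = bf_interaction.bf01 if isinstance(bf_interaction, BayesFactorResult) else float(
        bf_interaction
    )
    if anova.p_interaction < alpha:
        return "interactive"
    mains = anova.p_emotion < alpha and anova.p_loss < alpha
    if mains and bf01 >= bf_null_threshold:
        return "additive"
    if mains:
        return "partial"
    return "indeterminate"


def analyze_measures(
    table: pd.DataFrame,
    measures: Sequence[str] | None = None,
    alpha: float = 0.05,
    bf_null_threshold: float = 3.0,
    r_scale: float = 0.707,
) -> list[MeasureReport]:
    """Full per-measure factorial report over a long condition table."""
    if measures is None:
        measures = sorted(table["measure"].unique()) if "measure" in table.columns else ["measure"]
    reports = []
    for m in measures:
        cells = cell_matrix(table, m if "measure" in table.columns else None)
        anova = rm_anova_2x2(cells)
        bf = interaction_bf01(cells, r_scale=r_scale)
        e_sig = anova.p_emotion < alpha
        l_sig = anova.p_loss < alpha
        reports.append(
            MeasureReport(
                measure=m,
                anova=anova,
                emotion_significant=e_sig,
                loss_significant=l_sig,
                conjunction=e_sig and l_sig,
                interaction_significant=anova.p_interaction < alpha,
                bf01_interaction=bf.bf01,
                adjudication=adjudicate(anova, bf, alpha, bf_null_threshold),
                alpha=alpha,
                bf_null_threshold=bf_null_threshold,
            )
        )
    return reports


def report_frame(reports: Sequence[MeasureReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        rows.append(
            {
                "measure": r.measure,
                "F_emotion": r.anova.F_emotion,
                "p_emotion": r.anova.p_emotion,
                "F_loss": r.anova.F_loss,
                "p_loss": r.anova.p_loss,
                "F_interaction": r.anova.F_interaction,
                "p_interaction": r.anova.p_interaction,
                "df1": r.anova.df[0],
                "df2": r.anova.df[1],
                "emotion_significant": r.emotion_significant,
                "loss_significant": r.loss_significant,
                "conjunction": r.conjunction,
                "interaction_significant": r.interaction_significant,
                "bf01_interaction": r.bf01_interaction,
                "adjudication": r.adjudication,
                "alpha": r.alpha,
                "bf_null_threshold": r.bf_null_threshold,
            }
        )
    return pd.DataFrame(rows)
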