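"""Frequentist and default-prior Bayesian tests for the 2x2 factorial analyses.

Covers every procedure the behavioral pipeline needs: one-sample and paired
t tests, the within-subject 2x2 ANOVA computed through per-subject
contrasts (where each F is identically the square of the contrast's paired
t), Pearson correlation, Bonferroni control, the JZS default Bayes factor
for t statistics (Cauchy prior on the standardized effect) and the default
Bayes factor for a Pearson correlation (stretched-beta prior on the
population correlation).  Bayes factors are reported as BF01, evidence for
the null over the alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, special
from scipy import stats as sps

from .rl import ChoiceData

__all__ = [
    "CELLS",
    "TestResult",
    "BayesFactorResult",
    "AnovaResult2x2",
    "one_sample_t",
    "paired_t",
    "pearson_corr",
    "rm_anova_2x2",
    "jzs_bf01_t",
    "jeffreys_bf01_corr",
    "interaction_bf01",
    "bonferroni",
    "choice_summary",
    "classify_inherent_value",
    "cell_matrix",
]

#: canonical 2x2 cell order: (emotion, loss)
CELLS: tuple[tuple[str, str], ...] = (
    ("positive", "loss"),
    ("positive", "no_loss"),
    ("neutral", "loss"),
    ("neutral", "no_loss"),
)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: tuple[float, ...]
    p: float
    estimate: float
    n: int


@dataclass(frozen=True)
class BayesFactorResult:
    bf01: float
    method: str
    prior_scale: float
    integration_error: float


@dataclass(frozen=True)
class AnovaResult2x2:
    F_emotion: float
    F_loss: float
    F_interaction: float
    df: tuple[int, int]
    p_emotion: float
    p_loss: float
    p_interaction: float
    contrast_emotion: float
    contrast_loss: float
    contrast_interaction: float
    n: int


def cell_matrix(table: pd.DataFrame, measure: str | None = None) -> np.ndarray:
    """Pivot a long condition table (subject, emotion, loss, value) into an
    n_subjects x 4 array in :data:`CELLS` order, sorted by subject.

    Raises if any subject is missing a cell, naming the subjects.
    """
    df = table
    if measure is not None and "measure" in df.columns:
        df = df[df["measure"] == measure]
    wide = df.pivot_table(
        index="subject", columns=["emotion", "loss"], values="value", aggfunc="mean"
    )
    missing = [str(s) for s in wide.index[wide.isna().any(axis=1)]]
    needed = [c for c in CELLS if c not in wide.columns]
    if needed or missing:
        raise ValueError(
            f"incomplete 2x2 cells: missing columns {needed}, subjects with gaps {missing}"
        )
    return wide.loc[:, list(CELLS)].to_numpy(dtype=float)


def one_sample_t(values: Sequence[float], mu0: float = 0.0) -> TestResult:
    """Two-tailed one-sample t test of mean(values) against mu0, df = n-1.

    Zero variance is degenerate and raises, except the exactly-null case
    (every value equal to mu0, e.g. a paired test of identical samples)
    which returns t = 0, p = 1.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError(f"need at least 2 observations, got {n}")
    sd = x.std(ddof=1)
    if sd == 0:
        if x.mean() == mu0:
            return TestResult(statistic=0.0, df=(n - 1,), p=1.0, estimate=0.0, n=n)
        raise ValueError("degenerate input: zero variance")
    est = float(x.mean() - mu0)
    t = est / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return TestResult(statistic=float(t), df=(n - 1,), p=float(p), estimate=est, n=n)


def paired_t(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Paired t test, definitionally one_sample_t(a - b, 0)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    return one_sample_t(a - b, 0.0)


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson correlation with the classical two-tailed t-based p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise ValueError("degenerate input: zero variance")
    r, p = sps.pearsonr(x, y)
    t = r * math.sqrt((n - 2) / (1 - r * r)) if abs(r) < 1 else math.inf
    return TestResult(statistic=float(t), df=(n - 2,), p=float(p), estimate=float(r), n=n)


def _contrasts(cells: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-subject emotion, loss and interaction difference scores, in the
    raw-sum coefficients {+1, -1} over CELLS order (PL, PNL, NL, NNL)."""
    pl, pnl, nl, nnl = cells.T
    emotion = (pl + pnl) - (nl + nnl)
    loss = (pl + nl) - (pnl + nnl)
    interaction = (pl - pnl) - (nl - nnl)
    return emotion, loss, interaction


def rm_anova_2x2(table: pd.DataFrame | np.ndarray, measure: str | None = None) -> AnovaResult2x2:
    """Within-subject 2x2 ANOVA via contrasts: each effect's F(1, n-1) is the
    squared one-sample t of its per-subject difference score against zero.

    Accepts either a long condition table or an n x 4 cell array in CELLS
    order.  Degenerate (noise-free) contrasts are resolved by the limit of
    the F ratio: zero variance with zero mean gives F = 0 (no effect), zero
    variance with nonzero mean gives F = inf, p = 0 (a perfect effect).
    """
    cells = table if isinstance(table, np.ndarray) else cell_matrix(table, measure)
    n = cells.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    fs: list[float] = []
    ps: list[float] = []
    ests: list[float] = []
    for scores in _contrasts(cells):
        mean = float(scores.mean())
        sd = float(scores.std(ddof=1))
        if sd == 0:
            if mean == 0:
                fs.append(0.0)
                ps.append(1.0)
            else:
                fs.append(math.inf)
                ps.append(0.0)
        else:
            t = mean / (sd / math.sqrt(n))
            fs.append(t * t)
            ps.append(float(2.0 * sps.t.sf(abs(t), n - 1)))
        ests.append(mean)
    return AnovaResult2x2(
        F_emotion=fs[0],
        F_loss=fs[1],
        F_interaction=fs[2],
        df=(1, n - 1),
        p_emotion=ps[0],
        p_loss=ps[1],
        p_interaction=ps[2],
        contrast_emotion=ests[0],
        contrast_loss=ests[1],
        contrast_interaction=ests[2],
        n=n,
    )


def jzs_bf01_t(t: float, n: int, r_scale: float = 0.707) -> BayesFactorResult:
    """Default-prior (JZS) Bayes factor for a one-sample or paired t statistic.

    The alternative places a Cauchy(0, r_scale) prior on the standardized
    effect delta; the marginal likelihood integrates the noncentral-t density
    of the observed t over that prior.  BF01 is the point-null density over
    the marginal.  Symmetric in the sign of t.
    """
    if not math.isfinite(t):
        raise ValueError("t statistic must be finite")
    if n < 2:
        raise ValueError("need n >= 2")
    nu = n - 1
    sqrt_n = math.sqrt(n)

    def integrand(delta: float) -> float:
        return sps.nct.pdf(t, nu, sqrt_n * delta) * sps.cauchy.pdf(delta, 0.0, r_scale)

    marginal, err = integrate.quad(
        integrand, -np.inf, np.inf, epsabs=0, epsrel=1e-8, limit=200
    )
    null = sps.t.pdf(t, nu)
    bf01 = null / marginal
    return BayesFactorResult(
        bf01=float(bf01),
        method="jzs_t",
        prior_scale=float(r_scale),
        integration_error=float(err / marginal),
    )


def _corr_density_kernel(r: float, rho: float, n: int) -> float:
    # sampling density of the Pearson r given rho, up to rho-free factors
    # (they cancel in the Bayes-factor ratio)
    return (
        (1.0 - rho * rho) ** ((n - 1) / 2.0)
        * (1.0 - rho * r) ** (1.5 - n)
        * special.hyp2f1(0.5, 0.5, n - 0.5, (1.0 + rho * r) / 2.0)
    )


def jeffreys_bf01_corr(r: float, n: int, kappa: float = 1.0) -> BayesFactorResult:
    """Default Bayes factor for a Pearson correlation, two-sided.

    The alternative places a stretched-beta(1/kappa, 1/kappa) prior on the
    population correlation over (-1, 1); kappa=1 is the uniform prior.  The
    exact sampling density of r given rho is integrated against the prior.
    Symmetric in the sign of r.
    """
    if not abs(r) < 1:
        raise ValueError("|r| must be < 1")
    if n < 3:
        raise ValueError("need n >= 3")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    a = 1.0 / kappa

    def integrand(rho: float) -> float:
        prior = sps.beta.pdf((rho + 1.0) / 2.0, a, a) / 2.0
        return _corr_density_kernel(r, rho, n) * prior

    marginal, err = integrate.quad(integrand, -1.0, 1.0, epsabs=0, epsrel=1e-8, limit=200)
    null = _corr_density_kernel(r, 0.0, n)
    bf01 = null / marginal
    return BayesFactorResult(
        bf01=float(bf01),
        method="jeffreys_corr",
        prior_scale=float(kappa),
        integration_error=float(err / marginal),
    )


def interaction_bf01(
    table: pd.DataFrame | np.ndarray,
    r_scale: float = 0.707,
    measure: str | None = None,
) -> BayesFactorResult:
    """JZS Bayes factor on the per-subject interaction difference score.

    This is an explicit contrast-based approximation to a full Bayesian
    repeated-measures ANOVA: the interaction contrast is reduced to a
    one-sample t and handed to :func:`jzs_bf01_t`.  Degenerate (noise-free)
    cohorts use documented sentinels: interaction scores all exactly zero
    (perfectly additive) return bf01 = inf (maximal null support); a
    constant nonzero interaction score returns bf01 = 0 (a perfect
    interaction overwhelms the null).
    """
    cells = table if isinstance(table, np.ndarray) else cell_matrix(table, measure)
    _, _, interaction = _contrasts(cells)
    n = len(interaction)
    sd = float(np.std(interaction, ddof=1))
    if sd == 0:
        if float(np.mean(interaction)) == 0.0:
            return BayesFactorResult(
                bf01=math.inf,
                method="interaction_contrast",
                prior_scale=float(r_scale),
                integration_error=0.0,
            )
        return BayesFactorResult(
            bf01=0.0,
            method="interaction_contrast",
            prior_scale=float(r_scale),
            integration_error=0.0,
        )
    t = float(np.mean(interaction)) / (sd / math.sqrt(n))
    res = jzs_bf01_t(t, n, r_scale)
    return BayesFactorResult(
        bf01=res.bf01,
        method="interaction_contrast",
        prior_scale=res.prior_scale,
        integration_error=res.integration_error,
    )


def bonferroni(alpha_family: float, k: int) -> float:
    """Per-test threshold controlling the familywise alpha over k tests."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return alpha_family / k


def choice_summary(choices_by_phase: Mapping[int, ChoiceData]) -> pd.DataFrame:
    """Per-phase choice proportions and loss-following proportions.

    Proportions are over responded trials; the response rate is over all
    trials.  loss_after_chair is the fraction of responded chair-choice
    trials whose predetermined outcome was a loss (nan if no chair choices),
    likewise for plane.
    """
    rows = []
    for phase in sorted(choices_by_phase):
        cd = choices_by_phase[phase]
        if cd.n_responded == 0:
            raise ValueError(f"phase {phase} has no responded trials")
        resp = cd.responded
        ch = cd.choices[resp]
        # a loss is the worse (lower-coded) outcome under either supported coding
        is_loss = cd.rewards[resp] == cd.rewards.min()  # min over responded == global min on balanced runs
        chair = ch == 1.0
        rows.append(
            {
                "phase": phase,
                "prop_chair": float(chair.mean()),
                "prop_plane": float(1.0 - chair.mean()),
                "loss_after_chair": float(is_loss[chair].mean()) if chair.any() else np.nan,
                "loss_after_plane": float(is_loss[~chair].mean()) if (~chair).any() else np.nan,
                "response_rate": float(resp.mean()),
            }
        )
    return pd.DataFrame(rows)


def classify_inherent_value(
    choices_by_phase: Mapping[int, ChoiceData],
) -> dict[int, dict[str, object]]:
    """Label the more-often-chosen stimulus per phase as the deemed
    higher-inherent-value one; an exact 50/50 split is flagged as a tie (the
    subject is then excluded from high-vs-low paired comparisons)."""
    out: dict[int, dict[str, object]] = {}
    for phase in sorted(choices_by_phase):
        cd = choices_by_phase[phase]
        ch = cd.choices[cd.responded]
        if len(ch) == 0:
            out[phase] = {"high": None, "low": None, "tie": True}
            continue
        n_chair = int((ch == 1.0).sum())
        n_plane = len(ch) - n_chair
        if n_chair == n_plane:
            out[phase] = {"high": None, "low": None, "tie": True}
        elif n_chair > n_plane:
            out[phase] = {"high": "chair", "low": "plane", "tie": False}
        else:
            out[phase] = {"high": "plane", "low": "chair", "tie": False}
    return out
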