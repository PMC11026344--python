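import math

import numpy as np
import pandas as pd
import pytest

from conflictval.rl import ChoiceData
from conflictval.stats import (
    CELLS,
    bonferroni,
    cell_matrix,
    choice_summary,
    classify_inherent_value,
    interaction_bf01,
    jeffreys_bf01_corr,
    jzs_bf01_t,
    one_sample_t,
    paired_t,
    rm_anova_2x2,
)


# ----------------------------------------------------------------- t tests

def test_one_sample_t_symmetric_data_is_null():
    res = one_sample_t([1.0, 2.0, 3.0, 4.0, 5.0], 3.0)
    assert res.statistic == pytest.approx(0.0)
    assert res.p == pytest.approx(1.0)
    assert res.df == (4,)


def test_one_sample_t_sign_follows_shift():
    base = np.random.default_rng(1).normal(0, 1, 20)
    assert one_sample_t(base + 2.0, 0.0).statistic > 0
    assert one_sample_t(base - 2.0, 0.0).statistic < 0


def test_one_sample_t_matches_scalar_formula():
    """Textbook formula computed independently with plain floats."""
    x = list(np.random.default_rng(7).normal(0.3, 1.2, 35))
    res = one_sample_t(x, 0.1)
    n = len(x)
    mean = sum(x) / n
    var = sum((xi - mean) ** 2 for xi in x) / (n - 1)
    t_expected = (mean - 0.1) / math.sqrt(var / n)
    assert res.statistic == pytest.approx(t_expected, abs=1e-12)
    assert res.n == 35


def test_one_sample_t_rejects_degenerate_input():
    with pytest.raises(ValueError, match="zero variance"):
        one_sample_t([2.0, 2.0, 2.0], 1.0)
    with pytest.raises(ValueError):
        one_sample_t([1.0], 0.0)


def test_paired_t_identities():
    rng = np.random.default_rng(3)
    a, b = rng.normal(0, 1, 15), rng.normal(0.4, 1, 15)
    res_ab, res_ba = paired_t(a, b), paired_t(b, a)
    assert res_ab.statistic == pytest.approx(-res_ba.statistic)
    assert res_ab.statistic == pytest.approx(one_sample_t(a - b, 0.0).statistic, abs=1e-12)
    same = paired_t(a, a)  # identical samples: no effect, t = 0 by convention
    assert same.statistic == 0.0 and same.p == 1.0


def test_p_values_match_independent_t_sf():
    """Two-tailed p agrees with an independent continued-fraction
    incomplete-beta evaluation of the t survival function to 1e-10."""

    def betacf(a, b, x, iters=200):
        # Lentz continued fraction for the regularized incomplete beta
        qab, qap, qam = a + b, a + 1.0, a - 1.0
        c, d = 1.0, 1.0 - qab * x / qap
        if abs(d) < 1e-300:
            d = 1e-300
        d = 1.0 / d
        h = d
        for m in range(1, iters + 1):
            m2 = 2 * m
            aa = m * (b - m) * x / ((qam + m2) * (a + m2))
            d = 1.0 + aa * d
            c = 1.0 + aa / c
            d = 1.0 / max(abs(d), 1e-300) * math.copysign(1, d)
            h *= d * c
            aa = -(a + m) * (qab + m) * x / ((a + m2) * (qap + m2))
            d = 1.0 + aa * d
            c = 1.0 + aa / c
            d = 1.0 / max(abs(d), 1e-300) * math.copysign(1, d)
            de = d * c
            h *= de
            if abs(de - 1.0) < 1e-15:
                break
        return h

    def ibeta(a, b, x):
        if x in (0.0, 1.0):
            return x
        ln_front = (
            math.lgamma(a + b) - math.lgamma(a) - math.lgamma(b)
            + a * math.log(x) + b * math.log(1 - x)
        )
        front = math.exp(ln_front)
        if x < (a + 1) / (a + b + 2):
            return front * betacf(a, b, x) / a
        return 1.0 - front * betacf(b, a, 1 - x) / b

    def t_two_tailed(t, df):
        x = df / (df + t * t)
        return ibeta(df / 2.0, 0.5, x)

    rng = np.random.default_rng(11)
    for _ in range(20):
        x = rng.normal(rng.normal(0, 0.5), 1.0, int(rng.integers(5, 60)))
        res = one_sample_t(x, 0.0)
        assert res.p == pytest.approx(t_two_tailed(res.statistic, res.df[0]), abs=1e-10)


# -------------------------------------------------------------- 2x2 ANOVA

def _cells_frame(cells, measure="m"):
    rows = []
    for j, row in enumerate(cells):
        for (emotion, loss), v in zip(CELLS, row):
            rows.append(
                {"subject": j + 1, "measure": measure, "emotion": emotion, "loss": loss, "value": v}
            )
    return pd.DataFrame(rows)


def test_anova_additive_data_has_zero_interaction():
    base = np.array([1.0, 2.0, 3.0, 4.0])  # PL, PNL, NL, NNL with (PL-PNL)=(NL-NNL)
    # dyadic subject shifts keep the arithmetic exact in binary floating point
    cells = np.stack([base + shift for shift in (0.0, 0.5, -2.0, 0.25)])
    res = rm_anova_2x2(cells)
    assert res.contrast_interaction == pytest.approx(0.0)
    assert res.F_interaction == pytest.approx(0.0)


def test_anova_f_is_squared_contrast_t():
    rng = np.random.default_rng(4)
    cells = rng.normal(0, 1, (12, 4))
    res = rm_anova_2x2(cells)
    pl, pnl, nl, nnl = cells.T
    for scores, F in (
        ((pl + pnl) - (nl + nnl), res.F_emotion),
        ((pl + nl) - (pnl + nnl), res.F_loss),
        ((pl - pnl) - (nl - nnl), res.F_interaction),
    ):
        t = one_sample_t(scores, 0.0).statistic
        assert F == pytest.approx(t * t, rel=1e-12)


def test_anova_matches_pingouin_reference():
    """Reference-implementation oracle on 20 random within-subject datasets."""
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(20)
    for _ in range(20):
        n = int(rng.integers(8, 30))
        cells = rng.normal(0, 1, (n, 4)) + rng.normal(0, 1, (n, 1))
        df = _cells_frame(cells)
        res = rm_anova_2x2(cells)
        ref = pingouin.rm_anova(
            data=df, dv="value", within=["emotion", "loss"], subject="subject", detailed=True
        ).set_index("Source")
        assert res.F_emotion == pytest.approx(ref.loc["emotion", "F"], abs=1e-6)
        assert res.F_loss == pytest.approx(ref.loc["loss", "F"], abs=1e-6)
        assert res.F_interaction == pytest.approx(ref.loc["emotion * loss", "F"], abs=1e-6)
        assert res.p_interaction == pytest.approx(ref.loc["emotion * loss", "p_unc"], abs=1e-6)


def test_anova_long_table_requires_complete_cells():
    cells = np.random.default_rng(0).normal(0, 1, (5, 4))
    df = _cells_frame(cells)
    df = df.drop(df[(df.subject == 3) & (df.emotion == "positive") & (df.loss == "loss")].index)
    with pytest.raises(ValueError, match="3"):
        rm_anova_2x2(df, "m")


def test_cell_matrix_orders_canonically():
    cells = np.arange(8.0).reshape(2, 4)
    df = _cells_frame(cells)
    np.testing.assert_allclose(cell_matrix(df, "m"), cells)


# ------------------------------------------------------------ Bayes factors

def test_jzs_bf01_reproduces_published_defaults():
    """Spot values verified by two independent quadrature routes."""
    assert jzs_bf01_t(-0.781, 35).bf01 == pytest.approx(4.155, abs=0.01)
    assert jzs_bf01_t(1.487, 35).bf01 == pytest.approx(2.023, abs=0.01)


def test_jzs_bf01_symmetric_in_t():
    for t in (0.3, 1.1, 2.7):
        assert jzs_bf01_t(t, 20).bf01 == pytest.approx(jzs_bf01_t(-t, 20).bf01, rel=1e-8)


def test_jzs_bf01_maximal_at_zero():
    bfs = [jzs_bf01_t(t, 35).bf01 for t in np.linspace(-4, 4, 33)]
    assert max(bfs) == pytest.approx(jzs_bf01_t(0.0, 35).bf01, rel=1e-10)


def test_jzs_bf01_rejects_nonfinite():
    with pytest.raises(ValueError):
        jzs_bf01_t(float("nan"), 10)


def test_corr_bf01_reproduces_published_defaults():
    assert jeffreys_bf01_corr(-0.088, 35).bf01 == pytest.approx(4.21, abs=0.01)
    assert jeffreys_bf01_corr(0.088, 35).bf01 == pytest.approx(4.21, abs=0.01)
    assert jeffreys_bf01_corr(0.028, 35).bf01 == pytest.approx(4.69, abs=0.01)


def test_corr_bf01_symmetric_and_bounded_input():
    assert jeffreys_bf01_corr(0.4, 20).bf01 == pytest.approx(
        jeffreys_bf01_corr(-0.4, 20).bf01, rel=1e-8
    )
    with pytest.raises(ValueError):
        jeffreys_bf01_corr(1.0, 20)


def _bf01_t_oracle(t, n, r=0.707):
    """Independent route: Zellner-Siow g-prior quadrature on a coarse grid."""
    nu = n - 1
    z = np.linspace(1e-6, 1 - 1e-6, 20001)
    g = z / (1 - z)
    jac = 1.0 / (1 - z) ** 2
    dens = (
        (1 + n * g) ** -0.5
        * (1 + t * t / ((1 + n * g) * nu)) ** (-(nu + 1) / 2)
        * (r * r / 2) ** 0.5 / math.gamma(0.5) * g ** -1.5 * np.exp(-r * r / (2 * g))
    )
    bf10 = np.trapezoid(dens * jac, z) / (1 + t * t / nu) ** (-(nu + 1) / 2)
    return 1.0 / bf10


def _bf01_r_oracle(r, n, kappa=1.0):
    """Independent route: trapezoid over the exact r sampling density."""
    from scipy import special, stats as sps

    rho = np.linspace(-1 + 1e-9, 1 - 1e-9, 40001)
    dens = (
        (1 - rho**2) ** ((n - 1) / 2)
        * (1 - rho * r) ** (1.5 - n)
        * special.hyp2f1(0.5, 0.5, n - 0.5, (1 + rho * r) / 2)
    )
    prior = sps.beta.pdf((rho + 1) / 2, 1 / kappa, 1 / kappa) / 2
    marginal = np.trapezoid(dens * prior, rho)
    null = special.hyp2f1(0.5, 0.5, n - 0.5, 0.5)
    return null / marginal


def test_bayes_factors_match_independent_quadrature():
    """Both BF operations agree with coarse-grid oracles to 3 significant figures
    on random (statistic, n) pairs."""
    rng = np.random.default_rng(8)
    for _ in range(10):
        t = float(rng.uniform(-3, 3))
        n = int(rng.integers(10, 60))
        assert jzs_bf01_t(t, n).bf01 == pytest.approx(_bf01_t_oracle(t, n), rel=5e-4)
    for _ in range(10):
        r = float(rng.uniform(-0.8, 0.8))
        n = int(rng.integers(10, 60))
        assert jeffreys_bf01_corr(r, n).bf01 == pytest.approx(_bf01_r_oracle(r, n), rel=5e-4)


def test_interaction_bf_degenerate_sentinels():
    additive = np.tile([1.0, 2.0, 3.0, 4.0], (6, 1)) + np.arange(6)[:, None]
    assert interaction_bf01(additive).bf01 == math.inf
    crossed = np.tile([2.0, 1.0, 1.0, 2.0], (6, 1))  # constant nonzero interaction
    assert interaction_bf01(crossed).bf01 == 0.0


def test_interaction_bf_detects_large_interaction():
    rng = np.random.default_rng(5)
    cells = rng.normal(0, 0.5, (30, 4))
    cells[:, 0] += 3.0  # strong PL-specific displacement
    assert interaction_bf01(cells).bf01 < 1.0


def test_interaction_bf_declines_with_effect_size():
    """Averaged over replicate cohorts, null evidence falls as |c| grows."""
    rng = np.random.default_rng(6)
    means = []
    for c in (0.0, 1.0, 2.0):
        vals = []
        for _ in range(60):
            cells = rng.normal(0, 1.0, (20, 4))
            cells[:, 0] -= c / 2.0
            cells[:, 1] += c / 2.0
            vals.append(math.log(interaction_bf01(cells).bf01))
        means.append(np.mean(vals))
    assert means[0] > means[1] > means[2]


# ----------------------------------------------------------- multiplicity

def test_bonferroni_thresholds():
    assert bonferroni(0.05, 5) == pytest.approx(0.01)
    assert bonferroni(0.05, 1) == pytest.approx(0.05)
    assert bonferroni(0.10, 4) == pytest.approx(0.025)
    with pytest.raises(ValueError):
        bonferroni(0.05, 0)


# ------------------------------------------------------- choice summaries

def _choice_data(choices, rewards=None, responded=None):
    n = len(choices)
    return ChoiceData(
        choices=np.asarray(choices, dtype=float),
        rewards=np.asarray(rewards if rewards is not None else [1.0, 0.0] * (n // 2) + [1.0] * (n % 2)),
        responded=np.asarray(responded if responded is not None else [True] * n),
    )


def test_choice_summary_all_chair():
    cd = _choice_data([1.0] * 10)
    summary = choice_summary({1: cd})
    row = summary.iloc[0]
    assert row.prop_chair == 1.0 and row.prop_plane == 0.0
    assert math.isnan(row.loss_after_plane)
    assert row.response_rate == 1.0


def test_choice_summary_proportions_complement():
    cd = _choice_data([1.0, 0.0, 1.0, 0.0, 1.0, 1.0])
    row = choice_summary({1: cd}).iloc[0]
    assert row.prop_chair + row.prop_plane == pytest.approx(1.0)


def test_choice_summary_loss_following_balanced(frozen_schedule):
    """An unbiased agent on the frozen schedule sees ~50% losses after either choice."""
    from conflictval.rl import RLParams, simulate_agent

    params = RLParams(0.0, 0.0, 0.0, 0.0, 0.5, 0.5)  # pure coin-flip chooser
    vals = []
    for seed in range(40):
        cd = simulate_agent(params, frozen_schedule.phase(1), seed=seed)
        row = choice_summary({1: cd}).iloc[0]
        vals.extend([row.loss_after_chair, row.loss_after_plane])
    # pooled across 40 x 72 trials, the binomial error band is a few percent
    assert abs(np.mean(vals) - 0.5) < 0.03


def test_choice_summary_requires_responses():
    cd = ChoiceData(choices=[np.nan] * 3, rewards=[1.0] * 3, responded=[False] * 3)
    with pytest.raises(ValueError, match="phase 1"):
        choice_summary({1: cd})


def test_inherent_value_classification():
    more_chair = _choice_data([1.0] * 40 + [0.0] * 32)
    assert classify_inherent_value({1: more_chair})[1] == {
        "high": "chair", "low": "plane", "tie": False,
    }
    tied = _choice_data([1.0] * 36 + [0.0] * 36)
    assert classify_inherent_value({1: tied})[1]["tie"] is True
    more_plane = _choice_data([0.0] * 40 + [1.0] * 30)
    assert classify_inherent_value({1: more_plane})[1]["high"] == "plane"
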