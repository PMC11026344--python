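"""Rescorla-Wagner choice model: generative simulation and grid-search fitting.

The model carries one expected value per stimulus (chair, plane).  After
each responded trial the chosen stimulus's value moves toward the received
outcome code R_t by a fraction alpha of the prediction error R_t - V_t; the
unchosen value is untouched.  Choice probabilities come from a softmax over
the two values with per-stimulus inverse temperatures.  Six free parameters
(alpha_chair, alpha_plane, beta_chair, beta_plane, v0_chair, v0_plane) are
estimated by exhaustive grid search minimising the mean squared error
between the model's p(chair) and the observed 0/1 choices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .task_design import TrialRecord

__all__ = [
    "RLParams",
    "GridSpec",
    "ChoiceData",
    "FitResult",
    "PhaseFits",
    "REWARD_CODING_01",
    "REWARD_CODING_NEG0",
    "update_value",
    "choice_prob_chair",
    "simulate_agent",
    "mse_objective",
    "fit_grid",
    "fit_phases",
]

#: no-loss is the better outcome; values then live in [0, 1] like V0.
REWARD_CODING_01: Mapping[str, float] = {"loss": 0.0, "no_loss": 1.0}
#: alternative coding where a loss is a negative outcome.
REWARD_CODING_NEG0: Mapping[str, float] = {"loss": -1.0, "no_loss": 0.0}

PARAM_ORDER = ("alpha_chair", "alpha_plane", "beta_chair", "beta_plane", "v0_chair", "v0_plane")

_RANGES = {
    "alpha_chair": (0.0, 1.0),
    "alpha_plane": (0.0, 1.0),
    "beta_chair": (0.0, 10.0),
    "beta_plane": (0.0, 10.0),
    "v0_chair": (0.0, 1.0),
    "v0_plane": (0.0, 1.0),
}


@dataclass(frozen=True)
class RLParams:
    """The six free parameters, each confined to its closed range:
    learning rates and initial values in [0, 1], inverse temperatures in [0, 10]."""

    alpha_chair: float
    alpha_plane: float
    beta_chair: float
    beta_plane: float
    v0_chair: float
    v0_plane: float

    def __post_init__(self) -> None:
        for name, (lo, hi) in _RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")


@dataclass(frozen=True)
class GridSpec:
    """Ordered per-parameter value lists defining the Cartesian search grid.

    ``shared_beta=True`` ties the plane inverse temperature to the chair one
    (single-beta softmax as a design variant); the beta_plane axis is then
    ignored.
    """

    alpha_chair: tuple[float, ...]
    alpha_plane: tuple[float, ...]
    beta_chair: tuple[float, ...]
    beta_plane: tuple[float, ...]
    v0_chair: tuple[float, ...]
    v0_plane: tuple[float, ...]
    shared_beta: bool = False

    def __post_init__(self) -> None:
        for name in PARAM_ORDER:
            vals = getattr(self, name)
            if len(vals) == 0:
                raise ValueError(f"grid axis {name} is empty")
            lo, hi = _RANGES[name]
            for v in vals:
                if not lo <= v <= hi:
                    raise ValueError(f"grid value {name}={v} outside [{lo}, {hi}]")

    @classmethod
    def default(cls) -> "GridSpec":
        """11 evenly spaced points per axis (step 0.1 for alpha/V0, 1.0 for beta)."""
        unit = tuple(np.round(np.linspace(0, 1, 11), 10))
        beta = tuple(np.round(np.linspace(0, 10, 11), 10))
        return cls(unit, unit, beta, beta, unit, unit)

    @classmethod
    def coarse(cls) -> "GridSpec":
        """6 points per axis; the grid used for cohort-scale analyses and tests."""
        unit = tuple(np.round(np.linspace(0, 1, 6), 10))
        beta = tuple(np.round(np.linspace(0, 10, 6), 10))
        return cls(unit, unit, beta, beta, unit, unit)

    def axes(self) -> tuple[tuple[float, ...], ...]:
        axes = [getattr(self, name) for name in PARAM_ORDER]
        if self.shared_beta:
            axes[3] = (float("nan"),)  # placeholder; beta_plane follows beta_chair
        return tuple(axes)

    @property
    def n_points(self) -> int:
        return int(np.prod([len(a) for a in self.axes()]))


@dataclass
class ChoiceData:
    """Per-trial observed behavior for one phase.

    choices: 1.0 = chair, 0.0 = plane, nan on missed trials.
    rewards: outcome code R_t for every trial (predetermined, so defined even
    on missed trials).  responded: bool mask; missed trials are excluded from
    fitting and trigger no value update.
    """

    choices: np.ndarray
    rewards: np.ndarray
    responded: np.ndarray

    def __post_init__(self) -> None:
        self.choices = np.asarray(self.choices, dtype=float)
        self.rewards = np.asarray(self.rewards, dtype=float)
        self.responded = np.asarray(self.responded, dtype=bool)
        if not (len(self.choices) == len(self.rewards) == len(self.responded)):
            raise ValueError("choices, rewards and responded must have equal length")

    @property
    def n_trials(self) -> int:
        return len(self.choices)

    @property
    def n_responded(self) -> int:
        return int(self.responded.sum())


@dataclass(frozen=True)
class FitResult:
    params: RLParams
    mse: float
    n_trials_used: int
    grid_points_evaluated: int


@dataclass
class PhaseFits:
    results: dict[int, FitResult] = field(default_factory=dict)
    errors: dict[int, str] = field(default_factory=dict)


def update_value(v: float, r: float, alpha: float) -> float:
    """Delta-rule update: move v toward outcome r by alpha times the
    prediction error r - v.  Callers update only the chosen stimulus."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha={alpha} outside [0, 1]")
    return v + alpha * (r - v)


def choice_prob_chair(
    v_chair: float, v_plane: float, beta_chair: float, beta_plane: float
) -> float:
    """Softmax probability of choosing chair, computed stably via the
    max-subtracted logit.  Zero temperatures give indifference (0.5)."""
    if beta_chair < 0 or beta_plane < 0:
        raise ValueError("inverse temperatures must be >= 0")
    x_c = beta_chair * v_chair
    x_p = beta_plane * v_plane
    m = max(x_c, x_p)
    e_c = np.exp(x_c - m)
    e_p = np.exp(x_p - m)
    return float(e_c / (e_c + e_p))


def _rewards_from_schedule(
    phase_trials: Sequence[TrialRecord], reward_coding: Mapping[str, float]
) -> np.ndarray:
    return np.array([reward_coding[t.outcome] for t in phase_trials], dtype=float)


def simulate_agent(
    params: RLParams,
    phase_trials: Sequence[TrialRecord],
    reward_coding: Mapping[str, float] = REWARD_CODING_01,
    seed: int | np.random.Generator = 0,
    miss_rate: float = 0.0,
) -> ChoiceData:
    """Generate choices for one phase of the predetermined schedule.

    Each trial draws a Bernoulli choice from the current softmax p(chair);
    the trial's predetermined outcome supplies R_t regardless of the choice,
    and only the chosen stimulus's value is updated.  With probability
    miss_rate a trial is a non-response: no choice, no update.
    """
    if len(phase_trials) == 0:
        raise ValueError("empty schedule slice")
    if not 0.0 <= miss_rate < 1.0:
        raise ValueError(f"miss_rate={miss_rate} outside [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rewards = _rewards_from_schedule(phase_trials, reward_coding)
    n = len(phase_trials)
    choices = np.full(n, np.nan)
    responded = np.ones(n, dtype=bool)
    v_c, v_p = params.v0_chair, params.v0_plane
    for t in range(n):
        if miss_rate > 0 and rng.random() < miss_rate:
            responded[t] = False
            continue
        p = choice_prob_chair(v_c, v_p, params.beta_chair, params.beta_plane)
        choice = 1.0 if rng.random() < p else 0.0
        choices[t] = choice
        r = rewards[t]
        if choice == 1.0:
            v_c = update_value(v_c, r, params.alpha_chair)
        else:
            v_p = update_value(v_p, r, params.alpha_plane)
    return ChoiceData(choices=choices, rewards=rewards, responded=responded)


def mse_objective(
    choices: ChoiceData,
    params: RLParams,
    reward_coding: Mapping[str, float] | None = None,
) -> float:
    """Mean squared error between observed 0/1 choices and model p(chair).

    Forward pass: p(chair) on trial t uses values updated through trial t-1
    (trial 1 uses V0).  Missed trials are skipped without an update and
    excluded from the mean.  reward_coding is accepted for interface symmetry
    but ChoiceData already carries R_t; it is ignored.
    """
    if choices.n_responded == 0:
        raise ValueError("no responded trials to fit")
    v_c, v_p = params.v0_chair, params.v0_plane
    total = 0.0
    for t in range(choices.n_trials):
        if not choices.responded[t]:
            continue
        p = choice_prob_chair(v_c, v_p, params.beta_chair, params.beta_plane)
        obs = choices.choices[t]
        total += (obs - p) ** 2
        r = choices.rewards[t]
        if obs == 1.0:
            v_c = update_value(v_c, r, params.alpha_chair)
        else:
            v_p = update_value(v_p, r, params.alpha_plane)
    return total / choices.n_responded


def _grid_arrays(grid: GridSpec) -> tuple[np.ndarray, ...]:
    """Flattened parameter arrays in lexicographic order over PARAM_ORDER axes."""
    mesh = np.meshgrid(*[np.asarray(a, dtype=float) for a in grid.axes()], indexing="ij")
    arrays = [m.ravel() for m in mesh]
    if grid.shared_beta:
        arrays[3] = arrays[2].copy()
    return tuple(arrays)


def fit_grid(
    choices: ChoiceData,
    grid: GridSpec,
    reward_coding: Mapping[str, float] | None = None,
) -> FitResult:
    """Exhaustive vectorized grid search minimising :func:`mse_objective`.

    Every grid point's forward pass runs in parallel as numpy arrays over
    the trial loop.  Ties are broken by the first point in lexicographic
    order of (alpha_chair, alpha_plane, beta_chair, beta_plane, v0_chair,
    v0_plane), each axis ascending, which np.argmin's first-minimum rule
    delivers for 'ij'-indexed flattening.
    """
    if choices.n_responded == 0:
        raise ValueError("no responded trials to fit")
    a_c, a_p, b_c, b_p, v0_c, v0_p = _grid_arrays(grid)
    v_c = v0_c.copy()
    v_p = v0_p.copy()
    sq_err = np.zeros_like(v_c)
    n_used = 0
    for t in range(choices.n_trials):
        if not choices.responded[t]:
            continue
        x_c = b_c * v_c
        x_p = b_p * v_p
        m = np.maximum(x_c, x_p)
        e_c = np.exp(x_c - m)
        p = e_c / (e_c + np.exp(x_p - m))
        obs = choices.choices[t]
        sq_err += (obs - p) ** 2
        n_used += 1
        r = choices.rewards[t]
        if obs == 1.0:
            v_c = v_c + a_c * (r - v_c)
        else:
            v_p = v_p + a_p * (r - v_p)
    mse = sq_err / n_used
    idx = int(np.argmin(mse))
    params = RLParams(
        alpha_chair=float(a_c[idx]),
        alpha_plane=float(a_p[idx]),
        beta_chair=float(b_c[idx]),
        beta_plane=float(b_p[idx]),
        v0_chair=float(v0_c[idx]),
        v0_plane=float(v0_p[idx]),
    )
    return FitResult(
        params=params,
        mse=float(mse[idx]),
        n_trials_used=n_used,
        grid_points_evaluated=len(mse),
    )


def fit_phases(
    choices_by_phase: Mapping[int, ChoiceData],
    grid: GridSpec,
    reward_coding: Mapping[str, float] | None = None,
    expected_phases: Sequence[int] = (1, 2),
) -> PhaseFits:
    """Independent grid fit per phase; a failing or absent phase records its
    error without blocking the other phase."""
    out = PhaseFits()
    for phase in expected_phases:
        if phase not in choices_by_phase:
            out.errors[phase] = f"phase {phase} missing from choice data"
            continue
        try:
            out.results[phase] = fit_grid(choices_by_phase[phase], grid, reward_coding)
        except ValueError as exc:
            out.errors[phase] = str(exc)
    return out
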