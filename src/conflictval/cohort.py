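"""Synthetic study cohorts with known ground truth.

Emulates the behavioral side of the study end-to-end: a shared frozen trial
schedule, per-subject Rescorla-Wagner agents generating phase-wise choices,
and subject-level condition tables (pleasantness ratings or ROI outcome
estimates) built from an additive-plus-interaction cell-means model

    cell = mu + s_j + (a/2)*E + (b/2)*L + (c/4)*E*L + noise

with sign codes E = +1 for positive emotion, L = +1 for no-loss, a subject
random effect s_j ~ N(0, sigma_subject) and within-cell noise
N(0, sigma_noise).  With this coding ``a`` and ``b`` are marginal-mean
differences and ``c`` is the interaction difference-of-differences, so
truth plugs directly into the factorial contrasts downstream.

Defaults describe a plausible 35-subject cohort of this task: rating-scale
effects in the direction the task manipulations are built to produce
(no-loss rated more pleasant than loss, positive imagery more pleasant than
neutral) and an additive structure (c = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import task_design
from .rl import REWARD_CODING_01, ChoiceData, RLParams, simulate_agent
from .stats import CELLS
from .task_design import DesignConfig, TrialSchedule, generate_schedule

__all__ = [
    "CohortSpec",
    "Cohort",
    "DEFAULT_SCHEDULE_SEED",
    "sample_cohort",
    "rating_emulator",
    "write_cohort",
    "read_cohort",
]

#: seed of the frozen cohort-wide schedule (the study used one fixed order
#: for all participants)
DEFAULT_SCHEDULE_SEED = 20240101


@dataclass(frozen=True)
class EffectModel:
    """Cell-means model for a condition measure; see module docstring."""

    mu: float = 5.7
    a_emotion: float = 0.9
    b_loss: float = 3.1
    c_interaction: float = 0.0
    sigma_subject: float = 1.0
    sigma_noise: float = 1.5


@dataclass(frozen=True)
class ParamRanges:
    """Uniform sampling ranges for the per-subject RL parameters."""

    alpha: tuple[float, float] = (0.0, 0.4)
    beta: tuple[float, float] = (1.0, 5.0)
    v0: tuple[float, float] = (0.3, 0.7)


@dataclass(frozen=True)
class CohortSpec:
    n_subjects: int = 35
    rl_params: ParamRanges = field(default_factory=ParamRanges)
    effect_model: EffectModel = field(default_factory=EffectModel)
    phase_order_counterbalance: bool = True
    miss_rate: float = 0.0137
    seed: int = 0
    measure: str = "rating"

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError(f"n_subjects={self.n_subjects} must be >= 2")
        em = self.effect_model
        if em.sigma_subject < 0 or em.sigma_noise < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0.0 <= self.miss_rate < 1.0:
            raise ValueError(f"miss_rate={self.miss_rate} outside [0, 1)")


@dataclass
class Cohort:
    spec: CohortSpec
    schedule: TrialSchedule
    params: dict[int, RLParams]
    choices: dict[int, dict[int, ChoiceData]]  # subject -> phase -> data
    conditions: pd.DataFrame  # long: subject, measure, emotion, loss, value
    phase_order: dict[int, tuple[int, int]]
    truth: dict


def _cell_effects(em: EffectModel) -> np.ndarray:
    """Fixed-effect part of the four cells in CELLS order (PL, PNL, NL, NNL)."""
    out = np.empty(4)
    for i, (emotion, loss) in enumerate(CELLS):
        e = 1.0 if emotion == "positive" else -1.0
        l = 1.0 if loss == "no_loss" else -1.0
        out[i] = (
            em.mu
            + (em.a_emotion / 2.0) * e
            + (em.b_loss / 2.0) * l
            + (em.c_interaction / 4.0) * e * l
        )
    return out


def condition_cells(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """n_subjects x 4 raw (continuous) condition values in CELLS order."""
    em = spec.effect_model
    fixed = _cell_effects(em)
    s = rng.normal(0.0, em.sigma_subject, size=spec.n_subjects)
    noise = rng.normal(0.0, em.sigma_noise, size=(spec.n_subjects, 4))
    return fixed[None, :] + s[:, None] + noise


def _cells_to_long(cells: np.ndarray, measure: str) -> pd.DataFrame:
    rows = []
    for j in range(cells.shape[0]):
        for i, (emotion, loss) in enumerate(CELLS):
            rows.append(
                {
                    "subject": j + 1,
                    "measure": measure,
                    "emotion": emotion,
                    "loss": loss,
                    "value": float(cells[j, i]),
                }
            )
    return pd.DataFrame(rows)


def sample_cohort(spec: CohortSpec, design: DesignConfig | None = None) -> Cohort:
    """Draw a full synthetic cohort: RL agents on the shared frozen schedule
    plus a continuous condition table, all from spec.seed."""
    spec.validate()
    design = design or DesignConfig()
    root = np.random.SeedSequence(spec.seed)
    ss_params, ss_choices, ss_cells = root.spawn(3)
    schedule = generate_schedule(DEFAULT_SCHEDULE_SEED, design)

    prng = np.random.default_rng(ss_params)
    params: dict[int, RLParams] = {}
    pr = spec.rl_params
    for j in range(1, spec.n_subjects + 1):
        params[j] = RLParams(
            alpha_chair=float(prng.uniform(*pr.alpha)),
            alpha_plane=float(prng.uniform(*pr.alpha)),
            beta_chair=float(prng.uniform(*pr.beta)),
            beta_plane=float(prng.uniform(*pr.beta)),
            v0_chair=float(prng.uniform(*pr.v0)),
            v0_plane=float(prng.uniform(*pr.v0)),
        )

    choices: dict[int, dict[int, ChoiceData]] = {}
    phase_order: dict[int, tuple[int, int]] = {}
    child_rngs = [np.random.default_rng(s) for s in ss_choices.spawn(spec.n_subjects)]
    for j in range(1, spec.n_subjects + 1):
        order = (1, 2)
        if spec.phase_order_counterbalance and j % 2 == 0:
            order = (2, 1)
        phase_order[j] = order
        rng_j = child_rngs[j - 1]
        per_phase: dict[int, ChoiceData] = {}
        for phase in order:  # simulate in experienced order for reproducibility
            per_phase[phase] = simulate_agent(
                params[j],
                schedule.phase(phase),
                REWARD_CODING_01,
                seed=rng_j,
                miss_rate=spec.miss_rate,
            )
        choices[j] = per_phase

    cells = condition_cells(spec, np.random.default_rng(ss_cells))
    conditions = _cells_to_long(cells, spec.measure)
    truth = {
        "spec": _spec_to_dict(spec),
        "schedule_seed": DEFAULT_SCHEDULE_SEED,
        "rl_params": {j: asdict(p) for j, p in params.items()},
    }
    return Cohort(
        spec=spec,
        schedule=schedule,
        params=params,
        choices=choices,
        conditions=conditions,
        phase_order=phase_order,
        truth=truth,
    )


def rating_emulator(spec: CohortSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Subjective pleasantness ratings on the 1-9 scale.

    Applies the cell-means model, then rounds half-up to whole numbers and
    clips to [1, 9], matching integer ratings between the unpleasant (1) and
    pleasant (9) anchors.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(3)[2])
    cells = condition_cells(spec, rng)
    cells = np.clip(np.floor(cells + 0.5), 1.0, 9.0)
    return _cells_to_long(cells, "rating")


def _spec_to_dict(spec: CohortSpec) -> dict:
    d = asdict(spec)
    d["rl_params"] = {k: list(v) for k, v in asdict(spec.rl_params).items()}
    return d


# ---------------------------------------------------------------------------
# cohort bundle I/O: choices_s<ID>.csv per subject, conditions.csv, truth.yaml

def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    task_design.write_schedule(cohort.schedule, out / "schedule.csv")
    for j, per_phase in cohort.choices.items():
        rows = []
        for phase in sorted(per_phase):
            cd = per_phase[phase]
            trials = cohort.schedule.phase(phase)
            for i, t in enumerate(trials):
                responded = bool(cd.responded[i])
                if responded:
                    choice = "chair" if cd.choices[i] == 1.0 else "plane"
                else:
                    choice = "NA"
                rows.append(
                    {
                        "phase": phase,
                        "run": t.run,
                        "trial": t.trial,
                        "choice": choice,
                        "outcome": t.outcome,
                        "responded": responded,
                    }
                )
        pd.DataFrame(rows).to_csv(out / f"choices_s{j:02d}.csv", index=False, lineterminator="\n")
    cohort.conditions.to_csv(out / "conditions.csv", index=False, lineterminator="\n")
    with open(out / "truth.yaml", "w") as fh:
        yaml.safe_dump(cohort.truth, fh, sort_keys=True)
    return out


def read_choice_file(
    path: str | Path, reward_coding: Mapping[str, float] = REWARD_CODING_01
) -> dict[int, ChoiceData]:
    """Load one subject's per-trial choice CSV into per-phase ChoiceData."""
    df = pd.read_csv(path)
    out: dict[int, ChoiceData] = {}
    for phase, grp in df.groupby("phase", sort=True):
        choices = grp["choice"].map({"chair": 1.0, "plane": 0.0}).to_numpy(dtype=float)
        rewards = grp["outcome"].map(reward_coding).to_numpy(dtype=float)
        responded = grp["responded"].to_numpy(dtype=bool)
        out[int(phase)] = ChoiceData(choices=choices, rewards=rewards, responded=responded)
    return out


def read_cohort_choices(
    cohort_dir: str | Path, reward_coding: Mapping[str, float] = REWARD_CODING_01
) -> dict[int, dict[int, ChoiceData]]:
    out: dict[int, dict[int, ChoiceData]] = {}
    for path in sorted(Path(cohort_dir).glob("choices_s*.csv")):
        subject = int(path.stem.split("_s")[1])
        out[subject] = read_choice_file(path, reward_coding)
    return out


def read_cohort(cohort_dir: str | Path) -> tuple[pd.DataFrame, dict[int, dict[int, ChoiceData]]]:
    """Load the condition table and all per-subject choices from a bundle."""
    cohort_dir = Path(cohort_dir)
    cond_path = cohort_dir / "conditions.csv"
    if not cond_path.exists():
        raise FileNotFoundError(f"missing conditions table: {cond_path}")
    conditions = pd.read_csv(cond_path)
    return conditions, read_cohort_choices(cohort_dir)
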