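"""Constrained pseudorandomized trial schedules for the two-phase 2x2 task.

The task is a two-choice (chair vs plane) loss-avoidance paradigm in which
every trial's outcome (loss / no loss) and stimulus positions are
predetermined.  Emotional valence of the feedback image is yoked to the
outcome by a phase-specific mapping: in phase 1 a positive image signals a
loss and a neutral image signals no loss; phase 2 reverses the mapping.
Schedules are generated by seeded rejection sampling so that every run is
outcome-balanced and free of long streaks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DesignConfig",
    "TrialRecord",
    "TrialSchedule",
    "Violation",
    "InfeasibleDesignError",
    "generate_schedule",
    "validate_schedule",
    "displayed_loss",
    "read_schedule",
    "write_schedule",
    "PHASE_VALENCE_MAP",
]

#: feedback valence as a pure function of (phase, outcome)
PHASE_VALENCE_MAP = {
    (1, "loss"): "positive",
    (1, "no_loss"): "neutral",
    (2, "loss"): "neutral",
    (2, "no_loss"): "positive",
}

SCHEDULE_COLUMNS = [
    "phase",
    "run",
    "trial",
    "chair_side",
    "outcome",
    "feedback_valence",
    "isi_s",
    "iti_s",
]


class InfeasibleDesignError(RuntimeError):
    """Raised when rejection sampling cannot satisfy the design constraints."""


@dataclass(frozen=True)
class DesignConfig:
    """Parameters of the factorial task design.

    Defaults correspond to the main experimental task: 2 phases x 2 runs x
    36 trials with 18 predetermined loss outcomes per run, outcome streaks
    capped at 3, position streaks capped at 2, and ISI/ITI jitter drawn
    uniformly from whole seconds in [2, 6].
    """

    n_phases: int = 2
    runs_per_phase: int = 2
    trials_per_run: int = 36
    loss_per_run: int = 18
    max_outcome_streak: int = 3
    max_side_streak: int = 2
    jitter_values: tuple[int, ...] = (2, 3, 4, 5, 6)
    loss_per_trial: float = 2.0
    max_attempts: int = 10_000

    @classmethod
    def training(cls) -> "DesignConfig":
        """Preset for the 24-trial training run preceding each phase."""
        return cls(n_phases=1, runs_per_phase=1, trials_per_run=24, loss_per_run=12)


@dataclass(frozen=True)
class TrialRecord:
    phase: int
    run: int
    trial: int
    chair_side: str  # {"left", "right"}
    outcome: str  # {"loss", "no_loss"}
    feedback_valence: str  # {"positive", "neutral"}
    isi_s: float
    iti_s: float


@dataclass
class TrialSchedule:
    trials: list[TrialRecord]
    seed: int
    loss_per_trial: float = 2.0

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(t) for t in self.trials], columns=SCHEDULE_COLUMNS)

    def phase(self, phase: int) -> list[TrialRecord]:
        return [t for t in self.trials if t.phase == phase]

    def runs(self) -> Iterable[tuple[tuple[int, int], list[TrialRecord]]]:
        """Yield ((phase, run), trials) in schedule order."""
        keys: list[tuple[int, int]] = []
        groups: dict[tuple[int, int], list[TrialRecord]] = {}
        for t in self.trials:
            key = (t.phase, t.run)
            if key not in groups:
                groups[key] = []
                keys.append(key)
            groups[key].append(t)
        for key in keys:
            yield key, groups[key]


@dataclass(frozen=True)
class Violation:
    rule: str
    phase: int | None
    run: int | None
    trial: int | None
    message: str


def _max_streak(seq: Sequence[str]) -> int:
    best = cur = 0
    prev = object()
    for x in seq:
        cur = cur + 1 if x == prev else 1
        best = max(best, cur)
        prev = x
    return best


def _constrained_sequence(
    rng: np.random.Generator,
    labels: tuple[str, str],
    counts: tuple[int, int],
    max_streak: int,
    max_attempts: int,
) -> list[str]:
    """Shuffle a balanced multiset until no label repeats more than max_streak times."""
    pool = np.array([labels[0]] * counts[0] + [labels[1]] * counts[1])
    for _ in range(max_attempts):
        rng.shuffle(pool)
        if _max_streak(pool) <= max_streak:
            return [str(x) for x in pool]
    raise InfeasibleDesignError(
        f"could not place {counts[0]}x{labels[0]} / {counts[1]}x{labels[1]} "
        f"with streaks <= {max_streak} within {max_attempts} attempts"
    )


def generate_schedule(seed: int, config: DesignConfig | None = None) -> TrialSchedule:
    """Generate a constraint-satisfying pseudorandomized schedule.

    Identical (seed, config) pairs yield bit-identical schedules.  Raises
    :class:`InfeasibleDesignError` if the rejection-sampling attempt cap is
    exhausted (e.g. a loss count that cannot respect the streak cap).
    """
    config = config or DesignConfig()
    if not 0 <= config.loss_per_run <= config.trials_per_run:
        raise InfeasibleDesignError(
            f"loss_per_run={config.loss_per_run} outside [0, {config.trials_per_run}]"
        )
    rng = np.random.default_rng(seed)
    trials: list[TrialRecord] = []
    n = config.trials_per_run
    side_counts = (n - n // 2, n // 2)
    for phase in range(1, config.n_phases + 1):
        for run in range(1, config.runs_per_phase + 1):
            outcomes = _constrained_sequence(
                rng,
                ("loss", "no_loss"),
                (config.loss_per_run, n - config.loss_per_run),
                config.max_outcome_streak,
                config.max_attempts,
            )
            sides = _constrained_sequence(
                rng, ("left", "right"), side_counts, config.max_side_streak, config.max_attempts
            )
            isi = rng.choice(config.jitter_values, size=n)
            iti = rng.choice(config.jitter_values, size=n)
            for i in range(n):
                trials.append(
                    TrialRecord(
                        phase=phase,
                        run=run,
                        trial=i + 1,
                        chair_side=sides[i],
                        outcome=outcomes[i],
                        feedback_valence=PHASE_VALENCE_MAP[(phase, outcomes[i])],
                        isi_s=float(isi[i]),
                        iti_s=float(iti[i]),
                    )
                )
    return TrialSchedule(trials=trials, seed=seed, loss_per_trial=config.loss_per_trial)


def validate_schedule(
    schedule: TrialSchedule, config: DesignConfig | None = None
) -> list[Violation]:
    """Check every design invariant; returns an empty list iff all hold.

    Validation never raises on schedule content: each broken rule becomes a
    :class:`Violation` naming the rule and its location.
    """
    config = config or DesignConfig()
    violations: list[Violation] = []
    expected_total = config.n_phases * config.runs_per_phase * config.trials_per_run
    if len(schedule.trials) != expected_total:
        violations.append(
            Violation(
                "total_trial_count",
                None,
                None,
                None,
                f"expected {expected_total} trials, found {len(schedule.trials)}",
            )
        )
    jitter_lo, jitter_hi = min(config.jitter_values), max(config.jitter_values)
    for (phase, run), run_trials in schedule.runs():
        outcomes = [t.outcome for t in run_trials]
        sides = [t.chair_side for t in run_trials]
        n_loss = outcomes.count("loss")
        if len(run_trials) != config.trials_per_run:
            violations.append(
                Violation(
                    "trials_per_run",
                    phase,
                    run,
                    None,
                    f"run has {len(run_trials)} trials, expected {config.trials_per_run}",
                )
            )
        if n_loss != config.loss_per_run:
            violations.append(
                Violation(
                    "loss_count_per_run",
                    phase,
                    run,
                    None,
                    f"run has {n_loss} loss trials, expected {config.loss_per_run}",
                )
            )
        streak = _max_streak(outcomes)
        if streak > config.max_outcome_streak:
            violations.append(
                Violation(
                    "outcome_streak",
                    phase,
                    run,
                    _first_long_streak_end(outcomes, config.max_outcome_streak),
                    f"outcome streak of {streak} exceeds {config.max_outcome_streak}",
                )
            )
        streak = _max_streak(sides)
        if streak > config.max_side_streak:
            violations.append(
                Violation(
                    "side_streak",
                    phase,
                    run,
                    _first_long_streak_end(sides, config.max_side_streak),
                    f"chair-side streak of {streak} exceeds {config.max_side_streak}",
                )
            )
        for t in run_trials:
            expected = PHASE_VALENCE_MAP.get((t.phase, t.outcome))
            if t.feedback_valence != expected:
                violations.append(
                    Violation(
                        "valence_mapping",
                        t.phase,
                        t.run,
                        t.trial,
                        f"outcome {t.outcome} in phase {t.phase} must map to "
                        f"{expected}, found {t.feedback_valence}",
                    )
                )
            for name, value in (("isi_s", t.isi_s), ("iti_s", t.iti_s)):
                if not jitter_lo <= value <= jitter_hi:
                    violations.append(
                        Violation(
                            "jitter_range",
                            t.phase,
                            t.run,
                            t.trial,
                            f"{name}={value} outside [{jitter_lo}, {jitter_hi}]",
                        )
                    )
    return violations


def _first_long_streak_end(seq: Sequence[str], max_streak: int) -> int | None:
    cur = 0
    prev = object()
    for i, x in enumerate(seq):
        cur = cur + 1 if x == prev else 1
        prev = x
        if cur > max_streak:
            return i + 1  # 1-based trial index of first excess trial
    return None


def condition_counts(schedule: TrialSchedule) -> dict[tuple[str, str], int]:
    """Trial counts per (feedback_valence, outcome) cell of the 2x2 design."""
    counts: dict[tuple[str, str], int] = {}
    for t in schedule.trials:
        key = (t.feedback_valence, t.outcome)
        counts[key] = counts.get(key, 0) + 1
    return counts


def displayed_loss(
    schedule: TrialSchedule, losses_incurred: Sequence[int], seed: int
) -> list[float]:
    """Cumulative monetary loss displayed at the end of each run.

    The display subtracts a per-run integer jitter drawn uniformly from
    {0, 1, 2, 3} from the true cumulative loss (loss_per_trial x losses so
    far) to mask the predetermined loss counts, floored at 0.
    """
    if any(x < 0 for x in losses_incurred):
        raise ValueError("losses_incurred must be non-negative")
    rng = np.random.default_rng(seed)
    cumulative = np.cumsum(losses_incurred)
    out = []
    for cum in cumulative:
        u = int(rng.integers(0, 4))
        out.append(max(0.0, schedule.loss_per_trial * float(cum) - u))
    return out


def write_schedule(schedule: TrialSchedule, path: str | Path) -> None:
    schedule.to_frame().to_csv(path, index=False, lineterminator="\n")


def read_schedule(path: str | Path, *, seed: int = -1, loss_per_trial: float = 2.0) -> TrialSchedule:
    df = pd.read_csv(path)
    missing = set(SCHEDULE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"schedule file missing columns: {sorted(missing)}")
    trials = [
        TrialRecord(
            phase=int(r.phase),
            run=int(r.run),
            trial=int(r.trial),
            chair_side=str(r.chair_side),
            outcome=str(r.outcome),
            feedback_valence=str(r.feedback_valence),
            isi_s=float(r.isi_s),
            iti_s=float(r.iti_s),
        )
        for r in df.itertuples()
    ]
    return TrialSchedule(trials=trials, seed=seed, loss_per_trial=loss_per_trial)
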