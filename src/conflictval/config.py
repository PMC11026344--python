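"""Run configuration: defaults, validation, YAML round-trip, orchestration.

One master seed drives every stage through named SeedSequence substreams so
stages are independently reproducible; no operation reads the wall clock or
global RNG state.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import study
from .cohort import (
    DEFAULT_SCHEDULE_SEED,
    Cohort,
    CohortSpec,
    EffectModel,
    ParamRanges,
    sample_cohort,
    write_cohort,
)
from .pipeline import analyze_measures, compute_indices, correlate_indices, report_frame
from .rl import GridSpec, REWARD_CODING_01, REWARD_CODING_NEG0
from .task_design import DesignConfig, generate_schedule, validate_schedule, write_schedule

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config", "run_all"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved knobs for an end-to-end run.

    Defaults are smoke-run scale (8 subjects, coarse 6-point grid) so a
    default `run-all` finishes in minutes; scale up via a config file.
    """

    seed: int = 0
    out_dir: str = "runs/default"
    # cohort
    n_subjects: int = 8
    miss_rate: float = 0.0137
    phase_order_counterbalance: bool = True
    measure: str = "rating"
    effect_model: dict[str, float] = field(
        default_factory=lambda: dataclasses.asdict(EffectModel())
    )
    rl_param_ranges: dict[str, list[float]] = field(
        default_factory=lambda: {k: list(v) for k, v in dataclasses.asdict(ParamRanges()).items()}
    )
    # fitting
    grid: str = "coarse"  # {"coarse", "default"} or path to a YAML grid file
    reward_coding: str = "01"  # {"01", "neg0"}
    shared_beta: bool = False
    # inference
    r_scale: float = 0.707
    kappa: float = 1.0
    alpha: float = 0.05
    bf_null_threshold: float = 3.0

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            n_subjects=self.n_subjects,
            rl_params=ParamRanges(**{k: tuple(v) for k, v in self.rl_param_ranges.items()}),
            effect_model=EffectModel(**self.effect_model),
            phase_order_counterbalance=self.phase_order_counterbalance,
            miss_rate=self.miss_rate,
            seed=int(np.random.SeedSequence(self.seed).spawn(2)[1].generate_state(1)[0] % (2**31)),
            measure=self.measure,
        )

    def grid_spec(self) -> GridSpec:
        if self.grid == "coarse":
            base = GridSpec.coarse()
        elif self.grid == "default":
            base = GridSpec.default()
        else:
            with open(self.grid) as fh:
                axes = yaml.safe_load(fh)
            try:
                base = GridSpec(**{k: tuple(v) for k, v in axes.items()})
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"invalid grid file {self.grid}: {exc}") from exc
        if self.shared_beta:
            base = dataclasses.replace(base, shared_beta=True)
        return base

    def reward_map(self) -> dict[str, float]:
        return dict(REWARD_CODING_01 if self.reward_coding == "01" else REWARD_CODING_NEG0)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


_FIELDS = {f.name for f in dataclasses.fields(RunConfig)}


def _validate(cfg: RunConfig) -> RunConfig:
    if cfg.reward_coding not in ("01", "neg0"):
        raise ConfigError(f"reward_coding={cfg.reward_coding!r} not one of '01', 'neg0'")
    if not 0 < cfg.alpha < 1:
        raise ConfigError(f"alpha={cfg.alpha} outside (0, 1)")
    if cfg.r_scale <= 0 or cfg.kappa <= 0:
        raise ConfigError("prior scales must be positive")
    try:
        cfg.cohort_spec().validate()
        cfg.grid_spec()
    except (ValueError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc
    return cfg


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML config; absent keys take documented defaults, unknown
    keys are rejected by name, out-of-range values raise naming the field."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown = sorted(set(raw) - _FIELDS)
    if unknown:
        raise ConfigError(f"unknown config keys: {unknown}")
    try:
        cfg = RunConfig(**raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    return _validate(cfg)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> Path:
    """Execute design -> simulate -> fit -> stats -> analyze, logging each
    stage's outputs and sha256 digests; identical configs give identical
    digests.  A stage failure raises with the stage name, leaving earlier
    outputs in place."""
    _validate(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(config, out / "resolved_config.yaml")
    log: dict[str, Any] = {"seed": config.seed, "stages": {}}

    def _record(name: str, artifacts: list[Path]) -> None:
        log["stages"][name] = {str(p.relative_to(out)): _digest(p) for p in artifacts}

    stage = "design"
    try:
        # the schedule is frozen cohort-wide, as all participants saw one fixed order
        schedule = generate_schedule(DEFAULT_SCHEDULE_SEED)
        violations = validate_schedule(schedule)
        if violations:
            raise RuntimeError(f"generated schedule failed validation: {violations[:3]}")
        write_schedule(schedule, out / "schedule.csv")
        _record(stage, [out / "schedule.csv"])

        stage = "simulate"
        cohort: Cohort = sample_cohort(config.cohort_spec())
        cdir = write_cohort(cohort, out / "cohort")
        _record(stage, sorted(cdir.glob("*.csv")) + [cdir / "truth.yaml"])

        stage = "fit"
        fits = study.fit_cohort(cohort.choices, config.grid_spec(), config.reward_map())
        fits.to_csv(out / "fits.tsv", sep="\t", index=False, lineterminator="\n")
        _record(stage, [out / "fits.tsv"])

        stage = "stats"
        frames = [
            study.choice_tests(cohort.choices, config.r_scale),
            study.learning_rate_tests(fits, cohort.choices, config.r_scale),
            study.ratings_anova(cohort.conditions, config.measure, config.r_scale),
        ]
        pd.concat(frames, ignore_index=True).to_csv(
            out / "stats.tsv", sep="\t", index=False, lineterminator="\n"
        )
        _record(stage, [out / "stats.tsv"])

        stage = "analyze"
        reports = analyze_measures(
            cohort.conditions,
            alpha=config.alpha,
            bf_null_threshold=config.bf_null_threshold,
            r_scale=config.r_scale,
        )
        frame = report_frame(reports)
        frame.to_csv(out / "report.tsv", sep="\t", index=False, lineterminator="\n")
        measures = list(frame["measure"])
        indices = [compute_indices(cohort.conditions, m) for m in measures]
        corr = correlate_indices(indices, len(measures), config.alpha, config.kappa)
        corr.to_csv(out / "index_correlations.tsv", sep="\t", index=False, lineterminator="\n")
        summary = {
            "adjudication": dict(zip(frame["measure"], frame["adjudication"])),
            "n_subjects": config.n_subjects,
            "alpha": config.alpha,
            "bf_null_threshold": config.bf_null_threshold,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        _record(stage, [out / "report.tsv", out / "index_correlations.tsv", out / "summary.json"])
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return out
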