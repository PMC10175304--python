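"""Trial-log CSV schema, configuration files, and the pipeline driver.

The interchange format is a UTF-8 CSV with a mandatory header row and one
row per key press: ``participant, group, block, block_role, trial,
instruction, response, rt, correct`` (1-based block/trial indices).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from .analysis import TRIAL_COLUMNS
from .lba import LBAParams
from .sequences import ALPHABET, BLOCK_ROLES, CONDITIONS

logger = logging.getLogger("chunkrt")


class SchemaError(ValueError):
    """A trial-log file violates the expected schema."""


def write_trials(records: pd.DataFrame, path) -> None:
    """Write a trial log as CSV (lossless round-trip with read_trials)."""
    missing = [c for c in TRIAL_COLUMNS if c not in records.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    records.loc[:, TRIAL_COLUMNS].to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial-log CSV.

    Raises :class:`SchemaError` listing offending line numbers (1-based,
    header = line 1) for malformed rows.
    """
    df = pd.read_csv(path, dtype={"participant": str, "group": str})
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    bad: list[int] = []
    rt = pd.to_numeric(df["rt"], errors="coerce")
    bad += list(df.index[rt.isna() | (rt <= 0)])
    for col in ("instruction", "response"):
        bad += list(df.index[~df[col].isin(ALPHABET)])
    block = pd.to_numeric(df["block"], errors="coerce")
    bad += list(df.index[block.isna() | (block < 1) | (block > len(BLOCK_ROLES))])
    if bad:
        lines = sorted({int(i) + 2 for i in bad})
        raise SchemaError(f"{path}: malformed rows at lines {lines[:20]}")
    df["rt"] = rt
    df["block"] = block.astype(int)
    df["trial"] = pd.to_numeric(df["trial"]).astype(int)
    if df["correct"].dtype != bool:
        df["correct"] = (
            df["correct"].astype(str).str.lower().isin(["true", "1", "1.0"])
        )
    return df.loc[:, TRIAL_COLUMNS]


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SequenceConfig:
    condition: str = "size3"
    p_high: float = 0.9
    p_mid: float = 0.7
    residual_rule: str = "uniform"

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclass
class ModelConfig:
    w: float = 0.2
    n_iter: int = 20


@dataclass
class AnalysisConfig:
    rt_max: float = 1000.0
    reuse_window: int = 30
    control_scheme: str = "second-item"


@dataclass
class SimulateConfig:
    n_participants: int = 10
    rt_slope: float = 100.0
    rt_intercept: float = 150.0
    rt_noise_sd: float = 30.0
    learner_iters_per_block: int = 5


@dataclass
class Config:
    """Pipeline configuration; sections mirror the module parameters."""

    seed: int = 0
    sequence: SequenceConfig = field(default_factory=SequenceConfig)
    lba: LBAParams = field(default_factory=LBAParams)
    model: ModelConfig = field(default_factory=ModelConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)


_SECTIONS = {
    "sequence": SequenceConfig,
    "lba": LBAParams,
    "model": ModelConfig,
    "analysis": AnalysisConfig,
    "simulate": SimulateConfig,
}


def _build_section(cls, data: dict, name: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown keys in section {name!r}: {sorted(unknown)}")
    return cls(**data)


def config_from_dict(data: dict) -> Config:
    """Build a validated Config; unknown keys are rejected, defaults logged."""
    data = dict(data or {})
    kwargs = {}
    if "seed" in data:
        kwargs["seed"] = int(data.pop("seed"))
    for name, cls in _SECTIONS.items():
        section = data.pop(name, None)
        if section is None:
            logger.debug("config section %r missing; using defaults", name)
            kwargs[name] = cls()
        else:
            kwargs[name] = _build_section(cls, dict(section), name)
    if data:
        raise ValueError(f"unknown config sections: {sorted(data)}")
    return Config(**kwargs)


def load_config(path) -> Config:
    with open(path, "r", encoding="utf-8") as fh:
        return config_from_dict(yaml.safe_load(fh))


def save_results_json(results, path) -> None:
    """Serialise a fitted model (RationalChunkingResults) to JSON."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(results.to_dict(), fh, indent=2)


def save_truth_json(truth: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({pid: sorted(chunks) for pid, chunks in truth.items()}, fh,
                  indent=2)


def load_truth_json(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return {pid: frozenset(chunks) for pid, chunks in json.load(fh).items()}


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(config: Config) -> dict:
    """generate -> simulate -> analyze; returns the result bundle.

    The bundle holds the simulated trial log, the ground-truth chunk sets,
    per-participant chunk profiles, and the standard measure battery
    (N_AB / N_ABC counts, chunky boost, chunk increase, reuse probability).
    Fully deterministic given ``config.seed``.
    """
    from . import analysis
    from .simulate import CohortSpec, simulate_cohort

    logger.info("pipeline: condition=%s seed=%d", config.sequence.condition,
                config.seed)
    spec = CohortSpec(
        n_participants=config.simulate.n_participants,
        condition=config.sequence.condition,
        w=config.model.w,
        params=config.lba,
        rt_slope=config.simulate.rt_slope,
        rt_intercept=config.simulate.rt_intercept,
        rt_noise_sd=config.simulate.rt_noise_sd,
        seed=config.seed,
        learner_iters_per_block=config.simulate.learner_iters_per_block,
    )
    trials, truth = simulate_cohort(spec)
    logger.info("simulated %d trials for %d participants", len(trials),
                spec.n_participants)
    filtered, removed = analysis.filter_trials(trials, config.analysis.rt_max)
    logger.info("filtered %.1f%% of trials above %.0f ms", 100 * removed,
                config.analysis.rt_max)
    profiles = analysis.cohort_profiles(filtered, seed=config.seed)
    measures = {}
    checks = analysis.manipulation_check(filtered, seed=config.seed)
    for target, res in checks.items():
        measures[res.measure] = res
    boost = analysis.chunky_boost(
        filtered, "AB", control_scheme=config.analysis.control_scheme
    )
    measures[boost.measure] = boost
    increase = pd.Series(
        {pid: analysis.chunk_increase(prof, "AB") for pid, prof in profiles.items()},
        dtype=float,
    )
    measures["chunk_increase_AB"] = analysis.MeasureResult(
        "chunk_increase_AB", float(increase.mean()), increase
    )
    reuse = pd.Series(
        {
            pid: analysis.chunk_reuse_probability(
                prof, window=config.analysis.reuse_window
            )
            for pid, prof in profiles.items()
        },
        dtype=float,
    )
    measures["chunk_reuse"] = analysis.MeasureResult(
        "chunk_reuse", float(reuse.mean(skipna=True)), reuse
    )
    return {
        "trials": trials,
        "truth": truth,
        "profiles": profiles,
        "measures": measures,
        "removed_fraction": removed,
    }


def measures_frame(measures: dict) -> pd.DataFrame:
    """Tidy (participant, measure, value) table of a measure bundle."""
    return pd.concat([m.to_frame() for m in measures.values()],
                     ignore_index=True)
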