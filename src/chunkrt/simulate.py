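"""Synthetic SRT cohorts: the rational learner replayed trial by trial.

Each simulated participant receives a full 10-block session plan, responds
to every instruction through the LBA (with starting evidence set by the
participant's current chunk representation), and re-fits the chunk learner
on the instruction history after every block.  Model-unit reaction times
are mapped to milliseconds with an affine transform plus Gaussian noise —
purely an output convention, since the model itself is unscaled.

The emitted trial logs use the same schema the analysis module consumes,
so planted chunks can be scored for recovery end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import model as chunk_model
from .lba import LBAParams, StartEvidence, sample_drifts
from .model import PRIMITIVES, ChunkStats, _improve
from .sequences import ALPHABET, build_session, empirical_transition_matrix

#: condition -> (group label, default trade-off weight)
CONDITION_GROUPS: dict[str, tuple[str, float]] = {
    "independent": ("independent", 0.2),
    "size2": ("size2", 0.2),
    "size3": ("size3", 0.2),
    "illusory-fast": ("fast", 1.0),
    "illusory-accurate": ("accurate", 0.0),
}


@dataclass
class CohortSpec:
    """Configuration of one simulated cohort.

    rt_slope/rt_intercept map model time units to milliseconds
    (rt_ms = slope * rt_model + intercept + Normal(0, rt_noise_sd)); the
    defaults land simulated RTs in a plausible 200-1000 ms band.
    """

    n_participants: int = 20
    condition: str = "size3"
    w: float | None = None
    params: LBAParams = field(default_factory=LBAParams)
    rt_slope: float = 100.0
    rt_intercept: float = 150.0
    rt_noise_sd: float = 30.0
    seed: int = 0
    learner_iters_per_block: int = 5

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.rt_slope <= 0:
            raise ValueError("rt_slope must be > 0")
        if self.rt_noise_sd < 0:
            raise ValueError("rt_noise_sd must be >= 0")
        if self.condition not in CONDITION_GROUPS:
            raise ValueError(f"unknown condition {self.condition!r}")

    @property
    def group(self) -> str:
        return CONDITION_GROUPS[self.condition][0]

    @property
    def trade_off(self) -> float:
        return self.w if self.w is not None else CONDITION_GROUPS[self.condition][1]


class _Executor:
    """Online chunk execution state: committed chunk + pending predictions.

    Inside a committed chunk the next item is predicted deterministically.
    At a chunk boundary the start evidence is the representation's
    element-level next-item prediction after the previous instruction
    (the chunk-transition priors collapsed through chunk commitment; for a
    primitives-only representation this is exactly the empirical bigram
    prior).  When a within-chunk prediction conflicts with the shown
    instruction the commitment is aborted and the next trial is re-planned
    as a boundary (the participant re-orients after the conflict).
    """

    def __init__(self) -> None:
        self.pending: list[str] = []
        self.last_element: str | None = None

    def start_evidence(
        self,
        chunks: frozenset[str],
        stats: ChunkStats | None,
        epsilon: float,
    ) -> tuple[StartEvidence, str | None]:
        """(start evidence, predicted symbol or None) for the upcoming trial."""
        if self.pending:
            predicted = self.pending[0]
            return StartEvidence.within_chunk(predicted, epsilon), predicted
        probs = self._boundary_probs(chunks, stats)
        return StartEvidence.from_probs(probs, epsilon), None

    def _boundary_probs(
        self, chunks: frozenset[str], stats: ChunkStats | None
    ) -> np.ndarray:
        n = len(ALPHABET)
        if stats is None or self.last_element is None:
            return np.full(n, 1.0 / n)
        probs, _ = chunk_model._context_next_probs(
            self.last_element, chunks, stats
        )
        if probs.sum() <= 0:
            return np.full(n, 1.0 / n)
        return probs / probs.sum()

    def advance(
        self,
        instruction: str,
        chunks: frozenset[str],
        stats: ChunkStats | None,
    ) -> None:
        """Consume one trial: step inside the committed chunk, abort on a
        prediction conflict, or commit to a new chunk at a boundary."""
        self.last_element = instruction
        if self.pending:
            predicted = self.pending.pop(0)
            if predicted != instruction:
                self.pending = []
            return
        candidates = [c for c in chunks if c[0] == instruction]
        if stats is not None:
            committed = max(
                candidates,
                key=lambda c: (stats.marginal.get(c, 0.0), len(c)),
            )
        else:
            committed = instruction
        self.pending = list(committed[1:])


def simulate_participant(
    spec: CohortSpec, participant_id, seed: int
) -> tuple[pd.DataFrame, frozenset[str]]:
    """Replay one participant's session; return (trial log, learned chunks)."""
    ss = np.random.SeedSequence(seed)
    session_seed = int(np.random.default_rng(ss.spawn(1)[0]).integers(2**31 - 1))
    rng = np.random.default_rng(ss)
    plan = build_session(spec.condition, session_seed)
    params = spec.params
    w = spec.trade_off
    chunks: frozenset[str] = PRIMITIVES
    stats: ChunkStats | None = None
    executor = _Executor()
    history: list[str] = []
    rows = []
    for block_idx, block in enumerate(plan.blocks, start=1):
        for trial_idx, instruction in enumerate(block.sequence, start=1):
            start, _ = executor.start_evidence(chunks, stats, params.epsilon)
            means = params.drift_means(ALPHABET.index(instruction))
            v = sample_drifts(means, params.sigma, rng, 1)[0]
            times = (params.b - start.k) / v
            winner = int(np.argmin(times))
            response = ALPHABET[winner]
            rt_model = float(times[winner])
            rt_ms = (
                spec.rt_slope * rt_model
                + spec.rt_intercept
                + rng.normal(0.0, spec.rt_noise_sd)
            )
            rows.append(
                {
                    "participant": participant_id,
                    "group": spec.group,
                    "block": block_idx,
                    "block_role": block.role,
                    "trial": trial_idx,
                    "instruction": instruction,
                    "response": response,
                    "rt": max(rt_ms, 1.0),
                    "correct": response == instruction,
                }
            )
            executor.advance(instruction, chunks, stats)
        history.append(block.sequence)
        seq = "".join(history)
        gen = empirical_transition_matrix(seq)
        chunks, stats, _ = _improve(
            seq, chunks, gen, w, params, spec.learner_iters_per_block, rng
        )
    return pd.DataFrame(rows), chunks


def simulate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, dict]:
    """Simulate ``spec.n_participants`` sessions; return (log, truth chunk sets).

    Participant ids are "p01", "p02", ...; the truth dict maps each id to
    the chunk set the participant's learner ended the session with.
    """
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_participants)
    logs = []
    truth = {}
    for i, child in enumerate(children, start=1):
        pid = f"p{i:02d}"
        pseed = int(np.random.default_rng(child).integers(2**31 - 1))
        log, chunks = simulate_participant(spec, pid, pseed)
        logs.append(log)
        truth[pid] = chunks
    return pd.concat(logs, ignore_index=True), truth


def planted_truth(spec: CohortSpec, participant_ids) -> dict:
    """Per-participant multi-symbol chunks planted by the generative design.

    For inventory conditions these are the multi-symbol inventory tokens
    (AB for size-2, ABC for size-3); the independent and illusory
    conditions plant none.
    """
    from .sequences import default_inventory

    inv = default_inventory(spec.condition)
    tokens = (
        frozenset(t for t in inv.tokens if len(t) >= 2)
        if inv is not None
        else frozenset()
    )
    return {pid: tokens for pid in participant_ids}


def recovery_rate(
    truth: dict, profiles: dict, roles=None, min_count: int = 1
) -> float:
    """Fraction of target multi-symbol chunks recovered by chunk extraction.

    ``truth`` maps participant id to a set of chunks — typically
    :func:`planted_truth` (the chunks the generative design embeds) or the
    learned sets returned by :func:`simulate_cohort`.  A chunk counts as
    recovered when the participant's extracted profile contains it at
    least ``min_count`` times in the given roles (default: any block).
    """
    from .analysis import count_chunks

    total = hits = 0
    for pid, chunks in truth.items():
        planted = [c for c in chunks if len(c) >= 2]
        for c in planted:
            total += 1
            if pid in profiles and count_chunks(profiles[pid], c, roles) >= min_count:
                hits += 1
    if total == 0:
        return float("nan")
    return hits / total
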