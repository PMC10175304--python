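"""Rational chunk learning under a speed-accuracy trade-off.

The learner maintains a chunk set C (always containing the four primitive
symbols), parses the instruction sequence with greedy longest match,
estimates chunk marginals P_C(c) and transitions P_C(c_j | c_i) from the
parse, and iteratively proposes concatenating the chunk pair with the
highest joint probability P_C(c_i) * P_C(c_j | c_i).  A proposal is accepted
iff it strictly lowers the loss

    L = w * Rt + (1 - w) * Err,

where Rt is the LBA-expected mean reaction time of the parse
(within-chunk presses are fast, chunk-initial presses carry transition
uncertainty) and Err is the expected error rate against the element-level
generative matrix.  w = 0 optimises accuracy only; w = 1 optimises speed
only.  Both expectations are Monte-Carlo estimates from the LBA.

The public surface is statsmodels-like: build a
:class:`RationalChunkingModel` from a sequence, call :meth:`fit`, and read
the learned representation off the returned
:class:`RationalChunkingResults`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import lba
from .lba import LBAParams, StartEvidence, UnseenContextError
from .sequences import ALPHABET, TransitionMatrix, empirical_transition_matrix

PRIMITIVES: frozenset[str] = frozenset(ALPHABET)


def _validate_chunkset(chunks: Iterable[str]) -> frozenset[str]:
    chunks = frozenset(chunks)
    if not PRIMITIVES <= chunks:
        raise ValueError("a chunk set must contain all primitive symbols")
    for c in chunks:
        if not c or any(s not in ALPHABET for s in c):
            raise ValueError(f"invalid chunk {c!r}")
    return chunks


@dataclass
class ChunkStats:
    """Empirical chunk marginals and transitions from a sequence parse."""

    marginal: dict[str, float]
    transition: dict[tuple[str, str], float]
    chunk_counts: Counter
    pair_counts: Counter
    n_chunks: int

    def joint(self, c_i: str, c_j: str) -> float:
        return self.marginal.get(c_i, 0.0) * self.transition.get((c_i, c_j), 0.0)


@dataclass(frozen=True)
class LossBreakdown:
    """One evaluation of the speed-accuracy loss L = w*Rt + (1-w)*Err."""

    rt_term: float
    err_term: float
    w: float
    total: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must lie in [0, 1]")
        if not 0.0 <= self.err_term <= 1.0 + 1e-9:
            raise ValueError("error term must lie in [0, 1]")
        object.__setattr__(
            self, "total", self.w * self.rt_term + (1.0 - self.w) * self.err_term
        )


def parse(seq: str, chunks: Iterable[str]) -> list[str]:
    """Greedy left-to-right longest-match cover of ``seq`` with ``chunks``.

    Primitive retention guarantees the cover exists; the concatenation of
    the returned chunks equals ``seq`` exactly.
    """
    chunkset = _validate_chunkset(chunks)
    by_len = sorted(chunkset, key=len, reverse=True)
    out: list[str] = []
    i = 0
    n = len(seq)
    while i < n:
        for c in by_len:
            if seq.startswith(c, i):
                out.append(c)
                i += len(c)
                break
        else:  # pragma: no cover - primitives make this unreachable
            raise ValueError(f"symbol {seq[i]!r} not coverable")
    return out


def estimate_stats(parsed: Sequence[str]) -> ChunkStats:
    """Chunk marginal and transition probabilities from a parse (by counting)."""
    if not parsed:
        raise ValueError("cannot estimate statistics from an empty parse")
    chunk_counts = Counter(parsed)
    pair_counts = Counter(zip(parsed[:-1], parsed[1:]))
    n = len(parsed)
    marginal = {c: cnt / n for c, cnt in chunk_counts.items()}
    pred_totals = Counter()
    for (ci, _), cnt in pair_counts.items():
        pred_totals[ci] += cnt
    transition = {
        (ci, cj): cnt / pred_totals[ci] for (ci, cj), cnt in pair_counts.items()
    }
    return ChunkStats(marginal, transition, chunk_counts, pair_counts, n)


def average_chunk_length(parsed: Sequence[str]) -> float:
    """Parse-frequency-weighted mean chunk length = symbols / chunks."""
    if not parsed:
        raise ValueError("empty parse has no average chunk length")
    return sum(len(c) for c in parsed) / len(parsed)


def _context_next_probs(
    z: str, chunkset: frozenset[str], stats: ChunkStats
) -> tuple[np.ndarray, str]:
    """Predicted next-element distribution after element ``z``.

    If any learned chunk contains ``z`` at a non-final position, the model
    commits to the highest-marginal such chunk and predicts its within-chunk
    successor deterministically ("within").  Otherwise the trial is a chunk
    boundary: the context is the highest-marginal chunk ending in ``z`` and
    the distribution sums chunk-transition mass by initial element
    ("between").  Ties break lexicographically.
    """
    within = [c for c in chunkset if len(c) >= 2 and z in c[:-1]]
    if within:
        c_star = min(within, key=lambda c: (-stats.marginal.get(c, 0.0), c))
        succ = c_star[c_star.index(z) + 1]
        probs = np.array([1.0 if s == succ else 0.0 for s in ALPHABET])
        return probs, "within"
    enders = [c for c in chunkset if c.endswith(z)]
    ctx = min(enders, key=lambda c: (-stats.marginal.get(c, 0.0), c))
    try:
        probs = lba.boundary_start_probs(ctx, stats)
    except UnseenContextError:
        probs = np.full(len(ALPHABET), 1.0 / len(ALPHABET))
    return probs, "between"


def expected_rt(
    chunkset: Iterable[str],
    stats: ChunkStats,
    params: LBAParams,
    rng=None,
) -> float:
    """LBA-expected mean reaction time per key press under the chunk set.

    A chunk c_j parsed after c_i costs rt_between(c_j, c_i) for its first
    press and rt_within for each of the remaining |c_j| - 1 presses.  The
    expected per-press reaction time is the ratio of the
    P_C(c_i) P_C(c_j | c_i)-weighted expected chunk time to the expected
    chunk length, so that every key press carries equal weight regardless
    of how the representation groups presses into chunks.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    _validate_chunkset(chunkset)
    rt_within = lba.expected_rt_within(params, rng)
    pairs = [(ci, cj, p) for (ci, cj), p in stats.transition.items() if p > 0]
    if not pairs:
        return rt_within
    boundary = {}
    for ci, _, _ in pairs:
        if ci not in boundary:
            probs = lba.boundary_start_probs(ci, stats)
            boundary[ci] = StartEvidence.from_probs(probs, params.epsilon).k
    K = np.stack([boundary[ci] for ci, _, _ in pairs])
    instr = np.array([ALPHABET.index(cj[0]) for _, cj, _ in pairs])
    rt_b = lba._mc_min_rt_batch(K, instr, params, rng)
    time_total = 0.0
    press_total = 0.0
    for (ci, cj, p), rb in zip(pairs, rt_b):
        L = len(cj)
        wgt = stats.marginal[ci] * p
        time_total += wgt * (rb + (L - 1) * rt_within)
        press_total += wgt * L
    return float(time_total / press_total)


def expected_error(
    chunkset: Iterable[str],
    stats: ChunkStats,
    gen: TransitionMatrix,
    params: LBAParams,
    rng=None,
) -> float:
    """LBA-expected error rate against the generative element matrix.

    Err = sum_zi P_I(zi) sum_zj P_I(zj|zi) Pr[LBA response != zj], where the
    starting evidence after element zi follows the representation: a
    committed within-chunk prediction if zi sits non-finally inside a
    learned chunk, otherwise the boundary transition distribution.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    chunkset = _validate_chunkset(chunkset)
    pi = gen.stationary()
    rows_k = []
    for zi in ALPHABET:
        probs, _ = _context_next_probs(zi, chunkset, stats)
        rows_k.append(StartEvidence.from_probs(probs, params.epsilon).k)
    cells = []
    weights = []
    instr = []
    for i, zi in enumerate(ALPHABET):
        for j, zj in enumerate(ALPHABET):
            p = gen.probs[i, j]
            if p <= 0:
                continue
            cells.append(rows_k[i])
            weights.append(pi[i] * p)
            instr.append(j)
    win = lba._mc_choice_probs_batch(
        np.stack(cells), np.array(instr), params, rng
    )
    err = sum(
        w * (1.0 - win[m, j]) for m, (w, j) in enumerate(zip(weights, instr))
    )
    return float(min(max(err, 0.0), 1.0))


def loss(
    chunkset: Iterable[str],
    stats: ChunkStats,
    gen: TransitionMatrix,
    params: LBAParams,
    w: float,
    rng=None,
) -> LossBreakdown:
    """Evaluate L = w*Rt + (1-w)*Err for a chunk representation."""
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must lie in [0, 1]")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rt = expected_rt(chunkset, stats, params, rng)
    err = expected_error(chunkset, stats, gen, params, rng)
    return LossBreakdown(rt, err, w)


def propose(
    stats: ChunkStats, exclude: Iterable[str] = ()
) -> tuple[str, str, str] | None:
    """Chunk pair with the highest joint probability P_C(c_i) P_C(c_j | c_i).

    Returns (c_i, c_j, c_i + c_j), skipping candidates whose concatenation
    is in ``exclude`` (e.g. chunks already in the set).  Exact ties break
    lexicographically on (c_i, c_j).  Returns None when no admissible pair
    exists.
    """
    exclude = set(exclude)
    ranked = sorted(
        ((ci, cj) for (ci, cj) in stats.transition),
        key=lambda p: (-stats.joint(*p), p),
    )
    for ci, cj in ranked:
        if stats.joint(ci, cj) <= 0:
            break
        if ci + cj not in exclude:
            return ci, cj, ci + cj
    return None


def effective_transition_matrix(
    chunkset: Iterable[str], stats: ChunkStats
) -> TransitionMatrix:
    """Element-level transition matrix implied by the representation.

    An element absorbed non-finally into a chunk predicts its within-chunk
    successor with probability 1; a chunk-final element's row is the
    boundary next-element distribution of its highest-marginal chunk.  With
    primitives only this reduces to the empirical element bigram matrix.
    """
    chunkset = _validate_chunkset(chunkset)
    rows = []
    for z in ALPHABET:
        probs, _ = _context_next_probs(z, chunkset, stats)
        rows.append(probs / probs.sum())
    return TransitionMatrix(ALPHABET, np.stack(rows))


def chunk_parse_probability(runs: Sequence, chunk: str) -> tuple[float, float]:
    """Mean and SEM of a chunk's parse marginal across independent runs.

    ``runs`` holds :class:`RationalChunkingResults` (or (chunkset, stats)
    pairs); a run where the chunk is absent contributes 0.
    """
    if len(runs) == 0:
        raise ValueError("need at least one run")
    vals = []
    for run in runs:
        stats = run.stats if hasattr(run, "stats") else run[1]
        vals.append(stats.marginal.get(chunk, 0.0))
    vals = np.asarray(vals)
    sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return float(vals.mean()), sem


def _improve(
    seq: str,
    chunkset: frozenset[str],
    gen: TransitionMatrix,
    w: float,
    params: LBAParams,
    n_iter: int,
    rng: np.random.Generator,
    current: LossBreakdown | None = None,
) -> tuple[frozenset[str], ChunkStats, list[LossBreakdown]]:
    """Run ``n_iter`` propose/accept iterations from an existing chunk set."""
    parsed = parse(seq, chunkset)
    stats = estimate_stats(parsed)
    if current is None:
        current = loss(chunkset, stats, gen, params, w, rng)
    trajectory = [current]
    for _ in range(n_iter):
        prop = propose(stats, exclude=chunkset)
        if prop is None:
            break
        _, _, candidate = prop
        cand_set = chunkset | {candidate}
        cand_parsed = parse(seq, cand_set)
        cand_stats = estimate_stats(cand_parsed)
        cand_loss = loss(cand_set, cand_stats, gen, params, w, rng)
        if cand_loss.total < current.total:
            chunkset, stats, current = cand_set, cand_stats, cand_loss
            trajectory.append(current)
    return chunkset, stats, trajectory


def rational_update(
    seq: str,
    gen: TransitionMatrix | None,
    w: float,
    params: LBAParams | None = None,
    n_iter: int = 20,
    seed=None,
) -> tuple[frozenset[str], list[LossBreakdown]]:
    """Functional entry point: learn a chunk set from a sequence.

    Equivalent to ``RationalChunkingModel(seq, gen, w, params).fit(...)``
    but returns the raw (chunk set, accepted-loss trajectory) pair.
    """
    res = RationalChunkingModel(seq, generative=gen, w=w, params=params).fit(
        n_iter=n_iter, seed=seed
    )
    return res.chunks, res.loss_trajectory


class RationalChunkingModel:
    """Rational chunking learner for one instruction sequence.

    Parameters
    ----------
    sequence : str
        Instruction symbols over {A, B, C, D}.
    generative : TransitionMatrix, optional
        Element-level generative matrix P_I used by the error term.  When
        omitted, the empirical bigram matrix of ``sequence`` is used (the
        natural choice for chunk-inventory training sequences, which have
        no stated element-level generator).
    w : float
        Speed-accuracy trade-off weight in [0, 1].
    params : LBAParams, optional
        Accumulator configuration (standard defaults).
    """

    def __init__(
        self,
        sequence: str,
        generative: TransitionMatrix | None = None,
        w: float = 0.2,
        params: LBAParams | None = None,
    ) -> None:
        if not sequence:
            raise ValueError("sequence must be non-empty")
        if any(s not in ALPHABET for s in sequence):
            raise ValueError("sequence contains symbols outside the alphabet")
        if not 0.0 <= w <= 1.0:
            raise ValueError("w must lie in [0, 1]")
        self.sequence = sequence
        self.generative = (
            generative
            if generative is not None
            else empirical_transition_matrix(sequence)
        )
        self.w = float(w)
        self.params = params if params is not None else LBAParams()

    @classmethod
    def from_dataframe(
        cls,
        trials,
        roles: Iterable[str] = ("training",),
        **kwargs,
    ) -> "RationalChunkingModel":
        """Build from a trial-log table, concatenating instruction columns of
        the given block roles (default: the six training blocks)."""
        roles = set(roles)
        sub = trials[trials["block_role"].isin(roles)]
        sub = sub.sort_values(["block", "trial"])
        return cls("".join(sub["instruction"]), **kwargs)

    def fit(self, n_iter: int = 20, seed=None) -> "RationalChunkingResults":
        """Run the propose/accept loop for ``n_iter`` iterations."""
        if n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        chunks, stats, traj = _improve(
            self.sequence, PRIMITIVES, self.generative, self.w, self.params,
            n_iter, rng,
        )
        return RationalChunkingResults(self, chunks, stats, traj)


class RationalChunkingResults:
    """Learned chunk representation with its loss trajectory and diagnostics."""

    def __init__(
        self,
        model: RationalChunkingModel,
        chunks: frozenset[str],
        stats: ChunkStats,
        loss_trajectory: list[LossBreakdown],
    ) -> None:
        self.model = model
        self.chunks = chunks
        self.stats = stats
        self.loss_trajectory = loss_trajectory

    @property
    def parsed(self) -> list[str]:
        return parse(self.model.sequence, self.chunks)

    @property
    def average_chunk_length(self) -> float:
        return average_chunk_length(self.parsed)

    @property
    def effective_matrix(self) -> TransitionMatrix:
        return effective_transition_matrix(self.chunks, self.stats)

    @property
    def final_loss(self) -> LossBreakdown:
        return self.loss_trajectory[-1]

    def parse_probability(self, chunk: str) -> float:
        """Marginal probability of ``chunk`` in the final parse (0 if absent)."""
        return self.stats.marginal.get(chunk, 0.0)

    def summary(self) -> str:
        lines = [
            "Rational chunking results",
            "=" * 41,
            f"sequence length    {len(self.model.sequence):>10d}",
            f"trade-off w        {self.model.w:>10.3f}",
            f"chunks learned     {len(self.chunks):>10d}",
            f"avg chunk length   {self.average_chunk_length:>10.3f}",
            f"Rt term (model u.) {self.final_loss.rt_term:>10.4f}",
            f"Err term           {self.final_loss.err_term:>10.4f}",
            f"loss (initial)     {self.loss_trajectory[0].total:>10.4f}",
            f"loss (final)       {self.final_loss.total:>10.4f}",
            "-" * 41,
            "chunk        P_C(c)",
        ]
        for c in sorted(self.chunks, key=lambda c: (-self.stats.marginal.get(c, 0), c)):
            lines.append(f"{c:<12s} {self.stats.marginal.get(c, 0.0):.4f}")
        return "\n".join(lines)

    def plot_loss(self, ax=None):
        """Accepted-loss trajectory; returns the matplotlib Axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        totals = [lb.total for lb in self.loss_trajectory]
        ax.plot(range(len(totals)), totals, marker="o")
        ax.set_xlabel("accepted update")
        ax.set_ylabel("loss  w*Rt + (1-w)*Err")
        return ax

    def to_dict(self) -> dict:
        """JSON-serialisable document of the learned representation."""
        return {
            "w": self.model.w,
            "chunks": sorted(self.chunks),
            "marginal": dict(sorted(self.stats.marginal.items())),
            "transition": {
                f"{ci}->{cj}": p
                for (ci, cj), p in sorted(self.stats.transition.items())
            },
            "loss_trajectory": [
                {"rt": lb.rt_term, "err": lb.err_term, "total": lb.total}
                for lb in self.loss_trajectory
            ],
            "params": {
                "v_instruction": self.model.params.v_instruction,
                "sigma": self.model.params.sigma,
                "b": self.model.params.b,
                "epsilon": self.model.params.epsilon,
                "n_draws": self.model.params.n_draws,
            },
        }
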