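"""Instruction-sequence generators for the serial reaction time (SRT) task.

The task shows one of four cues (A, B, C, D) per trial and the participant
presses the mapped key (D, F, J, K) as fast as possible.  A session has 10
blocks of 100 trials: two baseline blocks, six training blocks, and two test
blocks.  Baseline and test blocks are always drawn from the "illusory"
first-order Markov matrix, which contains highly probable bigrams (A->B and
C->D at 0.9, B->C and D->A at 0.7) but no deterministic chunk.  Training
blocks depend on the condition: chunk-inventory sampling for the
independent / size-2 / size-3 conditions, or the illusory matrix again for
the speed-accuracy instruction conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

ALPHABET: tuple[str, ...] = ("A", "B", "C", "D")
RESPONSE_KEYS: tuple[str, ...] = ("D", "F", "J", "K")

BLOCK_ROLES: tuple[str, ...] = ("baseline",) * 2 + ("training",) * 6 + ("test",) * 2
TRIALS_PER_BLOCK: int = 100
N_BLOCKS: int = len(BLOCK_ROLES)

CONDITIONS: tuple[str, ...] = (
    "independent",
    "size2",
    "size3",
    "illusory-fast",
    "illusory-accurate",
)

_ROW_TOL = 1e-9


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic element-level transition matrix.

    ``probs[i, j]`` is the probability that symbol ``symbols[j]`` follows
    symbol ``symbols[i]``.
    """

    symbols: tuple[str, ...]
    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        n = len(self.symbols)
        if probs.shape != (n, n):
            raise ValueError(
                f"probs must be square with dimension {n}, got {probs.shape}"
            )
        if np.any(probs < -_ROW_TOL) or np.any(probs > 1 + _ROW_TOL):
            raise ValueError("transition probabilities must lie in [0, 1]")
        rows = probs.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-9):
            raise ValueError(f"rows must sum to 1 within 1e-9, got {rows}")
        probs = np.clip(probs, 0.0, 1.0)
        probs.setflags(write=False)
        object.__setattr__(self, "symbols", tuple(self.symbols))
        object.__setattr__(self, "probs", probs)

    def index(self, symbol: str) -> int:
        try:
            return self.symbols.index(symbol)
        except ValueError:
            raise KeyError(f"unknown symbol {symbol!r}") from None

    def entry(self, predecessor: str, successor: str) -> float:
        return float(self.probs[self.index(predecessor), self.index(successor)])

    def row(self, symbol: str) -> np.ndarray:
        return self.probs[self.index(symbol)]

    def stationary(self) -> np.ndarray:
        """Stationary distribution (left eigenvector for eigenvalue 1)."""
        vals, vecs = np.linalg.eig(self.probs.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()


@dataclass(frozen=True)
class ChunkInventory:
    """Sampling inventory of chunk tokens, e.g. {AB: 1/3, C: 1/3, D: 1/3}."""

    tokens: tuple[str, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        tokens = tuple(self.tokens)
        weights = tuple(float(w) for w in self.weights)
        if not tokens:
            raise ValueError("inventory must contain at least one token")
        if len(tokens) != len(weights):
            raise ValueError("tokens and weights must have equal length")
        for t in tokens:
            if not t:
                raise ValueError("tokens must be non-empty")
            for s in t:
                if s not in ALPHABET:
                    raise ValueError(f"token symbol {s!r} not in alphabet")
        if any(w < 0 or w > 1 for w in weights):
            raise ValueError("weights must lie in [0, 1]")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1 within 1e-9")
        object.__setattr__(self, "tokens", tokens)
        object.__setattr__(self, "weights", weights)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "ChunkInventory":
        items = list(mapping.items())
        return cls(tuple(t for t, _ in items), tuple(w for _, w in items))


@dataclass(frozen=True)
class Block:
    role: str
    sequence: str


@dataclass(frozen=True)
class SessionPlan:
    """A full 10-block session: condition label, blocks, key mapping, seed."""

    condition: str
    blocks: tuple[Block, ...]
    key_mapping: Mapping[str, str]
    seed: int

    def __post_init__(self) -> None:
        if len(self.blocks) != N_BLOCKS:
            raise ValueError(f"a session has exactly {N_BLOCKS} blocks")
        roles = tuple(b.role for b in self.blocks)
        if roles != BLOCK_ROLES:
            raise ValueError(f"block roles must be {BLOCK_ROLES}, got {roles}")
        for b in self.blocks:
            if len(b.sequence) != TRIALS_PER_BLOCK:
                raise ValueError(
                    f"every block has exactly {TRIALS_PER_BLOCK} trials"
                )
        mapping = dict(self.key_mapping)
        if set(mapping) != set(ALPHABET) or set(mapping.values()) != set(
            RESPONSE_KEYS
        ):
            raise ValueError("key_mapping must be a bijection onto the key set")
        object.__setattr__(self, "key_mapping", mapping)

    @property
    def instruction_sequence(self) -> str:
        return "".join(b.sequence for b in self.blocks)

    def training_sequence(self) -> str:
        return "".join(b.sequence for b in self.blocks if b.role == "training")


def make_illusory_matrix(
    p_high: float = 0.9,
    p_mid: float = 0.7,
    residual_rule: str = "uniform",
    alphabet: Sequence[str] = ALPHABET,
) -> TransitionMatrix:
    """Build the illusory-chunk generative matrix.

    A->B and C->D get probability ``p_high``; B->C and D->A get ``p_mid``.
    The residual mass of each row is split over the remaining successors:
    ``"uniform"`` spreads it over the other three symbols, ``"no-repeat"``
    over the two symbols that are neither the favoured successor nor the
    predecessor itself.
    """
    if not (0.0 <= p_high <= 1.0 and 0.0 <= p_mid <= 1.0):
        raise ValueError("p_high and p_mid must lie in [0, 1]")
    alphabet = tuple(alphabet)
    n = len(alphabet)
    favoured = {0: (1, p_high), 1: (2, p_mid), 2: (3, p_high), 3: (0, p_mid)}
    probs = np.zeros((n, n))
    for i, (j, p) in favoured.items():
        probs[i, j] = p
        if residual_rule == "uniform":
            rest = [k for k in range(n) if k != j]
        elif residual_rule == "no-repeat":
            rest = [k for k in range(n) if k != j and k != i]
        else:
            raise ValueError(f"unknown residual_rule {residual_rule!r}")
        for k in rest:
            probs[i, k] = (1.0 - p) / len(rest)
    return TransitionMatrix(alphabet, probs)


def uniform_matrix(alphabet: Sequence[str] = ALPHABET) -> TransitionMatrix:
    """Memoryless uniform transitions (the independent condition)."""
    n = len(alphabet)
    return TransitionMatrix(tuple(alphabet), np.full((n, n), 1.0 / n))


def empirical_transition_matrix(
    seq: str, alphabet: Sequence[str] = ALPHABET
) -> TransitionMatrix:
    """Element-level bigram frequencies of ``seq`` as a stochastic matrix.

    Rows for symbols never observed as predecessors fall back to uniform.
    """
    alphabet = tuple(alphabet)
    idx = {s: i for i, s in enumerate(alphabet)}
    n = len(alphabet)
    counts = np.zeros((n, n))
    for a, b in zip(seq[:-1], seq[1:]):
        counts[idx[a], idx[b]] += 1
    rows = counts.sum(axis=1, keepdims=True)
    probs = np.where(rows > 0, counts / np.where(rows > 0, rows, 1), 1.0 / n)
    return TransitionMatrix(alphabet, probs)


def sample_markov_sequence(
    matrix: TransitionMatrix,
    n: int,
    seed=None,
    init: str = "stationary",
) -> str:
    """Sample a length-``n`` symbol sequence from a first-order Markov chain.

    ``init`` is either ``"stationary"`` (the default; the first symbol is
    drawn from the stationary distribution) or a symbol of the alphabet.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return ""
    rng = _as_rng(seed)
    symbols = matrix.symbols
    if init == "stationary":
        start = int(rng.choice(len(symbols), p=matrix.stationary()))
    else:
        start = matrix.index(init)
    cum = np.cumsum(matrix.probs, axis=1)
    us = rng.random(n - 1)
    out = np.empty(n, dtype=np.int64)
    out[0] = start
    cur = start
    for t in range(1, n):
        cur = int(np.searchsorted(cum[cur], us[t - 1], side="right"))
        cur = min(cur, len(symbols) - 1)
        out[t] = cur
    return "".join(symbols[i] for i in out)


def sample_chunk_sequence(inventory: ChunkInventory, n: int, seed=None) -> str:
    """Concatenate i.i.d. inventory tokens and hard-truncate to ``n`` symbols.

    Whole tokens are drawn until the concatenation reaches length ``n``; a
    partial token may therefore end the sequence.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return ""
    rng = _as_rng(seed)
    weights = np.asarray(inventory.weights)
    min_len = min(len(t) for t in inventory.tokens)
    parts: list[str] = []
    total = 0
    while total < n:
        batch = max(8, math.ceil((n - total) / min_len))
        draws = rng.choice(len(inventory.tokens), size=batch, p=weights)
        for i in draws:
            parts.append(inventory.tokens[int(i)])
            total += len(inventory.tokens[int(i)])
            if total >= n:
                break
    return "".join(parts)[:n]


def random_key_mapping(seed=None) -> dict[str, str]:
    """Uniform random bijection from the cue alphabet onto {D, F, J, K}."""
    rng = _as_rng(seed)
    perm = rng.permutation(len(RESPONSE_KEYS))
    return {s: RESPONSE_KEYS[int(p)] for s, p in zip(ALPHABET, perm)}


def default_inventory(condition: str) -> ChunkInventory | None:
    """The training-block inventory a condition implies (None for illusory)."""
    if condition == "independent":
        return ChunkInventory.from_mapping({s: 0.25 for s in ALPHABET})
    if condition == "size2":
        return ChunkInventory.from_mapping({"AB": 1 / 3, "C": 1 / 3, "D": 1 / 3})
    if condition == "size3":
        return ChunkInventory.from_mapping({"ABC": 0.5, "D": 0.5})
    if condition in ("illusory-fast", "illusory-accurate"):
        return None
    raise ValueError(f"unknown condition {condition!r}")


def build_session(
    condition: str,
    seed: int,
    matrix: TransitionMatrix | None = None,
    inventory: ChunkInventory | None = None,
) -> SessionPlan:
    """Assemble a 10-block session plan for one participant.

    Baseline and test blocks are sampled from the illusory matrix; training
    blocks come from the condition's chunk inventory (independent / size-2 /
    size-3) or from the same matrix (the instruction conditions).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if matrix is None:
        matrix = make_illusory_matrix()
    if inventory is None:
        inventory = default_inventory(condition)
    if condition in ("independent", "size2", "size3") and inventory is None:
        raise ValueError(f"condition {condition!r} requires a chunk inventory")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(N_BLOCKS + 1)
    key_mapping = random_key_mapping(np.random.default_rng(children[0]))
    blocks = []
    for role, child in zip(BLOCK_ROLES, children[1:]):
        rng = np.random.default_rng(child)
        if role == "training" and inventory is not None:
            seq = sample_chunk_sequence(inventory, TRIALS_PER_BLOCK, rng)
        else:
            seq = sample_markov_sequence(matrix, TRIALS_PER_BLOCK, rng)
        blocks.append(Block(role, seq))
    return SessionPlan(condition, tuple(blocks), key_mapping, seed)


def session_frame(plan: SessionPlan) -> pd.DataFrame:
    """Tabulate a session plan: one row per trial, 1-based indices."""
    rows = []
    for b, block in enumerate(plan.blocks, start=1):
        for t, symbol in enumerate(block.sequence, start=1):
            rows.append(
                {
                    "block": b,
                    "block_role": block.role,
                    "trial": t,
                    "instruction": symbol,
                    "mapped_key": plan.key_mapping[symbol],
                }
            )
    return pd.DataFrame(rows)
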