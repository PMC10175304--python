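"""Linear ballistic accumulator (LBA) for four-alternative SRT responses.

One evidence accumulator per response key.  On each trial every accumulator
starts at ``k_i = log(P(z_i))`` — the log of the model's predicted
probability of symbol ``z_i`` — and rises linearly with a drift rate drawn
from a normal distribution (rejection-sampled to be positive).  The
instructed symbol's accumulator has mean drift ``v_instruction`` (default
0.5) and the other three share the remainder equally, so mean drifts sum
to 1.  The first accumulator to reach the threshold ``b`` gives the overt
response; the crossing time ``(b - k_i) / v_i`` is the model reaction time
(in unscaled model time units).

Predicted probabilities below the floor ``epsilon`` are raised to
``epsilon`` before the log, so starting evidences are bounded below.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .sequences import ALPHABET


class UnseenContextError(KeyError):
    """Raised when chunk statistics contain no transitions for a context."""


@dataclass
class LBAParams:
    """Accumulator configuration.

    v_instruction : mean drift of the instructed accumulator.
    sigma         : trial-to-trial drift standard deviation.
    b             : decision threshold (> 0).
    epsilon       : floor on predicted probabilities before the log.
    n_draws       : Monte-Carlo sample count for expectations.
    """

    v_instruction: float = 0.5
    sigma: float = 0.03
    b: float = 1.0
    epsilon: float = 0.01
    n_draws: int = 2000

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("decision threshold b must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError("epsilon must lie in (0, 1)")
        if not 0.0 < self.v_instruction < 1.0:
            raise ValueError("v_instruction must lie in (0, 1)")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")

    def drift_means(self, instruction_index: int, n: int = len(ALPHABET)) -> np.ndarray:
        """Mean drifts: v for the instructed accumulator, (1-v)/(n-1) others."""
        means = np.full(n, (1.0 - self.v_instruction) / (n - 1))
        means[instruction_index] = self.v_instruction
        return means


@dataclass
class StartEvidence:
    """Vector of starting evidences k_i = log(predicted probability)."""

    k: np.ndarray

    def __post_init__(self) -> None:
        k = np.asarray(self.k, dtype=float)
        if np.any(k > 1e-12):
            raise ValueError("starting evidences must satisfy k_i <= 0")
        self.k = k

    @classmethod
    def from_probs(cls, probs: Sequence[float], epsilon: float) -> "StartEvidence":
        p = np.clip(np.asarray(probs, dtype=float), epsilon, 1.0)
        return cls(np.log(p))

    @classmethod
    def uniform(cls, n: int = len(ALPHABET)) -> "StartEvidence":
        return cls(np.full(n, np.log(1.0 / n)))

    @classmethod
    def within_chunk(
        cls, predicted: str, epsilon: float, alphabet: Sequence[str] = ALPHABET
    ) -> "StartEvidence":
        """Within-chunk trial: k = 0 for the predicted item, log(eps) else."""
        probs = [1.0 if s == predicted else 0.0 for s in alphabet]
        return cls.from_probs(probs, epsilon)


@dataclass(frozen=True)
class TrialOutcome:
    response: str
    rt: float
    correct: bool


def sample_drifts(
    means: np.ndarray, sigma: float, rng: np.random.Generator, size: int
) -> np.ndarray:
    """Draw (size, n) positive drift rates ~ Normal(means, sigma).

    Negative draws are rejection-sampled, preserving the stated means in the
    regime where negativity is vanishingly rare (sigma = 0.03 against means
    >= 1/6).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    v = rng.normal(means, sigma, size=(size, means.size))
    bad = v <= 0
    while np.any(bad):
        v[bad] = rng.normal(np.broadcast_to(means, v.shape)[bad], sigma)
        bad = v <= 0
    return v


def simulate_lba_trial(
    start: StartEvidence,
    instruction: str,
    params: LBAParams,
    rng: np.random.Generator,
    alphabet: Sequence[str] = ALPHABET,
) -> TrialOutcome:
    """Race the four accumulators once and return the winning response."""
    alphabet = tuple(alphabet)
    if instruction not in alphabet:
        raise ValueError(f"instruction {instruction!r} not in alphabet")
    if start.k.size != len(alphabet):
        raise ValueError("start evidence must cover all symbols")
    means = params.drift_means(alphabet.index(instruction), len(alphabet))
    v = sample_drifts(means, params.sigma, rng, 1)[0]
    times = (params.b - start.k) / v
    winner = int(np.argmin(times))
    response = alphabet[winner]
    return TrialOutcome(response, float(times[winner]), response == instruction)


def _mc_min_rt_batch(
    k: np.ndarray,
    instr_idx: np.ndarray,
    params: LBAParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Monte-Carlo mean first-crossing time for a batch of (k, instruction).

    ``k`` has shape (m, n_acc); returns shape (m,).
    """
    k = np.atleast_2d(k)
    m, n_acc = k.shape
    others = (1.0 - params.v_instruction) / (n_acc - 1)
    means = np.full((m, n_acc), others)
    means[np.arange(m), instr_idx] = params.v_instruction
    v = rng.normal(means[:, None, :], params.sigma, size=(m, params.n_draws, n_acc))
    bad = v <= 0
    while np.any(bad):
        v[bad] = rng.normal(
            np.broadcast_to(means[:, None, :], v.shape)[bad], params.sigma
        )
        bad = v <= 0
    times = (params.b - k[:, None, :]) / v
    return times.min(axis=2).mean(axis=1)


def _mc_choice_probs_batch(
    k: np.ndarray,
    instr_idx: np.ndarray,
    params: LBAParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Monte-Carlo win probability of each accumulator, batched over rows."""
    k = np.atleast_2d(k)
    m, n_acc = k.shape
    others = (1.0 - params.v_instruction) / (n_acc - 1)
    means = np.full((m, n_acc), others)
    means[np.arange(m), instr_idx] = params.v_instruction
    v = rng.normal(means[:, None, :], params.sigma, size=(m, params.n_draws, n_acc))
    bad = v <= 0
    while np.any(bad):
        v[bad] = rng.normal(
            np.broadcast_to(means[:, None, :], v.shape)[bad], params.sigma
        )
        bad = v <= 0
    times = (params.b - k[:, None, :]) / v
    winners = times.argmin(axis=2)
    out = np.zeros((m, n_acc))
    for j in range(n_acc):
        out[:, j] = (winners == j).mean(axis=1)
    return out


def boundary_start_probs(
    context_chunk: str,
    stats,
    alphabet: Sequence[str] = ALPHABET,
) -> np.ndarray:
    """Next-element probabilities at a chunk boundary.

    For each symbol z, the summed chunk-transition probability of chunks
    initiating with z, given the previously parsed ``context_chunk``.
    """
    alphabet = tuple(alphabet)
    probs = np.zeros(len(alphabet))
    seen = False
    for (ci, cj), p in stats.transition.items():
        if ci == context_chunk:
            seen = True
            probs[alphabet.index(cj[0])] += p
    if not seen:
        raise UnseenContextError(context_chunk)
    return probs


def expected_rt_within(params: LBAParams, rng=None) -> float:
    """Monte-Carlo mean RT of a within-chunk key press.

    The instruction matches the predicted item, so its accumulator starts at
    k = log(1) = 0 and the others at log(epsilon).  The value does not
    depend on which chunk is being executed.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    start = StartEvidence.within_chunk(ALPHABET[0], params.epsilon)
    return float(_mc_min_rt_batch(start.k, np.array([0]), params, rng)[0])


def expected_rt_between(
    c_j: str,
    c_i: str,
    stats,
    params: LBAParams,
    rng=None,
) -> float:
    """Monte-Carlo mean RT of the first key press of chunk ``c_j`` after ``c_i``.

    Starting evidences come from the chunk-transition distribution out of
    ``c_i``, summed over chunks by their initial element and floored at
    epsilon.  Raises :class:`UnseenContextError` for a context with no
    observed transitions.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    probs = boundary_start_probs(c_i, stats)
    start = StartEvidence.from_probs(probs, params.epsilon)
    instr = ALPHABET.index(c_j[0])
    return float(_mc_min_rt_batch(start.k, np.array([instr]), params, rng)[0])
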