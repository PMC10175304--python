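"""Behavioral chunking measures computed from SRT trial logs.

A trial log is a pandas DataFrame with one row per key press and columns
``participant, group, block, block_role, trial, instruction, response, rt,
correct`` (rt in milliseconds, 1-based block/trial indices).

The measures mirror a standard SRT chunking battery:

* a 3-component Gaussian mixture splits each participant's RTs into
  within-chunk (fastest), between-chunk, and post-error slow-down
  (slowest) components, and trials are classified by maximum posterior;
* chunks are read off the classification by joining each between-chunk
  trial with the run of within-chunk trials that follows it, using the
  participant's *responses* (an erroneous press reflects the prediction);
* chunky boost: baseline-to-test signed Cohen's d speed-up of a bigram's
  second item, relative to control bigrams;
* chunkiness: baseline-to-test drop of the 1-D Wasserstein distance
  between a trigram's 2nd- and 3rd-item RT distributions, relative to
  control trigrams;
* chunk counts / increase, and the reuse probability of earlier chunks
  inside later size->=3 chunks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.mixture import GaussianMixture

from .sequences import ALPHABET, TransitionMatrix

TRIAL_COLUMNS: tuple[str, ...] = (
    "participant",
    "group",
    "block",
    "block_role",
    "trial",
    "instruction",
    "response",
    "rt",
    "correct",
)

RT_MAX_MS: float = 1000.0
MIN_TRIALS_FOR_MIXTURE: int = 30

LABEL_WITHIN = "within"
LABEL_BETWEEN = "between"
LABEL_SLOW = "slow"


# ---------------------------------------------------------------------------
# filtering and participant exclusion


def filter_trials(
    records: pd.DataFrame, rt_max: float = RT_MAX_MS
) -> tuple[pd.DataFrame, float]:
    """Drop trials slower than ``rt_max`` ms; return (kept, removed fraction)."""
    if len(records) == 0:
        return records, 0.0
    keep = records["rt"] <= rt_max
    return records[keep].copy(), float((~keep).mean())


def exclude_participants(
    records: pd.DataFrame, experiment: int
) -> tuple[list, pd.DataFrame]:
    """Apply the cohort exclusion rules; return (kept ids, report table).

    Experiment 1: drop participants whose baseline+test mean RT exceeds
    1000 ms or whose baseline+test accuracy is below 90% (strict
    inequalities; a participant exactly at a threshold is kept).
    Experiment 2: the same baseline/test criteria, plus training-block
    criteria by group — fast: mean training RT above 750 ms; accurate:
    training accuracy below 90%.
    """
    if experiment not in (1, 2):
        raise ValueError("experiment must be 1 or 2")
    rows = []
    for pid, sub in records.groupby("participant", sort=True):
        bt = sub[sub["block_role"].isin(["baseline", "test"])]
        tr = sub[sub["block_role"] == "training"]
        mean_rt = float(bt["rt"].mean())
        acc = float(bt["correct"].mean())
        reasons = []
        if mean_rt > RT_MAX_MS:
            reasons.append("baseline/test mean RT > 1000 ms")
        if acc < 0.90:
            reasons.append("baseline/test accuracy < 90%")
        if experiment == 2:
            group = str(sub["group"].iloc[0])
            if group == "fast" and float(tr["rt"].mean()) > 750.0:
                reasons.append("fast group: training mean RT > 750 ms")
            if group == "accurate" and float(tr["correct"].mean()) < 0.90:
                reasons.append("accurate group: training accuracy < 90%")
        rows.append(
            {
                "participant": pid,
                "mean_rt": mean_rt,
                "accuracy": acc,
                "excluded": bool(reasons),
                "reason": "; ".join(reasons),
            }
        )
    report = pd.DataFrame(rows)
    kept = report.loc[~report["excluded"], "participant"].tolist()
    return kept, report


# ---------------------------------------------------------------------------
# reaction-time mixture


@dataclass
class RTMixture:
    """3-component Gaussian RT mixture, components sorted by ascending mean.

    Semantics: component 0 = within-chunk (fastest), 1 = between-chunk,
    2 = post-error slow-down (slowest).
    """

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    variance_floored: bool = False

    def __post_init__(self) -> None:
        order = np.argsort(self.means)
        self.means = np.asarray(self.means, float)[order]
        self.sds = np.asarray(self.sds, float)[order]
        self.weights = np.asarray(self.weights, float)[order]
        if np.any(self.sds <= 0):
            raise ValueError("component standard deviations must be positive")
        if abs(self.weights.sum() - 1.0) > 1e-6:
            raise ValueError("component weights must sum to 1")

    def posterior(self, rts: Sequence[float]) -> np.ndarray:
        """Posterior responsibilities, shape (n, 3)."""
        rts = np.asarray(rts, float)[:, None]
        dens = self.weights * sps.norm.pdf(rts, self.means, self.sds)
        total = dens.sum(axis=1, keepdims=True)
        total[total == 0] = 1.0
        return dens / total


def fit_rt_mixture(
    rts: Sequence[float],
    seed: int = 0,
    n_components: int = 3,
    variance_floor: float = 25.0,
) -> RTMixture:
    """EM fit of a Gaussian mixture to one participant's reaction times.

    ``variance_floor`` (ms^2) regularises degenerate components instead of
    crashing on near-point clusters; the fit flags when it engaged.
    Requires at least 30 trials.
    """
    rts = np.asarray(rts, float)
    if rts.size < MIN_TRIALS_FOR_MIXTURE:
        raise ValueError(
            f"need at least {MIN_TRIALS_FOR_MIXTURE} trials, got {rts.size}"
        )
    gm = GaussianMixture(
        n_components=n_components,
        n_init=10,
        init_params="k-means++",
        reg_covar=variance_floor,
        random_state=seed,
    )
    gm.fit(rts[:, None])
    raw_vars = gm.covariances_.reshape(-1)
    floored = bool(np.any(raw_vars <= variance_floor * 1.5))
    return RTMixture(
        means=gm.means_.reshape(-1),
        sds=np.sqrt(raw_vars),
        weights=gm.weights_,
        variance_floored=floored,
    )


def classify_trials(records: pd.DataFrame, mixture: RTMixture) -> np.ndarray:
    """Label each trial within/between/slow by maximum posterior responsibility."""
    post = mixture.posterior(records["rt"].to_numpy())
    labels = np.array([LABEL_WITHIN, LABEL_BETWEEN, LABEL_SLOW])
    return labels[post.argmax(axis=1)]


# ---------------------------------------------------------------------------
# chunk extraction


@dataclass(frozen=True)
class ExtractedChunk:
    symbols: str
    participant: object
    block: int
    block_role: str
    start_trial: int
    end_trial: int

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass
class ChunkProfile:
    """Ordered, non-overlapping chunks extracted from one participant's log."""

    participant: object
    chunks: list[ExtractedChunk]

    def in_roles(self, roles: Iterable[str]) -> list[ExtractedChunk]:
        roles = set(roles)
        return [c for c in self.chunks if c.block_role in roles]


def extract_chunks(records: pd.DataFrame, labels: Sequence[str]) -> ChunkProfile:
    """Join between-chunk trials with following within-chunk runs into chunks.

    Each chunk is one between-labeled trial plus the maximal run of
    within-labeled trials that follows it, built from the participant's
    *responses*.  Slow-labeled (post-error) trials act as boundaries and
    join no chunk; chunks never span block boundaries.  A within-run with
    no preceding between trial (block start or after a slow trial) still
    forms a chunk.
    """
    if len(records) != len(labels):
        raise ValueError("labels must align with records")
    pids = records["participant"].unique()
    if len(pids) != 1:
        raise ValueError("extract_chunks expects a single participant's records")
    df = records.copy()
    df["_label"] = np.asarray(labels)
    chunks: list[ExtractedChunk] = []
    for (block, role), sub in df.groupby(["block", "block_role"], sort=True):
        sub = sub.sort_values("trial")
        cur_syms: list[str] = []
        cur_start = cur_end = None
        for _, row in sub.iterrows():
            lab = row["_label"]
            if lab == LABEL_SLOW:
                if cur_syms:
                    chunks.append(
                        ExtractedChunk(
                            "".join(cur_syms), pids[0], int(block), role,
                            cur_start, cur_end,
                        )
                    )
                cur_syms, cur_start = [], None
                continue
            if lab == LABEL_BETWEEN or not cur_syms:
                if cur_syms:
                    chunks.append(
                        ExtractedChunk(
                            "".join(cur_syms), pids[0], int(block), role,
                            cur_start, cur_end,
                        )
                    )
                cur_syms = [row["response"]]
                cur_start = int(row["trial"])
            else:
                cur_syms.append(row["response"])
            cur_end = int(row["trial"])
        if cur_syms:
            chunks.append(
                ExtractedChunk(
                    "".join(cur_syms), pids[0], int(block), role,
                    cur_start, cur_end,
                )
            )
    return ChunkProfile(pids[0], chunks)


def count_chunks(
    profile: ChunkProfile, target: str, roles: Iterable[str] | None = None
) -> int:
    """Number of extracted chunks exactly equal to ``target`` in given roles."""
    pool = profile.chunks if roles is None else profile.in_roles(roles)
    return sum(1 for c in pool if c.symbols == target)


def chunk_increase(profile: ChunkProfile, target: str) -> int:
    """Delta N = N_test - N_baseline for one chunk string."""
    return count_chunks(profile, target, ["test"]) - count_chunks(
        profile, target, ["baseline"]
    )


def chunk_reuse_probability(
    profile: ChunkProfile, window: int = 30, min_len: int = 3
) -> float:
    """Fraction of eligible chunks that contain an earlier chunk.

    Eligible chunks have size >= ``min_len`` and no immediate same-symbol
    repetition.  A chunk counts as reuse when any of the previous ``window``
    extracted chunks of size >= 2 occurs in it as a contiguous substring.
    Returns NaN when no chunk is eligible.
    """
    n_eligible = n_reused = 0
    history: list[str] = []
    for chunk in profile.chunks:
        s = chunk.symbols
        eligible = len(s) >= min_len and all(a != b for a, b in zip(s, s[1:]))
        if eligible:
            n_eligible += 1
            prev = history[-window:]
            if any(len(p) >= 2 and p in s for p in prev):
                n_reused += 1
        history.append(s)
    if n_eligible == 0:
        return float("nan")
    return n_reused / n_eligible


# ---------------------------------------------------------------------------
# participant pipeline


def participant_profile(
    records: pd.DataFrame, seed: int = 0, rt_max: float = RT_MAX_MS
) -> ChunkProfile:
    """Filter, fit the RT mixture, classify, and extract one participant's chunks."""
    kept, _ = filter_trials(records, rt_max)
    mixture = fit_rt_mixture(kept["rt"].to_numpy(), seed=seed)
    labels = classify_trials(kept, mixture)
    return extract_chunks(kept, labels)


def cohort_profiles(
    records: pd.DataFrame, seed: int = 0, rt_max: float = RT_MAX_MS
) -> dict:
    """Per-participant chunk profiles for a whole trial log."""
    return {
        pid: participant_profile(sub, seed=seed, rt_max=rt_max)
        for pid, sub in records.groupby("participant", sort=True)
    }


# ---------------------------------------------------------------------------
# measures


@dataclass
class MeasureResult:
    """A named behavioral measure: cohort value + per-participant values."""

    measure: str
    value: float
    per_participant: pd.Series
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = self.per_participant.rename("value").reset_index()
        df.columns = ["participant", "value"]
        df.insert(1, "measure", self.measure)
        return df


def manipulation_check(
    records: pd.DataFrame,
    targets: Sequence[str] = ("AB", "ABC"),
    roles: Iterable[str] = ("training",),
    seed: int = 0,
) -> dict[str, MeasureResult]:
    """N_target counts (e.g. N_AB, N_ABC) per participant over given roles."""
    profiles = cohort_profiles(records, seed=seed)
    out = {}
    for target in targets:
        vals = pd.Series(
            {
                pid: count_chunks(prof, target, roles)
                for pid, prof in profiles.items()
            },
            dtype=float,
        )
        out[target] = MeasureResult(
            f"N_{target}", float(vals.mean()), vals, {"roles": sorted(roles)}
        )
    return out


def signed_cohens_d(
    baseline_rts: Sequence[float], test_rts: Sequence[float]
) -> float:
    """(mean_baseline - mean_test) / pooled sd; positive = faster at test.

    Pooled sd is the classical sqrt(((n1-1)s1^2 + (n2-1)s2^2)/(n1+n2-2)).
    Returns 0 when the pooled sd vanishes (identical constant samples).
    """
    x = np.asarray(baseline_rts, float)
    y = np.asarray(test_rts, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    if n1 + n2 <= 2:
        pooled = 0.0
    else:
        pooled = np.sqrt(
            ((n1 - 1) * x.var(ddof=1 if n1 > 1 else 0) +
             (n2 - 1) * y.var(ddof=1 if n2 > 1 else 0)) / (n1 + n2 - 2)
        )
    diff = x.mean() - y.mean()
    if pooled == 0:
        return 0.0
    return float(diff / pooled)


def control_bigrams(bigram: str, scheme: str = "second-item") -> list[str]:
    """Control bigrams for a chunky-boost target.

    ``"second-item"`` keeps the second item and varies the first (for AB:
    BB, CB, DB); ``"first-item"`` keeps the first item and varies the
    second (for AB: AA, AC, AD).
    """
    a, b = bigram
    if scheme == "second-item":
        return [x + b for x in ALPHABET if x != a]
    if scheme == "first-item":
        return [a + y for y in ALPHABET if y != b]
    raise ValueError(f"unknown control scheme {scheme!r}")


def _second_item_rts(
    records: pd.DataFrame, bigram: str, roles: Iterable[str]
) -> np.ndarray:
    """RTs of the bigram's second item, conditioned on the first preceding it.

    Pairs are consecutive trials (t-1, t) of the same participant and block
    whose instructions spell the bigram.
    """
    roles = set(roles)
    sub = records[records["block_role"].isin(roles)].sort_values(
        ["participant", "block", "trial"]
    )
    out = []
    for (_, _), g in sub.groupby(["participant", "block"], sort=False):
        instr = g["instruction"].to_numpy()
        trial = g["trial"].to_numpy()
        rt = g["rt"].to_numpy()
        hit = (
            (instr[:-1] == bigram[0])
            & (instr[1:] == bigram[1])
            & (trial[1:] == trial[:-1] + 1)
        )
        out.append(rt[1:][hit])
    return np.concatenate(out) if out else np.array([])


def chunky_boost(
    records: pd.DataFrame,
    bigram: str,
    control_scheme: str = "second-item",
) -> MeasureResult:
    """Baseline-to-test Cohen's-d speed-up of a bigram minus its controls.

    For each participant, the signed d of the bigram's second-item RT
    (baseline vs test) minus the mean signed d over the control bigrams.
    Participants lacking occurrences in baseline or test contribute NaN and
    are ignored in the cohort mean.
    """
    controls = control_bigrams(bigram, control_scheme)
    vals = {}
    for pid, sub in records.groupby("participant", sort=True):
        def d_of(bg):
            base = _second_item_rts(sub, bg, ["baseline"])
            test = _second_item_rts(sub, bg, ["test"])
            if base.size == 0 or test.size == 0:
                return np.nan
            return signed_cohens_d(base, test)

        d_target = d_of(bigram)
        d_controls = [d_of(c) for c in controls]
        d_controls = [d for d in d_controls if not np.isnan(d)]
        if np.isnan(d_target) or not d_controls:
            vals[pid] = np.nan
        else:
            vals[pid] = d_target - float(np.mean(d_controls))
    per = pd.Series(vals, dtype=float)
    return MeasureResult(
        f"chunky_boost_{bigram}",
        float(per.mean(skipna=True)),
        per,
        {"controls": controls, "scheme": control_scheme},
    )


def control_trigrams(targets: Sequence[str]) -> list[str]:
    """All no-immediate-repetition symbol triples except the targets."""
    targets = set(targets)
    out = []
    for a in ALPHABET:
        for b in ALPHABET:
            for c in ALPHABET:
                t = a + b + c
                if a != b and b != c and t not in targets:
                    out.append(t)
    return out


def _trigram_rt_pair(
    records: pd.DataFrame, trigram: str, roles: Iterable[str]
) -> tuple[np.ndarray, np.ndarray]:
    """RTs of a trigram's 2nd and 3rd items, conditioned on the leading item."""
    roles = set(roles)
    sub = records[records["block_role"].isin(roles)].sort_values(
        ["participant", "block", "trial"]
    )
    rt2, rt3 = [], []
    for (_, _), g in sub.groupby(["participant", "block"], sort=False):
        instr = g["instruction"].to_numpy()
        trial = g["trial"].to_numpy()
        rt = g["rt"].to_numpy()
        if instr.size < 3:
            continue
        hit = (
            (instr[:-2] == trigram[0])
            & (instr[1:-1] == trigram[1])
            & (instr[2:] == trigram[2])
            & (trial[1:-1] == trial[:-2] + 1)
            & (trial[2:] == trial[:-2] + 2)
        )
        rt2.append(rt[1:-1][hit])
        rt3.append(rt[2:][hit])
    if rt2:
        return np.concatenate(rt2), np.concatenate(rt3)
    return np.array([]), np.array([])


def chunkiness(
    records: pd.DataFrame,
    trigram: str,
    control_trigrams_list: Sequence[str] | None = None,
) -> MeasureResult:
    """Baseline-to-test drop of within-trigram RT heterogeneity vs controls.

    Per participant: W = Wasserstein distance between the 2nd- and 3rd-item
    RT distributions of the trigram; Delta W = W_baseline - W_test; the
    measure is Delta W_trigram minus the mean Delta W over control trigrams.
    """
    controls = (
        list(control_trigrams_list)
        if control_trigrams_list is not None
        else control_trigrams([trigram])
    )
    vals = {}
    for pid, sub in records.groupby("participant", sort=True):
        def dW(tri):
            b2, b3 = _trigram_rt_pair(sub, tri, ["baseline"])
            t2, t3 = _trigram_rt_pair(sub, tri, ["test"])
            if min(b2.size, b3.size, t2.size, t3.size) == 0:
                return np.nan
            wb = sps.wasserstein_distance(b2, b3)
            wt = sps.wasserstein_distance(t2, t3)
            return wb - wt

        d_target = dW(trigram)
        d_controls = [dW(c) for c in controls]
        d_controls = [d for d in d_controls if not np.isnan(d)]
        if np.isnan(d_target) or not d_controls:
            vals[pid] = np.nan
        else:
            vals[pid] = d_target - float(np.mean(d_controls))
    per = pd.Series(vals, dtype=float)
    return MeasureResult(
        f"chunkiness_{trigram}",
        float(per.mean(skipna=True)),
        per,
        {"controls": controls},
    )


# ---------------------------------------------------------------------------
# regression design tables


def chunkify_matrix(
    base: TransitionMatrix, deterministic_bigrams: Sequence[str]
) -> TransitionMatrix:
    """Overwrite rows with deterministic transitions (e.g. C2 = TR + {AB}).

    For each bigram (x, y), row x becomes one-hot at y (row-stochasticity
    forces the other entries of that row to 0); remaining rows copy
    ``base``.
    """
    probs = np.array(base.probs, copy=True)
    for bg in deterministic_bigrams:
        i, j = base.index(bg[0]), base.index(bg[1])
        probs[i, :] = 0.0
        probs[i, j] = 1.0
    return TransitionMatrix(base.symbols, probs)


def build_rt_regressors(
    records: pd.DataFrame,
    named_matrices: Mapping[str, TransitionMatrix],
) -> pd.DataFrame:
    """Design table for log-RT regressions on test-block trials.

    One row per correct, non-initial test trial whose predecessor trial is
    present: log(rt), participant, group, and for each named matrix the
    entry (instruction(t-1) -> instruction(t)).  Mixed-effects fitting
    itself is left to a statistics backend (e.g. statsmodels MixedLM).
    """
    sub = records[records["block_role"] == "test"].sort_values(
        ["participant", "block", "trial"]
    )
    rows = []
    for (pid, block), g in sub.groupby(["participant", "block"], sort=False):
        instr = g["instruction"].to_numpy()
        trial = g["trial"].to_numpy()
        rt = g["rt"].to_numpy()
        correct = g["correct"].to_numpy()
        group = g["group"].iloc[0]
        for t in range(1, len(g)):
            if trial[t] != trial[t - 1] + 1 or not correct[t]:
                continue
            row = {
                "participant": pid,
                "group": group,
                "block": int(block),
                "trial": int(trial[t]),
                "log_rt": float(np.log(rt[t])),
            }
            for name, mat in named_matrices.items():
                row[name] = mat.entry(instr[t - 1], instr[t])
            rows.append(row)
    return pd.DataFrame(rows)
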