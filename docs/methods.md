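# Methods

This note documents the model, its parameters, the numerical choices made
where the design was genuinely open, and what the synthetic cohorts do and
do not establish.

## Task and sequence generators

A session has 10 blocks of 100 trials: two baseline blocks, six training
blocks, two test blocks.  Baseline and test blocks are always drawn from
the "illusory" first-order Markov matrix over {A, B, C, D}: A→B and C→D
have probability `p_high` = 0.9, B→C and D→A `p_mid` = 0.7.  Only those
four entries are structurally fixed; the residual row mass is split
uniformly over the remaining three successors by default (an explicit
assumption — a `no-repeat` rule that excludes self-transitions is also
available).  Training blocks depend on the condition:

| condition          | training generator                   | group, default w |
|--------------------|--------------------------------------|------------------|
| independent        | i.i.d. uniform singles               | independent, 0.2 |
| size2              | tokens {AB, C, D} at 1/3 each        | size2, 0.2       |
| size3              | tokens {ABC, D} at 1/2 each          | size3, 0.2       |
| illusory-fast      | illusory matrix                      | fast, 1.0        |
| illusory-accurate  | illusory matrix                      | accurate, 0.0    |

Chunk-inventory sequences concatenate whole i.i.d. tokens until the block
length is reached and hard-truncate, so a partial token may end a block
(block boundaries are not required to respect tokens).  Markov sequences
start from the stationary distribution unless an initial symbol is given.
One master seed per session is split deterministically per block
(`numpy.random.SeedSequence`).

## LBA response model

Four evidence accumulators, one per key.  Parameters (defaults):
`v_instruction` = 0.5 (mean drift of the instructed accumulator; the
other three share (1−v)/3 so means sum to 1), `sigma` = 0.03 (drift sd),
`b` = 1 (threshold), `epsilon` = 0.01 (floor on predicted probabilities
before the log), `n_draws` = 2000 (Monte-Carlo samples per expectation).
Drifts are rejection-sampled to be positive, which preserves the stated
means (at sigma = 0.03 against means ≥ 1/6 a negative draw essentially
never occurs).  Starting evidence is k_i = log of the predicted
probability of symbol i: within-chunk trials put k = 0 on the predicted
item and log ε elsewhere; chunk-boundary trials use the chunk-transition
mass out of the previous chunk, summed by initial element and floored at
ε.  Model times are unscaled; the millisecond mapping lives in the cohort
simulator.  No non-decision time offset is modelled.

## Loss and learning

L(C) = w·Rt + (1−w)·Err.  Rt is the expected reaction time **per key
press**: the transition-weighted expected chunk time
(rt_between + (|c|−1)·rt_within) divided by the transition-weighted
expected chunk length.  The per-press normalisation matters: weighting
chunk *tokens* equally instead makes the quantity increase when chunks
absorb presses (fewer, shorter-weighted tokens remain), which would stop
a speed-optimising learner from ever chunking; per-press weighting is
also the quantity a trial-averaged empirical RT estimates.  Err is the
expected error rate against the element-level generative matrix,
weighting each cell (z_i → z_j) by the stationary probability of z_i and
the transition probability, with the response distribution given by the
LBA under the representation's prediction after z_i.  Both expectations
are Monte-Carlo estimates.

Prediction after an element z follows a commitment rule: if any learned
chunk contains z at a non-final position, the model commits to the
highest-marginal such chunk and predicts its successor deterministically;
otherwise the trial is a boundary and the prediction is the next-element
distribution out of the highest-marginal chunk ending in z (exact ties
break lexicographically).  The same rule defines the *effective
transition matrix*, the element-level transitions the representation
implies: committed rows are one-hot, boundary rows are the chunk-level
next-element distribution; with primitives only this reduces exactly to
the empirical bigram matrix.

Learning starts from the four primitives (which are never removed, so
every sequence stays parseable), parses with greedy left-to-right longest
match, and for `n_iter` iterations (default 20) proposes concatenating
the chunk pair with the highest joint probability P_C(c_i)·P_C(c_j|c_i),
skipping candidates already in the set.  A proposal is accepted iff the
loss of the re-parsed sequence strictly decreases relative to the stored
current loss; the accepted-loss trajectory is therefore non-increasing by
construction.  Rejected candidates may be re-proposed later.  Statistics
are re-estimated from the full sequence after every accepted update.

Because the losses are Monte-Carlo estimates, a candidate whose true loss
change is exactly zero is accepted on roughly half of its proposals.
This is a feature, not a defect: on sequences whose structure is fully
deterministic (e.g. the size-3 inventory, where P(B|A) = 1 already at the
element level) chunking changes neither Rt nor Err in expectation, and
the resulting indifference is what lets the learner drift into acquiring
AB and then ABC there, while on independent uniform sequences the error
penalty of a spurious chunk (~0.19 at w = 0.2) exceeds the Monte-Carlo
noise (~1e-3) by two orders of magnitude and such chunks are reliably
rejected.  When no element-level generative matrix is supplied the
empirical bigram matrix of the training sequence is used for Err.

## Cohort simulator

`simulate_cohort` replays the learner online: each simulated participant
receives a full session plan; every trial is answered by one LBA race
whose starting evidence comes from the participant's current execution
state, and the learner runs a few propose/accept iterations (default 5)
on the instruction history after each block.  The executor commits to the
highest-marginal chunk starting with the current instruction and predicts
its remaining items on the following trials; a prediction that conflicts
with the shown instruction aborts the commitment, and the next trial is
re-planned as a boundary.  Boundary starting evidence uses the
representation's element-level prediction after the previous instruction
(the chunk-transition priors collapsed through commitment; identical to
the empirical bigram prior for a primitives-only representation) — using
the raw transition row of the previously completed chunk instead makes
rare long-chunk contexts so sparse that ε-floored ~1 s presses dominate
and invert the fast/accurate speed ordering.

Model time maps to milliseconds as rt_ms = 100·rt + 150 + Normal(0, 30),
chosen once so simulated RTs land in a plausible 200–1000 ms band; this
affine convention is configurable and carries no theoretical content.

What the synthetic cohorts emulate: condition-dependent chunk
acquisition, within- vs between-chunk RT separation, slow erroneous
presses after wrong predictions, and the fast/accurate group directions.
What they do not: non-decision time, motor noise correlated across keys,
fatigue and attention drift, post-error slowing as a distinct latent
process (slow presses arise only from low starting evidence), and
between-participant parameter variability.  Passing the pipeline on
simulated cohorts therefore shows the measures detect the model's own
signal, not that real participants behave this way.

## Analysis battery

Trials slower than 1000 ms are discarded before RT-based analyses (the
removed fraction is reported).  Participant exclusion: mean baseline+test
RT above 1000 ms or accuracy below 90% (strict inequalities; both
experiments), plus training-block rules in the instruction experiment
(fast group: mean RT above 750 ms; accurate group: accuracy below 90%).

Each participant's filtered RTs are fitted with a 3-component Gaussian
mixture over all blocks jointly (sklearn EM, k-means++ initialisation, 10
restarts, fixed seed, `reg_covar` = 25 ms² as a variance floor flagged
when it engages; at least 30 trials required).  Components sorted by mean
are labelled within-chunk / between-chunk / post-error slow-down, and
every trial gets the label with maximum posterior responsibility.  Chunks
are extracted by joining each between-labelled trial with the following
run of within-labelled trials, using the participant's **responses**
(an erroneous press reflects the prediction); slow-labelled trials join
no chunk and act as boundaries, as do block boundaries; an orphan
within-run (block start, or after a slow trial) still forms a chunk.

Measures:

* **N_target / ΔN** — counts of an extracted chunk string by block role;
  ΔN = N_test − N_baseline.
* **Chunky boost Δd** — signed Cohen's d (pooled-sd formula
  sqrt(((n1−1)s1²+(n2−1)s2²)/(n1+n2−2)); positive = faster at test) of a
  bigram's second-item RT, minus the mean over control bigrams.  Default
  controls share the second item (for AB: BB, CB, DB); a same-first-item
  scheme (AA, AC, AD) is selectable.
* **Chunkiness ΔW** — baseline-to-test drop of the 1-D Wasserstein
  distance between a trigram's 2nd- and 3rd-item RT distributions, minus
  the mean over control trigrams (all no-immediate-repeat triples by
  default).
* **Chunk reuse probability** — over extracted chunks of size ≥ 3 without
  immediate repetitions, the fraction containing one of the previous 30
  chunks (of size ≥ 2, so that reuse is not trivially true) as a
  contiguous substring; undefined (NaN) when no chunk is eligible.
* **Regression tables** — one row per correct, non-initial test trial:
  log RT plus the entry (instruction(t−1) → instruction(t)) of each
  supplied matrix (the generative TR, `chunkify_matrix` variants C2/C3
  with deterministic rows, or learned effective matrices).  Mixed-effects
  fitting itself is delegated to a statistics backend such as statsmodels
  MixedLM; this package guarantees the design table.

## Problem sizes and determinism

All randomness funnels through seeded `numpy.random.Generator`s; every
pipeline output is bit-reproducible from the master seed.  The standard
evaluation sizes are 1,000-trial sequences with 20 seeded runs for the
learner's regime checks, 120 runs of 600 trials for the
independent-sequence control, and 6–20 participants for cohort-level
direction checks — sizes at which the reported quantities are stable to
well within their acceptance bands while a full evaluation completes in
about a minute on one CPU.

## Known limitations

* The proposal step only concatenates existing chunks; chunks are never
  pruned, so late-stage sets at w = 1 contain rarely-used intermediates.
* Tie-indifference (above) makes the learned set on deterministic
  sub-structures depend on the Monte-Carlo seed; only parse
  *probabilities* averaged over runs are stable quantities there.
* LBA parameters are fixed, not fitted; hierarchical estimation from
  trial logs is out of scope.
* The effective matrix's commitment rule is winner-take-all; graded
  mixtures over chunks sharing an initial element are not represented.
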