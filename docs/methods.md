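# Methods

This note documents the models, procedures, and design choices behind
`sixarm`: what is simulated, how the agents learn, how they are fitted to
individual animals, what the statistics test, and what the synthetic data
generator does and does not emulate.

## The task

Six parallel arms (1–6) joined by a back corridor; a reward well at the end
of each arm; animals enter each session from a rest box. Behavior has two
phases.

**Exploration.** Any arm visit is rewarded unless it repeats the immediately
preceding arm. A session ends after a fixed number of rewards (default 25;
the default 15 sessions give 375 exploratory trials).

**Spatial alternation.** A *contingency* is an arm triple (outer, center,
outer), e.g. 234. Center visits are rewarded iff the preceding visited arm
was not the center. Outer visits are rewarded iff the preceding arm was the
center *and* the most recent outer arm visited before that center visit was
a different outer arm; at the start of a session, before either outer arm
has been visited, only the first condition applies. Visits to the other
three arms are never rewarded but still count as the "preceding arm". The
canonical check: under contingency 234 the sequence 3-4-3-2-3-4-3 earns
seven rewards.

Sessions end after a fixed number of center-arm visits plus one further
visit (10 per session on the first day of the first contingency, 20 on the
first day of later contingencies and the second day of the first, 40
otherwise; three sessions per day). Trials are *outbound* when they start
from the center arm and *inbound* otherwise (including trials starting from
non-contingency arms). The default contingency order is 234, 123, 345, 246,
234, 456.

Deliberate simplifications: the 30-minute wall-clock session limit is not
modeled (sessions end only by visit count), and "missed pokes" — approaches
that do not break the reward-well beam — are not simulated; every model
visit counts. Both are measurement-side artifacts of the physical rig, not
part of the reward logic. The population-level adaptive rule for switching
contingencies (advance when >80% of animals exceed 80% reward) is replaced
by fixed per-contingency budgets for determinism; budgets are fully
configurable, and when fitting an animal the schedule should carry that
animal's actual per-session budgets.

Whether the closing visit of a session could itself be a center visit is
unobservable in practice (after the limit-th center visit the next visit
cannot revisit the center); we end the session at the first post-limit visit
regardless of arm.

## The agents

All variants are actor-critic REINFORCE learners with a one-step working
memory: the state is s_t = (a_{t-1}, a_t), the previous and current
location. With six arms plus the rest box as a possible previous location
and a rest-box start state, there are 43 states: 36 arm pairs (the six
same-arm pairs are representable but unreachable, since revisits are
disallowed), 6 (rest, arm) pairs, and 1 (rest, rest) start state.

Action propensities are a sum of components:

    m(a, s_t) = b(a | a_t, a_{t-1})                        (M1)
              + b_i(a)                                     (+ M2)
              + b_n1 · 1[a = a_t ± 1] + b_n2 · 1[a = a_t ± 2]   (+ M3)

`b` is a 6×43 table of state-dependent transition propensities; `b_i` a
6-vector of location-independent arm preferences; `b_n1`, `b_n2` scalar
preferences for arms one/two positions from the current arm, applied in both
directions where the track allows and in one direction at the edges (the
M3noArm variant drops `b_i`). Propensities pass through a softmax with the
current arm's probability forced to zero; from the rest box all six arms are
available. Adding a constant to all propensities leaves the policy unchanged
(the implementation subtracts the maximum before exponentiation).

Learning uses the TD prediction error δ_t = r + γ·V(s_{t+1}) − V(s_t)
against a 43-entry state-value table V. Each component receives the
REINFORCE increment α·δ·(1[chosen] − p) — for the transition table only in
the visited state's column, for the arm preferences across all six arms, and
for the neighbor scalars using the *summed* probability mass of the eligible
neighbor arms (at the edges only the in-range arm contributes; on the
session-start step, with no current arm, the neighbor increment is zero).
V(s_t) receives α·δ. Every entry of every component also decays by (1 − ω)
on every trial, including entries of states not visited on that trial; with
α = 0 and ω > 0 everything decays geometrically to indifference. A single
(α, ω) pair governs all rules. Parameters: learning rate α ∈ [0, 1],
discount γ ∈ [0, 1), forgetting rate ω (fitting bounds [0.001, 0.015]).

The published update rule for the neighbor preferences is printed with the
arm-preference symbol on its left-hand side; we read it, per its surrounding
text, as the update of b_n1/b_n2 (i = 1, 2) rather than a second update of
b_i.

Choices about things the equations leave open:

- **Initialization.** All propensities and V start at zero — the symmetric,
  preference-free prior that is also the forgetting target. Exploration (or
  forced exploration, below) then shapes them.
- **Session boundaries.** The return to the rest box is not modeled. The
  last within-session update uses its own on-track successor state; no TD
  update bridges sessions. The next session starts in the (rest, rest)
  state.
- **Memory gating.** The previous arm always enters the memory slot; there
  is no learned gate.
- **Randomness.** Repeat k of an n-repeat run draws from a fresh generator
  seeded `seed + k` and consumes exactly one uniform per trial, so a batch
  run is bit-identical to running each repeat alone. The batch engine
  (`sixarm._engine`) vectorizes across repeats and stores propensities
  rescaled by a per-repeat decay accumulator so the uniform (1 − ω) decay
  costs O(1) per entry actually touched; it is tested for exact equality
  against the scalar reference operations. Degenerate parameter regions
  where the policy almost never samples the center arm are guarded by a
  session cap of 60 visits per required center visit (unreachable under any
  fitted or reward-maximizing setting).

**Teacher forcing.** To initialize an agent from an animal, its choices are
overridden by the animal's exploratory visit sequence while rewards,
prediction errors, and all updates proceed normally. Forcing consumes no
randomness.

## Fitting (approximate Bayesian computation)

The likelihood of an on-policy learner is intractable, so parameters are
chosen to match summary statistics: the agent is forced through the animal's
exploration, plays the alternation schedule freely (up to the last fitted
contingency), and the average over repeats (default 200; desk-scale runs use
50) of its inbound and outbound error indicator series is compared with the
animal's. Both sides are smoothed with a Gaussian of SD 2.25 trials (in each
trial type's own index; the SD is configurable), compared by RMS per
contingency, averaged over the fitted contingencies (default 2 and 3), and
the two trial types are summed with equal weight — so a constant offset d on
both curves scores exactly 2d. Model repeats are truncated or edge-padded to
the animal's per-type trial counts before averaging. A trial is counted as
an error iff it was unrewarded; the first visit of a session (from the rest
box) belongs to neither trial type.

Every objective evaluation reuses one simulation seed, making the objective
deterministic in the parameters. Optimization is simulated annealing —
geometric cooling from T0 = 1 by a factor 0.95 per step (default 400 steps;
desk-scale runs use 40–60), Gaussian proposals with width 10% of each bound
range, reflected at the bounds — restarted at least 4 times from random
in-bounds points; the restart with minimal error wins, and the annealing
configuration is recorded in the result. A batch wrapper repeats the whole
fit (default 20 times) and reports per-parameter medians and interquartile
ranges.

Reward-maximizing parameters (used to compare the best each variant can do)
come from a coarse grid (default 5 points per parameter, all evaluations
sharing a seed, exact ties resolving to the lowest grid index) followed by
one local refinement.

## Behavioral metrics

- **Exploratory preferences** (computed within sessions; transitions never
  cross session boundaries): per-arm visit probabilities and their maximum;
  the 6×6 transition matrix; neighbor frequency (transitions of ±1 arm);
  directional inertia (fraction of transitions continuing the previous
  transition's direction); and the two-away fraction among non-neighbor
  transitions.
- **Sweeps.** A sweep is a maximal monotone run of consecutive visits; at a
  direction change the pivot visit belongs to the run it terminates. Span is
  the number of arms covered (|end − start| + 1), so 2-4-6 spans five arms
  in three visits. The large-sweep rate is the fraction of visits in runs
  spanning more than three arms.
- **Direction alternation.** Each trial is labeled continue/reverse against
  the previous transition's direction; an alternation event is a flip of
  that label between consecutive trials. All contingencies' correct
  sequences alternate perfectly, which is the higher-order structure this
  metric captures.
- **Performance curves.** Reward probability smoothed with a Gaussian of SD
  10 visits, within contingency blocks only; inbound/outbound error
  likelihoods smoothed in their own trial index (SD 10 for display curves,
  2.25 for fitting) and linearly interpolated onto the visit axis;
  trials-to-criterion is the first visit at which the smoothed reward
  probability exceeds 0.75 (a curve that never crosses is censored at its
  final trial + 1 wherever a number is needed). All smoothing uses a
  truncated (±4 SD) kernel renormalized at the series edges, so smoothed
  values are convex combinations of the inputs and rates stay in [0, 1].

## Statistics

- **Per-animal Monte-Carlo nulls** for the three exploratory preferences,
  each conditioning on more of the animal's own behavior: uniform arm choice
  (for the maximum arm probability), iid draws from the animal's own arm
  probabilities (for neighbor frequency), and first-order Markov chains with
  the animal's own transition matrix (for inertia). p = fraction of null
  draws ≥ observed, floored at 1/n_draws (10⁻⁴ at the default 10,000
  draws). The three tests share a Bonferroni level of 0.05/3.
- **Population randomness test.** With per-animal evidence
  Φ_i = p(data | random), each Monte-Carlo sample classifies every animal
  independently as random with probability Φ_i (the natural reading of the
  mixture; documented as a choice) and contributes the fair-binomial lower
  tail P(Binom(N, ½) ≤ m) for the number m classified random; the p-value is
  the sample average. Note the tail is accumulated over the *random* count m
  — summing over the non-random count, as the printed formula literally
  suggests, would give p → 1 rather than p → 2^−N when every animal shows
  strong preferences, contradicting the reported values. An exact version
  (Poisson-binomial DP) serves as the oracle for N ≤ 12 and beyond.
- **Paired permutation test**: sign flips of paired differences, statistic
  the mean difference, add-one smoothing (floor 1/(n_perms + 1)),
  one- or two-tailed.
- **Crossing permutation test** between two models' repeats: the statistic
  Δd is the difference of the models' mean-curve 75%-crossing delays
  relative to the animals' curve, averaged over contingencies (default 2–5);
  repeat labels are permuted jointly across contingencies. Because Gaussian
  smoothing is linear, per-repeat curves are smoothed once and group means
  assembled from them.
- **Rank-order variance explained**: squared Pearson correlation of the two
  rank vectors (average ranks on ties) — 1.0 for identical *or* exactly
  reversed orderings.
- **Median split**: split at the median score (middle animal to the low
  group when odd), Wilcoxon rank-sum test on the outcomes. The published
  "two-tailed paired rank sum test" phrase mixes the names of the paired
  signed-rank and unpaired rank-sum tests; the unpaired rank-sum is used
  where groups are compared, and the paired permutation test where pairs
  are.

## The synthetic cohort

`sixarm.synth` generates rats whose exploration follows a kernel with the
statistical structure the analyses assume: softmax over
log-weights + neighbor bias (±1 transitions) + inertia bias (transitions
continuing the previous direction; at the edges no continuing move exists,
so the bias simply has nothing to act on), immediate revisits excluded.
Alternation behavior is one stochastic realization of an M3 agent with known
(α, γ, ω), initialized by forcing through the rat's own exploration — the
same procedure used on real animals, so recovery experiments are honest.
The default cohort draws heterogeneous weights (Dirichlet), biases, and
in-bounds parameters for 24 rats over the six-contingency schedule; all
counts are configuration, and the tests use smaller cohorts.

What the generator does *not* emulate: missed pokes, wall-clock limits,
session-to-session drift, satiety or motivation effects, sex differences,
and any generalization of task structure (the generator is exactly M3, so
analyses that detect deviations from M3 in real animals will find none in
synthetic ones). Passing tests therefore validate the machinery and the
internal consistency of the method — not claims about real rats.

## Problem sizes

Desk-scale runs (test suite and the acceptance script) use: 10-rat cohorts,
2 days per contingency, 50-repeat fitting objectives with 40 annealing steps
and 4 restarts, 20-repeat grid evaluations with 100-repeat final curves, and
10,000-draw Monte-Carlo nulls. These sizes keep a full run in minutes on one
CPU while leaving every qualitative result (recovery of α, the M3 < M2 < M1
learning-speed ordering, test calibration) stable; all of them are
parameters, and study-scale values (24 rats, 200 repeats, 400 annealing
steps) are the documented defaults of the corresponding functions.
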