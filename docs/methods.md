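# Methods

## Overview

`sensemaker` simulates six geospatial probability-estimation tasks and runs
two solvers on them side by side: an instance-based cognitive agent whose
every judgment is a *blended retrieval* from declarative memory, and a
normative Bayesian reference. Biases are read off the gap between the two —
an agent less certain than the reference on the same evidence is *anchoring*
(under-adjustment); more certain is *confirmation*. Nothing in the agent
encodes a bias directly: the directions emerge from the memory kernel, the
task statistics, and the strategies that connect them.

## The memory kernel

A chunk `i` has activation

```
A_i = B_i + S_i + P_i + eps_i
```

* `B_i = ln(n_i)` — base level from the number of presentations. The decay
  and constant-offset terms of the general base-level law are disabled
  (`d = 0`, `beta = 0`), which is the only reading that keeps the formula
  defined without inventing a decay value; frequency effects remain, recency
  effects do not.
* `S_i` — spreading activation `sum W_kj (S - ln fan)`, with maximum
  associative strength `S = 4`. Implemented but off by default: the
  integrated agent never sets source weights.
* `P_i` — partial matching: mismatch scale `P = 2` times the summed slot
  similarities, each similarity in `[-1, 0]` (0 = identical).
* `eps_i` — transient logistic noise with scale `s = 0.25`; `s` doubles as
  the Boltzmann temperature of retrieval. The optional permanent noise
  component is omitted.

Retrieval samples chunk `i` with probability `exp(A_i/s) / sum exp(A_j/s)`.
Blended retrieval returns the compromise value `v` minimizing
`sum_i P_i * dissim(v, v_i)^2`, where `dissim = -similarity`. Under the
linear similarity this objective is quadratic and the optimum is the
retrieval-probability-weighted mean; the implementation searches a candidate
grid (step 0.01 on probability-valued slots) unioned with the stored values,
breaking exact ties toward the smallest candidate, so runs are reproducible
bit for bit at a fixed seed.

Two similarity regimes are available for probability magnitudes:

* linear: `-|a - b|` over the unit domain;
* ratio: `-(1 - min/max)`, magnitude-sensitive, so values near zero become
  sharply dissimilar (0.01 vs 0.02 mismatches at 0.5 where the linear
  mismatch is 0.01); the 0/0 case is a perfect match.

## Task environment

Stimuli live on a continuous 100 x 100 grid. Events are drawn from an
isotropic Gaussian around each category's centroid (rejection-resampled into
the grid) and, on road tasks, snapped to the nearest road point. Category
parameters default to dispersions uniform in [5, 15] grid units and
frequencies drawn from {1, 2}, reproducing the frequency/distance trade-off
qualitatively; all are configurable. On the first trial every category is
guaranteed at least one event (otherwise no centroid could be formed).

Road networks are perturbed grids: horizontal and vertical polylines with
jittered waypoints, parsed into an intersection graph (shapely geometry,
networkx graph). A disconnected draw is regenerated internally. The
feature-layer tasks regenerate the network and the four centroids each
trial.

Feature outcomes are sampled generatively with the odds implied by the
likelihood rules: government buildings at 4:1 under categories A/B (so
P(government | A or B) = 0.8), dense traffic at 4:1 under A/C, the probe's
region matching the true category with probability 2/5, and signal chatter
at `P(chatter | inspected = truth) = 0.7` against
`P(chatter | inspected != truth) = 0.1` — the unique pair that makes the
printed 7 (chatter) and 1/3 (silence) likelihood ratios exactly
Bayes-consistent. On the fixed-order five-layer task the inspected SIGINT
category is chosen uniformly at random by the environment.

Schedules: Task 1 — two categories, 10 trials of 9 labeled events plus a
probe (100 events on display by the end); Tasks 2–3 — four categories, 5
trials of 19 events plus a probe; Task 3 on one road network shared by all
trials; Tasks 4–6 — 10 trials each on fresh networks, with 1 (SOCINT), 4
(all layers, random order) and 3 (agent-chosen) feature updates per trial.

## Agent strategies

**Centroids.** The location estimate of a category is the blend of its event
chunks (mismatch between locations is the linear difference scaled by the
display size, `2|d1 - d2| / 100`; the 2-D blend is separable and done per
coordinate with shared retrieval probabilities). The reported centroid then
blends the trial's raw estimate with all previously stored centroid
estimates — a centroid-of-centroids. Each trial stores exactly one centroid
chunk per category, so later probability judgments carry no base-rate
information (base-rate neglect by construction), and the estimate lags
drifting evidence (anchoring in learning).

**Probabilities.** Tasks 1–3 likelihoods are Gaussian in the distance from
the estimated centroid with the estimated dispersion and *no frequency
term*. Every self-generated probability is reported through the adjustment
memory (below) with the identity factor; the blend's regression toward the
local consensus compresses extreme values and flattens the reported
distribution relative to the normative one.

**Probability adjustment.** Memory is seeded with (prior, factor, posterior)
triplets on a prior grid of step 0.05 and factors {1/7, 1/4, 1/3, 1/2, 1, 2,
3, 4, 7} (the rule factors, their inverses and identity), posterior
`p f / (p f + 1 - p)`. An adjustment is a blended retrieval cueing the prior
(partial match, penalty `2 |M_k - M_j|`) and the factor (exact match). An
unseeded factor falls back to the closed form (logged configuration
constant). Updates follow the positive-only strategy: only categories named
by the rule are re-estimated; the rest keep their prior and a single
renormalization — mirroring the response interface — closes the books. The
full-Bayes strategy (exact multiplication on all categories) is available
for reference.

**Resource allocation.** Two blended retrievals over past episodes
(lead-probability, allocated-share, outcome): expected outcome from the
context, then the allocated share from context plus expected outcome. The
remainder is split among the other categories in proportion to their
probabilities, with largest-remainder rounding to integer percents summing
to 100. After feedback the actual episode plus up to two counterfactuals
(winner-take-all and pure probability matching) are stored, on forced-choice
trials as well (switchable). Forced-choice trials allocate 100% to the
leader, ties to the first category in canonical order.

A note on what this mechanism does and does not produce. The aggregate
signature — mean leader allocation strictly between probability matching
and winner-take-all, closer to matching — emerges robustly. A controlled
paired-seed manipulation of early feedback alone (flipping only the first
trial's outcome) does not systematically shift later allocations toward
matching: expectation-matching retrieval treats a zero-outcome all-in
episode as a *match* for a pessimistic expectation rather than a deterrent.
The tests therefore assert the aggregate band and the deterministic
consequences of the mechanism, not the paired-seed direction.

**Path planning and distance percepts.** The road network is parsed into
two-intersection segments. From the start the agent greedily appends the
adjoining segment scoring best on two equally weighted cues — segment
length and the remaining straight-line distance from the next intersection
to the probe — with Boltzmann choice noise, one-step backtracking at dead
ends, and a veridical shortest-path fallback (flagged) if the search
exhausts. Ties go to the lower segment id. Each traversed segment
contributes the power-law percept

```
D = (1.02 * (cow_walk / crow_flies) + crow_flies) ^ 0.82
```

implemented exactly as written despite its unit mixing (a dimensionless
curve-complexity ratio added to a distance inside the power); whether a
normalized variant was intended cannot be settled from the source, so the
printed form is used and flagged here. It underestimates long and curvy
roads, increasingly so with curvature.

**Layer selection.** Situation-action-outcome-utility episodes are stored
for every feature update (fixed-order tasks included). Utility is the
weighted distance `d = sum p_i (1 - p_i)` of the post-update distribution
(0 at certainty, 0.75 at a uniform four-way split; the post-update reading
of the outcome). Selection blends stored utilities per available layer,
matching on leader probability and a 0.25-bit-wide entropy bucket, and takes
the minimum-d layer. With no episode for a layer, a depth-one
difference-reduction look-ahead enumerates that layer's outcomes with
rule-implied predictive probabilities, perturbs the expected d with logistic
noise (simulation inaccuracy), and commits the simulated episode. SIGINT
always inspects the current leader — the confirmation-prone default. A
reinforcement-learned preference (reward = entropy drop in bits; no-gain
updates punished, floored at -0.05; delta rule, alpha = 0.2, the magnitudes
being this package's choice) breaks ties; remaining exact ties (utilities
equal to 9 decimals) fall to a canonical order SIGINT, IMINT, MOVINT, SOCINT,
ranked by best-single-outcome diagnosticity (7 > 4 = 4 > 2). From a uniform
prior the exact depth-one expectations tie SIGINT, IMINT and MOVINT at 0.66
(SOCINT 0.72), so this tie-break is what makes the uniform-prior first pick
SIGINT-on-leader.

## Normative reference

Location posteriors are `P(cat | probe) ∝ frequency * Gaussian(distance;
dispersion)`, Euclidean on open grids, shortest-path road distance (treated
as one-dimensional displacement) on road tasks — using the generative
parameters, which makes the reference exactly Bayes for the simulator's own
stimuli. Feature updates multiply by the exact rule weights (SOCINT 2 on the
region; IMINT/MOVINT 4 on the favored pair; SIGINT 7 or 1/3 on the inspected
category) and renormalize; layers are independent, so update order is
irrelevant.

## Metrics

Entropy is in bits throughout. Negentropy `N = 100 (E_max - E) / E_max` with
`E_max = 2` (four hypotheses) or 1 (two). `K(P||M)` floors zero
probabilities at 1e-6 before logs (the response interface only admits 1–99%
anyway); similarity `S = 100 * 2^-K`. RSR rescales a model's similarity
against the uniform-null similarity, floored at zero, with the `S_PR = 100`
singularity reported as NaN. RMR divides the frequency of the model's chosen
layer sequence by the modal sequence's frequency. S2 is the percentage
allocated to the ground-truth category. Bias labels compare negentropies at
tolerance 1e-9.

## Protocol and reproducibility

A subject is a fresh agent with a unique seed run through Tasks 1–6 in
order, memory persisting across tasks; the default experiment runs 45
subjects. Seeding uses a root `SeedSequence` spawning independent
per-subject, per-task streams for the environment and a separate stream for
the agent, so every stochastic draw is attributable and reruns at a fixed
seed are identical. The full 45-subject protocol takes about a minute on one
CPU; the averaged adjustment sweep (1000 runs per prior and regime, the
protocol under which the adjustment curves are defined) about one more.

## What the synthetic stimuli do and do not show

The generator reproduces the *structure* of the study's stimuli (Gaussian
event clouds, road networks, rule-governed feature outcomes, schedules), not
the unpublished stimulus sets themselves. Absolute performance numbers are
therefore stimulus-dependent and not comparable figure-for-figure; what the
tests assert are the structural signatures — trialwise anchoring in the
event tasks, layerwise anchoring in the fixed-order feature task, the
adjustment-curve shapes under both similarity regimes, and the
probability-matching band in free allocation. Human data are not modeled or
shipped, so human-fit statistics are out of scope.

## Known limitations

* No perceptual/motor timing, no production-rule engine: task procedures are
  the agent's control flow.
* Recency effects are absent from base-level activation by construction
  (decay disabled), so centroid recency weighting enters only through
  re-presentation counts.
* The greedy planner's cue weights (1, 1) are a free choice; only the
  qualitative preference for the nearest next intersection is constrained.
* The paired-seed early-feedback effect on allocation discussed above.
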