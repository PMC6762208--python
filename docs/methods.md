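# Methods

## Model

The learner maintains `L` latent components, each a linear cue→reward
association `V_l` with an effort matrix `B_l` (running cue second-moment
estimate) and a belief `p_l`; plus two pooled scalars, the error variance
`σ²` ("expected uncertainty") and the change statistic `q` ("unexpected
uncertainty").  A trial updates these in a fixed order: per-state errors
from pre-update strengths → belief filter → change-point test (spawning a
state if `q > ν` strictly) → value update → effort update → variance
update → any between-trial context event.  Every stage is deterministic;
the only randomness anywhere in the package is schedule construction,
and that only when a shuffled variant is explicitly requested.

Assumptions worth keeping in mind when interpreting simulations:

- Latent states are mutually exclusive alternatives following a
  sticky Markov chain (self-transition `1 − γ(L−1)/L`); beliefs are
  filtered *approximately*, with a standard-normal density of the
  standardized error as emission weight.  The filter is exact for the
  stated chain given the emission weights — the test suite checks
  equality with an independently coded forward recursion to 1e-12 — but
  the emission model itself is the agent's working assumption, not a
  property of the reward stream.
- The normal emission weight is used as printed, `φ(E/σ)` without a
  `1/σ` density factor.  The factor cancels in the belief normalization
  and in the change statistic's ratio `φ(0)/l₀`, so the printed form is
  self-consistent.
- Rewards are centered (±1/2) and cue vectors carry pairwise interaction
  features, so a zero strength means a 50-50 reward expectation and
  compounds can be discriminated from their elements.  Reported
  "associative strength" of a cue is the belief-weighted expected reward
  if the cue were presented alone; the `uncenter` flag shifts it by +1/2
  to the 0/1 scale used by the RW baseline.

## Parameters

| name | default | role |
|------|---------|------|
| `alpha0` | 0.05 | value learning rate; also the effort-matrix decay (dimensionless, per trial) |
| `beta0` | 0.05 | variance learning rate |
| `gamma` | 0.05 | latent-state transition probability mass; also the per-step belief corrosion during delays |
| `sigma0` | 0.5 | initial reward standard deviation (reward units) |
| `nu` | 0.2 | change-statistic threshold for recruiting a state (log-likelihood units) |
| `delta` | 0.6 | per-trial drift subtracted from the change statistic; sets the surprise level (≈ `(E/σ)²/2`) that accumulates evidence |
| `chi` | 5 | maximum rumination replays during a temporal gap |
| `max_states` | 15 | state cap; at the cap spawning is suppressed and the candidate statistic is kept |

The seven behavioural defaults are the fixed set used for every
simulated experiment; none is tuned per design.  The RW baseline uses a
constant rate of 0.15, no interaction features, uncentered 0/1 rewards,
and one always-on indicator cue per distinct spatial context.

## Numerical choices

- `B_l⁻¹c` is computed by a linear solve, never an explicit inverse, and
  `B_l` is re-symmetrized after each update to cancel roundoff.
- `σ²` is floored at 1e-8: under perfect prediction it would otherwise
  decay to zero and degenerate the belief filter.
- If the belief normalizer underflows (`l₀ < 1e-300`, i.e. every state's
  standardized error beyond ≈38), beliefs fall back to the Markov prior
  and a warning is logged.
- Effort matrices are positive definite in exact arithmetic for any
  `alpha0` in (0, 1) (each update is a convex combination with positive
  weight on a positive definite term), but for `alpha0` ≳ 0.7 the
  identity remnant of a belief-abandoned component decays below what
  double precision can resolve against the dominant rank-one term.  At
  the default 0.05 the property is comfortably verifiable and is fuzzed
  over hundreds of random schedules.
- A state spawned mid-trial has belief 0, so it receives no value update
  on its birth trial; its identity effort matrix does receive that
  trial's `(1 − alpha0)` decay, because spawning precedes the effort
  stage in the per-trial order.
- Rumination replays only the value update (errors recomputed each
  iteration; beliefs, effort, variance and `q` frozen), runs only for
  temporal shifts, and precedes the belief corrosion of the same event.

## Schedules

Each experiment is built programmatically as named conditions over a
shared cue universe, with per-stage trial counts that default to 20
repetitions of each trial type and can be overridden.  Alternation
(e.g. A+/A− partial reinforcement) is strict and deterministic so the
battery is exactly reproducible; a seeded shuffled variant exists for
robustness checks.  Two designs use non-default lengths, chosen where
the qualitative effect demands them and flat plateaus around the chosen
values were verified:

- **Wilson (1992)**: 5+5 repetitions in the first stage, 12+12 in the
  middle stage, then 20 light-alone trials.  The first stage is short
  because compound-only exposure drives the effort matrix toward rank
  one; after long exposure its inverse amplifies the first light-alone
  trial so strongly for *both* groups (a one-trial jump past asymptote)
  that the belief-driven group difference is swamped.  The middle stage
  is longer because that is where Group E learns the light-alone
  discrimination that later makes light-alone reinforcement surprising
  enough to recruit a new state — the mechanism that produces the
  Hall–Pearce-style associability advantage.
- **Memory modification**: 40 acquisition trials (≈87% of asymptote at
  `alpha0 = 0.05`), one retrieval trial, a delay of 1/5/100 steps, 20
  extinction trials, a 100-step delay, then test.  With weak acquisition
  the pooled σ stays so large that beliefs abandon the acquisition state
  within a couple of extinction trials in *every* delay condition and no
  reconsolidation window can appear.  The statistic is flat across
  extinction lengths 10–30 and acquisition 40–60.

The renewal design runs a same-context and a shifted-context condition;
its primary statistic (predictions on early reacquisition vs. early
acquisition trials) is taken as the minimum over the two conditions, so
a baseline that shows context-cue summation without rapid reacquisition
does not pass.  The context-shift supplement (shifted minus same on
early reacquisition) is reported alongside: note that the RW baseline
*does* pass this supplement — an always-on context cue genuinely carries
strength back into the acquisition context (ABA renewal by summation) —
while failing the rapid-return statistic that defines the battery row.

## What the simulations do and do not show

Schedules are idealized: indicator cues, strictly alternating partial
reinforcement, noise-free rewards, and integer "time steps" for delays.
Passing the battery shows the model reproduces the *direction* of each
group-level effect under these idealized designs with one fixed
parameter set — the standard used here for model comparison.  It does
not show effect *magnitudes* match any particular dataset, nor that the
parameters fit any individual; no fitting procedure is included.  The
Wilson and Rescorla (2000) statistics are sensitive to pretraining
length through the effort-matrix novelty gain (see above), and the
Rescorla (2000) pretraining simplifies the original compound-based
inhibitor training to A+/B− interleaving.

## Limitations

- Single scalar reward; no action selection or decision rule.
- Pooled (not per-state) variance, as in the model definition.
- No rule is defined for recruiting past the state cap beyond keeping
  the candidate change statistic; the cap is a memory bound, not theory.
- The battery's decision margin (0.01 on the ±1/2 reward scale) is a
  pragmatic threshold for "effect present", not a statistical test.
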