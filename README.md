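# lslearn — online latent-state associative learning

`lslearn` is a simulator for an online model of latent-state learning in
classical conditioning, written for computational cognitive-neuroscience
work on associative learning.  The agent entertains a growing set of
*latent states*, each holding its own Rescorla–Wagner-style linear
association between cue features and reward, and learns — trial by trial,
with memory that grows only in the number of states — which state is
active, how cues map to rewards within each state, and how uncertain it
should be.

## The model

On trial *t* the agent observes a cue vector **c**(t) (raw cues plus
pairwise interaction features) and a reward *R*(t) (coded ±1/2), and:

1. **Errors.** For each latent state *l*:
   *E*<sub>l</sub> = *R* − **c**′**V**<sub>l</sub>.
2. **Belief filtering** (approximate Bayesian / HMM forward step):
   *p*<sub>l</sub> ∝ ((1−γ)*p*<sub>l</sub> + γ/L) · φ(*E*<sub>l</sub>/σ),
   with φ the standard normal density and σ² the pooled error variance.
3. **Change-point detection** (Page-style CUSUM):
   *q* ← max(*q* + log(φ(0)/*l*₀) − δ, 0) where *l*₀ is the belief
   normalizer.  If *q* > ν a new state is recruited with strengths
   *R* **c**/(**c**′**c**) — it predicts the current reward exactly — and
   *q* resets to 0.
4. **Value learning.**
   **V**<sub>l</sub> ← **V**<sub>l</sub> + α₀ *p*<sub>l</sub>
   *B*<sub>l</sub><sup>−1</sup>**c** *E*<sub>l</sub>: associability is the
   belief times the inverse of that state's *effort matrix*
   *B*<sub>l</sub>, a running estimate of the cue second-moment matrix, so
   novel cue directions learn fast.
5. **Uncertainty.**  *B*<sub>l</sub> ← (1−α₀)*B*<sub>l</sub> +
   α₀ *p*<sub>l</sub>**cc**′ and σ² ← σ² + β₀(Σ<sub>l</sub>
   *p*<sub>l</sub>*E*<sub>l</sub>² − σ²).
6. **Context.**  Between trials, a temporal gap of ITI steps corrodes
   beliefs toward uniform by (1−γ)<sup>ITI−1</sup> after up to χ
   "rumination" replays of the last value update; a spatial/visual
   context change makes beliefs exactly uniform.

With one state and a single always-on cue this reduces exactly to the
Rescorla–Wagner model, which the package also implements as a baseline.

Defaults (fixed across every experiment): α₀ = β₀ = γ = 0.05, σ₀ = 0.5,
ν = 0.2, δ = 0.6, χ = 5, at most 15 states; RW uses α = 0.15.

## The experiment battery

`lslearn` ships programmatic builders for eleven classical conditioning
designs — blocking, overexpectation, conditioned inhibition, the Wilson
(1992) associability experiment, Rescorla (2000) experiments 1A/1B, two
partial-reinforcement-extinction designs, backwards blocking, renewal,
spontaneous recovery, and a Monfils–Schiller memory-modification design —
plus directional effect checks (a signed statistic per experiment, passed
when it exceeds a 0.01 margin on the reward scale).  The latent-state
learner reproduces all of them; the RW baseline reproduces exactly
blocking, overexpectation and conditioned inhibition.

## Worked example

```python
import lslearn as ls

exp = ls.build_schedule("blocking")
traj = ls.run_schedule(exp.conditions["main"], model="latent_state")
f = traj.frame
for t in (19, 39):
    row = f.iloc[t]
    print(f"trial {t+1:2d} (stage {int(row.stage)+1}): "
          f"V_A={row.strength_A:+.3f}  V_B={row.strength_B:+.3f}  "
          f"prediction={row.prediction:+.3f}")

report = ls.run_battery("latent_state")
print(f"latent_state: {len(report.passed_ids)}/{len(report.results)} effects reproduced")
res = report.result("blocking")
print(f"blocking statistic = {res.statistic:.3f} (margin {res.margin})")
```

prints

```
trial 20 (stage 1): V_A=+0.321  V_B=+0.000  prediction=+0.311
trial 40 (stage 2): V_A=+0.346  V_B=+0.072  prediction=+0.489
latent_state: 13/13 effects reproduced
blocking statistic = 0.275 (margin 0.01)
```

After 20 A+ trials cue A carries most of the (centered, ±1/2-scale)
associative strength; 20 AB+ compound trials later, B has gained only
0.07 — conditioning of A has *blocked* B, and the blocking statistic is
the A−B strength difference at the end of stage 2.

The same runs are available from a shell:

```bash
lslearn run --experiment blocking --out out/      # trajectory CSV per condition
lslearn battery --model latent_state --out report.json
lslearn params                                    # resolved configuration
```

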