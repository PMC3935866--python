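# Methods

## Model

The learner is a trial-based TD(λ) value estimator over a complete serial
compound: one binary feature per time step from CS onset (step 3) to the
end of the 10-step trial, so the feature vector has 8 components and
V(t) is just the summed weight of the feature active at t.  Two weight
populations share the features — excitatory (w⁺, clamped ≥ 0) and
inhibitory (w⁻, clamped ≤ 0) — and the net value is their sum.  The
prediction error uses the shifted-target convention

    δ(t) = r(t) + γ·V(t) − V(t−1),   V(t) = 0 before the CS,

which places the persistent CS response at the CS time step itself:
δ(cs) = γ·V(cs), and nothing earlier than the CS can learn to predict it
away.  Weight updates at step t use the eligibility trace accumulated
through t−1; the trace is then decayed by γλ and the current feature
added.  Two consequences follow from this ordering and are relied on
throughout:

* the CS-time δ meets an empty trace (trials are separated by long
  inter-trial intervals, so the trace is cleared at trial start) and can
  never self-reinforce;
* extinction is driven entirely by the negative omission-time errors,
  propagated backward through the trace, which erodes the value profile
  from the reward time toward the CS — late in extinction the CS-time
  error therefore decays slowly and the curves flatten.

### Update gating

Which errors each population sees is the one genuinely open architectural
choice, and it matters.  Three variants are implemented
(`ModelParams.update_rule`):

* **shared** (default): both populations are driven by every δ and the
  sign clamps do the gating.  During probabilistic acquisition, rewarded
  trials push w⁻ back up against its zero clamp, so inhibition stays
  silent and the net value converges to the programmed probability
  (asymptotic δ(CS) = p·γ^(reward−cs)).  During extinction every δ is
  negative, inhibition accumulates at rate β while the excitatory weights
  erode at α.
* **plus_both**: w⁺ sees every δ, w⁻ only negative δ.  Inhibition then
  accumulates during probabilistic acquisition itself and the learned
  value equilibrates below p (e.g. ≈ 0.17 at p = 0.25 instead of 0.25).
* **split**: each population sees only its own sign.  Extinction is then
  carried by β alone and, with the small β used here, essentially stalls.

The shared rule is the default because it is the only variant that
produces the full extinction-regime map (below): under plus_both the 25%
condition starts too close to the extinction criterion and always
extinguishes fastest, so the decreasing (PREE) regime never appears; under
split extinction does not complete at all.

### Arousal

Arousal A multiplies both learning rates.  It is pinned at 1 throughout
acquisition; at the first extinction trial it is set to the programmed
reward probability (the established reliability of reward, i.e. how
surprising its cessation is), and thereafter decays once per extinction
trial toward the magnitude of that trial's outcome-time prediction error:

    A(i+1) = η·A(i) + (1−η)·|δᵢ|

A larger decay factor η makes arousal more persistent.  Which δ of a trial
feeds the recursion is configurable (`arousal_source`): the outcome-time
error (default — the trial's informative surprise) or the largest |δ| in
the trial; the two differ only marginally in every sweep we ran.  Break
trials leave arousal untouched, and a reacquisition phase re-pins it at 1.

This produces the regime map: with arousal disabled, extinction time
simply grows with the amount of value to unlearn (increasing in p).  With
arousal, low-probability conditions extinguish with a proportionally small
learning rate; whether that is enough to make them the slowest depends on
how long the rate differences persist (η) and how much value was learned
(acquisition length).  At 30 acquisition trials the curve is inverted-U
for η ≥ 0.93; at 100 trials it becomes strictly decreasing (PREE) at
η = 0.99.

### Forgetting and spontaneous recovery

Forgetting happens only during the break: per break trial, w⁺ is scaled
by ψ⁺ = 0.999999 and w⁻ by ψ⁻ = 0.9, the trace is cleared, and no
prediction errors occur.  After a 20-trial break the inhibition has lost
a factor 0.9²⁰ ≈ 0.12 while the excitatory weights are intact to six
decimal places, so the CS response rebounds — spontaneous recovery — and
re-extinguishes quickly.  (The two decay factors are assigned this way —
near-1 for excitatory, 0.9 for inhibitory — because that assignment is
what makes break-time decay release inhibition; the reverse would erase
the association itself and no recovery would occur.)

### Drugs

Simulated dopaminergic manipulations scale the prediction error before it
is used for anything (weight updates, arousal, the extinction criterion):
reduction (dopamine activation) maps δ → δ − d·|δ|, shrinking positive
errors and deepening negative ones, so reward value is underestimated and
extinction hastens; enhancement (dopamine inactivation) is the mirror
image.  Dose 0 is exactly the identity (bit-for-bit identical
trajectories).  The transform is active during both acquisition and
extinction by default (`drug_window`), matching an injection given before
acquisition with extinction following immediately.

## Parameters

| symbol | name | default | meaning |
|---|---|---|---|
| α | `alpha` | 0.08 | excitatory learning rate |
| β | `beta` | 0.04 | inhibitory learning rate |
| λ | `lambda_trace` | 0.9 | eligibility-trace decay |
| γ | `gamma` | 1.0 | within-trial discount |
| ψ⁺ | `psi_plus` | 0.999999 | excitatory break decay |
| ψ⁻ | `psi_minus` | 0.9 | inhibitory break decay |
| η | `eta` | 0.97 | arousal decay factor |
| — | `trial_length` | 10 | steps per trial |
| — | `cs_time` | 3 | CS onset step |
| — | `reward_time` | 8 | reward step |
| — | `extinction_criterion` | 0.12 | threshold on δ(CS) |

γ deserves a note: the trial is short and value never has to span an
inter-trial interval, so no within-trial discounting (γ = 1) is the
default.  This makes the asymptotic CS response equal the reward
probability, which places the 25% condition's response (0.25) far enough
above the 0.12 criterion for a slow-extinction regime to exist at low p;
with γ = 0.98 the asymptote drops to ≈ 0.22 and the decreasing-PREE label
is no longer reached anywhere on the η grid.  The criterion is evaluated
on the drug-transformed δ, every extinction trial, strict inequality,
1-based count.

## Session generator

Acquisition schedules are exact-count shuffles, not i.i.d. Bernoulli
draws: a 20-trial block at probability p contains exactly 20p rewards in a
seeded pseudorandom order, mirroring behavioral sessions in which the
reward count was fixed by design.  Longer simulated acquisitions
concatenate independently shuffled 20-trial blocks (a remainder block of r
trials carries half-up-rounded r·p rewards).  Both behavioral designs are
available: trial-constant (20 trials; 5/10/15/20 rewards) and
reward-constant (20 rewards; 80/40/27/20 trials).  An optional
maximum-consecutive-omissions constraint can bound reward droughts (real
low-probability sessions delivered a pellet every few trials); it is off
by default and, notably, barely changes any headline result — bounding
gaps at 4 omissions shrinks the variance of the 25% condition's
trials-to-extinction but also removes the slow right tail, slightly
*weakening* the PREE margin.

What the generator does not emulate: pre-training (simulated agents start
with zero CS value, where real animals plausibly carried residual value
into acquisition), inter-trial-interval durations, satiety or motivational
drift, and the behavioral stopping rule (five consecutive no-approach
trials) — extinction is declared from the model's own prediction error
instead.  Passing tests therefore validate the model's internal logic and
regime structure, not quantitative agreement with any particular animal.

## Numerical and statistical choices

* Double precision throughout; the learning engine is fully
  deterministic — all randomness lives in the seeded session builders.
* Sweep cells average the same explicit seed list (common random numbers
  across η and dose axes); results are tidy per-seed DataFrames.
* Cells that do not reach the criterion within the 70-trial extinction
  phase are censored at 70 and flagged; any censoring in a curve forces
  the `flat_or_mixed` label.
* Curve classification uses a 0.5-trial tolerance on per-cell means:
  strictly-decreasing (PREE) and strictly-increasing require every
  pairwise step to clear it; inverted-U requires an interior maximum
  exceeding both endpoints by more than it.
* Problem sizes: figure-style sweeps use 20 seeds per cell; the
  regime-threshold script uses 800 per cell (5 η × 4 p grid, ≈ 3–5
  minutes on one core).

## Known limitations

* **The PREE margin is intrinsically narrow.**  At full convergence,
  trials-to-extinction scales like ln(p/0.12)/p, which falls by only a few
  percent from p = 0.25 to p = 0.5.  Measured at η = 0.99 with 100
  acquisition trials, the 25%-vs-50% margin is +0.53 ± 0.19 trials —
  real, but of the same size as the classification tolerance, so the
  PREE label at η = 0.99 can flip to `flat_or_mixed` for some seed
  populations.  The inverted-U threshold (η = 0.93 at 30 trials) is
  stable in every population we tested.
* **Simulated dose-response magnitudes are qualitative.**  Error
  reduction hastens extinction most strongly at low probabilities, and
  enhancement does the reverse (it also flattens/bends the
  100%-normalized curve as expected), but the absolute collapse of the
  25% condition under a 0.1 reduction dose is milder here (≈ 17 trials)
  than the few-trial extinction such a manipulation can produce when the
  learned 25% value sits closer to the criterion — which is exactly where
  the plus_both gating variant puts it.  No single gating variant we
  found reproduces both that collapse and the PREE regime; the default
  favors the regime map and the variant is exposed for users who want
  the opposite trade-off.
* The model has no representation of reaction times, motivation, or
  context; spontaneous recovery is purely a weight-decay phenomenon with
  a single fixed break length.
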