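# td-arousal

A temporal-difference simulator of how probabilistic rewards are
extinguished, for computational-neuroscience work on conditioning, dopamine
prediction errors, and the partial reinforcement extinction effect (PREE).

## The problem

When a cue (CS) that predicted food with some probability *p* stops being
rewarded, how fast does the conditioned response die out?  Behaviorally the
answer depends on training in a non-obvious way: after moderate training
the extinction-rate-vs-probability curve is **inverted-U shaped** (50%
rewards are the slowest to extinguish), while after extensive training it
becomes **monotonically decreasing** — the classic PREE, where rare rewards
are the hardest to give up.  A plain TD learner produces neither: its
extinction is always slower for higher probabilities, because they have
more value to unlearn.

This package implements a TD(λ) model that reconciles these regimes by
adding a slowly decaying **arousal** signal (a Pearce–Kaye–Hall-style
associability) that scales the learning rate during extinction, and a dual
excitatory/inhibitory weight architecture whose **break-only forgetting**
produces spontaneous recovery.

## The model

Each trial is 10 time steps; the CS arrives at step 3 and the reward
(magnitude 1) at step 8.  Stimuli use a complete serial compound: one
feature per post-CS time step.  Value is carried by two weight populations
over those features, excitatory **w⁺ ≥ 0** and inhibitory **w⁻ ≤ 0**, with
V(t) = (w⁺ + w⁻)·x(t).  Per time step,

    δ(t) = r(t) + γ·V(t) − V(t−1)                 (γ = 1 within the trial)
    w⁺ ← clamp₊( w⁺ + α·A·δ(t)·e ),   α = 0.08
    w⁻ ← clamp₋( w⁻ + β·A·δ(t)·e ),   β = 0.04
    e  ← γλ·e + x(t),                  λ = 0.9   (reset each trial)

Both populations are driven by every prediction error; the sign clamps do
the gating, so during acquisition rewarded trials push w⁻ back to zero and
the net value converges to the reward probability itself, while in
extinction w⁻ accumulates the learned inhibition.

Arousal *A* is pinned at 1 during acquisition.  At the first extinction
trial it is set to the programmed reward probability (how unexpected the
cessation of reward is), then decays per trial toward the magnitude of the
outcome-time prediction error:

    A ← η·A + (1−η)·|δ|,     η ∈ {0.91 … 0.99}

During a break no prediction errors occur; weights simply decay, the
inhibitory ones much faster (ψ⁻ = 0.9 per trial) than the excitatory ones
(ψ⁺ = 0.999999) — releasing the inhibition and producing spontaneous
recovery.  Extinction of a session is declared at the first trial whose
CS-time error satisfies |δ(CS)| < 0.12.

Simulated dopaminergic drugs act multiplicatively on the prediction error:
error *reduction* (dopamine activation) maps δ → δ − d·|δ|, *enhancement*
(dopamine inactivation) maps δ → δ + d·|δ|, where d is the dose.

## Worked example

Sweep the four standard reward probabilities at moderate training
(30 acquisition trials, η = 0.97), 20 schedule seeds per cell:

```python
from td_arousal import ModelParams, sweep

res = sweep(ModelParams(eta=0.97), n_acqs=(30,), etas=(0.97,),
            seeds=list(range(20)))
print(res.cell_means()[["probability", "trials_to_extinction",
                        "end_value"]].to_string(index=False))
print(res.shape_labels()[["eta", "n_acq", "shape_label"]]
      .to_string(index=False))
```

prints

```
 probability  trials_to_extinction  end_value
        0.25                 34.45   0.211512
        0.50                 37.00   0.401458
        0.75                 33.45   0.637172
        1.00                 28.00   0.818533
 eta  n_acq shape_label
0.97     30  inverted_U
```

`end_value` is δ(CS) on the last acquisition trial — the learned reward
value, close to the programmed probability.  Extinction is slowest at 50%
(37 trials) and faster at both ends: the inverted-U.  With 100 acquisition
trials and η = 0.99 the same sweep returns `decreasing_PREE` — rare rewards
extinguish slowest.  Disable arousal (`ModelParams(arousal_enabled=False)`)
and the label becomes `increasing` at every η.

The same experiment from the shell, plus a single-session trace:

```sh
td-arousal simulate --prob 0.5 --n-acq 30 --eta 0.97 --seed 0 --out demo
# {"probability": 0.5, "n_acq": 30, "seed": 0,
#  "trials_to_extinction": 36, "reached_criterion": true}
td-arousal reproduce-fig4 --out out4      # inverted-U sweep, fig4c.csv
td-arousal reproduce-fig5 --out out5      # full eta x training regime map
td-arousal reproduce-fig6 --out out6      # drug dose-response tables
```

Every command writes tidy CSVs and a `manifest.json` (config hash and the
full seed list) so runs are byte-for-byte repeatable.

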