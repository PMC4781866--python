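# attnalloc

Calculating the covert allocation of attention — a probability on a 0–1
scale — from nothing but correct-response counts in a cognitive two-armed
bandit task, together with a faithful simulator of that task and a
parameter-recovery analysis pipeline.

## The task and the model

Each trial briefly shows two rows of three digits (digits 1–7, row sums on
7–17). Exactly one row's sum appears among seven options on a following
probe screen; the top row holds the match with a fixed programmed
probability `PT` (the bottom row with `PB = 1 − PT`). Sessions have 132
trials — 22 cued (the subject is told which row matters) and 110 uncued —
split into halves of 66. A subject with limited capacity attends one row
per trial; call `p` the probability of attending the top row on uncued
trials and `g` the probability of answering correctly by guessing when the
attended row turns out not to be the matching one (chance: 1/7 ≈ 0.143).

Conditioning on which row held the match, the correct-response rates are
linear in the latent parameters:

```
PCT = p + (1 − p)·g          (top row held the match)
PCB = (1 − p) + p·g          (bottom row held the match)
```

Adding the equations eliminates `p`; substituting back gives closed-form
estimates from observed rates:

```
g = (PCT + PCB) − 1          p = (PCB − 1) / (PCT + PCB − 2)
```

Lapses of attention and arithmetic slips are handled by multiplying both
equations by an accuracy term `A`, estimated from cued trials (where errors
cannot reflect misallocation): `g = (PCT + PCB) − A` and
`p = (PCB − A) / (PCT + PCB − 2A)`. Sampling error can make these
"specious" (`p` outside [0, 1] or `g < 0`); the estimator then retries with
accuracy pooled over two sessions and finally under the idealised
assumptions `A = 1`, `g = 1/7`, recording the fallback rung it used.

The simulator reproduces the task's combinatorics exactly (balanced row
sums, probe screens that exclude the unmatched row's sum, half-session
cue scheduling) and drives subjects with fixed, probability-matching,
maximizing, or incremental-learning attention policies, a lapse rate, and
a two-path latency model in which correct guesses are slow.

## Worked example

Simulate one lapse-free subject who probability-matches (`p = 0.75`) in the
`PT = 0.75` condition for two sessions, then invert the tallies:

```python
from attnalloc import (
    ConditionDesign, SubjectPolicy, build_session_schedule,
    simulate_subject, tally_block, estimate_block, subject_rngs,
)

design = ConditionDesign.from_top(0.75)
policy = SubjectPolicy(kind="fixed", p0=0.75, lapse_rate=0.0)
rng = subject_rngs(42, 1)[0]
schedules = [build_session_schedule(rng, design, session_index=s) for s in (1, 2)]
records = simulate_subject(schedules, policy, rng)
est = estimate_block(tally_block(records))
print(f"uncued correct rates: PCT = {est.rates.pct:.3f}, PCB = {est.rates.pcb:.3f}")
print(f"cued accuracy A = {est.accuracy.pooled:.3f}")
print(f"p-hat = {est.solution.p:.3f}, g-hat = {est.solution.g:.3f} "
      f"({est.solution.variant}, {est.solution.validity})")
```

prints

```
uncued correct rates: PCT = 0.799, PCB = 0.214
cued accuracy A = 1.000
p-hat = 0.796, g-hat = 0.013 (linear, valid)
```

From 220 uncued trials the inversion recovers this subject's allocation to
within 0.05 of the true 0.75; the guess-rate estimate is noisy at the
single-subject level (its standard error here is ≈ 0.07). Averaging the
same estimate over a 50-subject cohort gives

```
cohort mean p-hat = 0.756 (true 0.75)
cohort mean g-hat = 0.166 (chance 1/7 = 0.143)
```

A command-line interface wraps the same pipeline: `attnalloc simulate`,
`attnalloc estimate`, `attnalloc analyze` and `attnalloc recover` (see
`attnalloc --help`). Every artifact embeds the seed and a config hash, and
identical seeds reproduce trial logs byte for byte.

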