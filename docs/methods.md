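# Methods

## The forward model

The task is a cognitive analogue of a two-armed bandit: two simultaneously
presented digit rows "pay off" (contain the probed sum) with fixed
complementary probabilities `PT` and `PB = 1 − PT`. The model assumes

1. attention is a limited capacity: exactly one row is processed per trial
   (top with probability `p` on uncued trials);
2. the unattended row leaves no usable trace, so when the attended row is
   not the matching one the subject guesses uniformly over the seven probe
   options (correct-guess rate `g`, chance value 1/7);
3. lapses of attention and addition errors occur at a rate `1 − A` that is
   independent of which row is attended, and are measured by cued-trial
   accuracy, where misallocation is impossible.

These give the conditional correct-response rates

```
PCT = A · (p + (1 − p)·g)
PCB = A · ((1 − p) + p·g)
```

and the overall rate `PT·PCT + PB·PCB`, which is maximized at `p = 1`
(`PT > PB`) or `p = 0` (`PT < PB`) for any `g < 1` — the maximizing
benchmark against which probability matching (`p = PT`) is compared.

## Inversion and its variants

Adding the two equations eliminates `p`. Two closed forms are provided
and every solution records which produced it:

- `equal_accuracy_paper` (default): `g = (PCT + PCB) − A`,
  `p = (PCB − A)/(PCT + PCB − 2A)` — the accuracy substitution applied
  literally to the error-free solutions. Under the multiplicative model
  above, this ĝ estimates `A·g`, not `g`; at `A ≈ 0.9` the attenuation is
  ≈ 0.014 on the chance value and vanishes at `A = 1`. The estimate of `p`
  is unaffected.
- `equal_accuracy_consistent`: `g = (PCT + PCB − A)/A`, identical `p` —
  the algebraically exact inverse of the multiplicative model.

Both collapse to the error-free linear model at `A = 1` (recorded as
variant `linear`). A `row_accuracy` variant solves the system with
row-specific cued accuracies `a_top`, `a_bottom`; under the multiplicative
error model this reduces, after normalising each rate by its accuracy, to
a linear solution `p = (1 − PCB/a_b)/(2 − PCT/a_t − PCB/a_b)`. A bounded
least-squares path solves the same system numerically and is the contract
of record for the row-specific case; when no solution exists in the unit
square the exact algebraic values are returned carrying a validity flag.

Validity classification: `specious_p` when `p ∉ [0, 1]`, `specious_g`
when `g ∉ [0, 1]`, `degenerate` when `PCT + PCB = 2A` leaves `p`
unidentifiable (both rates at ceiling relative to accuracy). A tolerance
of 1e-9 keeps floating-point round-off from flagging legal boundary
solutions. Specious values are flagged, never clipped.

## Estimation from trial logs and the fallback ladder

Rates come from a block's uncued tallies (conditional on matching row);
accuracy from cued tallies. Because cued trials are sparse (11 per
half-session, 22 per session), half-session estimates take their accuracy
term from the enclosing session, with the subject's pooled sessions as the
next rung. The ladder is: per-session accuracy → pooled-session accuracy →
idealised assumptions (`A = 1`, `g` fixed at 1/7, `p` solved from each
single-row equation and the two solutions averaged — the model does not
dictate which row's equation to prefer, and averaging is symmetric). Each
estimate records the terminal rung; a block that is specious even at the
last rung stays flagged rather than being dropped, so no estimate silently
disappears. Blocks with a zero denominator in either conditional rate are
marked degenerate, not imputed.

The specious phenomenon itself is a small-sample effect: when cued and
uncued accuracies diverge by sampling error and allocation is extreme, the
inverted `p` overshoots 1. Pooling the cued sample halves its standard
error and demonstrably reduces the specious rate (this is an acceptance
property of the package, checked on 500 simulated subjects at `p = 0.9`,
`A = 0.9`).

## The simulator

The generator reproduces the procedure's structure exactly:

- 132 trials/session (22 cued + 110 uncued), halves of 66 with a rest
  boundary after trial 66; cued top-cue counts 6/11 then 5/11 per half
  (0.55/0.45); uncued top-match counts are the nearest-integer realisation
  of `PT·55` per half with the residual carried to the sibling half so the
  session total is the nearest integer to `PT·110`; order is uniformly
  shuffled within halves.
- Row digits are uniform over ordered triples from 1–7 with the allocated
  sum and no three identical digits. The balanced-sum quota is enforced
  over all 264 rows of a session (264/11 = 24 appearances per sum) — the
  only scope on which the quota divides evenly. The two rows of a trial
  never share a sum.
- Probe screens list the matching sum and six distractors drawn without
  replacement from 7–17 excluding both rows' sums. Excluding the
  non-matching row's sum is essential: a wrong-row attender must never
  find their computed sum among the options, otherwise the uniform-guess
  rate of 1/7 that the inversion relies on would not hold.
- Subject policies: `fixed` (constant `p`), `matcher` (p tracks the
  running top-match frequency), `maximizer` (attends the row with the
  higher running match frequency; ties keep the current p), `learner`
  (linear-operator update `p ← (1−α)p + α·1{top matched}` with default
  α = 0.05, a stochastic-learning account of the matching-to-maximizing
  drift). Policies are exercise machinery, not claims about mechanism.
- Lapses occur at rate `1 − A` on every trial. The default `wrong_choice`
  mode resolves a lapse as an incorrect response, which makes cued
  accuracy equal `A` and multiplies the uncued equations by `A` exactly —
  the generative counterpart of the estimator's error model. A
  `random_guess` mode (lapse → uniform guess) is provided as an
  alternative hypothesis; under it the multiplied equations are only
  approximate.
- Latencies: two log-normal paths truncated at the 20 s response deadline,
  attend-path median 2500 ms and guess-path median 4000 ms (σ = 0.3).
  The ~1500 ms guess surcharge encodes the idea that a guesser first scans
  all seven options and fails to find the computed sum. The locations are
  plumbing with plausible magnitudes, not fitted values; analyses depend
  only on the ordering.
- Exposure calibration is simulated as a staircase against a logistic
  accuracy-vs-duration function: the coarse descending series (600, 400,
  300, 200, 150 ms in 4-trial blocks), then 16-trial blocks with the step
  halving at each reversal down to a 10 ms floor, returning the shortest
  duration that sustained ≥ 90% accuracy. The final fine step sizes are a
  design choice (halving to 10 ms).

RNG discipline: one root seed, per-subject `SeedSequence` spawns; identical
seeds give byte-identical trial logs.

## What the synthetic data do and do not emulate

The generator reproduces the task's combinatorial structure, the latent
(p, g, A) data-generating process, adaptive allocation policies, and the
latency dichotomy. It does not emulate: visual/perceptual processes (no
masking, acuity, or exposure-duration effects on uncued accuracy — the
calibration module is a separate, self-contained simulation), sequential
dependencies beyond the policies' own updates, subject-to-subject
parameter heterogeneity beyond the policy settings, or motivational
effects of payment (earnings are book-kept at $0.10 per correct answer but
feed back into no default policy). Passing recovery tests therefore shows
the estimator is consistent for data satisfying the model's assumptions;
it cannot show that human data satisfy them.

## Analysis pipeline

Half-session blocks (1A, 1B, 2A, 2B) are the unit of analysis; partial
blocks are flagged, never truncated. Condition-level mean allocations are
regressed on predictiveness by ordinary least squares (condition means,
not subject-level points, feed the fit; subject-level fits are available
by passing those points instead). Deviations from maximizing recode `p̂`
as `p̂` (PT < 0.5) or `1 − p̂` (PT > 0.5), square-root transformed to tame
the pile-up at zero; the 1:1 condition has no maximizing solution and is
excluded by construction. Latency summaries average correct responses only,
in three classes (cued, uncued-more-predictive, uncued-less-predictive);
in the 1:1 condition the "more predictive" row is the one that drew more
correct uncued responses over the subject's whole run, ties to top. Empty
classes are reported with n = 0, not zero-filled. Error spreads on
allocation points are across-subject standard errors.

`recovery_experiment` packages the validation loop: simulate cohorts under
a named policy, estimate every half-session block and the subject-pooled
counts, and report bias/RMSE of `p̂` (fixed-policy cohorts), the mean and
standard error of `ĝ`, specious fractions, fallback-rung usage, and
per-block allocation slopes.

## Problem sizes and numerical choices

Acceptance-level checks use 200 subjects × 2 sessions for parameter
recovery, 500 subjects for the specious-pooling property, 200 subjects per
condition for the probability-matching line (slope tolerance [0.95, 1.05],
intercept ±0.03), 100 per condition for learner block slopes (learning
rate 0.02, chosen so the matching-to-maximizing drift spans all four
blocks), and 30 for latency ordering — sizes at which binomial sampling
error is far smaller than the asserted tolerances. The independent oracle
for the inversion is a 2-D grid search (step 1e-3, locally refined below
1e-6) minimizing squared residuals; closed forms agree with it to 1e-6.
Round-trip identity at `A = 1` holds to 1e-12 away from the degenerate
boundary `g = 1` (where the denominator of `p` vanishes).

## Known limitations

- The row-specific inversion implemented here is the linear solution of
  the multiplicative error model (plus its numerical twin); a quadratic
  row-specific solution under a different error model is not implemented.
- No uncertainty intervals on `p̂` or `ĝ` are provided; variability is
  assessed across simulated replicates.
- Inferential statistics (ANOVA, t-tests) on human data are out of scope;
  the pipeline is descriptive and simulation-based.
- The `matcher`/`maximizer`/`learner` policies are illustrative generators
  of the qualitative allocation patterns, not fitted cognitive models.
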