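# Methods

## The psychometric model

Performance in the 3-AFC triplet task is modelled by a Weibull-family
sigmoid in pen units,

    Ψ(x) = λγ + (1 − λ)[1 − (1 − γ)·exp(−10^{β(x+T)})],   x = −pen,

with guess rate γ (the lower asymptote; 1/3 for triplets), lapse rate λ
(capping the upper asymptote at λγ + 1 − λ), slope β in inverse pen units
and location T. The stimulus axis is the *negated* pen number so that Ψ
increases with concentration and larger T means greater sensitivity, the
orientation in which thresholds are conventionally reported on this scale.
With the default shape (β = 3.5, γ = 1/3, λ = 0.01) the attainable range is
(0.3333, 0.9933) and the transition from near-ceiling to near-chance spans
roughly one pen — an extremely steep function, which has consequences
discussed below.

**Threshold anchoring.** `WeibullParams.threshold` can be *anchored*: with
`anchor_p=0.8` the stored threshold is literally the 80%-correct level (the
anchored and unanchored locations differ by the closed-form offset
log10(−ln((1−(p−λγ)/(1−λ))/(1−γ)))/β ≈ +0.0255 pens at p = 0.8). The QUEST
engine's candidate grid uses this convention, so "targeting the threshold at
80% correct" holds by construction rather than by post-hoc conversion.

## The QUEST engine

A grid posterior over anchored candidate thresholds: prior 𝒩(start_pen = 7,
sd = 20) truncated to [−23, 37] (start ± 1.5 sd) with step 0.01. The sd of
20 pen units makes the prior nearly flat (max/min density ratio ≈ 3 across
the grid); the grid deliberately extends far below pen 1 because real runs
produce posterior means below the physical range, which the cleaning step
later clamps. Each Bernoulli update multiplies by Ψ (or 1−Ψ) evaluated at
the *actually presented* pen, in log space with explicit renormalization.

**Trial placement** is configurable (`placement = "mode" | "mean" |
"median"`) and defaults to the posterior **mode**, the placement originally
recommended for this class of procedures. The choice was made empirically:
with the near-flat prior, the discrete 16-pen stimulus set and only 20
trials, placing at the posterior *mean* concentrates final estimates so
tightly that the nonlinearity of Ψ drags the mean achieved performance at
the estimate down to ≈ 0.74, well below the 80% design target, whereas mode
placement achieves ≈ 0.79–0.81 across seeds (1000-run simulations with the
observer equal to the assumed function, threshold at pen 8). Mode placement
also reproduces two qualitative signatures of real runs: rapid excursions to
pen 1 early in a run (a plateaued posterior after one or two misses has its
mode at the strong end), and occasional raw estimates below pen 1. The
final estimate is always the posterior mean, regardless of placement.

Discretization rules: proposals are rounded to the nearest pen with ties
toward the stronger (lower) pen — an arbitrary but fixed convention — and
clamped into [1, 16]. If the last two presented pens are equal and both
responses were correct, the next trial is forced one pen weaker (one pen
stronger after two misses), re-clamped; the override inspects the realized
history, including trials it itself forced.

**Known limitation.** With 20 trials and the flat prior, the estimate is
nearly unbiased only for mid-range thresholds: simulations show the cleaned
estimate biased by about −2 pens at a true (80%-level) threshold of 4 and
+0.6 at 14 (n = 300 runs each). Off-center observers are under-resolved in
20 trials; a longer run or an informative prior would be needed to remove
this.

## The staircase engine

Phase A (starting concentration): begin at pen 16 or 15; each miss moves two
pens stronger (clamped at pen 1, which is then simply re-presented); a hit
repeats the same pen, and a second consecutive hit fixes the starting
concentration. Phase B starts fresh at that pen: one pen stronger per miss,
one pen weaker after two consecutive hits *at the same pen* (the
hit-counter resets on every move). A reversal is logged at the pen where the
direction-changing response occurred (the extremum of the excursion, before
the move); the starting concentration is not counted as a reversal. The run
ends at the seventh reversal with threshold = mean of the last four reversal
pens; a demanded pen 17 ends the run with the sentinel value 16, and a
configurable cap (default 200 trials) aborts runs of responders that never
identify pen 1. Clamped non-moves at pen 1 do not log reversals of their
own; direction bookkeeping uses intended moves.

**Convergence level.** The one-up/two-down rule targets √(1/2) ≈ 70.71%
correct only in the small-step limit. Under the simulation conditions used
here (observer β = 1/pen, γ = 1/3, λ = 0, threshold at pen 8) the fixed
one-pen step is comparable to the psychometric spread, and the measured mean
of the observer's true probability correct at the raw threshold is ≈ 65–66%
(1000 runs). Two effects contribute: the discrete walk equilibrates a few
tenths of a pen on the weak side of the nominal 70.71% level (the classic
step-size deviation of transformed up-down rules), and the run-to-run spread
of the mean-of-four-reversals estimator (≈ 0.5–1 pen) interacts with the
concavity of Ψ near its shoulder (Jensen's inequality costs ≈ 2 points even
for an unbiased estimate). Both were verified to persist with 51 reversals
and with phase A skipped, so this is a property of the procedure at these
conditions, not of the implementation.

## Simulated observers and the synthetic cohort

`ObserverSpec` realizes Ψ as Bernoulli draws (one uniform per trial) or a
pure 1/3 guesser. The cohort generator emulates a test–retest study: true
thresholds drawn 𝒩(7, 3²) per participant (means and SDs chosen to match
typical healthy-sample summaries on this scale), retest truth = test truth
+ 1 pen systematic sensitivity gain + 𝒩(0, 2²) session drift, all truths
clipped to [1, 16]; observers use the assumed shape (β = 3.5, λ = 0.01) by
default; staircase starting pens alternate 16/15 across participants. All
randomness descends from one `SeedSequence`, so a spec with the same seed
reproduces the table exactly.

What the generator does *not* model: adaptation or habituation from repeated
strong-pen presentations, attention drift within a session, the dependence
of lapse rate on fatigue, or any relationship between threshold and slope.
Passing recovery tests therefore show that the pipeline is consistent with
its own generative assumptions — stationary observers with known Ψ — not
that real noses behave this way. Because both the truth and the procedures
are bounded by the physical pen range, recovered quantities shrink near the
ends of the scale (e.g. the mean recovered retest gain for QUEST runs about
half a pen hot at n = 200 because its estimate bias varies with the true
threshold; the staircase recovers ≈ 1.1 of the true +1).

## Agreement statistics

Differences are Test − Retest within a procedure and Staircase − QUEST
between procedures (session means); sample SDs use n − 1 throughout, and
cleaning always precedes statistics. RC = 1.96·SD of differences; limits of
agreement d̄ ± 1.96·SD. Exact-paired CIs for the limits use the noncentral-t
characterization of one-sided tolerance limits: the q-confidence bound for
d̄ + 1.96σ is d̄ + s·t′_q(n−1, nc = 1.96√n)/√n, giving equal-tailed
intervals; the lower limit's interval is its mirror image. The
normal-approximation half-width 1.96·s·√(3/n) serves as an independent
cross-check in the tests (agreement within 10% for n ≥ 30). For the
corrected two-method limits, σ_d² = s_d̄² + ½s_xw² + ½s_yw², where s_d̄² is
the variance of per-participant differences of session means and s_w² =
Σ(test−retest)²/(2n) within each method; their CIs use a delta-method
variance (each variance component contributes 2s⁴/df with df = n−1 for
s_d̄² and n for the within components, t_{n−1} multiplier) — a standard
first-order treatment; exact small-sample coverage is not claimed.

Degenerate inputs: zero-variance differences return point limits with CIs
omitted; the Wilcoxon statistic on all-zero differences is reported as NaN
with p = 1 (the signed-rank test is undefined there); constant inputs to
rank correlations raise a degenerate-data error.

The duration conversion uses 28.5 s per triplet trial (20 trials ↦ exactly
9.5 min). Published roundings of other trial counts differ by up to ~0.3
min from this constant; the exact 20-trial anchor was preferred.

## Problem sizes and tolerances

Simulation-based checks use 500–1000 runs per condition (SE of the reported
percent-correct means ≈ 0.3–1 point) and cohorts of 36–200 participants;
the brute-force Bayes oracle comparison runs on a coarse grid (step 0.5)
for 5 trials at 1e-10; posterior normalization is asserted at 1e-12; the
closed-form psychometric inverse round-trips at 1e-9 within ±1 pen of
threshold (outside that band the steep function saturates in double
precision).
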