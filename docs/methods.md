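# Methods

## Data model

The canonical unit is the long trial table: one row per (agent, condition,
item) with `correct ∈ {0,1}` and `confidence ∈ [0,100]`. Confidence is kept
real-valued — integer inputs are not rounded — because rating granularity is
an empirical property of the data, not of the format. Three answering
conditions are admitted by default, with guess rates 2C = 0.5, 4C = 0.25,
OP = 0 (open-ended answering has no practical guessing success); the chance
map is configurable for other designs. Missing responses are rejected rather
than imputed: every downstream quantity conditions on observed trials, and
silent imputation would bias the type-2 measures in either direction. The
pooled pseudo-condition `"All"` is materialized once in the agent summaries
and metric tables so that per-condition and pooled rows always come from the
same code path.

## Type-2 ROC estimator

The criterion set is the observed distinct confidence values in descending
order plus one sentinel above the maximum, with an inclusive `≥` criterion;
the area is the trapezoid over (FAR₂, HR₂). This nonparametric construction
equals the tie-aware rank statistic P(c⁺ > c⁻) + ½ P(c⁺ = c⁻) exactly, which
the test suite verifies against a brute-force pairwise oracle to 1e-12.
Ties therefore count one half: ratings cluster on round numbers, and any
other tie convention biases the estimate. An agent with no errors (or no
correct trials) in a block has no type-2 ROC; this is signalled as a
distinct *undefined* condition, not a validation failure, and propagates as
a missing value that group summaries exclude and count (`n_excluded`). That
exclusion is the auditable source of reduced error denominators when the
factorial machinery later drops agents with undefined cells.

## meta-J maximization

meta-J is the plug-in mutual information of the 2×2 (accuracy × binarized
confidence) frequency table in bits, with the 0·log 0 ≡ 0 convention.
Because the MI is constant between consecutive observed confidence values,
scanning the midpoints between consecutive distinct values plus one
candidate below the minimum and one above the maximum covers every distinct
binarization; the tests confirm equivalence with a dense-grid scan. Ties on
meta-J break toward the lowest threshold for reproducibility. The threshold
is optimized separately per (agent, condition) and re-optimized on the
pooled trials for the `"All"` row — pooling condition-specific thresholds is
nowhere defined, and re-optimization keeps `"All"` a genuine maximizer.
meta-J2r = meta-J / H(A) is reported as NaN when H(A) = 0 (all trials
correct or all incorrect). Log base 2 everywhere, so H(A) ≤ 1 bit and
meta-J2r ∈ [0, 1].

The plug-in MI has a positive small-sample bias of order
(levels−1)/(2 n ln 2); independence tests in the suite therefore allow a
small positive margin (≤ 0.01 bits at n = 10,000) rather than asserting
exact zero.

## Folded X-pattern

Item-level correct rates are computed across the agents of one group,
mapped to normalized discriminability d = (rate − chance)/(1 − chance), and
binned into four equal-probability bins by within-condition empirical
quantiles. Below-chance items keep their negative sign — folding happens
through the correct/incorrect split, not through |d|, and clipping would
hide below-chance items. Items exactly on a quantile edge fall to the lower
bin (deterministic under ties); if all items of a condition share one
discriminability the binning degenerates to a single flagged bin. Trials of
binned items are pooled and mean confidence is reported per correctness
branch; an empty branch is a missing cell, never zero.

## Association tests

Stimulus-level points average each item over a group's agents; agent-level
points average each agent over items. Agent-level aggregation defaults to
pooled (one point per agent) with a `per_condition` switch (one point per
agent per condition) because published study layouts use both readings; both
are exposed rather than asserting one. The correlation comparison uses the
two-sample Fisher r-to-z statistic
z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)) with a two-sided normal
p. The slope comparison fits `confidence ~ rate * group` by OLS; the
interaction coefficient is algebraically identical to the difference of the
two per-group slopes (verified to 1e-9), and its t-test has n − 4 residual
df. An exact fit (zero residual) is flagged degenerate instead of reporting
an unbounded t as if it were estimated. Two-sided p-values throughout.

## Mixed-design ANOVA

The factorial machinery supports one between-subjects factor crossed with
one or two within-subject factors, balanced within subjects (one value per
cell). It uses the multivariate-regression formulation: the subject ×
within-cell response matrix is regressed on a sum-coded between design
(Type III), and each effect is evaluated through an orthonormal contrast of
the within cells. Because the contrasts are orthonormal, the univariate
sums of squares equal the classical split-plot decomposition, which the
tests verify against a brute-force cell-means oracle to 1e-8 and against an
independent mixed-ANOVA implementation for the two-way design. The
three-way (group × correctness × condition) design is computed by the same
route; no delegation target covers it, hence the in-package implementation.

Greenhouse–Geisser ε is Box's ε̂ computed from the *pooled within-group*
(error) covariance projected through the effect's contrast — the same
choice R's car/afex make; implementations that use the grand covariance
differ in the third decimal. ε = 1 exactly for two-level factors. Mauchly's
test uses the standard chi-square approximation with the second-order Box
series correction. The correction policy is configurable: `auto` (correct
when Mauchly rejects at 0.05 — the trigger threshold is otherwise
unstated in study reports), `always`, or `never`.

Generalized eta squared is SS_effect / (SS_effect + ΣSS_error), where the
error sum runs over every error stratum (subjects within groups plus each
within-effect error); with orthonormal contrasts that sum is the trace of
the full residual cross-product matrix. This is the fully-manipulated-design
form of the Olejnik–Algina measure.

Subjects missing a within cell abort the fit by default (no imputation); the
pipeline passes `drop_incomplete=True`, which removes such subjects and
reports the count — reproducing how study-style reports end up with reduced
error denominators when some agents have undefined cells.

Post-hoc families are explicit comparison lists, by default one
simple-effects block per family (e.g. the three condition pairs within one
group), since the family size m is a modelling choice the caller must own;
adjusted p = min(1, m · raw p). Paired t-tests are used when the two cells
share their subjects, independent two-sample t otherwise.

## Synthetic cohort generator

The generator is a minimal signal-detection-flavoured mechanism that
produces the phenomena the analyses measure; it is not fitted to any real
dataset, and real data should be ingested directly instead of re-simulated.
Per trial: ability aᵢ ~ N(μ_a, σ_a), shared item difficulty bⱼ ~ N(0, σ_b),
effective discriminability d = max(0, aᵢ − bⱼ + ε₁) with trial noise
ε₁ ~ N(0, σ₁); P(correct) = g + (1−g)(1 − e^{−λd}) puts every condition on
its guess floor g; the metacognitive readout is r = d + ε₂ on correct trials
and r = d₀ − γd + ε₂ on errors (ε₂ ~ N(0, σ_meta)); confidence =
clip(B + S·r, 0, 100), rounded to integers by default to keep tie handling
exercised. The error branch builds the folded X by construction: γ > 0
makes error confidence fall with discriminability.

Defaults mirror the emulated study layout: two groups of 87 agents, 20 items
per condition. The `human_like` preset (μ_a = 1, σ_a = 0.5, B = 40, S = 30,
σ_meta = 0.3, γ = 0.5, d₀ = 0.5) yields graded, difficulty-tracking
confidence with correct rates around 0.75/0.73/0.52 for 2C/4C/OP —
realistic for general-knowledge questions. The `llm_like` preset (μ_a = 2.2,
σ_a = 0.3, B = 92, S = 4, σ_meta = 1.2, γ = 0.1) yields higher accuracy with
compressed ceiling confidence weakly coupled to correctness. `oracle` sets
σ_meta = 0 with γ = 0, d₀ = −1 so every error rating (B − S) sits strictly
below every correct rating (≥ B): per-agent AUROC is exactly 1 whenever
defined. `independent` draws confidence uniform on [0,100] ignoring the
readout: the zero-information control.

One root seed sequence is spawned into per-agent streams, so cohorts are
reproducible byte-for-byte and stable under partial regeneration.

What the generator does *not* emulate: item semantics and cultural content,
response-order effects, within-agent learning or fatigue, the particular
miscalibration geometry of any real model's confidence head. Passing tests
on synthetic cohorts therefore demonstrate that the estimators and tests
recover known structure, not that any empirical conclusion holds for a real
agent population.

## Problem sizes and numerics

The test suite exercises oracle equivalences on 200 random small instances
(n ≤ 20, heavy ties), analytic limits at n = 10,000, the metacognitive-noise
degradation grid {0, 1, 2, 4, 8} at 50 agents × 60 trials per point, and the
full default cohort (2 × 87 × 60 trials); these sizes give Monte-Carlo
error comfortably below the asserted margins while keeping the suite around
a minute. Statistical recovery tests average over replicates and bound the
replicate mean by its tightened standard error, rather than asserting a
single draw that would fail at its nominal rate. Floating-point
equivalences (trapezoid vs rank statistic, interaction vs slope difference)
are asserted at 1e-12/1e-9; entropy and MI use exact 0·log 0 handling, and
meta-J clips at 0 to absorb −1e-17-scale rounding.

## Known limitations

- The ANOVA requires balanced within-subject designs; unbalanced data need a
  mixed-effects model, which is out of scope.
- Huynh–Feldt correction and meta-d′/M-ratio model-based measures are not
  implemented; meta-J deliberately stays model-free.
- The plug-in MI bias is not corrected (no Miller–Madow/jackknife); at the
  60-trials-per-agent scale the bias is material for near-zero meta-J and
  should be kept in mind when comparing small blocks.
- Fisher-z comparisons assume independent samples; comparing correlations of
  the same agents across levels would need a dependent-correlation test.
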