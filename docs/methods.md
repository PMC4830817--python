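# Methods

This note records the models behind each simulator, the defaults and why
they were chosen, the numerical decisions, and what the synthetic data can
and cannot tell you about real intervention studies.

## Score model and test machinery

All simulators draw IQ-style scores: normal with mean 100 and SD 15 unless a
command overrides them. The inferential workhorse is the pooled-variance
Student two-sample *t*-test, two-sided at α = .05. Pooled rather than Welch
because every simulated design uses equal group sizes and equal SDs, where
the two coincide; `two_sample_t(..., welch=True)` exposes the unequal-
variance form for real data. Cohen's d always divides by the Bessel-corrected
pooled SD. One-sided tests halve the two-sided p (the direction observed).

Analytic power uses the noncentral *t* distribution with noncentrality
d·√(n₁n₂/(n₁+n₂)); at d = 0 it returns exactly α. Sample-size solving
returns the smallest integer n per group reaching the target power —
fractional n is never reported, so plugging the solved n back in slightly
overshoots the target, by design.

A documented discrepancy: the claim sometimes made for this design — that
with 20 per group, α = .05 and power .80 an effect of "about d = 0.5" is
detectable — does not survive the standard computation, which gives
d ≈ 0.909 (d = 0.5 needs 64 per group). The package implements the standard
computation and validates it against a Monte Carlo oracle; no attempt is
made to guess what assumptions would rescue the smaller figure.

## Randomness and reproducibility

`RandomStream` wraps numpy's PCG64. Replication i of any replicated
experiment uses `stream.child(i)`, a deterministic function of (root seed,
i) via `SeedSequence` spawn keys. Consequences: the same seed reproduces
byte-identical output, and enlarging a replication count extends — never
reshuffles — the earlier replications. The CLI derives everything from one
`--seed` per invocation.

## Sampling error (null-assignment experiments)

Each replication draws `total_n` i.i.d. scores and splits them in half;
because the draws are exchangeable, splitting the vector is distributionally
identical to random division, and the halves are two equal arms (odd totals
are rejected). Under this true null the rejection rate estimates α and the
running mean of p-values converges to .5. The demonstration is sometimes
shown with SD = 1; p-values under the null are scale-invariant, so the
package keeps the global default SD = 15 and exposes `sd` as a parameter.

Remedies: *rerandomization* redraws simple assignments until the absolute
standardized baseline difference is below a threshold, capped at 10,000
iterations (no cap is standard in the literature; 10,000 keeps a too-tight
threshold from hanging). *Blocking* ranks subjects by pretest score (random
tie-breaks), cuts the ranking into quantile blocks of near-equal size, and
assigns half of each block to each arm; odd-sized blocks alternate their
leftover via a running deficit so arm sizes never differ by more than one.

## Quantile splits and regression toward the mean

Pre/post scores are bivariate normal with identical margins N(mean, sd²) and
correlation ρ — "no test–retest effect" is modelled as equal means (zero
true change). The central parameter is ρ: the expected gain of a group
selected below the q-quantile at pretest is (ρ − 1)·sd·E[Z | Z ≤ z_q], with
the truncated-normal mean E[Z | Z ≤ z] = −φ(z)/Φ(z). The headline
demonstration does not state its ρ; ρ = 0 (independent redraws) reproduces
its pattern, is the worst case, and is the default — every command takes
`--rho`. Splits use the empirical type-7 quantile with "≤" membership, so
the low group at a quartile cut is at least a quarter of the sample.
Deviation-vs-gain curves use equal-count bins (stable bin SEs; equal-width
bins leave the extreme bins nearly empty).

## Correlated gain scores

Variable order is (training_pre, transfer_pre, training_post,
transfer_post). The analytic gain correlation is exact covariance algebra
and is the module's acceptance surface. The benchmark generative model —
pretests correlated at .92, posttests independent of everything, all SDs 15
— forces r_gain = .46; a widely circulated figure built from the same stated
constraints prints r = .10, which is unrecoverable without additional,
unstated structure, so the analytic value is what the package asserts.
Covariances are checked for symmetry and positive semi-definiteness
(eigenvalue tolerance 1e−8 relative); sampling uses the SVD path of numpy's
multivariate normal so PSD-boundary matrices (ρ = 1 blocks) remain valid.

The transfer test is the two-sample t on gain scores, algebraically
identical to the group × session interaction of a 2×2 repeated-measures
ANOVA; implementing it directly keeps the module dependency-free and makes
the equivalence explicit. Its report always includes per-group pre AND post
means, since gains alone hide baseline imbalance.

## Composite scores

Measurement j = construct + independent N(0, σ_Ej) error. Validity closed
forms are in the README. Estimators: row median; row mean (unit weights);
and a regression-weighted composite whose weights come from a one-factor
principal-axis fit (iterated communalities, SMC start) to the measurement
correlation matrix — the latent construct is never touched. Scores use the
regression (Thurstone) weights R⁻¹λ on standardized measurements, rescaled
to sum to one so composites stay on the score scale. For this error
structure the Thurstone weights are proportional to 1/σ_Ej² — the optimum —
so regression weighting ties unit weighting at equal error SDs (difference
below Monte Carlo noise) and beats it when error SDs differ; both facts are
tested against the closed forms. Collinear (singular) batteries raise an
error rather than returning unstable weights. No testing-effect term is
modelled: the battery represents three *different* assessments taken once.

## Multiple comparisons

FWER = 1 − (1−α)^k assumes independent comparisons; the dependent case is
noted but not modelled. Confusion counts are expected-value arithmetic by
default (exact, reproducing the worked example 800/200/450/8550, FDR 36%);
passing a stream switches to binomial draws for teaching. The
FDR-vs-prevalence curve draws power uniformly on [.50, 1] per replication
and computes FDR analytically, with a fixed-power .80 reference line. The
concrete FDR procedure is Benjamini–Hochberg (via statsmodels), chosen as
the canonical step-up method; Dunnett/Tukey/Scheffé are out of scope.

## Publication bias

Study pools draw n per group uniformly on the integers [5, 100] and true d
uniformly on [0, 2] ("uniform" is this package's reading; no sampling law is
standard). Publication = p < α. p-curves use bin width .01 by default (.05
reproduces the "rough" histogram). The sub-.05 bump uses an explicit
relocation model: a fraction of results in a window just above .05 is moved
uniformly into the bin immediately below .05 — one of several possible
p-hacking models, chosen because it conserves mass exactly and is
parameterized by a single interpretable fraction. Funnel dispersion
summaries use quantile bins of n; the strictly-decreasing-dispersion
property holds for fixed-d pools (as in the classic funnel picture) — in
mixed pools the spread of true effects dominates.

## Problem sizes and tolerances

Monte Carlo defaults follow the headline demonstrations: 1000 reps for
power curves and p-curve examples, 10,000 for null-assignment and histogram
uniformity checks, 10,000 subjects for the battery and pre/post samples.
Stochastic tests assert within 3 binomial or Fisher-z standard errors of the
analytic value; exact arithmetic is asserted to printed rounding. Property
tests (hypothesis) are derandomized. A few consistency tests use larger
samples (10⁵–2×10⁵ draws) where the quantity under test needs the extra
precision; all of it runs in seconds on one core.

## What the synthetic data does not capture

Everything here is normal, homoscedastic, and independently sampled:
no floor/ceiling effects, no attrition, no practice/testing effects, no
heteroscedasticity, no clustering, and no selection on covariates. Passing
tests therefore show that the *artifacts* behave as theory predicts under
clean conditions — real data can only make most of them worse. The biased
p-curve is a stylized selection model, not an estimate of any real
literature's hacking rate; and the gain-score benchmark fixes one particular
covariance structure among many that produce spurious correlation.
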