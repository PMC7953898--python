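# Methods

## Data model

A patient's toxicity profile is a vector Y ∈ {0, …, K}^d of CTCAE grades,
one entry per adverse event; K defaults to 5 and is a parameter everywhere.
All computation happens on the reduced frequency vector (RFV)
x = (x₁, …, x_K), x_k = #{i : Y_i = k}. Grade-0 entries are dropped when
forming the RFV; they contribute only to the profile length d, which is not
stored (samplers record their d in cohort metadata). Grades are clinical
1-based grades throughout: `grade_k` in a file means CTCAE grade k.

## The toxicity index

The original definition orders the grades decreasingly, Y₍₁₎ ≥ Y₍₂₎ ≥ …,
and sums Y₍ᵢ₎·wᵢ with weight wᵢ = Π_{j<i}(1 + Y₍ⱼ₎)^(−1): each further
event is discounted by everything at least as severe before it. This is
equivalent to the closed form on the RFV,

TI(x) = Σ_{k=2}^{K+1} k·g_k(x)·(1 − k^(−x_{k−1})),
g_k(x) = Π_{i=k}^{K} (1+i)^(−x_i),  g_{K+1} = 1,

and to the telescoped form TI = 2(1−g₁) + Σ_{k=2}^{K}(1−g_k) used by the
vectorized evaluator. The equivalence of all three code paths (plus a
nested single-expression K=5 specialization) is asserted in the test suite
on randomized inputs at 1e−12 relative tolerance. A truncated variant
τ_k accumulates the recursion τ_k − τ_{k−1} = (k+1)·g_{k+1}(x)·[1−(1+k)^(−x_k)]
from τ₀ = 0 and recovers TI at k = K.

Numerics: for total counts ≤ 50 the suffix products are computed directly
(exact for small integer counts); above that the products are accumulated
in log space to avoid underflow. Exact rational arithmetic is not used.

Key properties, all tested: a single grade-k event scores exactly k;
mx ≤ TI < mx+1 for nonzero RFVs; appending zero counts for higher grades
changes nothing; TI is strictly increasing w.r.t. the T-order (verified
exhaustively on the K=3, counts ≤ 4 grid), hence injective there, while mx
is nondecreasing only and avg is non-monotone (witnessed by the
(6,2)/(2,1) family of counterexamples).

## T-order and T-rank

x ≻ y iff at the largest index where the vectors differ, x's count is
larger — i.e. lexicographic order on grade-reversed tuples, which is how
the sorter implements it. Sorting is stable; identical RFVs keep input
order and share a (1-based, competition-style) rank. Comparisons report the
pivot grade at which they were decided.

## Poisson-Limit model

Grade counts from d i.i.d. categorical AEs are multinomial; conditioning
out the zero class gives Mult|0⟩(d, λ/d), which requires d ≥ λ₊ (the
sampler enforces this). As d → ∞ the RFV converges to Poi(λ) = Π_r
Poi(λ_r); the suite checks the marginal total-variation distance decreasing
over d ∈ {10, 100, 1000} and empirical closeness (TV < 0.01) at d = 10⁴.
Rate vectors may contain exact zeros; every downstream formula tolerates
them. λ̂ (pooled coordinatewise mean of RFVs) is the maximum-likelihood
rate estimate and the variance anchor of the test.

Seeding: every sampler takes one integer seed (or a Generator); paired
two-arm draws derive child seeds from one seed via a seed sequence, so a
whole trial is reproducible from a single integer.

## Analytic moments

With λ₊ = Σλ_r, normalized vector λ̄, and its moments m₁, m₂:

* avg:  M = (1 − e^(−λ₊))·m₁;
  σ² = e^(−λ₊)·[m₁²(1 − e^(−λ₊)) + Er(λ₊)(m₂ − m₁²)], where
  Er(t) = ∫₀¹ (e^(ts) − 1)/s ds = Ei(t) − log t − γ_EM.
* mx: with tail sums W_k = Σ_{r≥k} λ_r (W_{K+1} = 0), P(mx < k) = e^(−W_k),
  so M = Σ_k (1 − e^(−W_k)) and the second moment telescopes.
* TI: with a_i = i/(i+1), b_i = i(i+2)/(i+1)², U_k = Σ_{i≥k} a_i λ_i,
  V_{k,ℓ} mixing a_i on [k∧ℓ, k∨ℓ) and b_i on [k∨ℓ, K], and
  Γ_{k,ℓ} = e^(−V_{k,ℓ}) − e^(−(U_k+U_ℓ)):
  M = (1 − e^(−U₁)) + Σ_{k=1}^{K} (1 − e^(−U_k)) and
  σ² = Σ_{k,ℓ=2}^{K+1} kℓ·[second difference of Γ], with empty sums zero.

Er is evaluated by its power series Σ_{k≥1} t^k/(k·k!) for t ≤ 30 (no
cancellation, terms until relative change < 1e−16) and by scipy's
exponential integral above; the branches agree at the crossover to 1e−10
relative (tested). The un-telescoped form of ξ(z) = Σᵢ(1−e^(−zᵢ)) needs
boundary term e^(−z_{K+1}) = 1; the telescoped form is canonical here
because it is boundary-free and reproduces every worked value.
A widely quoted small-λ inequality bounding Er(λ) − [1 − 3λ/4] is
incorrect as usually typeset (it fails at λ = 0) and is not asserted.

Degenerate conventions: at λ = 0 all means, variances, and grade moments
are defined as 0 (their limits). Variances within 1e−10 of zero from below
are clamped to 0; anything more negative raises, as it signals a formula
bug rather than round-off.

Every mean and variance formula is validated against an independent
vectorized Monte-Carlo oracle: 20 random rate vectors (Unif(0,2)⁵) at 10⁵
replicates, within 4 standard errors (the variance SE via the
fourth-moment formula), plus the worked-example rates at 2×10⁵ replicates.

## Two-sample test

S_g = mean g(X) − mean g(Y); reject when |S_g| exceeds
z_{α/2}·sqrt(σ²_g(λ̂)(1/n+1/m)). MODEL mode evaluates σ²_g at the pooled
λ̂ under null and alternative alike, exactly as the test prescribes.
EMPIRICAL mode substitutes the pooled sample variance of the g-values
(denominator n+m−1) — the natural two-sample-t analogue; the variance of
the raw RFVs would not estimate var g(X), so pooling happens on the
g-scale. Both estimates are consistent under the null and the two z-scores
agree within ~10% at n = m = 500 (tested). p-values are two-sided normal.
Zero-variance edge cases return z = 0 (zero statistic) or ±∞ with a
degeneracy flag.

Tested asymptotics: null rejection rate within [0.035, 0.065] of α = 0.05
at n = m = 200 over 2000 trials for all three measures; TI power > 0.99 at
the worked-example rates with n = m = 100; and the avg test's structural
blindness — rates differing by the third-difference direction
(1, −3, 3, −1, 0), which preserves λ₊, m₁, and m₂, leave avg near
powerless (< 0.10 at n = m = 500) while the TI test retains real power.

## Power, slopes, ARE

The power approximation uses μ = M_g(λ) − M_g(γ) (sign chosen to match the
worked-example tabulation; power depends only on |μ|),
σ² = σ²_g(λ) + ρσ²_g(γ), and τ = z_{α/2}σ_g(λ)√(1+ρ). When the mean
functionals coincide the limiting power is 2Q(z_{α/2}√((1+ρ)/(1+ρν))),
ν = σ²_g(γ)/σ²_g(λ) — the unique reading of the limit consistent with the
power formula at μ = 0 (the identity is asserted in the tests) — equal to
α at ν = 1.

Anchoring caveat: the approximation's critical value uses σ_g(λ), but the
practical test anchors at the pooled λ̂, which under the alternative drifts
toward the mixture rate. At well-separated rates this makes the simulated
power of the pooled-anchored test exceed the approximation (by ~0.1 at the
simulation-setting rates below, n = 100). `simulate_power` therefore
accepts a fixed `variance_rate` anchor; validation of the power formula
uses the matched (λ-anchored) simulation, and the worked-example powers
(0.877 / 0.800 / 0.295 at n = m = 5) come from the formula as stated.

Gradients of the mean functionals are exact: upper-triangular tail
structure for mx (∂M/∂λ_j = Σ_{i≤j} e^(−W_i)) and TI
(∂M/∂λ_j = a_j(2e^(−U₁) + Σ_{2≤i≤j} e^(−U_i))); for avg,
∂M/∂λ_i = e^(−λ₊)m₁ + (1−e^(−λ₊))(i−m₁)/λ₊, derived by differentiating
the closed-form mean (undefined at λ = 0, which raises). All are checked
against central finite differences at 1e−6.

Slope: B = ⟨∇M_g(λ), δ⟩/(σ_g(λ)√(1+ρ)), Pitman slope B². The tests verify
linearity in δ, vanishing for δ ⊥ ∇M, and convergence of the power
approximation to Q(z+B)+Q(z−B) along γ = λ + δ/√n for n through 10²–10⁴.

The ARE experiment draws λ ~ Unif(0.01, 2)⁵ and δ ~ Unif(0.05, 0.3)⁵
(alternative arm γ = λ + δ), 10⁴ draws, ρ = 1, and reports per-draw ratios
B²_TI/B²_mx and B²_TI/B²_avg with exceedance fractions. With these
defaults TI's test is more efficient than mx's in ≈ 97% of draws and more
efficient than avg's in ≈ 93% (avg occasionally wins when δ is nearly
orthogonal to TI's gradient direction but aligned with avg's); draws with
zero variance cannot occur under these rate bounds. The experiment is
bit-for-bit reproducible under a fixed seed.

## Synthetic data: what it does and does not emulate

The generators implement exactly the study conditions the analysis
assumes: i.i.d. patients, independent Poisson (or multinomial) grade
counts, homogeneous AE distributions within an arm. Real trial data
violate several of these — AEs differ in their grade distributions
(a Poisson-Binomial refinement is out of scope), counts correlate across
grades and treatment cycles, and arms are rarely exchangeable in d. A
passing suite therefore certifies the mathematics and the implementation
under the model, not robustness of the test to model misspecification.
The worked ten-patient example ships as a fixture in both file layouts and
doubles as the IO round-trip oracle.

## Aggregation and IO conventions

Long AE files are aggregated per patient by summing AE occurrences across
all rows (cycles) by default; `worst-cycle` instead keeps the cycle whose
RFV has the highest T-rank. The pooling rule for multi-cycle data is a
genuine modeling choice with no single canonical answer; the simple sum is
the default because it preserves total burden, and the choice is logged.
Delimiter defaults to comma (tab via flag). Writers round-trip integer
fields exactly; test runs log group sizes, pooled rates, and variance mode
at INFO level for auditability.

## Problem sizes and runtime

All analytic computations are effectively instantaneous (K+1-dimensional
sums; the TI variance is a (K−1)²-term double sum). The randomized
reproductions use the published experiment sizes — 10⁴ ARE draws, 1000
power-simulation replicates, 2000 null-calibration trials at n = m = 200 —
chosen as the sizes at which the Monte-Carlo error is comfortably inside
the assertion tolerances; the whole suite runs in well under a minute.

## Known limitations

Non-integer (clinician-weighted) grades, longitudinal/duration weighting,
Clavien-Dindo scoring, heterogeneous AE distributions, and multiplicity
adjustment across measures or treatment pairs are out of scope. The
two-sample test is asymptotic; at very small n (like the ten-patient
example) the normal calibration is approximate. The avg test should be
understood as testing equality of (λ₊, m₁, m₂), not of λ itself.
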