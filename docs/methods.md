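# Methods

## Response fitting

Each (year, rotation) corn group is fit with a quadratic and a smooth
quadratic-plus-plateau. The plateau form constrains the join point to the
parabola's vertex, x0 = −b/(2c), so the response has a continuous first
derivative everywhere — the derivative-based optimum presupposes a
well-defined slope, and this is the standard smooth variant of the model.
Whether the join point should instead be a free parameter is a genuinely
open choice; the free variant is not implemented.

The plateau fit profiles x0 over a deterministic 1-kg grid and refines the
best candidate with a bounded scalar minimizer (no random starts, so
results are seed-independent). The profile starts just above the
second-smallest distinct rate: with treatment designs like
{0, 67, 134, 201, 268}, any join point below the second rate leaves a
single support point on the quadratic segment, the profile likelihood goes
flat, and the "fit" degenerates to a step function whose optimum collapses
toward x0. Requiring two distinct rates below the join is an
identifiability guard, not a biological claim. The profile extends to 1.5×
the largest rate; a best join point at either profile edge, or positive
curvature, is reported as non-convergence rather than raised.

Fits default to replicate-level observations (n ≈ 20 per group) with a
mean-level switch; with balanced replication the coefficient estimates are
identical, only the significance test's degrees of freedom differ.
Significance is the overall F-test against the intercept-only model at
α = 0.05; R² is 1 − SS_res/SS_tot for both forms. Model selection keeps the
converged, significant candidate with the smaller residual SS; exact ties
prefer the plateau (a biologically bounded response). Groups where nothing
survives are flagged non-responsive and their optimum propagates as
missing — never as zero — into across-years means.

## Optimum derivation

The derivative EONR solves b + 2cx = R for the price ratio R (default 5.6
kg grain per kg fertilizer N, a mass-for-mass break-even slope; fixed
across years). Plateau fits cap the solution at x0. Estimates are censored
to [0, max tested rate] with an explicit boundary flag rather than
extrapolated — observed optima in long-term trials do hit the top rate.
Convex or non-converged fits give an undefined (not zero) estimate.

The RTN scan computes both the first zero-crossing of the marginal net
return and the grid maximizer of cumulative net return Y(N) − R·N. These
agree on concave curves; on noisy non-concave input the cumulative
maximizer is returned and the disagreement logged, since "near zero"
marginal return is ambiguous there. Ties on the grid resolve to the lowest
rate.

Site pooling: (a) across-years — mean ± sample SD of defined yearly
estimates; (b) pooled — average yields per N rate across years, then one
fit → select → optimum chain on the mean response (no SD is defined).
Method comparisons report exact signed differences; display rounding is
the caller's business.

## Agreement statistics

RMSE and RRMSE (= 100·RMSE/observed mean) with bands good ≤ 15% <
moderate < 30% ≤ poor; the boundary values classify as good and poor
respectively, matching the band definitions' ≤ and ≥. Pairing defaults to
model value vs observed treatment mean (simulators emit one value per
treatment); a replicate-pairing variant exists for sensitivity checks.
Pooled "Mean" rows are computed over the concatenated pairs of their slice,
never by averaging per-rate statistics — the two differ whenever group
sizes or observed means differ. CV uses the sample (n−1) SD.

## Synthetic trial generator

The generator emulates the statistical structure of a 16-year, two-rotation
(continuous corn CC, soybean–corn SC), five-rate (0/67/134/201/268 kg N
ha⁻¹), four-replicate rainfed experiment. It is deliberately minimal — a
supply/loss/response composition with closed-form truth — not a process
model; no water balance, SOC pools or fixation dynamics are simulated.

Per year: annual precipitation ~ N(900, 180) mm clipped to [550, 1300];
April–June spring sum ~ N(400, 90) clipped to [150, min(700, annual)];
a July silking-window sum ~ N(110, 45) clipped at 0. Soil N supply is 80 kg
N ha⁻¹ for CC at reference spring precipitation (400 mm), 50% higher for
SC, declining 0.05% per mm of spring rain above reference (floored at half)
— wet springs mineralize into a leaky profile. Atmospheric deposition adds
0.01 kg N per mm of annual precipitation into the supply term (~7 kg in a
700-mm season; the rule is linear, so daily sums equal the annual product —
note a 900-mm mean year implies ~9 kg, slightly above the "about 7"
commonly cited, a discrepancy we record rather than resolve). The fraction
of applied fertilizer lost to denitrification/leaching grows exponentially
with spring precipitation: 0.08·exp(0.004·(P − 400)), capped at 0.8.

Expected yield is a smooth quadratic-plateau in plant-available N
A = S + (1−L)·N: y = f·(2000 + 85A − 0.16A²) up to the vertex A0 = 265.6 kg
N ha⁻¹, constant beyond, never negative; f is a multiplicative year effect
~ N(1, 0.13) truncated at 0.4 and replicate yields multiply in
(1 + N(0, 0.08)) noise. The truncations (year factor ≥ 0.4, precipitation
clips) only guard against negative or absurd draws. Because A is affine in
N, the implied response in applied N is itself a smooth quadratic-plateau,
so the fitting pipeline is correctly specified on noiseless data. The
closed-form optimum solves f·(b + 2cA)·(1−L) = R, giving CC ≈ 205 and SC ≈
155 kg N ha⁻¹ at reference conditions (default loss raises supply-adjusted
values into the 160–190 range) — near long-term observed site means —
while CC mean yields span roughly 4–13 Mg ha⁻¹ across rates and years.
Soybean rows (the SC rotation's other phase) draw from N(3400, 660) kg ha⁻¹
independent of the prior corn N rate. All randomness flows from one seeded
`numpy` generator; no global state.

What the generator does **not** emulate: spatial/block structure,
autocorrelated weather, carryover of residual fertilizer N between years,
measurement error distinct from plot noise, and non-plateau response shapes.
Passing recovery tests therefore shows the estimator chain is correct and
adequately powered under these idealized conditions, not that it is robust
to every pathology of real field data.

## Verification design and problem sizes

- Derivative EONR vs an independent numeric profit maximization over 1,000
  random concave quadratics (agreement ≤ 0.01 kg N).
- RTN on predicted-yield grids of those curves: within one 5-kg step of the
  analytic optimum for every interior case.
- Noiseless recovery: fit → select → optimum on exact treatment means over
  a 50-scenario sweep of supply, loss and year effect recovers the closed
  form within 2 kg N for interior optima (measured: exact to solver
  tolerance).
- Noisy recovery: a 50-year two-rotation experiment (100 year-rotation
  responses) at default noise; the median |estimated − true| EONR is
  required ≤ 25 kg N ha⁻¹. This criterion sits close to the intrinsic
  precision of a 5-point design with 8% replicate noise (median error ≈
  20–30 kg depending on realization); the positive skew of (R − b)/(2c)
  under noise and occasional censoring at the top rate are the dominant
  error sources.
- Mechanism: across 20 16-year experiments, regressing the generator's
  yearly optimum on spring precipitation gives a positive slope in ≥ 90% of
  runs; with the loss, supply and deposition couplings to precipitation all
  switched off (a true null — deposition alone ties supply to rainfall with
  a ≈ −0.005 kg N mm⁻¹ slope) the mean slope is within Monte-Carlo noise of
  zero. With pipeline-*estimated* optima the same slope is positive in only
  ≈ 79% of 16-year runs: the precipitation-driven component of the true
  optimum (≈ 9 kg N SD) is small against ≈ 35 kg N of estimation noise, so
  16 years under-powers detection — an echo of the low predictive power
  such regressions show on real data. The estimated-level fraction is
  reported by the acceptance script alongside the construction-level check.
- The soybean carryover check rejects at about the nominal 5% rate on
  generator output and recovers a planted slope when one is injected.

All Monte-Carlo suites use fixed seeds and run in seconds on one CPU; sizes
were chosen to make the checks statistically meaningful at interactive
runtimes.

## Data handling

Yields are normalized once at load time to kg ha⁻¹ (declared unit `kg_ha`
or `mg_ha`); analyses are unit-invariant by construction. Hard invariants
(unknown labels, negative rates/yields, duplicate treatment keys) raise on
load with the offending row; soft problems (groups with < 3 distinct rates,
unbalanced replication, yields beyond 3 interquartile ranges of their
treatment-group median) come back as a report and never mutate data. The
IQR rule with 4 replicates is deliberately sensitive (a few percent of
clean noisy records get flagged); the multiplier is configurable. A
`SC_val` rotation label is carried as a distinct group (an even-year
validation split convention) but treated identically by all computation.
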