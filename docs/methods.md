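# Methods

## Model and hypotheses

Two independent groups are modeled as Normal(δ, 1) and Normal(0, 1); δ is
the standardized mean difference.  H0 fixes δ = 0; the directional H1
places an analysis prior on δ > 0.  The pooled-variance two-sample t
statistic is sufficient for δ in this parametrization: given δ, t follows
a noncentral t with df = n₁ + n₂ − 2 and noncentrality δ·√(n_eff),
n_eff = n₁n₂/(n₁+n₂).  All Bayes factors are therefore computed from
(t, n₁, n₂) rather than raw data — exact, and it lets fixed-N simulation
draw t directly from its sampling distribution.

The Bayes factor is BF10 = m₁(t)/m₀(t) with m₀ the central-t density and
m₁(t) = ∫ f_nct(t; df, δ√n_eff) π(δ) dδ.  Log BF10 is the primary stored
quantity everywhere; BF values are exponentiated on demand.

## Analysis priors

* default: Cauchy(0, r = √2/2) truncated to δ > 0 (half-Cauchy).
* informed: Student-t(μ = 0.35, ν = 3, r = 0.102) truncated to δ > 0.

Cauchy is represented internally as Student-t with ν = 1 so all continuous
priors share one code path.  Truncation is expressed through general
(lower, upper) bounds with renormalization; the untruncated variants are
available behind a flag (`get_prior(name, truncated=False)`) for
sensitivity checks.  Truncated sampling uses the inverse-CDF transform,
which keeps draws seed-stable and inside the support (no rejection steps).
We adopted truncation at zero for both named priors because the
directional hypothesis demands it and because the truncated forms
reproduce the package's own fixed-N reference quantities (median BF 0.309
and 0.536 at t = 0, n = 20), which an untruncated informed prior shifts
visibly (0.542).

## Numerical evaluation of the marginal likelihood

`scipy.stats.nct` overflows (in its Boost gamma backend) at the large
df × noncentrality products that arise when a heavy-tailed prior is
integrated, so the noncentral-t log density is computed in-house from the
scale-mixture representation T = (Z + ncp)/W, W = √(χ²_df/df):

    f(t) = ∫₀^∞ w φ(tw − ncp) f_W(w) dw.

The log-integrand is concave in w (sum of log w, −w², −(tw − ncp)²
terms), so it is unimodal with Gaussian-like tails; its mode solves a
quadratic.  A 48-node Gauss–Legendre rule on mode ± 11 posterior standard
deviations evaluates the integral essentially to machine precision
(validated against `scipy.stats.nct.logpdf` to ~1e-8, the library's own
accuracy, wherever it does not overflow), entirely in log space and
vectorized over (t, df, ncp).

The δ-integral uses composite Gauss–Legendre panels (20 nodes per panel by
default) with breakpoints drawn from **two length scales at once**: fixed
quantiles of the prior (resolving a narrow informed prior or a
heavy Cauchy tail) and the likelihood bulk window δ̂ ± kσ̂ with
δ̂ = t/√n_eff, σ̂ = √(1 + t²/2df)/√n_eff (resolving a likelihood peak far
out in the prior tail).  Against adaptive Gauss–Kronrod quadrature the
rule agrees to better than 1e-9 relative on a (t, n) grid spanning
t ∈ [−20, 20], n ∈ [2, 2000] for both named priors.  The scalar `bf10`
entry point evaluates at two node resolutions and raises a
`QuadratureError` on relative disagreement above 1e-6 — it never returns a
silently unconverged number.  Point priors bypass quadrature with the
exact density ratio.

For large same-n batches (`log_bf10_batch`, used by the fixed-N engine),
the panel rule is evaluated on a t-grid of spacing 0.05 and interpolated
with a cubic spline; log BF10 is smooth enough in t that the interpolation
error is below 1e-8 (a regression test bounds it at 1e-6).  Points beyond
|t| = 50 fall back to direct quadrature.

## Critical t values and monotone shortcuts

For priors supported on δ > 0, log BF10 is strictly increasing in t; the
package asserts this numerically (1,000-point grid over t ∈ [−50, 50])
before any shortcut that relies on it.  Consequences used throughout:

* quantiles of the BF distribution equal BF at quantiles of the
  (non)central t distribution (`bf_quantile_analytic`);
* `critical_t(n, prior, b)` — the t solving BF10 = b — is found by
  bracketing root search (Brent) on [−50, 50] to relative BF error ≤ 1e-6;
* P(BF crosses a boundary) is a (non)central-t tail beyond the critical t
  (`prob_exceed_boundary`).

Because BF10 is bounded below in t under a directional prior, a lower
boundary can be unattainable at small n; those cases yield probability 0/1
with a logged warning rather than an error, and sequential thresholds
become −∞ (never crossed) there.

`critical_t_profile` solves for the critical t at every n in a range by
loose Brent roots on a coarse geometric subgrid, monotone-cubic
interpolation in log n, and vectorized secant polish to
|log BF − log b| ≤ 1e-8, falling back to exact scalar roots for any entry
that resists (none observed in practice).

## Fixed-N engine

Per replication: draw δ from the design prior (a *fresh* δ each
replication when the design prior is a distribution), then draw
t = (Z + δ√(n/2))/√(χ²_df/df) directly.  This is distributionally
identical to generating 2n raw normal observations (a KS test against the
central t at δ = 0 and a noncentral-mean check at δ = 0.8 are in the test
suite) and ~100× faster.  Groups are balanced (n₁ = n₂), matching how all
quantities here are reported ("observations per group").  Quantiles use
linear interpolation between order statistics (numpy's default); the
"expected Bayes factor" is the geometric mean exp(mean log BF) and is
always labeled as such, the median being reported separately.

## Sequential engine

Trajectories accumulate raw observations (one per group per stage,
balanced), because successive t statistics share observations and are
dependent.  Running sums and sums of squares give the pooled t at every
stage; a test verifies stage-wise equality with batch recomputation to
1e-10.  The stopping decision at per-group size n compares t against
precomputed critical values t*(n) for the two boundaries — mathematically
identical to evaluating BF10 at every stage (by strict monotonicity in t)
but removes quadrature from the inner loop.  Log-BF paths are materialized
for trajectories whose full path is requested.

Each trajectory runs on its own `SeedSequence`-spawned substream, so
results for trajectory i are invariant to m and to execution order.
Observations are drawn from the substream in geometrically growing blocks
(64, 128, 256, … capped at n_max); the block schedule is part of the
reproducibility contract.

Defaults: n_min = 10 per group, step = 1 per group per stage,
n_max = 5,000 per group with explicit censoring.  Censored trajectories
(BF still inside the boundaries at n_max) are labeled, logged prominently,
counted separately from misleading evidence, and excluded from final-N
quantiles only when present (with a warning) since their true final size
is right-censored.  With b = 6 the censored fraction at n_max = 2,000 is
below 1% for all design effects used here.

## Planning quantities

The critical sample size scans ascending n (step 1 by default) and returns
the smallest n whose crossing probability reaches the target γ (default
0.8, i.e. the 20% BF quantile clears the boundary).  The semi-analytic
route computes the whole scan from critical-t profiles in seconds; the
Monte Carlo route re-runs the fixed-N engine on a coarser grid (step 5)
and refines step-by-step inside the bracketing interval; a test holds the
two within two coarse steps of each other.  Evidence classification uses
the standard BF ladder with cut points 1/100, 1/30, 1/10, 1/3, 1, 3, 10,
30, 100; values exactly on a cut point go to the stronger-evidence side
(BF = 3 is "moderate", not "anecdotal"), and BF = 1 is its own "no
evidence" category.

## Scale of the shipped computations

The acceptance script and test suite run the fixed-N reference analysis at
the full m = 10,000 replications, critical-N checks semi-analytically plus
Monte Carlo at m = 2,000 per grid point, and the sequential reference
analysis at m = 2,000 trajectories with n_max = 2,000 per group — sizes at
which every reported quantity's Monte Carlo error is well inside the
tolerances asserted for it.

## What the simulations do and do not show

The generator emulates exactly the model the Bayes factor assumes: normal
populations, equal unit variances, balanced groups, independent
observations.  Passing tests therefore demonstrate internal correctness
and calibration of the design-analysis machinery, not robustness to
violations (unequal variances, non-normality, unbalanced or clustered
data), none of which the engines model.  Other known limitations:

* Welch-type (unequal-variance) likelihoods, paired designs, and
  utility-based stopping rules are out of scope.
* Critical-n values for targets in flat regions of the crossing-probability
  curve are intrinsically soft: near δ = 0 with γ = 0.8 the probability
  gains only ~4·10⁻⁴ per added observation, so any two implementations
  (or two Monte Carlo runs of the same implementation) can legitimately
  differ by tens of observations while agreeing to a fraction of a
  percentage point in probability.
* The sequential engine's n_max cap is a practical necessity; unbounded
  runs would terminate with probability one, but the far tail of the
  final-N distribution beyond the cap is not observed.
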