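# Methods

## The model

The Weibull-gamma (W-g) law is the member of the Weibull-generated
(Weibull-G, "transformed-transformer") family whose baseline is the
gamma distribution.  With gamma cdf `G(x) = P(k, x/s)` (regularized
lower incomplete gamma, shape `k > 0`, scale `s > 0`) and Weibull
generator (shape `c > 0`, scale `β > 0`), the transform
`W(G) = -log(1 - G)` gives

    F(x) = 1 - exp{ -[(-log w(x)) / β]^c },   w(x) = 1 - G(x) = Q(k, x/s),

for `x ≥ 0`, where `Q` is the regularized upper incomplete gamma
(the gamma survival function).  The density follows by differentiation:

    f(x) = c/(β s^k Γ(k)) · x^{k-1} e^{-x/s} / w(x)
           · [(-log w)/β]^{c-1} · exp{-[(-log w)/β]^c}.

Special cases: `c = β = k = s = 1` is the unit exponential;
`c = β = 1` is the gamma(k, s); `c = 1` is an "exponential-gamma" law
with density `x^{k-1} e^{-x/s} w^{1/β - 1} / (β s^k Γ(k))`.  Near the
origin `f(x) ~ x^{ck-1}`, so the density diverges for `ck < 1`, is
finite-positive for `ck = 1` and vanishes for `ck > 1`; the hazard
`f/(1-F)` can be decreasing, increasing, unimodal, U- or bathtub-shaped
depending on the parameter corner.  This shape flexibility — four
parameters, two of which act on the *transformed* scale — is the point
of the construction.

## Numerical design

**Log-space evaluation.**  All density work is in log space and `w` is
always computed as an upper tail.  `log Q(k, z)` uses three branches:
`log1p(-P)` when `P(k,z) < 1/2`; `log(gammaincc)` otherwise; and, where
`Q` underflows in double precision (`Q < 1e-280`), the optimally
truncated asymptotic series
`Q(k,z) ≈ z^{k-1} e^{-z}/Γ(k) · Σ_j (k-1)⋯(k-j)/z^j`, which in that
region agrees with 50-digit arithmetic to machine precision.  This
matters in practice: real-data optima sit at gamma shapes of order
1e-2 where naive `1 - P` evaluation destroys the likelihood.

**Quantiles and sampling.**  The quantile composes the gamma quantile
with the inverted generator: `x = s · P^{-1}(k, u)`,
`u = 1 - exp(-β(-log(1-p))^{1/c})`, with `u` evaluated through
`expm1`/`log1p`.  Three guarded Newton steps on `F(x) - p` polish the
result (round-trip `F(Q(p)) = p` holds to 1e-10 over
`p ∈ [1e-6, 1-1e-6]`); when `u` is within 1e-15 of 1 (the generator
pushes probabilities beyond double resolution) the quantile is solved
in log space by bisection on `-log w`, and for `k < 1e-3` a cdf
bisection fallback guards the ill-conditioned gamma inverse.  Sampling
is inverse-transform through one shared `numpy.random.Generator` with
an explicit seed contract.

**Density at x = 0.**  The analytic limit is returned when finite
(`0` for `ck > 1`, `c k^{1-c} β^{-c} (s^k Γ(k))^{-c}` for `ck = 1`) and
`+inf` is used as an explicit "infinite density" sentinel for `ck < 1`,
so that plotting and fitting never propagate NaN.  The support
convention at 0 is this package's choice; the literature leaves it
unstated.

## Series expansions

The density admits a formal rearrangement into gamma-type kernels
`A · x^{kM + a5 - 1} e^{-x/s}` over five indices (exponential series,
geometric expansion of `1/w`, generalized-binomial expansion of
`(-log(1-G))^a` with recursive constants `p_{a4,a3}`, incomplete-gamma
power series, and real powers of that series via the `q` recursion
`q_v = (1/(v a_0)) Σ_j (jm - v + j) a_j q_{v-j}`).  Moments, the mgf
and the characteristic function then follow term by term, e.g.
`μ_r = Σ A s^r Γ(r + kM + a5)` up to the shared prefactors.

Three things the implementation settles that the algebra leaves open:

* **Singular index tuples.**  The coefficient denominator carries the
  factor `a - a4` with `a = a1·c + c - 1` (density) or `a = a1·c`
  (cdf).  When `a` is a non-negative integer the factor vanishes — but
  always against a zero of the generalized binomial `C(a3-a, a3)`, and
  the 0·∞ product has the finite limit
  `(-1)^{a4} (a4-1)! (a3-a4)! / a3!`.  Evaluating the limit (the
  default, `singular="limit"`) is *required* for correctness: dropping
  the tuples (`singular="skip"`, retained for comparison) loses mass at
  every integer exponent, e.g. it turns `(-log(1-x))^2` at `x = 0.3`
  from 0.1272 into 0.1170.
* **The cdf-series denominator.**  For the cdf the log-power exponent
  is `a1·c` (no density Jacobian), so the denominator factor is
  `a1·c - a4`; using the density's `a1·c + c - a4 - 1` there fails even
  the nested-gamma check.
* **Truncation and divergence.**  The rearrangement is formal and the
  region of validity is unknown; truncated sums are accumulated in
  blocks of constant total index with early exit once a block falls
  below 1e-12 of scale, and every result carries a `converged` flag and
  the last block magnitude.  In nested cases (`c = β = 1`) blocks
  cancel exactly and the early exit returns the exact gamma values; at
  larger abscissae or for higher moments the blocks grow factorially
  and the flag reports divergence instead of silently returning noise.
  For this reason adaptive quadrature against the closed-form density
  (tolerance 1e-10, split at model quantiles, with log-space weights
  for the mgf) is the default public method for moments/mgf/cf, and a
  Monte Carlo route provides an independent cross-check.

## Likelihood, scores and fitting

The sample log-likelihood is the sum of log-densities (algebraically
the usual closed form in `log c, log β, log s, log Γ(k), log w`,
`log(-log w)` and `(-log w/β)^c`).  The analytic score is provided in
two variants: `wg_score_printed` reproduces a published set of partial
derivatives whose `∂ℓ/∂s` component, `-nk/s + Σx_i/s²`, omits the
chain terms through `w = Q(k, x/s)`; `wg_score_corrected` adds them
(`∂w/∂s = (x/s²)(x/s)^{k-1} e^{-x/s}/Γ(k)`) and matches central
differences to 1e-6 relative on all four components, vanishing at
interior optima.  `∂w/∂k` has no elementary form and is taken by
central differences of `log Q` in `k`.  Only the corrected score or
finite differences ever drive optimization.

**Unbounded likelihood.**  The W-g likelihood has no finite global
maximum: along `k → 0` with `c, β → ∞` (and along `k → ∞, s → 0`) the
likelihood increases without bound while the model degenerates.  Real
fits of this family in the literature are therefore *local* optima
determined by the optimizer and its starting point; the benchmark
optima for three of the five packaged datasets sit on the small-k ridge
(k̂ ≈ 0.004–0.009, ĉ ≈ 5–6).  `fit_wg` makes this explicit: it
maximizes over log-parameters inside the box `[1e-4, 1e4]^4` with a
deterministic multi-start (moment-matched gamma start at `c = β = 1`,
a near-Weibull start, a small-k ridge start, and seeded log-normal
perturbations; default 8 starts, seed 20190426), Nelder-Mead followed
by a BFGS polish, and reports the best point found with the start count
and a convergence flag.  Nelder-Mead is the primary engine because the
objective is cheap, four-dimensional and ridged; the quasi-Newton
polish sharpens interior optima.  On all five packaged datasets the
fitted log-likelihood meets or exceeds the published values.

Competitor models (gamma, Weibull, EE with cdf `(1-e^{-x/s})^α`, EG
with cdf `P(k, x/s)^α`) are fitted the same way with moment-matched
multi-starts.  The EE is deliberately parameterized by a *scale* `s`:
the published estimates (e.g. ŝ ≈ 53 for lifetimes with mean ≈ 47) are
only consistent with that reading.  AIC is `2·(#params) − 2·ℓ` and the
comparison table flags the minimum-AIC model among converged fits.

## Monte Carlo study

`run_study` draws `nsim` samples per sample size from a true W-g law
(inverse transform; replicate `i` uses seed `base + i`, offset per
sample-size block), refits each sample and aggregates
`bias = mean(θ̂) - θ` and `RMSE = sqrt(mean((θ̂ - θ)²))` per parameter.
Defaults mirror the published study conditions: cases
I = (1.5, 0.5, 0.5, 0.4) and II = (1.8, 0.3, 0.5, 0.4), sample sizes
(30, 100, 500), 1000 replicates.

The per-replicate fit is a single Nelder-Mead search on the **raw**
parameter scale started at the true values, with 10% initial-simplex
steps, relative function tolerance 1.49e-8 and an evaluation cap of
500 — the default behaviour of the optimizer most commonly used for
such studies in the applied literature.  This choice is load-bearing
and documented as a reproduction caveat: because the likelihood is
unbounded, an exhaustive optimizer run drifts down the ridges
(β̂ and ŝ wander by orders of magnitude) and no finite-moment summary
exists; the capped local search is what makes "the" MLE distribution
well-defined, and roughly half the replicates end at the cap rather
than at formal convergence.  All replicates enter the aggregates — 
dropping cap-hitters would bias the summary toward the early-converged
subset — and each cell reports its formally-converged count, with a
flag when that drops below 80%.  Consequently the study reproduces the
published bias/RMSE *structure* (RMSE strictly decreasing in n for
every parameter in both cases; n=500 means close to the published
ones) but not every mean cell digit-for-digit, since the original
optimizer, seeds and convergence handling are unstated.

## What the generator does and does not emulate

The synthetic sampler draws i.i.d. complete observations from the
exact W-g law — that is the stated design of the study it reproduces.
Real lifetime data bring censoring, ties from detection limits and
rounded recording (the packaged benchmark datasets contain heavy ties
at running-time caps, fitted here — as in the source analyses — as
complete observations), and model misspecification.  Passing tests
therefore certify the estimator pipeline under the model, not
robustness to censoring or misspecification; censored likelihoods are
out of scope.

## Known limitations

* The likelihood is unbounded; every reported W-g fit is a documented
  local optimum inside a parameter box, and fitted parameters on
  ridge datasets are not individually interpretable (the likelihood
  is nearly flat along the ridge even though the fit is stable in
  log-likelihood terms).
* The quadruple series has no proven convergence region; use the
  `converged` flag, or the quadrature/Monte-Carlo routes.
* Standard errors and interval estimates are not provided (AIC-based
  comparison only), matching the scope of the study reproduced.
* The datasets ship as printed in their sources, including one pair
  that is the same sample in different units (datasets 1 and 3, ×100).
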