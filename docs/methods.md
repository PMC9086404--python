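# Methods

## The model

`localtrend` tests pairwise association between two equal-length time series
(OTU abundances, gene expression, environmental covariates) through their
*local co-trending*, not their values.

**Discretization.** A series X_1..X_n becomes a trend sequence
d_1..d_{n-1} over {-1, 0, +1}: for X_i ≠ 0,

    d_i = +1  if (X_{i+1} - X_i)/|X_i| >= t
    d_i =  0  if -t < (X_{i+1} - X_i)/|X_i| < t
    d_i = -1  if (X_{i+1} - X_i)/|X_i| <= -t

and d_i = sign(X_{i+1}) when X_i = 0.  At t = 0 the alphabet is effectively
{-1, +1}; at t > 0 it is three-state.  The inequality at +t is inclusive, so
at t = 0 an exactly repeated value maps to +1.  Zero-heavy abundance tables
therefore see runs of equal zeros as "up" trends; `strict=True` sends ties
and sub-threshold changes to 0 instead.  No transformation is applied before
discretization (the trend of the raw series is the object of interest; at
t = 0 any monotone per-series transform leaves the symbols unchanged).

**Score.** The local trend score with delay bound D is

    LT(D) = max over (i, j, k), |i - j| <= D  of  sum_{l=0}^{k-1} d^X_{i+l} d^Y_{j+l},

the best aligned-window sum of symbol products, computed in O(m(2D+1)) by a
per-offset maximal-subarray scan (m = n - 1).  The empty window (k = 0) is
admissible, so LT(D) >= 0 and a zero score maps to p = 1.  The default score
is one-sided (positive co-trending); `two_sided=True` also scores against
the negated partner and reports the larger value.  One-sided is the shipped
default because it is the definition under which the tail law below is
calibrated (the two-sided variant roughly doubles tail mass and would need a
different reference law).

**Null variance.** Trend sequences of stationary series are modelled as
sign-symmetric first-order Markov chains: two-state with stay probability
`a`; three-state with stay `b`, flip `c` and zero-exit `d` (stationary mass
phi_1 = d/(1 - b - c + 2d) on each of ±1).  Under independence of X and Y
the product chain Z_i = d^X_i d^Y_i has long-run variance

    sigma^2 = E(Z_1^2) + 2 sum_k E(Z_1 Z_{k+1}),

with closed forms driven by the geometric autocovariances
E(d_1 d_{k+1}) = (2a-1)^k (two-state) and 2 phi_1 (b-c)^k (three-state):

    two-state:    sigma^2 = (1 + r_X r_Y)/(1 - r_X r_Y),       r = 2a - 1
    three-state:  sigma^2 = 4 phi_1^X phi_1^Y (1 + q)/(1 - q), q = rho_X rho_Y, rho = b - c
    mixed:        sigma^2 = 2 phi_1^Y (1 + r_X rho_Y)/(1 - r_X rho_Y)

A pair uses the two-state, three-state or mixed formula according to the
*observed* symbol sets of the two chains; a chain whose zero state never
transitions onward (empty zero row in the pair counts) falls back to the
two-state model, and single-state chains are flagged degenerate.

**Tail law.** For a mean-zero chain with long-run variance sigma^2 the
maximal increment H_m = max_{i<=j} (S_j - S_i) of its random walk satisfies
H_m/(sigma sqrt(m)) → sup_{0<=v<=1} |W_v|: by Lévy's theorem the running
drawup of a Brownian path has the same law as reflected Brownian motion, so
the one-sided maximal increment converges to the supremum of |W|.  With
delay bound D the score is treated as the maximum of 2D+1 weakly dependent
copies, giving

    p ≈ L_D(x) = 1 - Theta(x)^(2D+1),   x = LT(D)/(sigma sqrt(m)),

with Theta(x) = P(sup|W| <= x).  The scaling length is m = n - 1 — the
length of the product chain, which is the walk the theorem concerns.

**Methods.** STLTA estimates the transition parameters from the observed
chains (averaged row ratios of the transition pair counts, with a
single-row fallback when one signed row is unobserved).  TLTA fixes them at
their i.i.d.-series values: a = 1/3 exactly at t = 0 (rank argument over
three i.i.d. continuous draws), and at t > 0 a cached Monte-Carlo estimate
from one long discretized i.i.d. sample (standard-normal marginal, 10^6
draws, fixed internal seed 20220426) — the marginal matters at t > 0, and
standard normal matches the simulation nulls.  The permutation test
shuffles one member of the pair and re-scores.

## Numerical choices

* Theta(x) is evaluated by two complementary alternating series, switching
  at x = 1: the theta series (4/pi) Σ (-1)^k/(2k+1) exp(-(2k+1)^2 pi^2/(8x^2))
  for x < 1 and the reflection series 1 - 4 Σ (-1)^k Phi_c((2k+1)x) for
  x >= 1 (the theta series converges slowly for large x).  Truncation: term
  below 1e-14 or 1000 terms; x below 1e-8 returns p = 1 outright.
* A fitted decay product with |q| >= 1 - 1e-9, or a vanishing stationary
  denominator, yields a flagged degenerate result instead of a p-value: the
  asymptotics require an ergodic chain.  The simulation harness counts
  degenerate replicates as non-rejections and reports them.
* Estimators are plain ratios — no pseudocounts.
* Co-optimal alignments are reported deterministically: smallest start in
  the first sequence, then in the second, then shortest window.
* Permutation p-values use the add-one estimator
  (1 + #{perm >= observed})/(n_perm + 1).

## Permutation convention

`permutation_test(..., permute="symbols")` (default) shuffles the trend
*symbols* of the second sequence; `permute="values"` shuffles the original
numeric values and re-discretizes.  For exchangeable (i.i.d.) series the
value permutation is an exact test, while the symbol permutation ignores
the serial dependence that discretization itself induces in the symbols and
is slightly anti-conservative even then.  The symbol convention is the
default because it is the behaviour of the published calibration grids this
package reproduces (the value convention cannot exceed the nominal level on
i.i.d. data, yet the reference grids report 0.058 there); users wanting the
exact variant for exchangeable data should pass `permute="values"`, which
is also what the uniformity property test exercises.  Under either
convention the permutation null misrepresents autocorrelated series — that
is precisely the failure mode STLTA addresses.

## Simulation design

The type-I-error harness draws independent pairs from three stationary
nulls (AR(1); ARMA(1,1) with MA coefficient 0.5; and an ARMA(1,1) paired
with a threshold AR(1) whose coefficient is rho2 below Y_{t-1} = -1 and 0.5
above), each started from a standard-normal draw with 100 burn-in samples
discarded.  The grid crosses six coefficient pairs with sample sizes
20–200 at alpha = 0.05, D = 0, for thresholds t = 0 and t = 0.5.  Replicate
r of a cell draws from `SeedSequence([seed, cell_key, r])`, so every
replicate is reproducible in isolation.  AR/ARMA recursions run through
`scipy.signal.lfilter`; the threshold branch is an explicit loop.

Problem sizes: the acceptance script (`scripts/acceptance.py`) runs
theory-based cells at the full 10,000 replicates and the permutation cell
at 2,000 replicates × 1,000 permutations; `run_table` defaults to 2,000
replicates per cell, the package's standard reduced-replication mode, with
published values judged within 3 binomial Monte-Carlo standard errors at
the executed replication.

## What the synthetic fixture does and does not emulate

`pipeline.make_fixture` produces OTU-like tables: AR(1) latent series
mapped through exp() to a positive abundance scale, optional planted
associations that share innovation *signs* (co-trending without equality),
and uniformly injected missing values.  It does not emulate compositional
(relative-abundance) coupling between rows, zero inflation, sequencing
depth variation, or seasonal structure — so passing recovery tests show
that the screen detects shared trend direction under autocorrelation and
missingness, not that it is robust to compositional artifacts.

## Known limitations

* The product chain Z_i is treated as first-order Markov; this is an
  approximation (the pair (d^X, d^Y) is Markov, its product alone is not
  exactly so), inherited by all theoretical p-values here.
* The tail approximation is asymptotic and conservative at small n
  (noticeably below nominal for n ≤ 60); the simulation grids quantify
  this.
* Chains are assumed sign-symmetric (T[-1,-1] = T[1,1]); series with strong
  drift violate this and tend toward degenerate fits.
* The delay correction Theta^(2D+1) treats the 2D+1 offsets as independent,
  an upper-bound-style approximation that grows crude for large D relative
  to n.
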