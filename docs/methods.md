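# Methods

## The problem

Given a multivariate time series `X_t = (X^1_t, …, X^N_t)` generated by a
stationary structural process

    X^j_t = f_j( parents(X^j_t) ) + η^j_t ,

with mutually independent dynamical noise η, the task is to estimate the
lag-resolved causal graph: which `X^i_{t−τ}` (τ ≥ 1) enter the structural
equation of which `X^j_t`.  The classical route — lag-specific Granger
causality, here called **FullCI** — tests every pair conditional on the
entire past of all variables up to `τ_max`.  In systems with dozens of
variables and a few hundred samples this fails for two separate reasons:
the regression dimensionality `N·τ_max` approaches or exceeds the sample
count, and conditioning on variables *driven by* the tested driver
"explains away" part of the dependence, shrinking the effect size (the
test statistic magnitude) and hence the detection power.

## The two-stage estimator

**Stage 1 — PC1 condition selection.**  For each variable, start from all
`N·τ_max` lagged candidates.  Iteration `p = 0` removes candidates without
unconditional dependence at a liberal level `α_PC`; iteration `p ≥ 1`
tests each remaining candidate conditional on the `p` currently strongest
other candidates, removing failures only at the end of the iteration
(PC-stable behaviour, immune to within-iteration ordering effects) and
re-sorting by the absolute statistic of the most recent test.  The
algorithm stops when no candidate has `p` others left to condition on.
This is the `q_max = 1` shortcut of the PC-stable skeleton search: instead
of iterating over all size-`p` subsets it trusts the dependence ranking,
which empirically retains the true parents with high probability while
shrinking the condition sets to near the true parent cardinality.
`q_max > 1` is exposed for completeness (subsets tried in lexicographic
order on the sorted candidates; a survivor's recorded score is then the
smallest absolute statistic observed, the most conservative choice).

`α_PC` is a regularization knob, not a test level.  Too small and true
parents are lost — which not only costs power but *inflates false
positives* in stage 2, because a missing parent leaves indirect paths
unblocked.  Too large and the condition sets grow, costing power.  For
the linear test the level is chosen per variable from {0.1, 0.2, 0.3,
0.4} by the AIC score `n·log(RSS) + 2k` of the implied OLS fit (ties go
to the smaller level); for GPDC/CMI the default is a fixed 0.2.  Note the
AIC keeps any screened survivor worth more than `n·r² > 2`, so it does
not always pick the sparsest set — that is the intended behaviour of the
score, not a defect.

**Stage 2 — the MCI test.**  Every ordered pair `(X^i_{t−τ}, X^j_t)` is
tested conditional on

    Z = P̂(X^j_t) \ {X^i_{t−τ}}   ∪   shift_τ( P̂(X^i_t) ) ,

the estimated parents of the target plus the estimated parents of the
driver shifted τ steps into the past.  The first block establishes
conditional independence (Markov property); the second removes the
autocorrelation-induced inflation of the null distribution and makes the
statistic comparable across links — on linear-Gaussian models the
population MCI partial correlation depends only on the coupling
coefficient, not on the autocorrelation of either variable, so the
statistic ranks links by causal strength.  `p_X` restricts how many
driver parents are used (default: all).  Shifted parents may exceed
`τ_max`; the sample alignment window is widened rather than dropping the
condition, since no lag bound applies to the driver's parents.

Two boundary behaviours are deliberate:

* `α_PC = 1` removes nothing, so every parent set is the full lag grid.
  The shifted driver parents are then conditionally redundant — the whole
  past separates them from the target — and are omitted, making the MCI
  test *exactly* the FullCI test (identical statistics through the same
  code path).  PC1 also short-circuits after the scoring pass in this
  case, since no removal can ever happen.
* All variables are standardized once per analysis.  This leaves ParCorr
  p-values unchanged but puts statistics on the correlation scale, so
  printed effect sizes (e.g. 0.15/0.13/0.11 for the worked example) are
  comparable across datasets.

Contemporaneous (τ = 0) links are out of scope throughout: the model
assumes no instantaneous causal effects, and lagged links need no
orientation step.

## Conditional-independence tests

**ParCorr** regresses x and y on Z by OLS (intercept included),
correlates the residuals and uses the exact Student-t transform
`t = r·sqrt((n−D−2)/(1−r²))`.  Collinear condition columns are dropped
with a warning (D reduced accordingly).  Analytic p-values are used
rather than permutations: standard, fast, and exact under the linear
Gaussian null.

**GPDC** replaces the OLS fits with Gaussian-process regressions (RBF
kernel plus white noise, hyperparameters by marginal-likelihood
maximization, median-heuristic initial length scale, and a
median-heuristic fallback with fixed noise if the optimizer fails) and
replaces the residual correlation with the empirical distance
correlation, which is zero iff independent in the population limit.  The
p-value is the right-tail rank of the statistic in a null distribution of
distance correlations between independent standard-normal samples of the
same `n` (1000 draws by default, cached per sample size, deterministic
given the seed).  The rationale: residuals of a correct additive GP fit
are approximately independent under H0, so the normal-sample null is a
good surrogate.  This calibration mechanism is this package's own design;
it is checked by the calibration tests rather than assumed.

**CMI** estimates conditional mutual information with the
nearest-neighbour (digamma) estimator under the maximum norm:
`ε_i` is the distance to the `k_CMI`-th neighbour in the joint space and

    I = ψ(k_CMI) + ⟨ ψ(n_z+1) − ψ(n_xz+1) − ψ(n_yz+1) ⟩ ,

with strict-inequality neighbour counts in the subspaces.  With empty Z,
`n_z = n − 1` and the expression reduces to the standard k-NN mutual
information estimator.  Ties are broken by seeded noise of amplitude
1e−10.  Significance comes from local-permutation surrogates: x-values
are shuffled among each point's `k_perm` nearest neighbours in Z-space
(each source value used at most once while any remains), which preserves
the x–Z dependence and breaks x–y|Z; with empty Z the surrogates are full
permutations.  `p = (1 + #{surrogate ≥ statistic}) / (1 + n_surrogates)`,
so the smallest attainable p is `1/(1+n_surrogates)`.  Defaults:
`k_CMI = 60`, `k_perm = 5`, 500 surrogates.

All stochastic elements — surrogates, null caches, tie-break noise,
simulations — draw from generators derived from one master seed plus
string/integer context keys (`_rng.py`), so every result is reproducible
bit-for-bit.

## Multiple testing and ranking

Optional FDR control maps the `m = N²·τ_max` p-values to
`q = min(P·m/r, 1)` with `r` the ascending rank (ties share the lower
rank).  This is deliberately the plain quotient form; the standard
step-up monotonicity correction is available behind a flag but off by
default.  `significant_links` ranks surviving links by descending
absolute MCI statistic — meaningful because of the statistic's
causal-strength interpretation.

## Causal-effect estimation

For linear models the average causal effect of `X^i_{t−τ} → X^j_t` is the
driver's coefficient in a regression of the target on a valid adjustment
set; significance is the drop-one-term F-test (equal to the two-sided
t-test for the single dropped term).  `ce_corr` uses no adjustment (on
standardized data it is the lagged correlation — biased by indirect paths
and common drivers, spanning anywhere from ~0 to well above the true
coefficient for links of identical strength), `ce_full` adjusts on the
whole past (unbiased but high-variance), `ce_pcmci` adjusts on the
estimated parents of the target (unbiased when the parent set is correct,
with far fewer regressors, hence lower variance and higher detection
rates), and `ce_true` is the oracle reference on the generating parents.

Scale convention: the regression coefficient estimates the structural
coefficient `c` on the *raw* data scale.  On standardized data every
effect is rescaled by `σ_parent/σ_target`, which spreads the distribution
across variables with heterogeneous autocorrelation; comparisons against
generating coefficients are therefore made on raw data, while `ce_corr`
is interpreted on standardized data.

## Synthetic models and the population oracle

The generator covers (i) the fixed worked example: six variables in three
independent driver→target pairs, cross-coupling `c = 0.15` at lag 2,
autoregressive coefficients 0.1/0.1, 0.5/0.5, 0.9/0.9, unit-variance
standard-normal noise everywhere (the original states standard-normal
noise explicitly only for the constructed Z-variable; we apply it
uniformly); (ii) random benchmark networks: every variable gets a lag-1
autodependency drawn from {0.1, …, 0.9} (spanning the weak/strong split
at 0.7) and `L` distinct cross-links drawn uniformly over ordered pairs
and lags 1…`max_lag` with coefficient ±`coeff_abs` (random sign, equal
magnitude ⇒ equal causal strength), redrawn until stationary (at most 100
attempts); and (iii) a constructed confounder column
`Z_t = 2·driver_{t−1} + η`.  Nonlinear links apply `f(c·parent)` with
`f ∈ {u², tanh}` — configurable, since the exact benchmark nonlinearities
of the original study are not fixed here.  Simulation discards a burn-in
of `10·max_lag + 100` steps (geometric mixing is fast for |a| ≤ 0.9) and
aborts if any value exceeds 1e8.

For linear models the exact stationary covariance of the stacked vector
`(X_t, …, X_{t−w})` comes from the companion-form VAR and a discrete
Lyapunov solve; population partial correlations follow from the precision
matrix of the relevant submatrix.  This oracle is what turns the worked
example's printed effect sizes into analytic statements: whole-past
conditioning gives 0.148/0.133/0.111 for the three pairs (rounding to
0.15/0.13/0.11), while parent conditioning gives `c/√(1+c²) = 0.1483` for
all three — the autocorrelation-invariance of the MCI statistic.

What the generator does *not* emulate: observational (measurement) noise,
nonstationary trends and regime shifts, seasonality, deterministic
chaotic dynamics, missing data, and unobserved confounders.  Passing
tests therefore demonstrate correctness of the estimators under the
stated model class, not robustness to those real-data features.

## Benchmark harness

`link_detection_rates` simulates `n` realizations, runs a method on each
and counts per-link detections at level α.  Conventions: only cross-links
are reported (auto-links excluded); a true pair detected at a wrong lag
counts as a false positive (lag-strict, the stricter reading); links are
grouped by the mean *generating* lag-1 coefficient of the pair against
0.7 (noiseless group assignment).  `compare_methods` evaluates every
method on identical realizations (paired seeds derived from the model
index only) and summarizes per-link TPR/FPR distributions.

## Problem sizes used in the shipped checks

The shipped test suite runs the quantitative checks at desk scale chosen
once for this package: false-positive calibration on 100 realizations of
five AR(1) processes per autocorrelation regime at T = 500; graph
recovery on 100 random N = 5 networks at T = 2000 (AIC-selected `α_PC`,
Bonferroni-corrected threshold, cross-link graph); power ordering against
FullCI on N = 10, L = 10, T = 150 networks (2 topologies × 50
realizations); effect-estimation ordering on N = 20, T = 150, c = 0.3
over 100 networks; GPDC/CMI calibrations at 40–100 repetitions with 99
surrogates.  The finite-sample cross-check of the worked example uses a
single T = 10⁶ realization (sampling error ≈ 0.001 ≪ the 0.01
tolerance).  Exact graph recovery is assessed at the Bonferroni level
`0.05/(N²τ_max)` because at a raw 5% level the expected number of false
positives among 75 tested links is ≈ 3.5, making exact recovery a
family-wise, not per-link, property.

## Known limitations

* Causal sufficiency, stationarity, faithfulness and the absence of
  contemporaneous effects are assumed, not tested.
* GPDC's null calibration assumes the GP residuals are approximately
  independent normal under H0; heavy-tailed noise or a badly fit kernel
  will miscalibrate it.
* The CMI test inherits the k-NN estimator's bias at small n and large
  condition dimension; with `k_perm` too large the surrogates break the
  x–Z dependence and the test becomes conservative.
* FullCI (and `ce_full`) are undefined once `N·τ_max` reaches the sample
  count; the package raises instead of silently regularizing.
* The AIC selection of `α_PC` is defined for the linear test only.
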