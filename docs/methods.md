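# Methods

## Data-generating model

Examinees are simulated from the continuous-trait model. Abilities for
N examinees are drawn from a K-variate normal with mean zero, unit
variances, and a single equicorrelation r between every subskill pair
(positive definite for −1/(K−1) < r < 1; for K = 3 the determinant is
(1−r)²(1+2r)). Responses are Bernoulli under the compensatory
multidimensional 3PL,

    P(X_ij = 1 | θ_i) = c_j + (1 − c_j) · σ(a_j·θ_i + d_j),

with σ the logistic function **without** the 1.7 scaling constant —
the packaged item parameters are on the logistic metric. The packaged
instrument has J = 30 items and K = 3 subskills (retrieving
information, straightforward inference, integrated inference); 14, 14
and 11 items load on the three subskills respectively, 39 loadings in
all, with nine two-attribute items. Guessing parameters range from
0.07 to 0.56 and intercepts from −0.53 to 5.01 — several items are
answered correctly by over 95% of simulated examinees, which matters
for what is estimable (see *Limitations*).

Study-design defaults: r ∈ {0.1, 0.3, 0.5, 0.7, 0.9}, N = 3,000, 25
replications per condition. The `desk` preset (N = 1,500, 5
replications, 11-point quadrature) exists so a full condition runs in
about a minute on one CPU; pooled classification rates at that scale
have a standard error below 0.01, comfortably inside the 0.03
tolerance used by the reproduction tests. The test suite's shared
fixture uses 3 replications for the same reason.

Seeding: condition r, replication t draws abilities with seed
`base + round(100r)·10⁴ + t` and responses with the same seed offset
by 5·10⁵. Replications are therefore order-independent work units and
every table is reproducible from the config alone.

### What the generator does and does not emulate

It reproduces the study conditions exactly: equicorrelated multinormal
abilities, complete binary responses, fixed instrument. It does not
model testlet effects or other local dependence, polytomous responses,
missingness, or person misfit. Results on simulated data therefore
speak to model-induced information loss under a correctly specified
continuous-trait world, not to robustness against such real-data
features.

## MIRT engine

Marginal maximum likelihood via EM on a fixed rectangular grid:
`quad_points` equally spaced nodes per dimension on [−5, 5] (default
15, i.e. 3,375 nodes for K = 3), with prior weights proportional to
the multinormal density at the nodes, normalized. The E-step computes
each person's posterior over the grid; the M-step maximizes the
expected complete-data log-likelihood item by item with L-BFGS-B and
analytic gradients (slopes bounded to [0, 8] on the Q-matrix support,
intercepts to [−20, 20]).

*Guessing.* Unpenalized 3PL lower asymptotes are weakly identified, so
c_j is estimated on the logit scale under a normal prior with mean
logit(0.2) and sd 1.0 (configurable, or fixed at supplied values). The
EM objective including this prior is what the monotonicity guarantee
applies to.

*Latent density.* Three modes: `identity` (fixed standard multinormal;
parameter count nnz(Q) + 2J = 99 for the packaged instrument, matching
the convention that counts only item parameters), `fixed` (supplied
correlation matrix), and `estimated` (unit variances, correlations
re-estimated each cycle from the posterior second moments on the grid,
clipped to ±0.99; adds K(K−1)/2 parameters). The study driver defaults
to `estimated`, since the accuracy gains of MIRT at high subskill
correlation come precisely from exploiting the estimated correlations
in EAP scoring.

*Convergence.* EM stops when the largest absolute parameter change
drops below 1e−4 or after `max_iter` cycles (driver default 300); a
non-converged run is returned flagged, not raised. At r = 0.9 the
correlation/slope ridge makes the last decimal slow — runs typically
stop near 8e−4 with classification output indistinguishable from
converged runs. Probabilities are clipped to [1e−9, 1 − 1e−9] inside
likelihoods.

*Scoring.* EAP (posterior mean on the grid) under the fit's latent
density; mastery probabilities are Φ(EAP) — the population-marginal
transform of the reported score vector, not the posterior probability
of exceeding a θ threshold.

*Fit indices.* −2LL, AIC = −2LL + 2p, BIC = −2LL + p·ln N, and the
limited-information M2 on univariate and bivariate margins: the
statistic is N·e′Ce with e the residual of sample vs model margins,
C the reduced weight matrix built from the asymptotic margin
covariance Ξ (entries assembled from model-implied joint probabilities
up to order four, computed by quadrature) and a finite-difference
Jacobian of the margins in the free parameters. df = J(J+1)/2 − p,
RMSEA = sqrt(max(M2 − df, 0)/(df·N)) with N (not N − 1) in the
denominator; a singular Ξ triggers a flagged ridge fallback. Null
simulations at small J show M2 tracking the chi-square(df) reference.

## CDM engines

Both models run EM over the 2^K attribute patterns in canonical
lexicographic order ((0,…,0) first) with a **saturated structural
distribution** (2^K − 1 free proportions, updated as the mean
posterior), which reproduces the conventional parameter counts of 85
(G-DINA) and 76 (R-RUM) on the packaged instrument.

*G-DINA* (identity link, saturated): one success probability per
reduced pattern of each item's required attributes; closed-form M-step
(posterior-weighted success proportions), probabilities clipped to
[1e−4, 1 − 1e−4]. An empty expected count leaves the parameter at its
previous value with a warning. No monotonicity constraints are imposed
beyond clipping; a post-hoc `monotonicity_report` lists violations
instead. Start values are spaced 0.2 → 0.8 by the number of mastered
required attributes.

*R-RUM*: baseline π\*_j and penalties r\*_jk, maximized per item on
the logit scale by bounded quasi-Newton (start π\* = 0.8, r\* = 0.4).

*Classification.* MLE (argmax of the response likelihood over
patterns, structural proportions excluded — the rule used for all
classification results) or MAP (argmax of the posterior). Ties break
toward the earliest canonical pattern and are counted on the fit.
Posterior mastery probability of subskill k is the posterior mass of
all patterns with α_k = 1.

## Classification statistics

A person is a master when mastery probability ≥ cut-off — equality
counts as mastery, the convention forced by treating a true
probability of 0.11 as mastery at cut-off 0.10. The cut-off grid is
0.10 to 0.90 in steps of 0.01 (81 values). SCCR is computed both per
subskill (used for every subskill-1 reproduction) and averaged over K;
PCCR ≤ min_k SCCR_k always, since whole-row agreement implies cellwise
agreement. Estimated CDM states do not vary with the cut-off — only
the true and MIRT states do — so a latent-class model's SCCR curve
peaks where the cut-off makes the true mastery proportion match the
model's estimated mastery proportion (≈ 0.63–0.66 on subskill 1),
while MIRT's curve dips near the middle of the probability scale and
rises toward the extremes.

Histograms of mastery probabilities use equal-width half-open bins on
[0, 1] with the final bin closed; 50 bins by default. True
probabilities Φ(θ) are exactly uniform, the "flat line" reference. The
U-shape check on CDM posteriors uses decile bins (the two extreme
deciles hold over half the posterior mass at study settings; with 50
bins the extreme bins alone hold about a quarter, the shape being
spread over several near-extreme bins).

## Numerical and design choices

- Items and persons are 0-indexed internally, 1-indexed in outputs.
- CSV everywhere: comma-separated, UTF-8, header row required.
- MIRT parameter counting excludes latent correlations unless the
  `estimated` mode is in use, and excludes guessing when it is fixed.
- The brute-force oracles (dense-grid integration at ≥ 10,001 points,
  full latent-class enumeration, loop-based rates, random-restart
  likelihood bounds) share no code with the engines; every
  engine-vs-oracle test routes through `skilldiag.oracles`.

## Limitations

- Slope recovery on the packaged instrument is information-limited:
  items answered correctly by ≳ 95% of examinees (intercepts near 5)
  carry almost no slope information at N = 3,000, so single-run slope
  RMSE sits around 0.15–0.2 even with guessing fixed at truth, and the
  true/estimated slope correlation hovers at 0.89–0.93 across
  datasets. Classification accuracy is insensitive to this (EAP
  ordering is preserved), which is why the SCCR surfaces reproduce
  tightly while item-level recovery is marginal.
- With guessing estimated, the logit-normal prior trades bias on
  high-c items (the instrument's largest is 0.56) against variance
  elsewhere; runs needing exact item-parameter comparisons should fix
  guessing.
- No exploratory/rotated MIRT, bifactor or testlet structure, no
  DINA/DINO/ACDM variants, no polytomous responses or missing data,
  and no standard-setting procedure for choosing an operational
  cut-off.
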