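# Methods

## Model and assumptions

Cities are modelled as populations of G demographic groups whose
members interact at rates shaped by group identity.  Per-capita
interactions scale as N^δ (δ = 1/6, the reference exponent of urban
scaling theory); a within-group boost h_in raises same-group contact
and a between-group reduction h_bet lowers cross-group contact, with
every group assumed to avoid all out-groups at the same rate (one h_bet
per group, no pairwise avoidance matrix).  Mean implicit bias follows a
power-law learning curve of between-group exposure, b ~ k_inter^(−α)
with learning rate α ∈ (0, 1).  For two groups this gives

    b = C · N^(−δα) · (f₁ − f₁²)^(−α) · (2 − h₁ − h₂)^(−α),

and all inference happens on logarithms.  The between-group reductions
are not observable; they are proxied linearly by residential
segregation, h_g = h_bet + b_bet·s_g, where s_g is one of four aspatial
indices computed from census-tract-level counts.  All proportionality
constants are explicit parameters (prefactor, default 1) so the forward
model is deterministic and its log is exactly linear in
[ln N, ln(f₁ − f₁²), ln(2 − h₁ − h₂)] with coefficients
(−δα, −α, −α).

The model is ecological: it predicts city means, not individuals, and
it is correlational — the pipeline's precedence tests probe temporal
ordering, not causation.

## Segregation indices

Four measures per group from the M × 2 tract table: mean deviance
(unweighted mean absolute deviation of tract shares from the city
share), dissimilarity (tract-population-weighted and normalized), the
segregation Gini (pairwise mean absolute share difference, computed via
the sorted-cumulative-weight identity in O(M log M); the naive double
loop survives as a test oracle), and the correlation ratio η²
(isolation index rescaled to [0, 1]).  A printed variant of η² that
omits the per-tract totals from the sum is exposed behind
`literal=True`; it is not a normalized index (it fails the
even-distribution-zero and complete-segregation-one checks) and exists
only for comparison.  Tracts with zero population are rejected rather
than skipped, because silently dropping them would change M in the mean
deviance.

## Two-stage inference

Stage one: OLS of ln b on ln N, unweighted (cities equally weighted; a
respondent-count weighting exists but is off by default).  Cities enter
when their observation has more than `min_responses` respondents
(default 500; 250/1000 as robustness alternates).  Stage two: OLS of
the stage-one residuals on the diversity adjustment ln(f₁ − f₁²) and
the segregation regressor s₁ + s₂, which arises from the linearization
ln(2 − x) ≈ ln 2 − x/2 (error < 0.01 for x ≤ 0.26) with the proxy
constants absorbed into the fitted coefficients.  Learning rates:
α̂_scaling = −β₁/δ (δ fixed at 1/6, exposed as a parameter, not
estimated jointly) and α̂_diversity = −β₂; the signs are chosen so a
positive learning rate means bias falls with exposure.  CIs for the α̂s
are linearly transformed coefficient CIs (exact for a scalar multiple).

Two caveats are documented rather than hidden.  First, the two-stage
estimates equal a joint regression only when the stage-two regressors
are uncorrelated with ln N in the sample; correlated designs introduce
O(1/n) differences.  Second, variance shares are nested-model R²
increments averaged over the two addition orders and rescaled to the
ln b variance, so the three shares sum to the total model R².  When the
two stage-two regressors are correlated (as they are in random worlds,
where unevenness covaries with composition), the order-averaging splits
their shared variance between them; the shares isolate unique
contributions only in orthogonal designs.  A regressor with zero sample
variance is dropped with a warning and reported with coefficient and
share 0.

VIFs are 1/(1 − R²_j) from regressing each column on the others;
perfect collinearity reports infinity rather than raising.  The
individual-level model is a logistic regression of 1{D-score > 0} on
city-level ln N, diversity adjustment and segregation sum plus
respondent race (recoded to White/Black/Multiracial vs a combined base),
education (14-point code collapsed to three bands at cuts 6/11 —
configurable, since the band boundaries are a convention) and birth
sex; empty categories are dropped with a warning and a degenerate
outcome raises instead of returning a silent estimate.  No
multiple-testing correction is applied across years or measures: the
repeated fits test one hypothesis on separate datasets.

## Synthetic worlds

The generator is the package's study design, not a tuning knob.  Its
defaults: 150 cities; populations log-uniform on [5·10⁴, 2·10⁷]
(spanning the CBSA range); tract size 4,000; majority fraction uniform
on [0.55, 0.95]; unevenness level uniform on [0.02, 0.3]; α = 0.2
(the midpoint of plausible diversity-coefficient magnitudes), δ = 1/6,
h_bet = 0.1, b_bet = 0.5; log-additive bias noise 0.1; respondent-level
SD 0.4 around the city mean.

Tract group shares are Beta distributed with mean equal to the target
composition and concentration κ = (1 − s)/s, so the unevenness knob s
is the large-tract limit of the correlation ratio (s = 0 gives a
perfectly even city, s → 1 single-group tracts).  Counts are
integer-rounded by capped largest-remainder apportionment, conserving
group and city totals exactly.  The realized composition is whatever
the drawn shares imply — rescaling to a pre-set composition would
destroy the drawn unevenness — so at extreme unevenness with few tracts
a single-group city can arise; such cities are excluded from bias
generation with a logged warning, mirroring the real-data hazard of
zero-diversity cities.

What the generator does not emulate: spatial arrangement of tracts (the
indices are aspatial by design), migration dynamics, respondent
self-selection, or any empirical size/segregation distribution beyond
the stated ranges.  Passing tests therefore validate the statistical
machinery under the model's own assumptions, not the model's fit to
real cities.

Noise-free exact-recovery checks use a fully crossed design
(`crossed_cities`): 15 two-tract templates (5 compositions × 3
unevenness spreads) at a common base population, each replicated at 10
geometric population scales by integer multiplication.  Because the
indices and fractions are scale invariant, composition and segregation
are exactly orthogonal to ln N in that sample, and with the
`linearized=True` generation option (which uses the same linearized
segregation factor the regression embodies) the two-stage fit recovers
α to machine precision.  Default generation uses the exact
(2 − h₁ − h₂)^(−α) factor; the replicate studies that assess coverage
generate from the linearized form so the estimator is calibrated
against its own model.

## Noise ceiling

For each of `n_splits` (default 500) random partitions of each city's
respondents into halves, per-city half means are correlated across
cities: between halves (lower bound) and each half against the
full-sample mean, averaged (upper bound), then averaged over splits.
Pearson correlations by default (the R² framing is variance-based);
Spearman by flag.  Odd respondent counts assign the extra respondent to
a half uniformly at random per split.  With between-city SD τ,
within-city SD σ and n respondents per city, the lower bound converges
to τ²/(τ² + 2σ²/n).  Because each half overlaps the full sample, the
upper bound does not vanish under pure noise (it tends to 1/√2); it is
an upper bound, not an unbiased estimate.  The noise-corrected R² is
reported as R² divided by the squared lower bound.

## Temporal precedence

Per city and lag L, the restricted model regresses y_t on an intercept
and y_{t−1..t−L}; the unrestricted model adds x_{t−1..t−L}.  Both
sum-of-squared-residual statistics are computed: the asymptotic χ²
variant (nobs·(SSR_r − SSR_u)/SSR_u, L df) and the F variant, which is
exact under iid normal errors with exogenous x.  On 10-point series the
χ² variant rejects ~16% of true nulls at the 5% level, so the F variant
is the default decision rule for the percentage summaries; the χ² is
returned alongside.  Variables are tested on the transformed scales
used in fitting (ln N, diversity adjustment, segregation sum, ln b),
with no differencing (the panels are too short for stationarity
pre-processing to be meaningful).  With T time points the all-lags form
needs T ≥ 3L + 2, so lag 3 requires at least 11 years; a 10-year panel
supports lags 1 and 2 only, and requesting more raises an informative
error.  Null calibration is near-exact when the predicted series is
stationary; when it is integrated (a random walk), the small-sample
rejection rate roughly doubles — a generic caveat for Granger tests on
very short panels.  Percentages of significant cities are summarized
with a bootstrap-over-cities standard error (default 1000 resamples),
and standard errors across the four segregation measures combine as the
root mean square.

## Numerical and design choices

* Seeded determinism everywhere: every generator and every resampling
  procedure is a pure function of its arguments and seed; the CLI
  pipeline report is byte-identical across runs with the same seed.
* CSV I/O is loss-free: integers exact, reals written at full `repr`
  precision and parsed with round-trip float parsing.
* Degenerate inputs raise typed, specific errors (zero-diversity vs
  over-segregated cities, empty tracts, constant series, degenerate
  logistic outcomes) rather than propagating NaNs.
* Replicate-study sizes (500 replicates of 150 cities for coverage;
  2000 replicates for null calibration; 40 experiment seeds for
  precedence power) were chosen to keep Monte-Carlo error well below
  the effect sizes being checked while completing in about a minute
  each on a single core.

## Known limitations

* The multi-group bias formula is implemented only as the interaction
  decomposition; the bias pipeline is two-group, matching the IAT's
  White/Black contrast.
* The two-stage procedure inherits the ordering asymmetry of
  residual-on-residual regression; joint-fit comparisons are asserted
  only for orthogonal designs.
* The noise-ceiling upper bound is overlap-inflated by construction
  (see above).
* Precedence tests on 10-point integrated series are at the edge of
  what the asymptotics support; results there are calibrated for
  stationary targets and conservative interpretation is advised.
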