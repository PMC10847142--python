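# urbanbias

Why do people in some U.S. cities carry stronger implicit racial biases
than in others?  A complex-systems answer links three structural facts
about a city — its population size, its demographic diversity, and its
residential racial segregation — to the amount of inter-group contact
its residents experience, and through a learning curve, to the average
level of implicit bias measured by the racial Implicit Association Test
(IAT).  This package implements that model and its full statistical
pipeline as a tested, reusable analysis, exercised end to end on a
synthetic-city generator so that no census or IAT download is required.
It is written for quantitative social scientists and urban-science
researchers who want to fit, stress-test, or extend the model.

## The model

Urban scaling theory gives per-capita social interactions k ~ N^δ with
δ = 1/6.  With G groups of fractions f_g, a within-group boost h_in and
a between-group reduction h_bet per group, per-capita interactions split
into

    k = N^δ [ Σ_g f_g²(1 + h_in_g) + Σ_g Σ_{j≠g} f_g f_j (1 − h_bet_g) ].

Treating implicit bias b (a mean IAT D-score) as a cognitive processing
cost that declines with out-group exposure along a power-law learning
curve b ~ k_inter^(−α), the two-group case factorizes into a scaling
term, a diversity term, and a segregation term:

    b = C · N^(−δα) · (f₁ − f₁²)^(−α) · (2 − h₁ − h₂)^(−α),

with h_g = h_bet + b_bet·s_g proxied linearly by a residential
segregation measure s_g.  Inference is a two-stage OLS on logs:

    ln b_i = C + β₁ ln N_i + ε_i                       (scaling stage)
    ε_i    = C₂ + β₂ ln(f₁ − f₁²) + β₃ (s₁ + s₂) + ξ_i  (adjustment stage)

yielding two independent learning-rate estimates, α̂_scaling = −β₁/δ and
α̂_diversity = −β₂.  Around this core the package provides the four
classic aspatial segregation indices (mean deviance, dissimilarity,
Gini, correlation ratio), split-half noise-ceiling estimation for the
city means, Granger-style temporal-precedence tests on multi-year city
panels, and an individual-level logistic control model.

## Worked example

The numbered scripts under `analysis/` run the whole study on a
synthetic world of 150 cities drawn from the forward model
(δ = 1/6, α = 0.2, log-multiplicative noise 0.1):

```sh
python analysis/01_simulate_cities.py --seed 1
python analysis/02_segregation_indices.py
python analysis/03_fit_learning_rates.py
```

which prints, among other things:

```
fit on 150 cities (mean-deviance measure) -> results/fit.json
beta1 = -0.0297  (CI -0.0419 .. -0.0175)
beta2 = -0.2209  beta3 = +0.2322
alpha_scaling  = 0.1784  (CI 0.1051 .. 0.2517)
alpha_diversity = 0.2209  (CI 0.1748 .. 0.2669)
variance shares: {'scaling': 0.135, 'diversity': 0.327, 'segregation': 0.043}
max VIF across measures: 1.63
```

Both learning-rate estimates bracket the generating α = 0.2 and their
confidence intervals overlap — the model's convergent-estimates
property.  β₁ < 0 is the bias scaling slope (−δα = −1/30 under the
model); the negative β₂ says more diverse cities have lower bias; the
variance shares decompose the explained variance of ln b across the
three structural factors.  `04_noise_ceiling.py` then bounds the
explainable variance given respondent-level noise, and
`05_temporal_precedence.py` shows that when structural change drives
bias at a one-year lag, the forward precedence percentage dominates the
reverse one.  The same stages are available as a CLI
(`urbanbias simulate|segregation|fit|noise-ceiling|precedence|pipeline`);
`urbanbias pipeline --seed S` is byte-reproducible.

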