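# Methods

This note documents the statistical machinery in `sf36map`: the models, the
numerical choices, what the synthetic cohorts do and do not emulate, and the
design decisions taken where the problem is genuinely open.

## The mapping problem

The EQ-5D-3L describes health as five dimensions (mobility, self-care,
usual activities, pain/discomfort, anxiety/depression), each at level 1
(no problems), 2 (some/moderate) or 3 (extreme). A country-specific value
set converts a state into a utility anchored at 1 (full health, 11111) and
0 (death); severe states can score below 0. The SF-36 yields eight 0–100
domain scores (PF, RP, BP, GH, VT, SF, RE, MH) and two norm-based summaries
(PCS, MCS). Mapping estimates the EQ-5D utility from the SF-36, so QALYs
can be computed for datasets that collected only the profile instrument.

## Value-set scoring

The canonical tariff form is the additive N3 model:

    U(s) = 1 − c·1[s ≠ 11111] − Σ_d δ_d(level_d) − n3·1[any level 3]

with all decrements ≥ 0, so U(11111) = 1 exactly and worsening any single
dimension never increases utility. The packaged default is the Korean TTO
value set (c = 0.050, n3 = 0.050, level-3 decrements summing to 1.071),
which scores 33333 at exactly −0.171. The loader verifies both anchors for
any tariff declaring itself `korea` and supports a generic 243-row lookup
for non-additive value sets. Utilities are never clipped or truncated at 0:
"worse than death" values are meaningful and retained.

## Design matrices

The specification ladder m1–m6 covers the model sets used in crosswalk
practice: all eight domain scores (m1), the same with backward elimination
(m2), plus squared terms (m3), plus demographics (m4), PCS + MCS (m5), and
PCS, MCS, their squares and interaction (m6). Columns are ordered
[intercept, main effects, squared, interactions, demographics].

Score covariates are divided by `scale_divisor` (default 10) before any
squaring or interaction. The choice is numerical, not substantive: /10
keeps squared-term magnitudes comfortable, and OLS is exactly equivariant
to the divisor (rescaling coefficients by powers of d reproduces divisor-1
predictions to 1e−10; this is a tested contract). Demographics are never
scaled; sex/education/marital status are dummy-coded against the first
observed category, age enters linearly. Missing or out-of-range scores
reject the row with an itemized reason — never imputation.

## OLS with cluster-robust variance

β solves the normal equations; the covariance is the cluster sandwich
c·(XᵀX)⁻¹ [Σ_g Xgᵀe_g e_gᵀX_g] (XᵀX)⁻¹ with the CR1-style factor
c = [G/(G−1)]·[(n−1)/(n−k)]. With every observation its own cluster this is
identically HC1 (tested); with fewer than two clusters the estimator falls
back to HC with a warning. Wald p-values use the standard-normal reference
by default (a t with G−1 degrees of freedom is available via `use_t`) and
robust — not classical — variances, matching the fitting assumption.

Backward elimination removes one term per refit — the non-intercept term
with the largest robust-Wald p-value — while any p ≥ α (default 0.05).
Elimination is deliberately **non-hierarchical**: a squared term may outlive
its main effect, since published crosswalk fits retain such patterns and no
hierarchy rule is standard here. Ties on p are broken by dropping the later
column in design order, for determinism. In simulation with five null
predictors at α = 0.05 the per-term retained-spurious rate is ≈ 0.056
(independent statsmodels-based oracle; the package reproduces it within
binomial error).

Predictions are unclipped by default — OLS happily predicts above 1 at the
healthy end, and reporting that honestly is informative; clipping to
[−0.171, 1] is an explicit flag.

## Two-part model

The index has a large point mass at 1 (the "ceiling"; 43% in the mixed
derivation data the presets emulate). Part 1 is a logistic regression for
P(y = 1), fitted by Newton/IRLS with step-halving, so the (penalized)
deviance is monotone non-increasing across iterations; convergence is a
relative log-likelihood change below 1e−8, max 100 iterations. Suspected
perfect separation (diverging coefficients) triggers a ridge-penalized
refit (λ = 1e−4 on non-intercept terms) with a warning. Part 2 is
cluster-robust least squares on the y < 1 subset, sharing the design.

Combination rule: the default is the two-part expectation
E[y|x] = p̂ + (1 − p̂)·ŷ₂, the standard in two-part econometrics. A
classify-then-predict rule (predict exactly 1 when p̂ ≥ threshold, else ŷ₂)
is selectable by flag: published two-part crosswalks whose predicted maxima
are exactly 1.000 are consistent with such a rule, and since the literature
does not pin the combination down, both are first-class and the choice is
recorded with the fit.

## Multinomial response mapping

Each dimension j gets a 3-level multinomial logit (reference level 1),
fitted by Newton through `statsmodels.MNLogit`; a dimension observed at
only two levels collapses to a binary logit with a warning, and separation
falls back to a ridge-penalized fit. The headline pseudo-R² is McFadden's
1 − ℓ_model/ℓ_null (Cox–Snell and Nagelkerke are also computed, since the
variant used in published work is often unidentifiable).

Level assignment uses the inverse-CDF rule on a uniform draw u:
level 1 iff u ≤ P₁; level 2 iff P₁ < u ≤ 1 − P₃; level 3 otherwise, with
the boundary cases inclusive exactly as stated. For any (P₁, P₃) on the
simplex the three level sets partition [0, 1] with measures
(P₁, 1 − P₁ − P₃, P₃) — a tested property. One independent uniform is drawn
per subject **per dimension** (five per subject): the per-dimension reading
of the draw index matches the model's independence-across-dimensions
assumption, which is explicit — the joint state distribution is the product
of the five marginals, and dependence between dimensions is out of scope.
The default is a single simulation (`n_draws=1`), mirroring how response
mapping is typically deployed; `n_draws > 1` averages utilities over draws
for variance assessment. The RNG is numpy's seeded `default_rng`; a seed is
required for every stochastic entry point.

Because simulated states are scored through the tariff, MNL predictions
always lie in [min tariff value, 1] — the only family of the three with
that guarantee.

## Validation metrics

MAE = mean |o − p|, RMSE = √(mean (o − p)²) (so MAE ≤ RMSE always, with
equality iff all absolute errors are equal), and the proportions of
predictions with absolute error **strictly** greater than 0.05 and 0.1 —
an error of exactly 0.05 does not count toward its threshold. R² is
reported only for linear fits; MNL models carry the per-dimension
pseudo-R² range instead; no global analogue is improvised for the two-part
model. For context, 0.05–0.1 brackets the minimal important difference
(≈0.074) usually quoted for the EQ-5D index.

## Published coefficients and the scale caveat

The six published OLS crosswalk models are shipped exactly as printed
(coefficients, SEs, non-significance flags), protected by a checksum test.
The source does not state the covariate units used at fit time, and neither
candidate convention is self-consistent: evaluated at the source's own
reported covariate means, model m1 predicts ≈ 3.85 under raw 0–100
covariates and ≈ 0.40 under /10 covariates, against a reported predicted
mean of 0.816. The intended units (or a misprint) cannot be recovered from
the publication, so `crosswalk()` has **no default convention**: the caller
must choose `raw` or `div10`, and every prediction is paired with a
mandatory caveat record. This refusal-to-guess is deliberate — a silent
default would produce plausible-but-unverifiable utilities.

## Synthetic cohorts

A single latent health factor h = μ + b_g + e_i (cluster effect
b_g ~ N(0, 0.3²), individual e_i ~ N(0, 1)) drives both instruments:

* domain scores and PCS/MCS are linear in h with Gaussian noise, truncated
  to [0, 100] (truncation, not resampling, so the generator exhibits mild
  instrument ceilings like real SF-36 data);
* dimension levels follow a proportional-odds link
  P(level ≤ k | h) = σ(c_k + s·h), realized by one uniform per subject per
  dimension; the index is then scored from the levels through the tariff,
  making levels and index consistent by construction.

Preset parameters were calibrated once, by simulation at n = 30 000,
against the cohort summaries of the original derivation data: general
population (target index mean 0.945, ceiling 65.4% → achieved ≈ 0.944,
≈ 68%), diabetes (0.914, 53.1% → ≈ 0.905, ≈ 53%), stroke (0.513, 3.4% →
≈ 0.508, ≈ 5%), and `mixed` concatenates the three in the source 448 : 770 :
442 proportions. Domain-score links are anchored at the general/stroke
published means. The calibrated thresholds and latent means are frozen
constants; they are study conditions, not tuning knobs.

What the generator does **not** emulate: real sampling designs and
nonresponse, multi-factor structure (physical vs mental health as separate
factors), dependence between EQ-5D dimensions beyond what the shared latent
factor induces, and item-level SF-36 behaviour. Passing recovery and
workflow tests on these cohorts therefore demonstrates the estimators'
correctness under the assumed single-factor mechanism, not the empirical
accuracy of any particular published crosswalk on real patients.

An optional `true_mapping` adds a `Y_TRUE` column generated from a known
linear model of the scores; recovery tests fit that model back and check
per-coefficient bias (< 0.01 at n = 10 000) and CI coverage (≥ 93% of
replicates inside ±1.96 SE, 200 replicates).

## Problem sizes and numerics

The test suite and the acceptance script use survey-scale cohorts
(n ≈ 1200–2211 for workflow checks, n = 10 000 for bias checks, 200
replicates for coverage and elimination operating characteristics,
50 000 draws for Monte-Carlo convergence against the exact 243-state
expectation Σ_s Π_j P_{level_j(s)} U(s)). Logistic/MNL convergence
tolerances are 1e−8 (relative log-likelihood) with ridge fallbacks at
λ = 1e−4; rank deficiency in OLS designs is detected via QR and reported
by column name rather than silently pseudo-inverted.

## Known limitations

* Out-of-scope by design: scoring the 36 raw SF-36 items into domain or
  summary scores (a licensed norm-based algorithm), EQ-5D-5L states and
  3L↔5L crosswalks, VAS scoring, CLAD/Tobit/GLS/Bayesian-network mapping
  families, and inference on MAE differences between models.
* The cluster-robust logistic part uses the model-based (information)
  covariance, not a clustered sandwich.
* Mapped utilities are a second-best substitute for directly collected
  EQ-5D data; uncertainty in mapped utilities is generally underestimated,
  and this package does not implement a variance-correction procedure.
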