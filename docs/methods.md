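# Methods

This note records the model, the algorithmic conventions, the simulator's
generative assumptions, and the numerical and design choices behind
`emacat`, in the spirit of a statistical software methods appendix.

## Measurement model

Responses are modeled by a multidimensional graded response model (MGRM)
over m latent domains (m = 14 by default: 12 risk domains plus passive and
active suicidal ideation). For item j with discrimination vector
aⱼ ∈ ℝᵐ (sparse; nonzero only on loaded domains) and intercepts
dⱼ₁ > dⱼ₂ > dⱼ₃ > dⱼ₄, boundary probabilities are cumulative logits

    P*ₖ(θ) = logistic(aⱼ·θ + dⱼₖ),   P*₀ ≡ 1, P*₅ ≡ 0,

and category probabilities pₖ = P*ₖ₋₁ − P*ₖ for the five Likert responses.
Two conventions worth making explicit:

- **Slope/intercept parameterization.** The intercept form (aⱼ·θ + dⱼₖ) is
  used rather than slope/difficulty (aⱼ·(θ − bⱼₖ)) because it is the
  natural multidimensional generalization — a scalar difficulty has no
  unique meaning against a vector slope. Strictly decreasing intercepts
  guarantee strictly positive category probabilities.
- **Logistic link with D = 1.** No 1.7 normal-ogive scaling constant is
  applied. Parameters calibrated under a D = 1.7 convention must be
  multiplied by 1.7 before import.

Expected (Fisher) item information is the rank ≤ 1 matrix

    Iⱼ(θ) = gⱼ(θ) aⱼaⱼᵀ,   gⱼ = Σₖ (wₖ₋₁ − wₖ)² / pₖ,   wₖ = P*ₖ(1 − P*ₖ),

with w₀ = w₅ = 0. Expected information is used everywhere — selection,
stopping, posterior precision — because D-optimality and the ellipsoid
stopping rule are defined on it. Category probabilities are floored at
1e-10 inside information and log-likelihood evaluations so extreme θ cannot
produce division blow-ups.

## Scoring

θ̂ is the posterior mode (MAP) under the multivariate normal prior
N(μ, Σ), with μ = 0 and Σ the calibrated interfactor correlation matrix by
default. The optimizer is damped Newton ascent with the analytic gradient
and the expected-information Hessian surrogate H = Σ⁻¹ + Σⱼ Iⱼ(θ), which is
positive definite by construction, so every step is an ascent direction;
step halving (up to 40 halvings) guards the far field. Convergence is
declared at gradient norm < 1e-6 with a 200-iteration cap; non-convergence
raises an error carrying the best iterate. The procedure is deterministic
given (responses, start), and with no responses returns the prior mean
exactly.

The accumulated information Σ⁻¹ + Σⱼ Iⱼ(θ̂) is stored alongside its
prior-free part Σⱼ Iⱼ(θ̂); the former is inverted for posterior standard
deviations, the latter feeds the D-rule determinant.

## Adaptive administration

- **Warm-up.** Exactly one item per domain, selected greedily: at each of
  the m warm-up steps the D-criterion best item of every still-uncovered
  domain is evaluated against the running information matrix and the
  globally best one administered. This guarantees the m-item floor and
  direct measurement of every domain at every occasion.
- **Selection.** After warm-up, the next item is
  argmaxⱼ det(A + Iⱼ(θ̂)) over unadministered items. A includes the prior
  precision (Bayesian D-optimality) so determinants are nonsingular from
  the first item; the rank-1 identity
  det(A + g aaᵀ) = det(A)(1 + g aᵀA⁻¹a) reduces each candidate to one
  quadratic form, vectorized over the pool. Ties break lexicographically by
  item id (a deterministic, platform-independent rule). The stopping
  determinant, by contrast, uses item information only; both choices are
  configuration switches (`selection_includes_prior`,
  `stopping_includes_prior`).
- **Re-scoring.** The state is re-estimated after every response (also
  during warm-up), warm-started at the previous estimate. Per-administration
  re-scoring is required by the CT-rule, which needs an estimate history.
- **Stopping.** Checked after every administration once n ≥ m, with
  precedence D > CT > MAX:
  - D-rule: det Σⱼ Iⱼ(θ̂) ≥ (v/c)², with
    v = 2π^{m/2}[χ²ₘ(1−α)]^{m/2}/(m Γ(m/2)) and c defaulting to the
    m-dimensional unit-ball volume. The threshold is the (v/c)² implied by
    the ellipsoid-volume derivation (the level-(1−α) ellipsoid has volume
    v/√det ≤ c); a (v·c)² variant is selectable via `threshold_form`
    because the inequality's printed rendering in the source literature is
    typographically ambiguous. At m = 14 and default c the threshold is far
    above what 50 polytomous items can reach, so real sessions end by CT
    or at the cap — consistent with the strongly bimodal survey-length
    distributions such protocols report.
  - CT-rule: max-over-domains |Δθ̂| < ε (default 0.01) for 2 consecutive
    administrations (the last three estimates). ε = 0 is permitted and
    simply disables the rule.
  - Maximum length 50 (must be ≥ m).
- **Carry-over.** Occasion 1 starts from a full-bank MAP fit to baseline
  responses; occasion t > 1 from the final estimates of the most recent
  completed occasion. By default carry-over sets the optimizer start and
  the provisional θ̂ used for the first selections, while the prior stays
  at the calibration N(0, R) — the measurement model is precalibrated and
  fixed, so the prior is not re-centered per occasion. Re-centering the
  prior instead is available as `carryover="prior_mean"` for sensitivity
  analyses. Missed occasions carry the last estimates forward.
- **Degenerate inputs.** A responder that raises or returns an out-of-range
  category aborts the session, which is returned flagged incomplete with
  its partial record. An exhausted pool before any rule fires raises.

## Item bank and joint prior

The synthetic bank generator reproduces the published bank shape: primary
item counts per risk domain (32, 30, 22, 13, 11, 14, 16, 14, 14, 7, 12, 4;
total 189) plus 9 passive- and 9 active-ideation items. Primary
discriminations are log-uniform on [0.8, 2.5]; cross-loadings occur with
probability 0.15 (uniform magnitude [0.3, 0.8], capped below the primary
loading); category boundaries are sorted normal draws (SD 0.7, minimum
spacing 0.15) around an item location uniform on [−1, 2], so the bank is
most informative from average to high severity — the operating range such
instruments are designed for.

The joint 14×14 prior correlation joins the two separately calibrated
blocks: the published 12×12 risk-domain correlations (including the 0.00
entry between psychological pain and negative urgency, kept as printed) and
the 2×2 ideation block with r = 0.92. The risk-by-ideation
cross-correlations were never reported because the blocks were calibrated
separately; they default to 0.3 (moderate, between the weakest and typical
within-block values) and are configurable. If assembly yields an indefinite
matrix, it is repaired by clipping eigenvalues at 1e-4 and rescaling to
unit diagonal — deterministic and order-independent — and the repair is
logged. Already-PD input passes through exactly.

Bank serialization uses a diffable CSV (one item per row:
`item_id, prompt, a_0..a_13, d_1..d_4, primary_domain`, with the prior in a
companion `<stem>.prior.csv` headed by `name:role` labels) and a
single-document JSON mirror; floats round-trip via `repr` at full
precision.

## Study simulator

The simulator generates what the engine needs to be tested end to end, not
a full model of EMA behavior.

- **Latent trajectories.** θ_it = b_i + e_it with person means
  b ~ MVN(0, diag(√ICC)·R·diag(√ICC)) and deviations following a
  stationary vector AR(1) (scalar φ, default 0.4) with stationary
  covariance diag(√(1−ICC))·R·diag(√(1−ICC)). Total stationary variance is
  1 per domain, preserving the calibration metric, and the between-person
  variance share equals the configured ICC. Default per-domain ICCs are the
  published domain values (0.39–0.63). The AR(1) form is a stand-in: no
  dynamic model is identified by ICCs and cross-sectional correlations
  alone, so passing tests certify ICC and correlation structure, not any
  claim about real temporal dynamics (heterogeneous person-specific
  dynamics, regime switching, and reactivity are all absent).
- **Prompt schedule.** Six prompts/day in 2-hour windows from 9 AM to 9 PM,
  uniform within window, day redrawn until adjacent gaps ≥ 15 minutes
  (per-window rejection probability ≈ 0.8%, so redraws are rare). 21 days
  gives the expected 126 prompts.
- **Compliance.** Completion ~ Bernoulli(logistic(0.45 − 0.10·week + b_i)),
  b_i ~ N(0, 1.9²). The defaults put mean completion near 0.56 and the
  latent-scale person ICC (σ²/(σ² + π²/3)) near 0.53, matching the reported
  anchors; those anchors come from 29 real participants, so they calibrate
  the generator and are not treated as reproduction targets.
- **Risk monitoring.** The three static items (intent 1–10, plan, attempt)
  are generated from true active-ideation severity through logistic links
  with high thresholds (alerts are rare events) and never enter the
  adaptive test. The alert rule is intent > 8, or any plan, or any attempt,
  and is monotone by construction.
- **Reproducibility.** One study seed drives everything through a
  `SeedSequence` spawn tree (trajectories, compliance, schedule, baseline
  responses, per-occasion response draws, risk items).

## Evaluation metrics

- Jaccard index and overlap coefficient on administered-item sets, averaged
  over all unordered pairs of a participant's sessions. Jaccard ≤ overlap
  coefficient always.
- One-way random-effects ICC(1) via ANOVA mean squares,
  (MSB − MSW)/(MSB + (k₀ − 1)·MSW) with the standard k₀ group-size
  adjustment for unbalanced data, clipped to [0, 1]. The
  method-of-moments estimator keeps the metrics layer free of model-fitting
  dependencies and agrees with mixed-model ICCs under balance.
- Recovery statistics (per-domain bias, RMSE, Pearson correlation);
  zero-variance input yields an undefined (NaN) correlation, never 0.
- Frequency-table descriptives expand counts to the raw score vector; SD
  uses n−1; median and quartiles use nearest-observation quantiles (no
  interpolation), which reproduces the integer medians/IQRs printed in
  published burden tables; comparisons to printed values round half-up to
  2 decimals.
- Compliance rate = completed / expected (126 by default).

## Evaluation conventions and problem sizes

The end-to-end recovery evaluation (tests and `scripts/acceptance.py`) uses
100 persons × 20 occasions with the default synthetic bank, default
stopping, and default compliance — large enough for stable correlations
(~1100 completed sessions) while keeping a full run in minutes on one CPU.
Two conventions:

- **Fixed-form benchmark.** The comparison form is a single random 14-item
  fixed survey administered at the same true latent states with fresh
  model-consistent response draws and scored by the same MAP pipeline
  (prior and carry-over starts included), so the only difference is item
  choice. Adaptive and fixed surveys necessarily administer different
  items, so "same responses" can only mean same respondents and truths.
- **ICC recovery.** Recovery of the configured 0.39–0.63 per-domain ICC
  grid is summarized by the mean absolute per-domain deviation, with the
  maximum also reported. At 100 persons the per-domain ANOVA ICC estimate
  carries a sampling SD near 0.04 (plus a small upward bias from the AR(1)
  within-person autocorrelation at 20 occasions per person), so the
  worst-of-14-domains deviation is dominated by Monte-Carlo noise; the mean
  absolute deviation is the stable summary of generator-estimator
  agreement at this size.

## Known limitations

- No exposure control or content balancing beyond the warm-up; heavily
  informative items repeat across occasions (the overlap metrics exist to
  quantify exactly this).
- The MGRM assumes fixed item parameters over time: no drift, reactivity,
  or measurement non-invariance across occasions or persons.
- The D-rule with default c is effectively unreachable at m = 14 with
  polytomous items; it matters for low-dimensional configurations and for
  the degenerate-configuration analyses.
- MAP point estimates are shrunken toward the prior mean; posterior SDs
  come from the expected-information approximation, not the exact
  posterior.
- The simulator's compliance is missing-completely-at-random given person
  and week; real missingness may correlate with momentary severity.
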