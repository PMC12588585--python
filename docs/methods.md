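# Methods

`dcepref` implements the analysis pipeline of a binary-attribute,
forced-choice discrete choice experiment (DCE): design construction,
respondent simulation, response quality control, logit estimation, and the
transformation of fitted coefficients into preference outputs. The default
configuration reproduces a five-attribute remote-care engagement survey
(communication, clinical care, education, ease of use, convenience), each
attribute binary with a positive (1) and a negative/neutral (0) level.

## Design

With `k` binary attributes there are `2^k` profiles. Every profile is
paired with its elementwise complement, giving `2^(k-1)` forced-choice
questions in which each attribute's positive level on one side faces its
negative level on the other, so every question forces a trade. For `k = 5`
this is 32 profiles in 16 questions.

**Side assignment.** Complement pairs always differ in their first
attribute, so "lexicographically smaller profile is option A" would put
the first attribute's negative level on side A in *every* question,
confounding side effects with that attribute (an all-B straightliner would
be indistinguishable from a first-attribute-dominant responder). The
canonical rule used instead: the pair representative (first attribute at
level 0) is option A when its level sum is even, otherwise its complement
is. For `k >= 3` this balances every attribute 8/8 across sides, makes
nontrading and positive dominance mutually exclusive, and keeps a
respondent-side bias orthogonal to every attribute contrast. Question
presentation order is a seeded permutation of the canonical pairing order.

**Sample size.** The conjoint rule of thumb `N > 500 c / (t a)` (levels per
attribute `c`, questions `t`, alternatives per question `a`) is implemented
with a strict inequality in exact integer arithmetic; `(c, t, a) =
(2, 16, 2)` gives 32 respondents.

## Estimation model

Each answered question is expanded into its two alternative rows; each row
is treated as a Bernoulli observation of being chosen, with

    logit P(chosen) = alpha + sum_i beta_i x_i  =  U(x),

the alternative's level vector `x` as regressors. This is a *binary* logit
on alternative rows, not a conditional (paired) logit — deliberately so:
only this parameterization yields the intercept-bearing utilities
`U = alpha + sum(beta x)` that the downstream uptake tables use. A paired
`ConditionalLogit` is provided as a labelled extension; on complementary
data its estimates equal exactly half the row-logit betas, because the
row-expanded likelihood is twice the paired likelihood at half scale.

Fitting is Newton–Raphson with step-halving (the log-likelihood never
decreases), convergence when the gradient max-norm < 1e-8 or the update
max-norm < 1e-10. Standard errors come from the inverse observed
information; 95% intervals use the Normal multiplier 1.96; the reported
goodness of fit is McFadden's pseudo R² = 1 − ll/ll₀. Separation raises an
error naming the diverging direction (a vanishing gradient with saturated
probabilities is not convergence); rank-deficient design matrices raise an
error listing the collinear columns.

### Structural consequences of the complementary row expansion

The expanded data are invariant under `(x, y) -> (1 - x, 1 - y)` (each
row's question partner). Two exact consequences, both verified by tests:

1. **The intercept is not free.** The likelihood satisfies
   `L(alpha, beta) = L(-alpha - sum(beta), beta)`, and since the binary
   logit likelihood is strictly concave, the MLE sits at the fixed point:
   `alpha_hat = -sum(beta_hat) / 2`, always.
2. **A respondent random intercept is unidentifiable.** At the (enforced)
   symmetric intercept, each question pair contributes
   `log sigmoid(eta + b) + log sigmoid(eta - b)` to a respondent's
   log-likelihood — an even, concave function of the intercept `b` —
   regardless of the observed choice. The per-respondent likelihood is
   therefore even in `b` and maximized at `b = 0`, so the marginal
   likelihood of the mixed model is maximized at `sigma_re = 0` on *any*
   complete complementary data set. The row-expanded mixed logit can never
   detect heterogeneity.
3. **Information-based SEs are optimistic.** The two rows of a question
   are perfectly anticorrelated, so treating them as independent
   overstates the information (by about a factor of two). Measured
   coverage of nominal 95% Wald intervals with information-based SEs is
   roughly 72–90%. `cov_type="cluster"` provides the sandwich estimator
   (clusters = respondents), whose measured coverage is ≈ 95–98%; it is
   used wherever calibrated intervals matter. The default remains the
   information-based SE, the conventional logit output.

### Mixed logit

`MixedLogit` adds `b_r ~ Normal(0, sigma_re^2)` per respondent and
maximizes the marginal likelihood via Gauss–Hermite quadrature (default 31
nodes; node contributions accumulated with log-sum-exp so nothing
underflows; 31 vs 61 nodes agree to < 1e-6 at moderate `sigma`). With
`sigma` fixed at 0 the marginal log-likelihood equals the plain logit's
exactly. Because of consequence (2) above, the default row-mode fit always
returns `sigma_re_ = 0`; `collapse_pairs=True` instead fits one Bernoulli
per question (did the respondent choose side A, with side A's levels as
regressors). Under the simulator's generative rule that collapsed model is
correctly specified and the variance component is recovered (±0.25 at
n = 1000 in tests). Standard errors come from a central-difference
numerical Hessian at the optimum; the `sigma` SE is reported as NaN at the
zero boundary.

## Simulator

The generator is the study-conditions oracle for every downstream test.
A rational respondent `r` chooses option A of question `q` with

    P(choose A) = sigmoid(alpha + b_r + beta . x_A(q)).

This is exactly the row-level model the analysis fits, so the generator's
`(alpha, beta)` coincide with the binary-logit estimand — the property
parameter-recovery experiments need. When `alpha = -sum(beta)/2` (which
the published weights satisfy exactly: −3.357 = −6.714/2, an instance of
structural consequence (1)), the rule is equivalent to a logistic
random-utility comparison of the two alternatives at half scale, i.e. a
standard Gumbel-noise choice rule. A random-utility rule with a respondent
intercept shared by both alternatives was rejected because the intercept
cancels from every forced-pair choice probability, leaving both `alpha`
and `sigma_re` without any observable meaning.

`b_r` is respondent-level baseline propensity toward side A — the only
intercept-type heterogeneity a forced pair can express. Defaults:
`sigma_re = 0` (the published analysis reports no heterogeneity magnitude;
nonzero values are a simulation knob for the mixed-logit tests, not an
estimate).

Contaminating behaviors, assigned per respondent from a `BehaviorMix`:

- **nontraders** answer every question on one fixed side (side drawn
  fairly), emulating straightlining;
- **dominant** responders always pick the alternative with a given
  attribute positive — in a complementary design this determines all 16
  choices exactly;
- **dropouts** answer a Uniform{1..15} prefix of the presented questions
  and leave the rest missing (the survey reported a 57% completion rate
  but no dropout curve, so a uniform stop point is assumed).

What the simulator does *not* emulate: question-order fatigue or learning,
attribute non-attendance, demographic covariates (none were collected),
and real respondents' deviations from the logit rule. Passing recovery
tests therefore show the pipeline is correct under its own model, not that
the model describes any particular cohort.

## Quality control

Screening order: (1) drop respondents with any missing answer;
(2) drop nontraders (all-A or all-B — the strict "all responses" rule, no
partial threshold); (3) flag positive attribute dominance per attribute
(and negative dominance, reported separately) but retain those respondents
— dominance is informative lexicographic preference, not noise; an
`exclude_dominant` switch supports sensitivity analyses. On simulated
cohorts the screens recover injected behavior labels exactly, because the
behaviors are deterministic; a rational respondent can in principle
straightline by chance, but at the default effect sizes the probability is
negligible at test sample sizes.

## Preference outputs

From a coefficient set (fitted or supplied): utility
`U = alpha + sum(beta x)` per combination, odds `exp(U)`, percentage
uptake `100 sigmoid(U)` (overflow-safe), tabulated for all `2^k`
combinations sorted by descending utility. Marginal probability between
two combinations is their uptake difference in percentage points; the mean
marginal probability of an attribute averages the gain from adding it over
all `2^(k-1)` combinations lacking it.

**Rounding.** Presentation rounding is decimal half-up (away from zero),
applied once at the edge; internal values stay at full float precision.
The published worked examples difference uptake values already rounded to
2 dp, while the published 1-dp per-attribute means match full-precision
arithmetic; both paths are exposed (`rounding_path="table" | "full"`,
table-path default) and each is tested against brute-force enumeration
over the table.

**Known reproduction limits.** Recomputing the published 32-row table from
the published 2-dp coefficients reproduces every row within ±0.01
(utility, odds) and ±0.05 points (uptake) and the exact ordering, but a
few cells differ in the last digit because the original analysis used
unrounded fitted coefficients: the communication-only row computes to
8.97% against a printed 8.98%, which propagates to one worked marginal
(+5.60 vs printed +5.61) and the communication table-path mean (18.03 vs
printed 18.04). These differences are inherent to the printed precision of
the inputs, not numerical error.

## Problem sizes and determinism

Every stochastic routine takes an explicit integer seed
(`numpy.random.default_rng`); identical configurations produce
byte-identical artifacts. Test and acceptance experiments use cohorts of
200–1000 respondents and a 50-replicate recovery study at n = 500, sizes
at which Monte-Carlo error is well below the asserted tolerances while the
full suite stays fast. A 50-replicate coverage band of 90–99% is tight
relative to binomial noise: even an exactly calibrated 95% interval falls
outside 45–49 covered replicates with probability ≈ 0.1 per coefficient,
which should be kept in mind when reading that check.

## Limitations

- The estimators implement the row-expansion analysis faithfully,
  including its quirks (enforced intercept, optimistic default SEs,
  vacuous row-mode random intercept); users wanting a textbook choice
  model should use `ConditionalLogit` or the collapsed mixed mode.
- No willingness-to-pay transform (the survey had no cost attribute), no
  random slopes or latent classes, no fractional-factorial or D-efficient
  design construction, no opt-out alternatives.
- The pseudo R² and coefficient values of the original survey depend on
  its raw responses, which are not machine-readable here; they are not
  reproduction targets of this package.
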