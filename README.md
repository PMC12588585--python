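# dcepref

Design, simulation and analysis of **binary-attribute forced-choice
discrete choice experiments** (DCEs), built around the preference study
design used to elicit what heart-failure patients value in remote-care
technology: five binary attributes (communication, clinical care,
education, ease of use, convenience), a full-factorial design of 32
profiles paired into 16 complementary forced-choice questions, and a
binary-logit random-utility analysis.

The package is aimed at health-preference researchers and methodologists
who want a tested, reproducible implementation of this pipeline end to
end: questionnaire construction, synthetic respondents with known ground
truth, response quality control (incomplete attempts, nontraders,
attribute-dominant responders), maximum-likelihood estimation, and the
translation of coefficients into engagement predictions.

## The model

Each alternative is a profile `x ∈ {0,1}^k` of attribute levels. The
analysis treats each alternative of each answered question as a Bernoulli
observation of being chosen, with

```
logit P(chosen) = α + Σᵢ βᵢ xᵢ = U(x)
```

fit by Newton–Raphson ML (`BinaryLogit`, a scikit-learn-style estimator;
`MixedLogit` adds a Normal respondent-level random intercept integrated by
Gauss–Hermite quadrature). The utility `U` of a combination then gives its
odds `exp(U)` and percentage **uptake probability** `100·exp(U)/(1+exp(U))`
— the modelled probability that a technology with those attributes is
chosen over its complement. Differences of uptake values between
combinations are **marginal probabilities** (percentage points of
engagement gained by adding attributes), and averaging the gain from one
attribute over all combinations lacking it gives its **mean marginal
probability**.

The complementary design has some sharp structural consequences for this
model (an enforced intercept `α = −Σβ/2`, optimistic information-based
SEs, and an unidentifiable row-mode random intercept); they are derived
and handled in [docs/methods.md](docs/methods.md).

## Worked example

Feed the published preference weights (α = −3.357; clinical care 2.022;
education 1.252; convenience 1.245; ease of use 1.155; communication
1.040) through the preference analysis:

```python
from dcepref import (REMOTE_CARE_SCHEME, REMOTE_CARE_WEIGHTS, CoefficientSet,
                     build_utility_table, mean_marginal_probability,
                     rank_attributes, minimum_sample_size)

coeffs = CoefficientSet(REMOTE_CARE_SCHEME, REMOTE_CARE_WEIGHTS.alpha,
                        dict(REMOTE_CARE_WEIGHTS.betas))
print(build_utility_table(coeffs).rounded().head(3).to_string(index=False))
print("ranking:", rank_attributes(coeffs))
for a in REMOTE_CARE_SCHEME.attributes:
    print(f"mean marginal {a}: {mean_marginal_probability(coeffs, a, 'full'):.1f} points")
print("minimum sample size:", minimum_sample_size(2, 16, 2))
```

prints

```
 level_communication  level_clinical care  level_education  level_ease of use  level_convenience  utility  odds  uptake_pct
                   1                    1                1                  1                  1     3.36 28.70       96.63
                   0                    1                1                  1                  1     2.32 10.15       91.03
                   1                    1                1                  0                  1     2.20  9.04       90.04
ranking: ['clinical care', 'education', 'convenience', 'ease of use', 'communication']
mean marginal communication: 18.0 points
mean marginal clinical care: 37.6 points
mean marginal education: 21.9 points
mean marginal ease of use: 20.1 points
mean marginal convenience: 21.8 points
minimum sample size: 32
```

A technology with every attribute positive has utility 3.36, odds 28.70
and a 96.63% uptake probability; one with none has 3.37%. Clinical care
is by far the most valued attribute: adding it to a technology that lacks
it raises predicted uptake by 37.6 percentage points on average — roughly
the value of any two other attributes combined — while communication adds
the least (18.0 points). The sample-size rule `N > 500·c/(t·a)` gives a
minimum of 32 respondents for this 16-question, two-alternative survey.

The same analysis runs from the shell:

```
dcepref design --seed 0 --out design.csv
dcepref analyze --coefficients coeffs.json --out results/
dcepref run --config pipeline.yaml     # simulate → QC → fit → analyze
```

## Simulation and recovery

`simulate_cohort` draws seeded synthetic cohorts choosing by the logistic
random-utility rule at specified coefficients, optionally contaminated
with nontraders (straightliners), attribute-dominant responders and
mid-survey dropouts. The QC stage recovers injected behaviors exactly, and
the estimation stage recovers the generating coefficients (cross-checked
against statsmodels to 1e-6, with calibrated cluster-robust intervals);
these recovery experiments are the package's substitute for the original
survey's raw responses, which are not machine-readable here.

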