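"""Synthetic survey respondents for the forced-choice DCE.

The generator draws cohorts with the statistical structure the downstream
analysis assumes, so that quality control and estimation can be validated
against known ground truth.  A *rational* respondent ``r`` carries a Normal
random intercept ``b_r ~ N(0, sigma_re^2)`` and, at each question, chooses
option A with probability

    P(choose A) = logistic(alpha + b_r + sum_i beta_i * x_Ai)

where ``x_A`` is option A's level vector.  This is exactly the row-level
binary logit the analysis fits, so the generator's ``alpha``/``betas`` are
the estimand of :func:`dcepref.estimation.fit_binary_logit`.  Because the
design pairs complements, ``alpha = -sum(betas)/2`` makes the rule coincide
with a logistic random-utility comparison of the two alternatives'
utilities (at half scale); see docs/methods.md.

Contaminating behaviors emulate the patterns the survey analysis screens
for: *nontraders* answer every question on one fixed side, *dominant*
responders always pick the alternative with a given attribute positive,
and *dropouts* stop answering partway through.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.special import expit

from .design import DCEDesign

__all__ = [
    "PreferenceModel",
    "BehaviorMix",
    "SimulatedResponseSet",
    "simulate_cohort",
    "REMOTE_CARE_WEIGHTS",
]

RATIONAL = "rational"
NONTRADER_A = "nontrader_A"
NONTRADER_B = "nontrader_B"
DROPOUT = "dropout"


class ConfigurationError(ValueError):
    """Invalid simulation configuration (rates, sizes, coefficients)."""


@dataclass(frozen=True)
class PreferenceModel:
    """Ground-truth utility parameters, in utility (log-odds) units.

    ``alpha`` is the intercept of the row-level logit, ``betas`` the
    per-attribute preference weights (keyed by attribute name), and
    ``sigma_re`` the standard deviation of the respondent-level random
    intercept.
    """

    alpha: float
    betas: Mapping[str, float]
    sigma_re: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_re < 0:
            raise ConfigurationError("sigma_re must be >= 0")

    def beta_vector(self, attributes: tuple[str, ...]) -> np.ndarray:
        missing = [a for a in attributes if a not in self.betas]
        if missing:
            raise ConfigurationError(f"missing betas for attributes: {missing}")
        return np.array([self.betas[a] for a in attributes], dtype=float)


#: Published preference weights for the five remote-care attributes —
#: the default ground truth for recovery experiments.
REMOTE_CARE_WEIGHTS = PreferenceModel(
    alpha=-3.357,
    betas={
        "communication": 1.040,
        "clinical care": 2.022,
        "education": 1.252,
        "ease of use": 1.155,
        "convenience": 1.245,
    },
)


@dataclass(frozen=True)
class BehaviorMix:
    """Rates of contaminating response behaviors.

    ``dominant_rates`` maps attribute name -> probability of a responder
    who always picks the alternative with that attribute positive.  The
    remaining mass is rational responders.
    """

    nontrader_rate: float = 0.0
    dominant_rates: Mapping[str, float] = field(default_factory=dict)
    dropout_rate: float = 0.0

    def __post_init__(self) -> None:
        rates = [self.nontrader_rate, self.dropout_rate, *self.dominant_rates.values()]
        if any(r < 0 or r > 1 for r in rates):
            raise ConfigurationError("behavior rates must lie in [0, 1]")
        if sum(rates) > 1 + 1e-12:
            raise ConfigurationError(
                "nontrader + dominant + dropout rates must sum to <= 1"
            )


@dataclass
class SimulatedResponseSet:
    """Simulated choices plus the ground truth that generated them.

    ``choices`` is an (n_respondents, n_questions) object array holding
    'A', 'B' or None (missing after a dropout's stop point).  ``behaviors``
    labels every respondent ('rational', 'nontrader_A', 'nontrader_B',
    'dropout', or 'dominant:<attribute>').
    """

    design: DCEDesign
    respondent_ids: list[str]
    choices: np.ndarray
    behaviors: list[str]
    model: PreferenceModel
    mix: BehaviorMix
    seed: int
    random_intercepts: np.ndarray

    def to_csv(self, path: str | Path) -> None:
        """Long response CSV: respondent_id, question_index, choice."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["respondent_id", "question_index", "choice"])
            for i, rid in enumerate(self.respondent_ids):
                for q in range(self.design.n_questions):
                    c = self.choices[i, q]
                    w.writerow([rid, q, c if c is not None else ""])

    def truth_to_json(self, path: str | Path) -> None:
        """Sidecar ground-truth labels for test harnesses."""
        data = {
            "seed": self.seed,
            "model": {
                "alpha": self.model.alpha,
                "betas": dict(self.model.betas),
                "sigma_re": self.model.sigma_re,
            },
            "behaviors": dict(zip(self.respondent_ids, self.behaviors)),
        }
        Path(path).write_text(json.dumps(data, indent=2))

    def records(self) -> dict[str, list[str | None]]:
        return {
            rid: list(self.choices[i])
            for i, rid in enumerate(self.respondent_ids)
        }


def _dominant_pattern(design: DCEDesign, attribute: str) -> list[str]:
    """The fully determined 16-choice pattern of an attribute-dominant
    responder: at every question, pick the side whose level for the
    attribute is 1 (well defined since the sides are complements)."""
    j = design.scheme.attributes.index(attribute)
    return ["A" if q.option_a[j] == 1 else "B" for q in design.questions]


def simulate_cohort(
    design: DCEDesign,
    model: PreferenceModel,
    mix: BehaviorMix,
    n_respondents: int,
    seed: int,
) -> SimulatedResponseSet:
    """Draw a fully seeded synthetic cohort.

    Behaviors are assigned per respondent from ``mix``; rational (and
    dropout) respondents choose by the logistic rule in the module
    docstring; dominant and nontrading respondents follow their
    deterministic patterns; dropouts answer a Uniform{1..n_questions-1}
    prefix of the presented questions and leave the rest missing.
    """
    if n_respondents < 1:
        raise ConfigurationError("n_respondents must be >= 1")
    rng = np.random.default_rng(seed)
    attrs = design.scheme.attributes
    beta = model.beta_vector(attrs)
    nq = design.n_questions

    dom_attrs = list(mix.dominant_rates)
    labels = [NONTRADER_A, NONTRADER_B, DROPOUT] + [f"dominant:{a}" for a in dom_attrs] + [RATIONAL]
    probs = np.array(
        [mix.nontrader_rate / 2, mix.nontrader_rate / 2, mix.dropout_rate]
        + [mix.dominant_rates[a] for a in dom_attrs]
        + [0.0]
    )
    probs[-1] = 1.0 - probs[:-1].sum()
    behavior = [labels[i] for i in rng.choice(len(labels), size=n_respondents, p=probs)]

    b_r = rng.normal(0.0, model.sigma_re, size=n_respondents) if model.sigma_re > 0 else np.zeros(n_respondents)

    xa = np.array([q.option_a for q in design.questions], dtype=float)
    eta_a = model.alpha + xa @ beta  # systematic part, option A side
    dom_patterns = {a: _dominant_pattern(design, a) for a in dom_attrs}

    choices = np.empty((n_respondents, nq), dtype=object)
    for i in range(n_respondents):
        lab = behavior[i]
        if lab == NONTRADER_A:
            row = ["A"] * nq
        elif lab == NONTRADER_B:
            row = ["B"] * nq
        elif lab.startswith("dominant:"):
            row = list(dom_patterns[lab.split(":", 1)[1]])
        else:  # rational or dropout: logistic choice rule
            p_a = expit(eta_a + b_r[i])
            row = ["A" if u < p else "B" for u, p in zip(rng.random(nq), p_a)]
            if lab == DROPOUT:
                stop = int(rng.integers(1, nq))  # answers questions [0, stop)
                row[stop:] = [None] * (nq - stop)
        choices[i] = row

    ids = [f"r{i:04d}" for i in range(n_respondents)]
    return SimulatedResponseSet(
        design=design,
        respondent_ids=ids,
        choices=choices,
        behaviors=behavior,
        model=model,
        mix=mix,
        seed=seed,
        random_intercepts=b_r,
    )


def choice_probabilities(design: DCEDesign, model: PreferenceModel) -> np.ndarray:
    """Exact P(choose option A) per question for a rational respondent
    with random intercept 0 — the oracle for simulation share checks."""
    beta = model.beta_vector(design.scheme.attributes)
    xa = np.array([q.option_a for q in design.questions], dtype=float)
    return expit(model.alpha + xa @ beta)
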