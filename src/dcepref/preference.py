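"""Preference outputs: utilities, odds, uptake probabilities, marginals.

Given fitted coefficients, every attribute-level combination has a latent
utility ``U = alpha + sum_i beta_i x_i``, odds ``exp(U)`` and a percentage
uptake probability ``100 * odds / (1 + odds)`` — the modelled probability
that a remote-care technology with those attributes would be chosen over
its complement.  The 2**k-row table of all combinations, sorted by
descending utility, is the headline output.

Two derived comparison measures:

* *marginal probability* — the percentage-point uptake difference between
  two named combinations;
* *mean marginal probability* — for one attribute, the marginal
  probability of adding it, averaged over every combination lacking it.

Published worked examples difference the 2-dp table percentages, while the
published 1-dp per-attribute means match full-precision arithmetic; both
paths are implemented (``rounding_path="table" | "full"``) and labelled.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from ._rounding import round_half_up
from .design import AttributeScheme, DesignError, Profile
from .estimation import LogitFit

__all__ = [
    "CoefficientSet",
    "UtilityTable",
    "utility_of",
    "uptake_probability",
    "build_utility_table",
    "marginal_probability",
    "mean_marginal_probability",
    "rank_attributes",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoefficientSet:
    """Intercept and per-attribute coefficients against a scheme."""

    scheme: AttributeScheme
    alpha: float
    betas: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = [a for a in self.scheme.attributes if a not in self.betas]
        extra = [a for a in self.betas if a not in self.scheme.attributes]
        if missing or extra:
            raise DesignError(
                f"betas must match scheme attributes; missing={missing}, extra={extra}"
            )

    @property
    def beta_vector(self) -> np.ndarray:
        return np.array([self.betas[a] for a in self.scheme.attributes], dtype=float)

    @classmethod
    def from_fit(cls, scheme: AttributeScheme, fit: LogitFit) -> "CoefficientSet":
        return cls(scheme=scheme, alpha=fit.alpha, betas=dict(fit.betas))

    @classmethod
    def from_json(cls, path: str | Path, scheme: AttributeScheme) -> "CoefficientSet":
        data = json.loads(Path(path).read_text())
        return cls(scheme=scheme, alpha=float(data["alpha"]),
                   betas={k: float(v) for k, v in data["betas"].items()})


def utility_of(coeffs: CoefficientSet, combo: Sequence[int]) -> float:
    """Latent utility ``alpha + sum(beta * level)``, full precision."""
    combo = coeffs.scheme.validate_profile(combo)
    return float(coeffs.alpha + np.dot(coeffs.beta_vector, combo))


def uptake_probability(utility: float) -> float:
    """Percentage uptake ``100 * exp(U) / (1 + exp(U))``, overflow-safe."""
    return float(100.0 * expit(utility))


@dataclass
class UtilityTable:
    """All combinations with utility, odds and uptake, utility-descending.

    ``frame`` holds full-precision values; :meth:`rounded` applies the
    2-dp half-up presentation rounding the published table uses.
    """

    scheme: AttributeScheme
    frame: pd.DataFrame

    @property
    def level_columns(self) -> list[str]:
        return [f"level_{a}" for a in self.scheme.attributes]

    def rounded(self) -> pd.DataFrame:
        out = self.frame.copy()
        for col in ("utility", "odds", "uptake_pct"):
            out[col] = out[col].map(lambda v: round_half_up(v, 2))
        return out

    def row_for(self, combo: Sequence[int]) -> pd.Series:
        combo = self.scheme.validate_profile(combo)
        mask = (self.frame[self.level_columns] == list(combo)).all(axis=1)
        return self.frame[mask].iloc[0]

    def to_csv(self, path: str | Path, rounded: bool = True) -> None:
        (self.rounded() if rounded else self.frame).to_csv(path, index=False)


def build_utility_table(coeffs: CoefficientSet) -> UtilityTable:
    """One row per attribute-level combination, sorted by utility desc.

    Ties in utility (possible with degenerate coefficients) are broken by
    the combination's binary-counting order, descending, so the sort is
    deterministic.
    """
    k = coeffs.scheme.k
    combos = list(itertools.product((0, 1), repeat=k))
    beta = coeffs.beta_vector
    records = []
    for combo in combos:
        u = coeffs.alpha + float(np.dot(beta, combo))
        records.append((*combo, u, float(np.exp(u)), uptake_probability(u)))
    frame = pd.DataFrame(
        records,
        columns=[f"level_{a}" for a in coeffs.scheme.attributes]
        + ["utility", "odds", "uptake_pct"],
    )
    order = sorted(
        range(len(combos)),
        key=lambda i: (-frame["utility"].iloc[i], -i),
    )
    frame = frame.iloc[order].reset_index(drop=True)
    return UtilityTable(scheme=coeffs.scheme, frame=frame)


def marginal_probability(
    coeffs: CoefficientSet,
    from_combo: Sequence[int],
    to_combo: Sequence[int],
    rounding_path: str = "table",
) -> float:
    """Uptake difference (percentage points) between two combinations.

    ``rounding_path="table"`` differences the 2-dp table percentages,
    mirroring the published worked arithmetic; ``"full"`` keeps full
    precision.
    """
    u_from = uptake_probability(utility_of(coeffs, from_combo))
    u_to = uptake_probability(utility_of(coeffs, to_combo))
    if rounding_path == "table":
        return round_half_up(u_to, 2) - round_half_up(u_from, 2)
    if rounding_path == "full":
        return u_to - u_from
    raise ValueError(f"rounding_path must be 'table' or 'full', got {rounding_path!r}")


def mean_marginal_probability(
    coeffs: CoefficientSet,
    attribute: str,
    rounding_path: str = "table",
) -> float:
    """Mean uptake gain from adding one attribute, over all bases lacking it.

    Averages ``uptake(base with attribute) - uptake(base)`` across the
    ``2**(k-1)`` combinations with the attribute at level 0.
    """
    if attribute not in coeffs.scheme.attributes:
        raise DesignError(f"unknown attribute {attribute!r}")
    j = coeffs.scheme.attributes.index(attribute)
    k = coeffs.scheme.k
    diffs = []
    for combo in itertools.product((0, 1), repeat=k):
        if combo[j] == 1:
            continue
        augmented = list(combo)
        augmented[j] = 1
        diffs.append(marginal_probability(coeffs, combo, augmented, rounding_path))
    return float(np.mean(diffs))


def marginal_report(
    coeffs: CoefficientSet,
    pair: tuple[Sequence[int], Sequence[int]] | None = None,
) -> dict:
    """Per-attribute mean marginals (both rounding paths) as a JSON-able dict."""
    report = {
        "mean_marginal_pct_points": {
            a: {
                "table_path_2dp": round_half_up(
                    mean_marginal_probability(coeffs, a, "table"), 2
                ),
                "full_precision_1dp": round_half_up(
                    mean_marginal_probability(coeffs, a, "full"), 1
                ),
            }
            for a in coeffs.scheme.attributes
        },
        "attribute_ranking": rank_attributes(coeffs),
    }
    if pair is not None:
        frm, to = pair
        report["pairwise_marginal_pct_points"] = {
            "from": list(frm),
            "to": list(to),
            "table_path": marginal_probability(coeffs, frm, to, "table"),
            "full_precision": marginal_probability(coeffs, frm, to, "full"),
        }
    return report


def rank_attributes(coeffs: CoefficientSet) -> list[str]:
    """Attributes by descending preference weight; ties alphabetical."""
    betas = coeffs.betas
    ranked = sorted(coeffs.scheme.attributes, key=lambda a: (-betas[a], a))
    values = [betas[a] for a in ranked]
    if len(set(values)) != len(values):
        logger.warning("tied preference weights; ties broken alphabetically")
    return ranked
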