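"""Full-factorial forced-choice questionnaire design.

A discrete choice experiment (DCE) over ``k`` binary attributes has
``2**k`` possible alternative profiles.  Pairing every profile with its
elementwise complement yields ``2**(k-1)`` forced-choice questions in which
a positive level of an attribute on one side always faces the negative
level on the other, so respondents must trade attributes on every question.
For the five-attribute remote-care survey this gives 32 profiles in 16
questions.

The module also implements the Johnson/Orme rule of thumb for the minimum
number of respondents of a conjoint survey, ``N > 500 * c / (t * a)``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "AttributeScheme",
    "Profile",
    "ChoiceQuestion",
    "DCEDesign",
    "DesignError",
    "enumerate_full_factorial",
    "pair_into_questions",
    "minimum_sample_size",
    "build_design",
    "REMOTE_CARE_SCHEME",
]

Profile = tuple[int, ...]


class DesignError(ValueError):
    """Invalid attribute scheme or profile set."""


@dataclass(frozen=True)
class AttributeScheme:
    """Named binary attributes of the choice alternatives.

    ``attributes`` fixes the computational order (the order level vectors
    are indexed in); ``level_labels`` maps each attribute to the text shown
    for level 0 (negative/neutral) and level 1 (positive).  Presentation to
    respondents lists attributes alphabetically, which is metadata only —
    ``display_order`` — and never affects computation.
    """

    attributes: tuple[str, ...]
    level_labels: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.attributes) == 0:
            raise DesignError("scheme must have at least one attribute")
        if len(set(self.attributes)) != len(self.attributes):
            raise DesignError("attribute names must be unique")
        for name, labels in self.level_labels.items():
            if name not in self.attributes:
                raise DesignError(f"level label for unknown attribute {name!r}")
            if len(labels) != 2:
                raise DesignError(f"attribute {name!r} must have exactly two levels")

    @property
    def k(self) -> int:
        return len(self.attributes)

    @property
    def display_order(self) -> tuple[str, ...]:
        return tuple(sorted(self.attributes))

    def validate_profile(self, profile: Sequence[int]) -> Profile:
        if len(profile) != self.k:
            raise DesignError(
                f"profile length {len(profile)} != {self.k} attributes"
            )
        if any(v not in (0, 1) for v in profile):
            raise DesignError("profile levels must be 0 or 1")
        return tuple(int(v) for v in profile)

    @classmethod
    def from_config(cls, path: str | Path) -> "AttributeScheme":
        """Load a scheme from a JSON or YAML config file.

        Expected shape::

            attributes:
              - name: communication
                level0: "..."
                level1: "..."
        """
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        entries = data["attributes"]
        names = tuple(e["name"] for e in entries)
        labels = {
            e["name"]: (e.get("level0", ""), e.get("level1", ""))
            for e in entries
        }
        return cls(names, labels)

    def to_config(self, path: str | Path) -> None:
        data = {
            "attributes": [
                {
                    "name": a,
                    "level0": self.level_labels.get(a, ("", ""))[0],
                    "level1": self.level_labels.get(a, ("", ""))[1],
                }
                for a in self.attributes
            ]
        }
        p = Path(path)
        if p.suffix in (".yml", ".yaml"):
            p.write_text(yaml.safe_dump(data, sort_keys=False))
        else:
            p.write_text(json.dumps(data, indent=2))


#: The five remote-care engagement attributes, in the order the published
#: tables index their level vectors.
REMOTE_CARE_SCHEME = AttributeScheme(
    attributes=(
        "communication",
        "clinical care",
        "education",
        "ease of use",
        "convenience",
    ),
    level_labels={
        "communication": (
            "Reduces or does not improve opportunities for contact",
            "Increases opportunities for contact and communication",
        ),
        "clinical care": (
            "No impact on current clinical care",
            "Improves clinical care from current practice",
        ),
        "education": (
            "No improvement in knowledge or ability to self-care",
            "Provides useful information aiding self-care",
        ),
        "ease of use": (
            "Overly complex or difficult to access",
            "Easy and intuitive to use",
        ),
        "convenience": (
            "No time saved, or creates extra work or worry",
            "Saves time and effort, fits the patient's lifestyle",
        ),
    },
)


@dataclass(frozen=True)
class ChoiceQuestion:
    """One forced-choice question: two complementary profiles."""

    index: int
    option_a: Profile
    option_b: Profile

    def __post_init__(self) -> None:
        if len(self.option_a) != len(self.option_b):
            raise DesignError("options must have equal length")
        if any(a + b != 1 for a, b in zip(self.option_a, self.option_b)):
            raise DesignError("option_b must be the elementwise complement of option_a")

    def option(self, side: str) -> Profile:
        if side == "A":
            return self.option_a
        if side == "B":
            return self.option_b
        raise ValueError(f"side must be 'A' or 'B', got {side!r}")


@dataclass(frozen=True)
class DCEDesign:
    """The full questionnaire: scheme, questions, and the order seed used."""

    scheme: AttributeScheme
    questions: tuple[ChoiceQuestion, ...]
    order_seed: int

    @property
    def n_questions(self) -> int:
        return len(self.questions)

    def profiles(self) -> list[Profile]:
        out: list[Profile] = []
        for q in self.questions:
            out.append(q.option_a)
            out.append(q.option_b)
        return out

    def to_csv(self, path: str | Path) -> None:
        cols = ["question_index", "alternative"] + [
            f"level_{a}" for a in self.scheme.attributes
        ]
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(cols)
            for q in self.questions:
                w.writerow([q.index, "A", *q.option_a])
                w.writerow([q.index, "B", *q.option_b])


def complement(profile: Profile) -> Profile:
    return tuple(1 - v for v in profile)


def enumerate_full_factorial(scheme: AttributeScheme) -> list[Profile]:
    """All ``2**k`` binary profiles, in binary counting order.

    Attribute 1 is the most significant bit, so enumeration runs
    ``(0,...,0), (0,...,1), ..., (1,...,1)``.
    """
    k = scheme.k
    return [
        tuple((i >> (k - 1 - j)) & 1 for j in range(k)) for i in range(2**k)
    ]


def _canonical_pairs(profiles: Iterable[Profile], k: int) -> list[tuple[Profile, Profile]]:
    """Pair each profile with its complement, assigning A/B sides.

    The representative of each pair is the profile with attribute 1 at
    level 0 (the lexicographically smaller of the two, since complements
    always differ in their first entry).  To keep the two sides balanced —
    each attribute positive on side A in exactly half the questions — the
    representative becomes option A when its level sum is even, and its
    complement becomes option A otherwise.
    """
    pset = set(profiles)
    if len(pset) != 2**k or any(len(p) != k for p in pset):
        raise DesignError(
            "profiles must form a complete full factorial without duplicates"
        )
    pairs = []
    for rep in sorted(p for p in pset if p[0] == 0):
        comp = complement(rep)
        if sum(rep) % 2 == 0:
            pairs.append((rep, comp))
        else:
            pairs.append((comp, rep))
    return pairs


def pair_into_questions(
    profiles: Sequence[Profile],
    order_seed: int,
    scheme: AttributeScheme | None = None,
) -> DCEDesign:
    """Split a full factorial into complementary forced-choice questions.

    Every profile appears in exactly one question, paired with its
    elementwise complement.  Question presentation order is a seeded
    permutation of the canonical pairing order (representatives in binary
    counting order), emulating randomized question order.
    """
    k = len(profiles[0]) if profiles else 0
    if scheme is None:
        scheme = AttributeScheme(tuple(f"attr{i+1}" for i in range(k)))
    if scheme.k != k:
        raise DesignError("scheme size does not match profile length")
    pairs = _canonical_pairs(profiles, k)
    rng = np.random.default_rng(order_seed)
    order = rng.permutation(len(pairs))
    questions = tuple(
        ChoiceQuestion(index=i, option_a=pairs[j][0], option_b=pairs[j][1])
        for i, j in enumerate(order)
    )
    return DCEDesign(scheme=scheme, questions=questions, order_seed=order_seed)


def build_design(scheme: AttributeScheme, order_seed: int = 0) -> DCEDesign:
    """Convenience: full factorial + complementary pairing in one call."""
    return pair_into_questions(enumerate_full_factorial(scheme), order_seed, scheme)


def minimum_sample_size(c: int, t: int, a: int) -> int:
    """Smallest integer N strictly greater than ``500 * c / (t * a)``.

    ``c`` levels per attribute, ``t`` questions, ``a`` alternatives per
    question.  For the 2-level, 16-question, 2-alternative survey this
    gives 32 respondents.
    """
    if c < 2 or t < 1 or a < 2:
        raise ValueError("require c >= 2, t >= 1, a >= 2")
    # exact integer arithmetic: floor(500c/(ta)) + 1 is the smallest integer
    # strictly above the bound whether or not it divides evenly
    return (500 * c) // (t * a) + 1
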