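"""Response quality control for forced-choice DCE data.

Three screening rules, applied in order:

1. *Completeness* — respondents missing any answer are excluded.
2. *Nontrading* — respondents whose answers are all A or all B carry no
   trade-off information and are excluded.
3. *Attribute dominance* — respondents who always chose the alternative
   with a given attribute positive (lexicographic preference) are flagged
   and reported per attribute, but retained by default; negative dominance
   (always choosing the level-0 side of an attribute) is detected and
   reported separately.

In a complementary design each side carries each attribute's positive
level in half the questions, so nontrading and positive dominance are
mutually exclusive, and a trading respondent can be positively dominant
for at most one attribute.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

from .design import DCEDesign

__all__ = [
    "RawResponseSet",
    "QCReport",
    "filter_incomplete",
    "detect_nontrading",
    "detect_dominance",
    "run_qc",
]

Choice = str | None


@dataclass
class RawResponseSet:
    """Raw per-respondent choices against a design.

    ``records`` maps respondent_id to a list of 'A'/'B'/None with one entry
    per question, indexed in the design's presentation order.
    """

    design: DCEDesign
    records: dict[str, list[Choice]]

    def __post_init__(self) -> None:
        nq = self.design.n_questions
        for rid, row in self.records.items():
            if len(row) != nq:
                raise ValueError(
                    f"respondent {rid!r} has {len(row)} entries, expected {nq}"
                )
            bad = [c for c in row if c not in ("A", "B", None)]
            if bad:
                raise ValueError(f"respondent {rid!r} has invalid choices {bad}")

    @property
    def n_respondents(self) -> int:
        return len(self.records)

    @classmethod
    def from_csv(cls, path: str | Path, design: DCEDesign) -> "RawResponseSet":
        """Read the long response CSV (respondent_id, question_index, choice)."""
        nq = design.n_questions
        records: dict[str, list[Choice]] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                rid = row["respondent_id"]
                q = int(row["question_index"])
                if not 0 <= q < nq:
                    raise ValueError(f"question index {q} outside design range")
                c = row["choice"].strip() or None
                records.setdefault(rid, [None] * nq)[q] = c
        return cls(design=design, records=records)

    def subset(self, ids: list[str]) -> "RawResponseSet":
        return RawResponseSet(self.design, {r: self.records[r] for r in ids})


@dataclass
class QCReport:
    """Counts and identifier lists from the screening rules."""

    n_initiated: int
    n_complete: int
    n_nontraders_excluded: int
    n_valid: int
    dominance_counts: dict[str, int]
    negative_dominance_counts: dict[str, int]
    excluded_ids: list[str]
    flagged_ids: list[str]

    def __post_init__(self) -> None:
        assert self.n_valid == self.n_complete - self.n_nontraders_excluded

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))

    def log_lines(self) -> list[str]:
        lines = [
            f"responses initiated: {self.n_initiated}",
            f"complete responses: {self.n_complete}",
            f"excluded as nontraders: {self.n_nontraders_excluded}",
            f"valid responses: {self.n_valid}",
        ]
        for a, n in self.dominance_counts.items():
            if n:
                lines.append(f"positive dominance for {a}: {n}")
        neg = sum(self.negative_dominance_counts.values())
        lines.append(
            "no cases of negative attribute dominance"
            if neg == 0
            else f"negative dominance cases: {neg}"
        )
        return lines


def filter_incomplete(raw: RawResponseSet) -> RawResponseSet:
    """Keep only respondents with a choice recorded for every question."""
    complete = [rid for rid, row in raw.records.items() if all(c is not None for c in row)]
    return raw.subset(complete)


def detect_nontrading(raw: RawResponseSet) -> list[str]:
    """Respondents whose answers are all 'A' or all 'B'."""
    out = []
    for rid, row in raw.records.items():
        if all(c == "A" for c in row) or all(c == "B" for c in row):
            out.append(rid)
    return out


def detect_dominance(raw: RawResponseSet, negative: bool = False) -> dict[str, list[str]]:
    """Per-attribute lists of dominant respondents.

    Positive dominance for attribute ``i``: at every question the chosen
    alternative has level 1 for ``i``.  With ``negative=True``, level 0.
    """
    design = raw.design
    target = 0 if negative else 1
    result: dict[str, list[str]] = {a: [] for a in design.scheme.attributes}
    for j, attr in enumerate(design.scheme.attributes):
        wanted = [
            "A" if q.option_a[j] == target else "B" for q in design.questions
        ]
        for rid, row in raw.records.items():
            if list(row) == wanted:
                result[attr].append(rid)
    return result


def run_qc(raw: RawResponseSet, exclude_dominant: bool = False) -> tuple[RawResponseSet, QCReport]:
    """Apply all screening rules; returns the valid set and the report.

    Dominant responders are retained by default (they are reported, not
    excluded); ``exclude_dominant=True`` drops them for sensitivity
    analyses.
    """
    complete = filter_incomplete(raw)
    nontraders = detect_nontrading(complete)
    valid_ids = [r for r in complete.records if r not in nontraders]
    valid = complete.subset(valid_ids)
    pos = detect_dominance(valid)
    neg = detect_dominance(valid, negative=True)
    flagged = sorted({rid for ids in pos.values() for rid in ids})
    excluded = sorted(set(raw.records) - set(valid_ids))
    if exclude_dominant:
        valid_ids = [r for r in valid_ids if r not in set(flagged)]
        valid = complete.subset(valid_ids)
    report = QCReport(
        n_initiated=raw.n_respondents,
        n_complete=complete.n_respondents,
        n_nontraders_excluded=len(nontraders),
        n_valid=complete.n_respondents - len(nontraders),
        dominance_counts={a: len(ids) for a, ids in pos.items()},
        negative_dominance_counts={a: len(ids) for a, ids in neg.items()},
        excluded_ids=excluded,
        flagged_ids=flagged,
    )
    return valid, report
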