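"""Scoring engine: per-disease scores, total score, triage recommendation.

The instrument's score for one participant is computed disease by disease:
each selected answer option contributes its configured integer weight to
every disease it carries a weight for, and a disease score is the plain sum
of those contributions. The total score is the sum of the per-disease
scores. A disease whose score reaches threshold 1 (``score >= threshold``;
a score equal to the threshold passes) triggers the advice to visit a
general physician; reaching threshold 2 triggers the advice to visit a
rheumatologist. The overall recommendation is the highest level attained
for *any* disease.

Unanswered questions contribute nothing; enforcement of ``required``
questions happens during response validation, not scoring. Each selected
option is counted exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .config import ScoringConfig
from .exceptions import ResponseValidationError, UnknownDiseaseError


class Recommendation(str, Enum):
    """Triage advice levels, ordered none < primary_care < rheumatology."""

    NONE = "none"
    PRIMARY_CARE = "primary_care"
    RHEUMATOLOGY = "rheumatology"

    @property
    def level(self) -> int:
        return {"none": 0, "primary_care": 1, "rheumatology": 2}[self.value]


@dataclass(frozen=True)
class ResponseSet:
    """One participant's answers: question id -> set of selected option ids."""

    participant_id: str
    selections: dict[str, frozenset[str]] = field(default_factory=dict)

    @staticmethod
    def from_raw(participant_id: str, selections: dict[str, set[str] | list[str]]):
        return ResponseSet(
            participant_id,
            {q: frozenset(opts) for q, opts in selections.items()},
        )


@dataclass(frozen=True)
class ScoreResult:
    participant_id: str
    disease_scores: dict[str, int]
    total_score: int
    passed_t1: frozenset[str]
    passed_t2: frozenset[str]
    recommendation: Recommendation


def validate_responses(config: ScoringConfig, responses: ResponseSet) -> list[str]:
    """Collect every inconsistency between ``responses`` and ``config``."""
    violations: list[str] = []
    qindex = config.question_by_id()
    for qid, selected in responses.selections.items():
        q = qindex.get(qid)
        if q is None:
            violations.append(f"answer references undeclared question {qid!r}")
            continue
        known = {o.id for o in q.options}
        for oid in selected:
            if oid not in known:
                violations.append(
                    f"question {qid!r}: selected option {oid!r} is not one of "
                    f"its options"
                )
        if q.kind in ("single_choice", "boolean") and len(selected) > 1:
            violations.append(
                f"question {qid!r} ({q.kind}): at most one option may be "
                f"selected, got {len(selected)}"
            )
    for q in config.questions:
        if q.required and not responses.selections.get(q.id):
            violations.append(f"required question {q.id!r} has no answer")
    return violations


def score_disease(
    config: ScoringConfig, responses: ResponseSet, disease: str, *, validate: bool = True
) -> int:
    """Sum the selected options' weights for one disease.

    An option without a weight entry for ``disease`` contributes 0.
    """
    if disease not in set(config.disease_ids()):
        raise UnknownDiseaseError(f"disease {disease!r} is not declared in the config")
    if validate:
        violations = validate_responses(config, responses)
        if violations:
            raise ResponseValidationError(violations)
    oindex = config.option_index()
    total = 0
    for qid, selected in responses.selections.items():
        opts = oindex[qid]
        for oid in selected:
            total += opts[oid].weights.get(disease, 0)
    return total


def score_responses(config: ScoringConfig, responses: ResponseSet) -> ScoreResult:
    """Compute the full :class:`ScoreResult` for one participant."""
    violations = validate_responses(config, responses)
    if violations:
        raise ResponseValidationError(violations)
    disease_scores = {
        d: score_disease(config, responses, d, validate=False)
        for d in config.disease_ids()
    }
    total = sum(disease_scores.values())
    thr = config.thresholds_by_disease()
    passed_t1 = frozenset(
        d for d, s in disease_scores.items() if s >= thr[d].threshold1
    )
    passed_t2 = frozenset(
        d for d, s in disease_scores.items() if s >= thr[d].threshold2
    )
    if passed_t2:
        rec = Recommendation.RHEUMATOLOGY
    elif passed_t1:
        rec = Recommendation.PRIMARY_CARE
    else:
        rec = Recommendation.NONE
    return ScoreResult(
        participant_id=responses.participant_id,
        disease_scores=disease_scores,
        total_score=total,
        passed_t1=passed_t1,
        passed_t2=passed_t2,
        recommendation=rec,
    )
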