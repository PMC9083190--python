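"""Cohort tables: response CSVs in, scored-cohort CSVs out.

Two flat CSV layouts are used throughout (comma separator, UTF-8, header
row mandatory, ``.`` decimal, booleans serialised as 0/1):

* **response table** — one row per participant, wide format: a
  ``participant_id`` column, one column per question id whose cell holds
  the selected option ids (semicolon-separated for multi-choice, empty for
  no selection), and an ``outcome`` column in {0, 1} (1 = immune-mediated
  outcome).
* **scored table** — one row per participant with ``participant_id``,
  one ``score_<disease>`` column per disease (optional on read), a
  ``total_score`` column, ``passed_t1``/``passed_t2`` 0/1 flags (threshold
  passed for *any* disease), ``passed_t1_diseases``/``passed_t2_diseases``
  semicolon-joined disease ids (optional on read), ``recommendation``
  (optional) and ``outcome``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .config import ScoringConfig
from .exceptions import CohortFormatError, ResponseValidationError
from .scoring import ResponseSet, ScoreResult, score_responses, validate_responses


@dataclass(frozen=True)
class LabelledParticipant:
    participant_id: str
    total_score: int
    passed_t1: bool
    passed_t2: bool
    outcome: int
    disease_scores: dict[str, int] | None = None

    def __post_init__(self):
        if self.outcome not in (0, 1):
            raise CohortFormatError(
                f"participant {self.participant_id!r}: outcome must be 0 or 1, "
                f"got {self.outcome!r}"
            )
        if self.passed_t2 and not self.passed_t1:
            raise CohortFormatError(
                f"participant {self.participant_id!r}: passed_t2 without passed_t1 "
                f"is inconsistent (threshold2 >= threshold1)"
            )


@dataclass
class ScoredCohort:
    name: str
    participants: list[LabelledParticipant] = field(default_factory=list)

    def __post_init__(self):
        if not self.participants:
            raise CohortFormatError(f"cohort {self.name!r} is empty")
        ids = [p.participant_id for p in self.participants]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortFormatError(
                f"cohort {self.name!r}: duplicate participant ids {dupes}"
            )

    @property
    def n(self) -> int:
        return len(self.participants)

    def total_scores(self) -> list[int]:
        return [p.total_score for p in self.participants]

    def outcomes(self) -> list[int]:
        return [p.outcome for p in self.participants]


def _parse_cell(cell) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return frozenset()
    text = str(cell).strip()
    if not text:
        return frozenset()
    return frozenset(tok.strip() for tok in text.split(";") if tok.strip())


def read_cohort_responses(
    path: str | Path, config: ScoringConfig
) -> list[tuple[ResponseSet, int]]:
    """Read a wide response table, validating every row against ``config``.

    Returns ``(ResponseSet, outcome)`` pairs in file order. Errors name the
    offending row (1-based, excluding the header) and token.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "participant_id" not in df.columns:
        raise CohortFormatError(f"{path}: missing required column 'participant_id'")
    if "outcome" not in df.columns:
        raise CohortFormatError(f"{path}: missing required column 'outcome'")
    qids = {q.id for q in config.questions}
    unknown_cols = set(df.columns) - qids - {"participant_id", "outcome"}
    if unknown_cols:
        raise CohortFormatError(
            f"{path}: columns {sorted(unknown_cols)} match no question id in the config"
        )
    out: list[tuple[ResponseSet, int]] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rowd = dict(zip(df.columns, row))
        raw_outcome = str(rowd["outcome"]).strip()
        if raw_outcome not in ("0", "1"):
            raise CohortFormatError(
                f"{path}: row {i}: outcome must be 0 or 1, got {raw_outcome!r}"
            )
        selections = {
            qid: _parse_cell(rowd[qid])
            for qid in df.columns
            if qid in qids and _parse_cell(rowd[qid])
        }
        rs = ResponseSet(str(rowd["participant_id"]), selections)
        violations = validate_responses(config, rs)
        if violations:
            raise CohortFormatError(
                f"{path}: row {i}: " + "; ".join(violations)
            )
        out.append((rs, int(raw_outcome)))
    return out


def write_cohort_responses(
    pairs: list[tuple[ResponseSet, int]], config: ScoringConfig, path: str | Path
) -> None:
    """Write ``(ResponseSet, outcome)`` pairs as a wide response table."""
    qids = [q.id for q in config.questions]
    rows = []
    for rs, outcome in pairs:
        row = {"participant_id": rs.participant_id}
        for qid in qids:
            row[qid] = ";".join(sorted(rs.selections.get(qid, frozenset())))
        row["outcome"] = outcome
        rows.append(row)
    pd.DataFrame(rows, columns=["participant_id", *qids, "outcome"]).to_csv(
        path, index=False
    )


def score_cohort(
    config: ScoringConfig,
    pairs: list[tuple[ResponseSet, int]],
    name: str = "cohort",
) -> tuple[ScoredCohort, list[ScoreResult]]:
    """Score every participant and assemble a :class:`ScoredCohort`."""
    participants = []
    results = []
    for rs, outcome in pairs:
        try:
            res = score_responses(config, rs)
        except ResponseValidationError as e:
            raise CohortFormatError(
                f"participant {rs.participant_id!r}: {e}"
            ) from e
        results.append(res)
        participants.append(
            LabelledParticipant(
                participant_id=rs.participant_id,
                total_score=res.total_score,
                passed_t1=bool(res.passed_t1),
                passed_t2=bool(res.passed_t2),
                outcome=outcome,
                disease_scores=res.disease_scores,
            )
        )
    return ScoredCohort(name=name, participants=participants), results


def write_scored_cohort(
    cohort: ScoredCohort,
    path: str | Path,
    results: list[ScoreResult] | None = None,
) -> None:
    """Write a scored table; per-disease columns included when available."""
    by_id = {r.participant_id: r for r in results} if results else {}
    rows = []
    for p in cohort.participants:
        row: dict = {"participant_id": p.participant_id}
        if p.disease_scores:
            for d, s in p.disease_scores.items():
                row[f"score_{d}"] = s
        row["total_score"] = p.total_score
        row["passed_t1"] = int(p.passed_t1)
        row["passed_t2"] = int(p.passed_t2)
        r = by_id.get(p.participant_id)
        if r is not None:
            row["passed_t1_diseases"] = ";".join(sorted(r.passed_t1))
            row["passed_t2_diseases"] = ";".join(sorted(r.passed_t2))
            row["recommendation"] = r.recommendation.value
        row["outcome"] = p.outcome
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_scored_cohort(path: str | Path, name: str | None = None) -> ScoredCohort:
    """Read a scored table, enforcing all participant invariants."""
    df = pd.read_csv(path)
    required = {"participant_id", "total_score", "passed_t1", "passed_t2", "outcome"}
    missing = required - set(df.columns)
    if missing:
        raise CohortFormatError(f"{path}: missing required columns {sorted(missing)}")
    score_cols = [c for c in df.columns if c.startswith("score_")]
    participants = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        for flag in ("passed_t1", "passed_t2"):
            if row[flag] not in (0, 1):
                raise CohortFormatError(
                    f"{path}: row {i}: {flag} must be 0 or 1, got {row[flag]!r}"
                )
        if row["outcome"] not in (0, 1):
            raise CohortFormatError(
                f"{path}: row {i}: outcome must be 0 or 1, got {row['outcome']!r}"
            )
        try:
            participants.append(
                LabelledParticipant(
                    participant_id=str(row["participant_id"]),
                    total_score=int(row["total_score"]),
                    passed_t1=bool(row["passed_t1"]),
                    passed_t2=bool(row["passed_t2"]),
                    outcome=int(row["outcome"]),
                    disease_scores=(
                        {c[len("score_"):]: int(row[c]) for c in score_cols}
                        if score_cols
                        else None
                    ),
                )
            )
        except CohortFormatError as e:
            raise CohortFormatError(f"{path}: row {i}: {e}") from e
    return ScoredCohort(name=name or Path(path).stem, participants=participants)
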