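"""Questionnaire scoring configuration: schema, loading, validation.

A :class:`ScoringConfig` encodes a complete screening instrument: the
diseases it screens for, the questions and answer options, the integer
weight each option contributes to each disease score, and the two
per-disease triage thresholds (threshold 1: advice to visit a general
physician; threshold 2: advice to visit a rheumatologist).

Everything scientific is configuration-driven; the package hard-codes no
disease set. The shipped default configuration (six immune-mediated
rheumatic diseases, 21 questions) is illustrative: it has the correct
schema and realistic score ranges but its weights and thresholds are
authored for this package, not taken from any deployed instrument.

Configurations are plain JSON or YAML. JSON is the canonical round-trip
format; YAML is accepted on load (distinguished by file extension, with a
JSON-first fallback for raw text). The formal JSON Schema for the format
ships as ``data/scoring_config.schema.json``.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .exceptions import ConfigFormatError, ConfigValidationError

SCHEMA_VERSION = "1"

QuestionKind = Literal["single_choice", "multi_choice", "boolean"]


class Disease(BaseModel):
    """A disease the instrument screens for."""

    model_config = ConfigDict(extra="forbid")

    id: str = Field(min_length=1)
    name: str = Field(min_length=1)


class AnswerOption(BaseModel):
    """One selectable answer, with its per-disease integer weights.

    A weight absent from ``weights`` means the option contributes 0 points
    to that disease. One option may carry weights for several diseases at
    once (one symptom can inform many diagnoses). Negative weights are
    permitted by the schema; the shipped default uses non-negative weights
    only.
    """

    model_config = ConfigDict(extra="forbid")

    id: str = Field(min_length=1)
    label: str = Field(min_length=1)
    weights: dict[str, int] = Field(default_factory=dict)


class Question(BaseModel):
    model_config = ConfigDict(extra="forbid")

    id: str = Field(min_length=1)
    text: str = Field(min_length=1)
    kind: QuestionKind
    options: list[AnswerOption]
    required: bool = False


class DiseaseThresholds(BaseModel):
    """Per-disease triage cut-offs. A score >= threshold passes it."""

    model_config = ConfigDict(extra="forbid")

    disease_id: str = Field(min_length=1)
    threshold1: int
    threshold2: int


class ScoringConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    version: str = SCHEMA_VERSION
    diseases: list[Disease]
    questions: list[Question]
    thresholds: list[DiseaseThresholds]

    # -- convenience lookups (derived, not part of the schema) ------------

    def disease_ids(self) -> list[str]:
        return [d.id for d in self.diseases]

    def question_by_id(self) -> dict[str, Question]:
        return {q.id: q for q in self.questions}

    def thresholds_by_disease(self) -> dict[str, DiseaseThresholds]:
        return {t.disease_id: t for t in self.thresholds}

    def option_index(self) -> dict[str, dict[str, AnswerOption]]:
        """question id -> option id -> option."""
        return {q.id: {o.id: o for o in q.options} for q in self.questions}

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.model_dump(), indent=indent, sort_keys=False)


def validate_config(config: ScoringConfig) -> list[str]:
    """Collect every invariant violation in ``config``.

    Returns an empty list iff the configuration is valid. Never raises on
    any structurally parseable config: all cross-reference and ordering
    rules are reported, each violation naming the offending entity and the
    rule it breaks.
    """
    violations: list[str] = []
    declared = set()
    for d in config.diseases:
        if d.id in declared:
            violations.append(f"disease id {d.id!r} declared more than once")
        declared.add(d.id)
    if not config.diseases:
        violations.append("config declares no diseases (at least one required)")

    qids = set()
    nonzero_weight_seen: set[str] = set()
    for q in config.questions:
        if q.id in qids:
            violations.append(f"question id {q.id!r} declared more than once")
        qids.add(q.id)
        if q.kind == "boolean" and len(q.options) != 2:
            violations.append(
                f"question {q.id!r}: boolean questions need exactly 2 options, "
                f"found {len(q.options)}"
            )
        oids = set()
        for o in q.options:
            if o.id in oids:
                violations.append(
                    f"question {q.id!r}: option id {o.id!r} declared more than once"
                )
            oids.add(o.id)
            for did, w in o.weights.items():
                if did not in declared:
                    violations.append(
                        f"question {q.id!r} option {o.id!r}: weight references "
                        f"undeclared disease {did!r}"
                    )
                elif w != 0:
                    nonzero_weight_seen.add(did)

    tdis = set()
    for t in config.thresholds:
        if t.disease_id in tdis:
            violations.append(
                f"thresholds for disease {t.disease_id!r} declared more than once"
            )
        tdis.add(t.disease_id)
        if t.disease_id not in declared:
            violations.append(
                f"thresholds entry references undeclared disease {t.disease_id!r}"
            )
        if not (0 < t.threshold1 <= t.threshold2):
            violations.append(
                f"disease {t.disease_id!r}: thresholds must satisfy "
                f"0 < threshold1 <= threshold2, got "
                f"threshold1={t.threshold1}, threshold2={t.threshold2}"
            )
    for did in declared:
        if did not in tdis:
            violations.append(f"disease {did!r} has no thresholds entry")
        if did not in nonzero_weight_seen:
            violations.append(
                f"disease {did!r} has no option with a nonzero weight anywhere "
                f"in the questionnaire"
            )
    return violations


def _parse_structured_text(text: str, fmt: str | None) -> dict:
    if fmt == "json":
        try:
            data = json.loads(text)
        except json.JSONDecodeError as e:
            raise ConfigFormatError(
                f"invalid JSON at line {e.lineno}, column {e.colno}: {e.msg}"
            ) from e
    elif fmt == "yaml":
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError as e:
            raise ConfigFormatError(f"invalid YAML: {e}") from e
    else:
        # raw text with unknown provenance: JSON first (canonical), then YAML
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            try:
                data = yaml.safe_load(text)
            except yaml.YAMLError as e:
                raise ConfigFormatError(
                    f"source is neither valid JSON nor valid YAML: {e}"
                ) from e
    if not isinstance(data, dict):
        raise ConfigFormatError(
            f"top level of a scoring config must be a mapping, got {type(data).__name__}"
        )
    return data


def load_scoring_config(source: str | Path) -> ScoringConfig:
    """Load and fully validate a scoring configuration.

    ``source`` is a path to a ``.json``/``.yaml``/``.yml`` file, or raw
    configuration text. Raises :class:`ConfigFormatError` on parse/shape
    failure and :class:`ConfigValidationError` (listing every violation)
    when the parsed config breaks an invariant.
    """
    def _looks_like_path(s: str) -> bool:
        if "\n" in s or len(s) > 4096:
            return False
        try:
            return Path(s).is_file()
        except OSError:
            return False

    fmt = None
    if isinstance(source, Path) or (isinstance(source, str) and _looks_like_path(source)):
        path = Path(source)
        suffix = path.suffix.lower()
        fmt = {"json": "json", ".json": "json", ".yaml": "yaml", ".yml": "yaml"}.get(
            suffix
        )
        text = path.read_text(encoding="utf-8")
    else:
        text = str(source)
    data = _parse_structured_text(text, fmt)
    try:
        config = ScoringConfig.model_validate(data)
    except ValidationError as e:
        errs = [
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in e.errors()
        ]
        raise ConfigFormatError(
            "config does not match the schema:\n" + "\n".join(f"  - {x}" for x in errs)
        ) from e
    violations = validate_config(config)
    if violations:
        raise ConfigValidationError(violations)
    return config


def write_scoring_config(config: ScoringConfig, path: str | Path) -> None:
    """Write a config as canonical JSON (or YAML if the extension says so)."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(
            yaml.safe_dump(config.model_dump(), sort_keys=False), encoding="utf-8"
        )
    else:
        path.write_text(config.to_json() + "\n", encoding="utf-8")


def config_json_schema() -> dict:
    """The formal JSON Schema for the configuration format."""
    return ScoringConfig.model_json_schema()


def default_config() -> ScoringConfig:
    """The shipped illustrative six-disease configuration."""
    text = (
        resources.files("rheumascore.data")
        .joinpath("default_config.json")
        .read_text(encoding="utf-8")
    )
    return load_scoring_config(text)
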