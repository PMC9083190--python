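"""Exception hierarchy for rheumascore.

All package errors derive from :class:`RheumascoreError` so callers (and the
CLI) can catch them uniformly and map them to a nonzero exit code.
"""

from __future__ import annotations


class RheumascoreError(Exception):
    """Base class for all rheumascore errors."""


class ConfigFormatError(RheumascoreError):
    """The scoring configuration could not be parsed (bad JSON/YAML or shape)."""


class ConfigValidationError(RheumascoreError):
    """A parseable configuration violates one or more invariants.

    Carries the full list of violations, not just the first.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        msg = "invalid scoring configuration:\n" + "\n".join(
            f"  - {v}" for v in self.violations
        )
        super().__init__(msg)


class ResponseValidationError(RheumascoreError):
    """A participant's answers are inconsistent with the configuration."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        msg = "invalid responses:\n" + "\n".join(f"  - {v}" for v in self.violations)
        super().__init__(msg)


class UnknownDiseaseError(RheumascoreError, KeyError):
    """A disease id was requested that the configuration does not declare."""


class CohortFormatError(RheumascoreError):
    """A cohort CSV file is malformed or references unknown ids."""


class EvaluationError(RheumascoreError):
    """A statistical evaluation was requested on degenerate input."""


class SimulationError(RheumascoreError):
    """A simulation configuration is inconsistent or a target is unattainable."""
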