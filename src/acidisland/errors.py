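"""Exception hierarchy for the acid-island pipeline.

All package errors derive from :class:`AcidIslandError` so callers can
catch pipeline failures without masking programming errors.
"""


class AcidIslandError(Exception):
    """Base class for all package errors."""


class SchemaError(AcidIslandError):
    """An input table is missing a required column or is structurally invalid."""


class RowError(AcidIslandError):
    """A single input row violates a record invariant."""


class DomainError(AcidIslandError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class FitError(AcidIslandError):
    """A regression cannot be fitted (too few points, degenerate design)."""


class BracketError(AcidIslandError):
    """A root bracket does not contain the sought threshold crossing."""


class NonMonotoneError(AcidIslandError):
    """The potential-acid-load curve is not strictly decreasing."""


class GenerationError(AcidIslandError):
    """The synthetic generator cannot satisfy its geometric constraints."""


class ConfigError(AcidIslandError):
    """A pipeline configuration is incomplete or inconsistent."""
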