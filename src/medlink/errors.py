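"""Exception hierarchy.

Readers and validators fail loud: integrity violations (bad offsets,
duplicate keys, unknown labels) raise instead of being repaired silently.
"""


class MedLinkError(Exception):
    """Base class for all package errors."""


class ConfigError(MedLinkError, ValueError):
    """Invalid configuration value."""


class DuplicateKeyError(MedLinkError, ValueError):
    """A key (fine type, CUI, candidate, span) occurs more than once."""


class UnknownTypeError(MedLinkError, KeyError):
    """A fine semantic type is not part of the scheme."""


class UnknownGroupError(MedLinkError, KeyError):
    """A group label is not part of the scheme."""


class InvalidSchemeError(MedLinkError, ValueError):
    """A type-scheme table violates the scheme invariants."""


class OffsetIntegrityError(MedLinkError, ValueError):
    """A mention's offsets do not reproduce its surface string."""


class DanglingAnnotationError(MedLinkError, ValueError):
    """An annotation refers to a document that does not exist."""


class DanglingCandidateError(MedLinkError, KeyError):
    """A candidate CUI does not resolve in the concept inventory."""


class InvalidEntryError(MedLinkError, ValueError):
    """A concept-inventory row violates entry invariants."""


class OrderingError(MedLinkError, ValueError):
    """Candidate scores are not non-increasing."""


class DegenerateTrainingError(MedLinkError, ValueError):
    """Training data carries no positive label for any group."""


class OracleUnavailableError(MedLinkError, ValueError):
    """A gold CUI needed by the oracle is missing or unresolvable."""


class UndefinedMetricError(MedLinkError, ZeroDivisionError):
    """A metric's denominator is empty (no gold items / no positives)."""


class NoOverlapError(MedLinkError, ValueError):
    """Two corpora share no documents, so they cannot be compared."""
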