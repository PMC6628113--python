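"""Exception hierarchy.

Everything derives from :class:`OlfthreshError` so callers can catch the
package's own failures in one clause; the mixin bases keep ``ValueError`` /
``RuntimeError`` semantics for generic code.
"""

__all__ = [
    "OlfthreshError",
    "DomainError",
    "ConfigError",
    "StateError",
    "InsufficientDataError",
    "DegenerateDataError",
    "SchemaError",
]


class OlfthreshError(Exception):
    """Base class for all package errors."""


class DomainError(OlfthreshError, ValueError):
    """An argument lies outside its mathematical or physical domain."""


class ConfigError(OlfthreshError, ValueError):
    """An invalid procedure or cohort configuration."""


class StateError(OlfthreshError, RuntimeError):
    """An operation was called on a state that does not admit it."""


class InsufficientDataError(OlfthreshError, ValueError):
    """Too few observations for the requested statistic."""


class DegenerateDataError(OlfthreshError, ValueError):
    """Data with zero variance where spread is required."""


class SchemaError(OlfthreshError, ValueError):
    """A file whose layout could not be interpreted."""
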