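"""Exception hierarchy shared across the package."""


class SleepSSMError(Exception):
    """Base class for all package errors."""


class ParseError(SleepSSMError, ValueError):
    """A token or field in an input record could not be interpreted."""


class StructureError(SleepSSMError, ValueError):
    """An input record violated a structural contract (gaps, duplicates, empty)."""


class ValidationError(SleepSSMError, ValueError):
    """A parsed value violated a domain invariant (negative duration etc.)."""


class RoleError(SleepSSMError, KeyError):
    """A signal record lacks a channel role required by the operation."""


class UndefinedIndexError(SleepSSMError, ZeroDivisionError):
    """A misperception ratio is undefined (objective denominator is zero)."""


class ComparisonError(SleepSSMError, ValueError):
    """A group comparison cannot be computed (e.g. all values missing)."""
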