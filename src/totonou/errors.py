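"""Typed exceptions raised across the package.

Every error raised on bad input names the defect (e.g. ``"ragged
channels"``) so callers and batch pipelines can log what was wrong
without parsing stack traces.
"""


class TotonouError(Exception):
    """Base class for all package-specific errors."""


class DataFormatError(TotonouError):
    """A file or in-memory structure violates a format invariant."""


class ParameterError(TotonouError, ValueError):
    """An argument is outside its valid domain or infeasible."""


class InsufficientDataError(TotonouError):
    """Not enough usable data to carry out the requested computation."""
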