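"""Package exception hierarchy.

The CLI maps :class:`InvalidInputError` to exit code 2 and
:class:`FitFailureError` to exit code 3.
"""


class UteqmtError(Exception):
    """Base class for package errors."""


class InvalidInputError(UteqmtError, ValueError):
    """Invalid parameters, protocol, spec, or input data."""


class FitFailureError(UteqmtError, RuntimeError):
    """A fit (or an entire cohort run) failed irrecoverably."""
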