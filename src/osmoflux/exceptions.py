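"""Exception hierarchy.

All package errors derive from :class:`OsmofluxError` so callers (and the CLI)
can distinguish data problems (exit code 1) from usage problems (exit code 2,
handled by the argument parser).
"""


class OsmofluxError(Exception):
    """Base class for all osmoflux errors."""


class InvalidInputError(OsmofluxError, ValueError):
    """A physical quantity or array argument violates a precondition."""


class InsufficientDataError(OsmofluxError, ValueError):
    """Too few samples / points / frames to run the requested estimator."""


class SchemaError(OsmofluxError, ValueError):
    """A trace or config file is missing a required metadata key."""


class FormatError(OsmofluxError, ValueError):
    """A trace or config file is structurally malformed."""


class InvalidModeError(OsmofluxError, ValueError):
    """A fluctuation mode order outside the admissible range was requested."""


class InvalidGeometryError(OsmofluxError, ValueError):
    """A contour or rendering geometry is inconsistent (e.g. exits the frame)."""
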