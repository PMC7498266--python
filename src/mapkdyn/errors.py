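"""Exception hierarchy.

``ParameterError``/``ValidationError`` signal bad inputs or configuration and
map to CLI exit code 2; any other ``MapkdynError`` is a runtime failure and
maps to exit code 1.
"""


class MapkdynError(Exception):
    """Base class for all package errors."""


class ParameterError(MapkdynError, ValueError):
    """A simulation or analysis parameter violates its invariants."""


class ValidationError(MapkdynError, ValueError):
    """An input file, table or configuration failed schema validation."""


class EmptyTraceError(MapkdynError):
    """Every frame of a trace was invalid."""


class FitError(MapkdynError):
    """A curve fit could not be performed (e.g. zero-mass profile)."""
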