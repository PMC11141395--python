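"""Exception hierarchy.

All package-specific failures derive from :class:`BiteCountError` so callers
can catch one base class; plain ``ValueError`` is reserved for bad parameter
values (negative window lengths and the like).
"""


class BiteCountError(Exception):
    """Base class for all bitecount errors."""


class SchemaError(BiteCountError):
    """A delimited file does not match the documented column schema."""


class DataError(BiteCountError):
    """File parsed but its content violates a series invariant."""


class BackendContractError(BiteCountError):
    """A landmark backend returned something other than 468 points or None."""


class DegenerateGeometryError(BiteCountError):
    """Mouth-corner key points coincide; the ratio denominator is zero."""


class PairingError(BiteCountError):
    """A video has no matching annotation record (or vice versa)."""


class TuningError(BiteCountError):
    """Threshold search cannot proceed (e.g. no meals survive filtering)."""


class ConfigError(BiteCountError):
    """A simulation or search configuration is internally inconsistent."""


class UndefinedAccuracyError(BiteCountError, ValueError):
    """Accuracy is undefined when the annotated total is zero."""
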