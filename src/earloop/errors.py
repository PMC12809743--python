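"""Exception hierarchy shared across the pipeline."""


class EarloopError(Exception):
    """Base class for all package-specific errors."""


class FormatError(EarloopError):
    """On-disk artifact is malformed (missing sidecar, bad line, bad schema)."""


class ValidationError(EarloopError):
    """A value violates a documented invariant (fs <= 0, VAS outside [0, 100], ...)."""


class ParameterError(EarloopError):
    """A caller-supplied parameter is outside its valid range."""


class SchemaError(EarloopError):
    """Feature dimensions or retained-dimension masks do not line up."""


class StateError(EarloopError):
    """Operation requires a fitted/complete object that is not in that state."""


class DegenerateInputError(EarloopError):
    """Input is rank-deficient or otherwise unusable (e.g. identical channels)."""


class CoverageError(EarloopError):
    """Frames or epochs do not cover the required span (empty aggregation bin)."""


class ExhaustionError(EarloopError):
    """A selection window has no unplayed songs left."""


class NoSignalError(EarloopError):
    """Every sample of a stream was flagged as noise; nothing to summarize."""
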