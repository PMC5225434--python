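"""Exception hierarchy for loopgate.

All package errors derive from :class:`LoopgateError` so callers (and the CLI)
can distinguish data/analysis failures from configuration problems.
"""


class LoopgateError(Exception):
    """Base class for all loopgate errors."""


class ParseError(LoopgateError):
    """A file could not be parsed (message names the offending line where known)."""


class TopologyError(LoopgateError):
    """Frames disagree with each other or with the supplied atom topology."""


class SelectionError(LoopgateError):
    """A selection expression is invalid or resolves to the wrong cardinality."""


class ValidationError(LoopgateError):
    """Data violates a structural invariant (non-finite coordinates, etc.)."""


class DegenerateFitError(LoopgateError):
    """Superposition target has fewer than 3 non-collinear atoms."""


class SpecError(LoopgateError):
    """A synthetic-data specification violates its invariants."""


class ConfigError(LoopgateError):
    """A pipeline configuration file is invalid (message names the field)."""
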