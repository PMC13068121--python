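"""Exception hierarchy for vestlat."""


class VestlatError(Exception):
    """Base class for all vestlat errors."""


class ConfigurationError(VestlatError):
    """Invalid configuration value; the message names the offending field."""


class DomainError(VestlatError, ValueError):
    """An asymmetry formula was evaluated outside its mathematical domain
    (e.g. a nonpositive denominator)."""


class StateError(VestlatError):
    """An operation was applied to an object in the wrong state
    (e.g. canonicalizing an already-canonical profile)."""


class EstimationError(VestlatError):
    """Too little data to estimate a quantity (e.g. < 2 complete gain pairs)."""


class ImputationError(VestlatError):
    """A query row shares no observed column with any training row."""


class ConvergenceError(VestlatError):
    """An iterative solver failed to converge; the message reports its state."""


class ParseError(VestlatError):
    """A cohort table could not be parsed; the message carries row/column
    coordinates."""


class StageError(VestlatError):
    """A pipeline stage failed; the message names the stage."""
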