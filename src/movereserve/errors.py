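"""Exception hierarchy shared across the pipeline stages."""


class MoveReserveError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MoveReserveError):
    """An invalid configuration field; the message names the field."""


class DimensionError(MoveReserveError):
    """Array/vector lengths do not match the contract."""


class ImputationError(MoveReserveError):
    """A missing minute has no donor day to impute from."""


class ScaleError(MoveReserveError):
    """Operation applied on the wrong count scale (AC vs LAC)."""


class JoinError(MoveReserveError):
    """Subjects present in one table but absent from another."""


class GridMismatchError(MoveReserveError):
    """A fitted model and new data disagree on the evaluation grid."""
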