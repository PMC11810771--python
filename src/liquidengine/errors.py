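"""Exception hierarchy for the engine."""


class LiquidEngineError(Exception):
    """Base class for all package errors."""


class UnknownMethodError(LiquidEngineError, KeyError):
    """No implementations registered under the requested method id."""


class UnknownImplementationError(LiquidEngineError, KeyError):
    """The (method, implementation) pair is not registered."""


class DuplicateImplementationError(LiquidEngineError, ValueError):
    """An implementation id was registered twice for the same method."""


class InvalidParameterError(LiquidEngineError, ValueError):
    """A method parameter violates its contract (even kernel, h <= 0, ...)."""


class InsufficientDataError(LiquidEngineError, ValueError):
    """An operation needs more observations than were supplied."""


class DegenerateStatisticsError(LiquidEngineError, ZeroDivisionError):
    """Statistics are degenerate for the requested ratio (FastAverage == 0)."""


class InvalidTimeError(LiquidEngineError, ValueError):
    """A run time is non-positive where a positive time is required."""


class StorageError(LiquidEngineError, OSError):
    """The run-time store could not be written; message carries the path."""


class MissingDefaultsError(LiquidEngineError, KeyError):
    """No factory-default benchmark table exists for the method."""


class NoBenchmarkError(LiquidEngineError, ValueError):
    """A benchmark table holds no candidate to fuzzy-match against."""


class NoImplementationError(LiquidEngineError, RuntimeError):
    """Selection was requested but no implementation is available."""
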