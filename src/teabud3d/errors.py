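"""Exception hierarchy shared across the package."""


class TeaBudError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(TeaBudError, ValueError):
    """A scene or generator specification violates its invariants."""


class InvalidBoxError(TeaBudError, ValueError):
    """A bounding box has non-positive width or height."""


class InvalidCurveError(TeaBudError, ValueError):
    """A precision-recall curve has decreasing recalls."""


class InvalidBatchError(TeaBudError, ValueError):
    """A ray batch has mismatched lengths or out-of-range values."""


class InvalidWeightsError(TeaBudError, ValueError):
    """A loss-weight set contains a negative weight."""


class InvalidThresholdError(TeaBudError, ValueError):
    """A filtering threshold is out of its valid range."""


class InsufficientPointsError(TeaBudError, ValueError):
    """An operation received fewer points than it needs."""


class EmptyClusterError(TeaBudError, ValueError):
    """A per-cluster operation received an empty cluster."""


class MissingNormalError(TeaBudError, ValueError):
    """An offset was requested for a candidate without a fitted-plane normal."""


class ConfigurationError(TeaBudError, ValueError):
    """A pipeline or clustering configuration is incomplete or inconsistent."""


class UndefinedMetricError(TeaBudError, ValueError):
    """A ratio metric has a zero denominator and is reported as missing."""


class InvalidDepthError(TeaBudError, ValueError):
    """A depth value is non-positive where positivity is required."""


class PlyFormatError(TeaBudError, ValueError):
    """A PLY file is malformed; the message names the byte offset."""
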