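"""Exception hierarchy shared across the package."""


class EpihybridError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(EpihybridError, ValueError):
    """A configuration field is missing, out of range, or inconsistent."""


class ShapeError(EpihybridError, ValueError):
    """An array does not have the shape a stage requires."""


class ParseError(EpihybridError, ValueError):
    """A text input could not be parsed; carries row/column context."""


class DomainError(EpihybridError, ValueError):
    """A numeric input lies outside the domain of an operation."""


class TrainingError(EpihybridError, RuntimeError):
    """Training cannot proceed (e.g. single-class data, degenerate features)."""


class UndefinedMetricError(EpihybridError, ZeroDivisionError):
    """A confusion-matrix statistic has an empty denominator."""


class BundleError(EpihybridError, ValueError):
    """A serialized model bundle is malformed or violates invariants."""
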