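"""Exception hierarchy shared across the pipeline stages."""


class ScnPhaseError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ScnPhaseError):
    """A file or in-memory structure violates the expected layout."""


class InsufficientDataError(ScnPhaseError):
    """Fewer frames, pixels or neurons than the analysis requires."""


class MaskError(ScnPhaseError):
    """Tissue mask is empty or inconsistent with the intensity grid."""


class ConfigError(ScnPhaseError):
    """A configuration value is outside its valid range."""


class CalibrationError(ScnPhaseError):
    """The order-parameter calibration has no solution on the first branch."""


class SimulationError(ScnPhaseError):
    """Numerical failure (e.g. NaN state) during Kuramoto integration."""
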