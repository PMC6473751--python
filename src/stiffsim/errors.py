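"""Exception and warning types shared across the package."""


class StiffsimError(Exception):
    """Base class for all package-specific errors."""


class InvalidMeasurementError(StiffsimError, ValueError):
    """A physical measurement violates its invariants (e.g. dry mass <= 0)."""


class InvalidInputError(StiffsimError, ValueError):
    """A derived-quantity input is outside its physical domain."""


class UnknownResidueError(StiffsimError, KeyError):
    """A peptide sequence contains a letter outside the 20 standard codes."""


class MissingCalibrationError(StiffsimError, ValueError):
    """A calibration table is empty or unusable."""


class GridError(StiffsimError, ValueError):
    """A discretization grid violates its invariants."""


class FitError(StiffsimError, RuntimeError):
    """A regression failed to converge or was ill-posed."""


class DesignError(StiffsimError, ValueError):
    """The experimental design is insufficient for the requested fit."""


class HorizonExceededError(StiffsimError, RuntimeError):
    """A requested event was not reached within the simulated horizon."""


class ConfigError(StiffsimError, ValueError):
    """A run configuration file is invalid."""


class NoTransportWarning(UserWarning):
    """Solute radius meets or exceeds the mesh size: in-gel diffusivity is 0."""


class ExtrapolationWarning(UserWarning):
    """A calibration lookup fell outside the table and was clamped."""


class LinearRangeWarning(UserWarning):
    """The linearized rate law was used outside its validity range."""
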