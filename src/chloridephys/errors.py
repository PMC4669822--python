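"""Exception hierarchy.

Exit-code mapping used by the CLI: ConfigError -> 2 (validation),
SimulationError / AnalysisError -> 3 (compute), ParseError -> 4 (I/O).
"""


class ChloridephysError(Exception):
    """Base class for all package errors."""


class ConfigError(ChloridephysError):
    """Invalid configuration or parameter set, detected before any compute."""


class SimulationError(ChloridephysError):
    """Numerical failure of a simulation (e.g. unstable integration step)."""


class ProtocolError(ChloridephysError):
    """A recording lacks the protocol epoch an analysis requires."""


class AnalysisError(ChloridephysError):
    """An analysis cannot produce a result from the given data."""


class CalibrationError(ChloridephysError):
    """Inconsistent fluorescence calibration (e.g. r_max <= r_min)."""


class SaturationError(AnalysisError):
    """A fura-2 ratio at or above r_max: concentration undefined."""


class ParseError(ChloridephysError):
    """A data file could not be read into a valid object."""
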