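"""Exception types shared across the package."""


class DustRiskError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(DustRiskError, ValueError):
    """A physical parameter violates its admissible range."""


class ConfigurationError(DustRiskError, ValueError):
    """A configuration value or combination is inconsistent or unsupported."""


class NoSolutionError(DustRiskError, ValueError):
    """A requested inversion or calibration has no solution."""
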