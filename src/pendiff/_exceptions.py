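"""Exception hierarchy."""


class PendiffError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PendiffError):
    """Inconsistent or infeasible configuration."""


class ParameterError(PendiffError):
    """Diffusion parameters outside their admissible domain."""


class DataError(PendiffError):
    """Malformed or internally inconsistent input data."""


class EstimationError(PendiffError):
    """Insufficient or degenerate data for estimation."""


class SimulationError(PendiffError):
    """Trial simulation failed to terminate within the step cap."""
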