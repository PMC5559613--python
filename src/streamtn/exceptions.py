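"""Package-wide exception hierarchy."""


class StreamTNError(Exception):
    """Base class for all streamtn errors."""


class NetworkError(StreamTNError):
    """Invalid stream-network topology or geometry."""


class ValidationError(StreamTNError, ValueError):
    """Invalid user input (tables, parameters, thresholds)."""


class ConfigError(StreamTNError):
    """Invalid or incomplete configuration."""


class FittingError(StreamTNError):
    """Model estimation failed (rank deficiency, non-PD covariance, ...)."""


class SimulationError(StreamTNError):
    """Synthetic-data generation failed."""
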