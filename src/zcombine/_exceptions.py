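"""Exception hierarchy shared across the package."""


class ZCombineError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ZCombineError, ValueError):
    """Invalid simulation or run configuration."""


class DesignError(ZCombineError, ValueError):
    """Invalid experimental design (arms, replicate counts, sample labels)."""


class EstimationError(ZCombineError, ValueError):
    """Degenerate or infeasible null-variance estimation."""
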