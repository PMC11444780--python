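"""Exception hierarchy shared across the package."""


class SplitcostError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(SplitcostError, ValueError):
    """Invalid generator or model parameter (non-positive shape/scale, bad n, ...)."""


class ConfigError(SplitcostError, ValueError):
    """Malformed or inconsistent run configuration."""


class CategorizationError(SplitcostError, ValueError):
    """A breakpoint scheme cannot be applied to the given values."""


class DesignError(SplitcostError, ValueError):
    """Invalid model design (rank deficiency, wrong predictor mode, ...)."""


class FitError(SplitcostError, RuntimeError):
    """Model fitting failed (non-convergence, non-bracketable optimum, ...)."""


class DataError(SplitcostError, ValueError):
    """Invalid dataset contents (non-positive mass, NaN predictor, mismatch)."""
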