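"""Exception types shared across the package."""


class DyadiscError(Exception):
    """Base class for package errors."""


class ConfigurationError(DyadiscError, ValueError):
    """A simulation or run configuration field is invalid; names the field."""


class SchemaError(DyadiscError, ValueError):
    """A table is missing columns or violates a declared range/uniqueness rule."""


class UndefinedCorrelationError(DyadiscError, ValueError):
    """Correlation requested on a zero-variance series; never silently zero."""


class DegenerateDataError(DyadiscError, ValueError):
    """Data too degenerate for the requested fit or inference (e.g. df <= 0)."""


class RankDeficiencyError(DyadiscError, ValueError):
    """Fixed-effect design matrix is collinear; fit refused rather than silent."""


class ConvergenceError(DyadiscError, RuntimeError):
    """Optimizer failed and inference on the fit was requested anyway."""
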