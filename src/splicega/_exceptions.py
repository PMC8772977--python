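"""Exception types shared across the package."""


class SpliceGAError(Exception):
    """Base class for all package errors."""


class MatrixParseError(SpliceGAError, ValueError):
    """A delimited matrix file could not be parsed."""


class EmptyMatrixError(SpliceGAError, ValueError):
    """No usable features remain after filtering."""


class ConfigError(SpliceGAError, ValueError):
    """An invalid configuration value."""


class DegenerateFeatureError(SpliceGAError, ValueError):
    """A zero-norm feature column reached a computation that requires X_j'X_j > 0."""


class DegenerateStatisticError(SpliceGAError, ValueError):
    """A test statistic is undefined for the given inputs."""
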