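"""Exception hierarchy.

Error classes are partitioned so the CLI can map them onto distinct exit
codes: configuration problems, malformed input data, infeasible downsampling
depths, degenerate statistical designs, and curve-fit failures.
"""


class SatDepthError(Exception):
    """Base class for all package errors."""


class ParameterError(SatDepthError, ValueError):
    """Invalid simulation or analysis parameters."""


class FormatError(SatDepthError, ValueError):
    """Malformed input file or in-memory container."""


class DepthError(SatDepthError, ValueError):
    """Requested downsampling depth is infeasible."""


class DesignError(SatDepthError, ValueError):
    """Statistical design is degenerate (e.g. a group with <2 samples)."""


class FitError(SatDepthError, RuntimeError):
    """Nonlinear fit failed to converge or produced a non-saturating curve."""


class ConfigError(SatDepthError, ValueError):
    """Invalid pipeline configuration."""
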