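"""Typed exceptions raised across the package.

Undefined measures raise rather than silently return 0, so pipelines must
handle dead channels explicitly.
"""


class CohbiasError(Exception):
    """Base class for all package errors."""


class SpectralError(CohbiasError):
    """Invalid input to the tapered-transform / epoching layer."""


class UndefinedMeasureError(CohbiasError):
    """A coherence measure is undefined for the given ensemble
    (all-zero amplitudes, zero variance, too few trials)."""


class GridError(CohbiasError):
    """Electrode-grid geometry is invalid or degenerate."""


class ConfigError(CohbiasError):
    """Malformed analysis or simulation configuration."""
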