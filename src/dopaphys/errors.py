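"""Exception hierarchy shared across the package.

Every error raised on bad input names the offending record (unit, cell or
file) so that batch runs can log and continue.
"""


class DopaphysError(Exception):
    """Base class for all package errors."""


class FormatError(DopaphysError):
    """On-disk data does not match the expected schema (missing columns/header)."""


class ValidationError(DopaphysError):
    """Data violates a type invariant (non-monotone spike times, NaN samples...)."""


class ConfigError(DopaphysError):
    """A simulation or protocol configuration is inconsistent or infeasible."""


class InsufficientDataError(DopaphysError):
    """Too few observations for the requested statistic (e.g. <10 ISIs)."""


class ProtocolError(DopaphysError):
    """A trace does not carry the protocol/stimulus metadata an analysis needs."""


class ResolutionError(DopaphysError):
    """Sampling rate too low to resolve the measured kinetics."""


class NormalizationError(DopaphysError):
    """Baseline-normalization undefined (zero baseline firing rate)."""


class SizeError(DopaphysError):
    """A requested simulation would be unreasonably large."""
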