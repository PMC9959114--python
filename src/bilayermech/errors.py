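"""Exception hierarchy.

CLI exit codes: :class:`DataError`, :class:`FormatError`, :class:`PipelineError`
and :class:`FitError` map to exit code 1 (bad data), :class:`ConfigurationError`
to exit code 2 (bad configuration).
"""


class BilayerMechError(Exception):
    """Base class for all package errors."""


class DomainError(BilayerMechError, ValueError):
    """A physical quantity is outside its valid domain (e.g. thickness <= 0)."""


class DataError(BilayerMechError):
    """Measured data violates an invariant (e.g. non-positive capacitance)."""


class FormatError(DataError):
    """A trace or manifest file could not be parsed."""


class PipelineError(BilayerMechError):
    """An analysis stage could not proceed (e.g. no voltage steps found)."""


class FitError(PipelineError):
    """A regression stage had too few or degenerate points."""


class ConfigurationError(BilayerMechError):
    """Invalid user configuration (e.g. too few bootstrap replicates)."""
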