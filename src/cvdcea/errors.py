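"""Exception hierarchy.

All package errors derive from :class:`CVDCEAError` so callers can catch
one base class; subclasses distinguish configuration mistakes from model
assembly failures and data problems.
"""


class CVDCEAError(Exception):
    """Base class for all cvdcea errors."""


class ConfigurationError(CVDCEAError, ValueError):
    """Invalid configuration value; the message names the offending field."""


class DomainError(CVDCEAError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class EligibilityError(CVDCEAError, ValueError):
    """An individual is not eligible for the requested operation
    (e.g. risk prediction for someone with prior CVD)."""


class CalibrationError(CVDCEAError, RuntimeError):
    """Risk calibration could not be completed; the message names the cell."""


class ModelError(CVDCEAError, RuntimeError):
    """Markov model assembly or simulation failure."""


class DataError(CVDCEAError, ValueError):
    """A data table is missing an entry or violates its invariants."""
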