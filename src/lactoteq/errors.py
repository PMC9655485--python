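"""Exception hierarchy for lactoteq.

All errors derive from :class:`LactoteqError` so callers can catch the
package's failures with a single ``except`` clause.
"""


class LactoteqError(Exception):
    """Base class for all lactoteq errors."""


class SchemaError(LactoteqError):
    """A table is missing required columns or has an unusable layout."""


class ValidationError(LactoteqError):
    """A record violates a domain invariant (negative concentration, ...)."""


class DomainError(LactoteqError):
    """An argument is outside the mathematical domain of an operation."""


class ConfigurationError(LactoteqError):
    """A configuration value is inconsistent or references unknown keys."""


class DegenerateSampleError(LactoteqError):
    """A sample cannot support the requested computation (e.g. 0 % lipid)."""


class UnusableCurveError(LactoteqError):
    """A calibration curve cannot yield detection limits (slope <= 0)."""
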