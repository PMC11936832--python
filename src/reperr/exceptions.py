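"""Exception hierarchy.

All reperr errors derive from :class:`ReperrError` so callers can catch the
package's failures with a single except clause.
"""


class ReperrError(Exception):
    """Base class for all reperr errors."""


class ConfigurationError(ReperrError, ValueError):
    """An input configuration value is invalid; the message names the field."""


class DataError(ReperrError, ValueError):
    """Input data violate a precondition (non-finite values, bad alignment...)."""


class InsufficientDataError(DataError):
    """Too few complete observations to fit the requested model."""


class DegenerateVariableError(DataError):
    """A variable has zero variance where positive variance is required."""


class EligibilityError(DataError):
    """No phenotype passes the eligibility threshold; message lists counts."""


class AlignmentError(DataError):
    """Two per-individual structures do not share the same individuals."""
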