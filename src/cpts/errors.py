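"""Exception taxonomy for the CPTS pipeline.

Pipeline drivers catch the *recoverable* subset of these (everything deriving
from :class:`CptsError` except :class:`ConfigurationError`) and convert them
into structured feasibility statuses rather than aborting a cohort run.
"""


class CptsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CptsError, ValueError):
    """Invalid configuration (bad ranges, negative noise, missing keys)."""


class InputError(CptsError, ValueError):
    """Structurally invalid input data (empty series, mask off geometry)."""


class FormatError(CptsError, ValueError):
    """Malformed stream file; carries file name and offending row."""

    def __init__(self, message: str, path=None, row=None):
        self.path = path
        self.row = row
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f", row {row}]" if row is not None else "]")
        super().__init__(message + loc)


class InvalidTrialError(CptsError):
    """Walking pressure trial with too few midgait steps.

    Carries the number of stances found and the minimum required so that
    feasibility reporting can record why the trial was rejected.
    """

    def __init__(self, n_steps: int, min_steps: int):
        self.n_steps = n_steps
        self.min_steps = min_steps
        super().__init__(
            f"invalid trial: {n_steps} midgait steps after trimming, "
            f"need at least {min_steps}"
        )


class ProtocolError(CptsError, ValueError):
    """Trial set violates the measurement protocol (e.g. not 4 two-step trials)."""


class NonAdherentError(CptsError):
    """Participant did not meet the valid-day rule (>=4 days with >=12 h wear)."""

    def __init__(self, n_valid_days: int, min_valid_days: int):
        self.n_valid_days = n_valid_days
        self.min_valid_days = min_valid_days
        super().__init__(
            f"non-adherent participant: {n_valid_days} valid monitoring days, "
            f"need at least {min_valid_days}"
        )


class UndefinedTSRError(CptsError, ZeroDivisionError):
    """Thermal stress response undefined (contralateral temperature unchanged)."""


class UndefinedAdherenceError(CptsError, ZeroDivisionError):
    """Adherence undefined: zero strides over the valid days."""


class MissingFactorError(CptsError):
    """A CPTS factor (PTI, strides, TSR) is missing for a required condition."""


class InfeasibilityError(CptsError, ValueError):
    """Generator asked to realise contradictory ground truth."""


class DegenerateTableError(CptsError, ValueError):
    """Contingency table collapses to a single row or column."""
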