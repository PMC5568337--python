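"""Exception hierarchy for iopgrs.

All package errors derive from :class:`IopgrsError` so callers can catch the
library's failures without masking programming errors.
"""


class IopgrsError(Exception):
    """Base class for all iopgrs errors."""


class ConfigError(IopgrsError):
    """Invalid configuration value (out-of-range frequency, bad noise spec, ...)."""


class SchemaError(IopgrsError):
    """Tabular input does not match the expected schema (missing rsID column, ...)."""


class ContractError(IopgrsError):
    """An operation's preconditions were violated by the caller."""


class CollinearityError(ContractError):
    """Design matrix is rank deficient; carries the offending column names."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            f"rank-deficient design; linearly dependent/constant columns: {self.columns}"
        )


class InsufficientDataError(ContractError):
    """Too few rows for the requested model."""


class DegenerateTableError(ContractError):
    """A 2x2 table has a zero margin; the chi-square test is undefined."""


class DegenerateLabelsError(ContractError):
    """Case/control labels are all one class (or too few of one class)."""


class GenerationInfeasibleError(IopgrsError):
    """Rejection sampling exhausted its attempt budget for one diagnostic group."""

    def __init__(self, group: str, attempts: int, obtained: int, needed: int):
        self.group = group
        self.attempts = attempts
        self.obtained = obtained
        self.needed = needed
        super().__init__(
            f"could not fill quota for group '{group}': {obtained}/{needed} eligible "
            f"after {attempts} draws; check vulnerability_prevalence and IOP model"
        )


class CalibrationError(IopgrsError):
    """Calibration search terminated without meeting every target."""

    def __init__(self, unmet):
        self.unmet = list(unmet)
        super().__init__(f"calibration failed to satisfy targets: {self.unmet}")


class AlleleMismatchError(IopgrsError):
    """Risk allele of a panel variant matches neither REF nor ALT in the VCF."""


class StageOrderError(ConfigError):
    """A requested pipeline stage depends on a stage that was not requested."""
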