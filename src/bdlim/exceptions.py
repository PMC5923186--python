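"""Exception hierarchy shared across the pipeline stages."""


class BdlimError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(BdlimError, ValueError):
    """A simulation or model specification violates its invariants."""


class AlignmentError(BdlimError, ValueError):
    """Row identifiers of two tables that must match do not."""


class ShapeError(BdlimError, ValueError):
    """An array has the wrong length or dimensions."""


class EmptyInputError(BdlimError, ValueError):
    """An operation received no data."""


class ValidationError(BdlimError, ValueError):
    """Input values outside their physical or logical range."""


class DegenerateOutcomeError(BdlimError, ValueError):
    """An outcome has zero residual variance and cannot be standardized."""


class CollinearityError(BdlimError, ValueError):
    """A regression design matrix is rank deficient."""

    def __init__(self, msg, columns=None):
        super().__init__(msg)
        self.columns = list(columns) if columns is not None else []


class MissingDataError(BdlimError, ValueError):
    """All values needed for a summary are missing."""


class DegenerateDistributionError(BdlimError, ValueError):
    """A sample with no spread cannot be split into quartiles."""


class UndefinedSiteError(BdlimError, ValueError):
    """A CpG site with zero total reads has no defined %5mC."""


class UnidentifiableExposureError(BdlimError, ValueError):
    """Exposure matrix carries no between-subject variation in any week."""


class IdentifiabilityError(BdlimError, ValueError):
    """Weight basis dimension incompatible with the number of lags."""


class IncompleteFitError(BdlimError, ValueError):
    """A fit object lacks the traces required for the requested summary."""


class ComparabilityError(BdlimError, ValueError):
    """Model fits being compared were not run on the same data."""


class NoContrastError(BdlimError, ValueError):
    """A binary term is constant within the analysis sample or stratum."""


class InvalidLevelError(BdlimError, ValueError):
    """Credible level outside the supported open interval (0.5, 1)."""


class SchemaError(BdlimError, ValueError):
    """An input table is missing required columns."""

    def __init__(self, msg, missing=None):
        super().__init__(msg)
        self.missing = list(missing) if missing is not None else []
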