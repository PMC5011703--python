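"""Exception types raised across the package."""


class TwinSemError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(TwinSemError):
    """A required column or phenotype is missing or mis-typed."""


class PairingError(TwinSemError):
    """Family structure is not two twins per family.

    Carries the offending family ids in ``families``.
    """

    def __init__(self, message: str, families=None):
        super().__init__(message)
        self.families = list(families or [])


class ValidityError(TwinSemError):
    """A model component (A, C or E) violates its mathematical constraints."""


class NumericError(TwinSemError):
    """A covariance matrix is singular or too ill-conditioned to use."""


class ConvergenceError(TwinSemError):
    """An optimisation failed, or nested/full log-likelihoods are inconsistent."""


class DegenerateDataError(TwinSemError):
    """The data carry no information for the requested statistic."""
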