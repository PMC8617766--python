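"""Exception hierarchy for the nutrascreen pipeline.

Every error raised by the library derives from :class:`NutraScreenError`
so callers can distinguish pipeline failures from programming errors.
"""


class NutraScreenError(Exception):
    """Base class for all nutrascreen errors."""


class InvalidControlError(NutraScreenError):
    """Control signal is zero or negative; percent inhibition is undefined."""


class InsufficientStandardsError(NutraScreenError):
    """Fewer than three calibration standards supplied."""


class DegenerateCurveError(NutraScreenError):
    """Calibration curve has zero slope (or undefined R²)."""


class NotEstimableError(NutraScreenError):
    """The dose-response series does not bracket 50 % inhibition.

    Attributes
    ----------
    bound : str
        ``">max"`` when every response stays below 50 %, ``"<min"`` when
        every response is already above 50 %.
    """

    def __init__(self, message: str, bound: str):
        super().__init__(message)
        self.bound = bound


class MissingDataError(NutraScreenError):
    """A (sample, endpoint) group contains no usable replicate."""


class DegenerateReferenceError(NutraScreenError):
    """Reference value makes the composite index undefined."""


class UnscorableSampleError(NutraScreenError):
    """All parameters of a sample are missing; no composite score exists."""


class VocabularyError(NutraScreenError):
    """A token falls outside its closed vocabulary."""


class NormalizationError(NutraScreenError):
    """Internal-standard normalization failed (names the offending sample)."""


class SizeError(NutraScreenError):
    """An operation received fewer/more items than it supports."""


class DegenerateInputError(NutraScreenError):
    """Input collapses to fewer than two usable rows/columns."""


class IncompleteDescriptorError(NutraScreenError):
    """A molecular descriptor required by a screen is missing."""


class IncompleteMatrixError(NutraScreenError):
    """Binding-energy matrix has missing entries under a complete-matrix rule."""


class ColumnError(NutraScreenError):
    """Requested column (target) does not exist."""


class InteractionParseError(NutraScreenError):
    """Malformed residue/bond token in an interaction row."""


class InsufficientReplicatesError(NutraScreenError):
    """A group has fewer than two replicates; ANOVA is impossible."""


class ContractError(NutraScreenError):
    """An input violates a structural contract (e.g. asymmetric matrix)."""


class UndefinedCorrelationError(NutraScreenError):
    """Pearson correlation undefined (zero variance or too few points)."""


class ParameterError(NutraScreenError):
    """A generator or configuration parameter is out of range."""


class ConfigError(NutraScreenError):
    """Pipeline configuration failed validation; carries the full error list."""

    def __init__(self, errors):
        super().__init__("; ".join(errors))
        self.errors = list(errors)
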