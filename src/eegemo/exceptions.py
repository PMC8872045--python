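"""Exception hierarchy for the pipeline."""


class EegemoError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(EegemoError, ValueError):
    """A numeric or enum parameter violates its precondition."""


class InvalidLabelError(EegemoError, ValueError):
    """Unknown condition label."""


class ConfigurationError(EegemoError, ValueError):
    """Inconsistent or incomplete run configuration."""


class EmptyInputError(EegemoError, ValueError):
    """Operation received no usable data (e.g. zero epochs)."""


class AllEpochsRejectedError(EegemoError, RuntimeError):
    """Artifact rejection removed every epoch; thresholds or data pathological."""


class DegenerateSignalError(EegemoError, ValueError):
    """Signal degenerate for the requested measure (constant trace, zero power,
    zero-variance band-power series)."""


class NumericalDegeneracyError(EegemoError, RuntimeError):
    """A decomposition or fit failed for numerical reasons (rank deficiency)."""


class InconsistencyError(EegemoError, ValueError):
    """Two inputs that must describe the same feature set disagree."""


class InsufficientDataError(EegemoError, ValueError):
    """Too few rows, classes or participants for the requested analysis."""
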