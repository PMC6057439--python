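"""Exception hierarchy shared across the pipeline.

Every stage raises a subclass of :class:`TendonMechError`; the composed
pipeline (`mechanics.derive_properties`) re-raises stage failures as
:class:`PipelineError` tagged with the stage name so callers can tell *where*
a trace failed without parsing messages.
"""


class TendonMechError(Exception):
    """Base class for all package errors."""


class FormatError(TendonMechError):
    """A file does not follow the expected dialect (bad column count etc.)."""


class InsufficientDataError(TendonMechError):
    """Fewer usable data rows than the operation requires."""


class DataError(TendonMechError):
    """Values violate a data invariant (negative frequency, bad monotonicity)."""


class ContractError(TendonMechError):
    """Caller violated an interface precondition (mixed levels, missing key)."""


class DomainError(TendonMechError):
    """Argument outside the mathematical domain of the operation."""


class GeometryError(TendonMechError):
    """Non-positive specimen geometry (area, gauge length)."""


class DegenerateTraceError(TendonMechError):
    """A load-displacement trace cannot be zeroed (e.g. all-zero load)."""


class NumericError(TendonMechError):
    """A numerical step failed (rank-deficient fit, too few samples)."""


class IntegrationError(TendonMechError):
    """Strain not monotone within an integration segment."""


class EmptyHistogramError(TendonMechError):
    """Histogram construction requested on an empty sample."""


class DegenerateFitError(TendonMechError):
    """Mixture component matrix is rank deficient (identical components)."""


class ConfigurationError(TendonMechError):
    """Invalid analysis / annealing configuration."""


class ParameterError(TendonMechError):
    """Synthetic-data generator parameters are infeasible."""


class FeasibilityError(TendonMechError):
    """Disc placement could not reach the requested packing fraction."""


class PipelineError(TendonMechError):
    """Failure inside a named pipeline stage.

    Attributes
    ----------
    stage : str
        Name of the stage that failed (e.g. ``"zero_trace"``).
    """

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.__cause__ = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
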