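"""Exception hierarchy for the scaffold-analytics pipeline.

Every stage raises a subclass of :class:`CrcScaffoldError`, so callers
(and the CLI) can distinguish pipeline errors from programming errors.
"""


class CrcScaffoldError(Exception):
    """Base class for all pipeline errors."""


class InvalidGeometryError(CrcScaffoldError):
    """A device-geometry or fluid constant violates its physical invariant."""


class InvalidTimeOrderError(CrcScaffoldError):
    """An observation time precedes the filtration start time."""


class InvalidHeightError(CrcScaffoldError):
    """A fluid-column height is negative."""


class UnreachableHeightError(CrcScaffoldError):
    """A target height below the start cannot be reached at zero permeability."""


class NoUsablePointsError(CrcScaffoldError):
    """Too few trace points remain inside the analysis window to fit."""


class InsufficientRepeatsError(CrcScaffoldError):
    """Reliability summaries need at least two repeats per sample."""


class InsufficientGroupError(CrcScaffoldError):
    """A statistical comparison received an undersized or missing group."""


class MissingControlError(CrcScaffoldError):
    """A (setting, timepoint) stratum has no untreated control wells."""


class FlatResponseError(CrcScaffoldError):
    """All viability responses are identical; no dose-response curve exists."""


class EmptyImageError(CrcScaffoldError):
    """A count record has zero total nuclei/cells."""


class MissingMeasurementError(CrcScaffoldError):
    """A requested fluorescence timepoint is absent from the record."""


class InvalidPValueError(CrcScaffoldError):
    """A p-value outside [0, 1] was passed to the star-label mapping."""


class SchemaError(CrcScaffoldError):
    """An input table does not match the documented column schema."""
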