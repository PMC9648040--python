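"""Exception hierarchy for vestikin."""


class VestikinError(Exception):
    """Base class for all vestikin errors."""


class InvalidParameterError(VestikinError, ValueError):
    """A simulation or analysis parameter violates its contract."""


class MissingSensorError(VestikinError, ValueError):
    """A required sensor recording (e.g. wrist/ankle for near-fall detection) is absent."""


class UndefinedMeasureError(VestikinError, ValueError):
    """A kinematic measure cannot be computed (e.g. zero in-balance time)."""


class InvalidReferenceError(VestikinError, ValueError):
    """A normalization reference cell is missing or degenerate (sigma <= 0)."""


class MissingDataError(VestikinError, ValueError):
    """A score request needs a trial/cell that is not in the measures table."""


class UndefinedCorrelationError(VestikinError, ValueError):
    """Pearson correlation is undefined (zero variance or too few points)."""


class InsufficientDataError(VestikinError, ValueError):
    """Fewer joined subjects than the analysis requires."""


class ValidationError(VestikinError, ValueError):
    """An input value is outside its admissible clinical range."""
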