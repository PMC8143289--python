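"""Exception hierarchy for the locrad pipeline.

Every stage raises a subclass of :class:`LocradError`, so callers can trap
pipeline failures without catching unrelated exceptions.
"""


class LocradError(Exception):
    """Base class for all locrad errors."""


class ConfigurationError(LocradError):
    """Invalid configuration value (non-positive spacing, bad counts, ...)."""


class GeometryError(LocradError):
    """Image and mask geometries are incompatible."""


class FormatError(LocradError):
    """A file could not be parsed in the expected format."""


class SchemaError(LocradError):
    """A table is missing required columns."""


class ValidationError(LocradError):
    """Input data violate a documented contract (duplicate ids, empty mask, ...)."""


class SelectionError(LocradError):
    """Feature or model selection could not produce a result."""


class NoUncorrelatedPairError(SelectionError):
    """No candidate feature pair passed the correlation filter."""


class NoSignificantCoupleError(SelectionError):
    """No candidate couple survived the multiple-testing correction."""


class ModelFilterError(SelectionError):
    """The model-filter cascade left no surviving SVM candidate."""


class EvaluationError(LocradError):
    """Evaluation requested on degenerate data (single-class labels, ...)."""


class PipelineError(LocradError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
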