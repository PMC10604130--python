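"""Exception hierarchy for the qpmorph pipeline.

Measurement-stage failures that map onto exclusion bookkeeping
(``LowContrastError``, ``NoCellDetectedError``) are caught by
:func:`qpmorph.morphometry.measure_cell` and turned into exclusion
reasons rather than propagated; everything else is a hard error.
"""


class QpmorphError(Exception):
    """Base class for all package errors."""


class ConfigurationError(QpmorphError):
    """A configuration object is incomplete or inconsistent."""


class ResolutionError(QpmorphError):
    """Pixel size too coarse for the requested cell geometry."""


class NoCellDetectedError(QpmorphError):
    """Segmentation found no connected component above the area floor."""


class LowContrastError(QpmorphError):
    """Within-head density contrast below the floor: acrosome/nucleus
    boundary cannot be resolved (maps to the 'unclear borders' exclusion)."""


class UnclassifiableError(QpmorphError):
    """Record is excluded or missing endpoints; WHO classification refused."""


class InsufficientDataError(QpmorphError):
    """Too few eligible cells/differences for the requested statistic."""


class UndefinedRatioError(QpmorphError):
    """SD ratio undefined (zero denominator)."""


class SchemaError(QpmorphError):
    """A measurement table does not conform to the declared CSV schema."""


class PipelineStageError(QpmorphError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
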