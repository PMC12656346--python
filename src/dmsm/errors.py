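"""Exception hierarchy shared across the pipeline."""


class DmsmError(Exception):
    """Base class for all package-specific errors."""


class FormatError(DmsmError):
    """A file does not conform to the declared dialect (e.g. missing joint columns)."""


class ValidationError(DmsmError):
    """Data violates a container invariant (timestamps, joint sets, boundaries...)."""


class ParameterError(DmsmError, ValueError):
    """A configuration value is out of its admissible range."""


class ContractError(DmsmError):
    """A caller-side precondition was violated (e.g. mismatched trajectory grids)."""


class DegenerateSkeletonError(DmsmError):
    """A geometric reference collapses (zero shoulder width, zero-length limb...)."""


class NoSwingDetectedError(DmsmError):
    """Lead-wrist speed never exceeds the onset threshold."""


class SegmentationError(DmsmError):
    """A phase-boundary event could not be found in order."""

    def __init__(self, event: str, message: str | None = None):
        self.event = event
        super().__init__(message or f"segmentation failed: event {event!r} not found")


class UndefinedSimilarityError(DmsmError):
    """The similarity is undefined for this input (e.g. all-static clip)."""


class NoMatchError(DmsmError):
    """The reference height is never approached in the search region."""
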