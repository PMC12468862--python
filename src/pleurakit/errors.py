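"""Exception hierarchy shared across the pipeline stages."""


class PleuraKitError(Exception):
    """Base class for all package-specific failures."""


class ImageError(PleuraKitError, ValueError):
    """Input raster violates the canonical image contract."""


class ParameterError(PleuraKitError, ValueError):
    """A stage parameter is outside its documented domain."""


class SegmentationError(PleuraKitError, RuntimeError):
    """Lung-field boundary detection failed.

    Carries ``stage`` so batch callers can report where in the
    profile-analysis chain an image was rejected.
    """

    def __init__(self, message: str, stage: str = "segmentation"):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


class CapabilityError(PleuraKitError, RuntimeError):
    """A requested optional backend is not installed in this environment."""
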