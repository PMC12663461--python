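"""Exception hierarchy shared across the pipeline."""


class AsymdivError(Exception):
    """Base class for all errors raised by this package."""


class MissingCalibrationError(AsymdivError):
    """An image lacks physical calibration and no sidecar supplies it."""

    def __init__(self, field: str, message: str | None = None):
        self.field = field
        super().__init__(message or f"missing calibration field: {field!r}")


class DegenerateGeometryError(AsymdivError):
    """A geometric construction (axis, plane, zone) is undefined."""


class DetectionError(AsymdivError):
    """Spot or structure detection failed for a frame."""


class MissingStageError(AsymdivError):
    """A pipeline stage output required by the report is absent."""
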