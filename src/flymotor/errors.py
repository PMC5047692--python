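"""Exception hierarchy shared across the pipeline."""


class FlymotorError(Exception):
    """Base class for all pipeline errors."""


class ParameterError(FlymotorError, ValueError):
    """A simulation or analysis parameter is out of its valid range."""


class PlacementError(FlymotorError, RuntimeError):
    """Rejection sampling could not place objects under the geometric constraints."""


class TraceError(FlymotorError, RuntimeError):
    """Centerline tracing failed (e.g. empty foreground)."""


class GeometryError(FlymotorError, ValueError):
    """A trace or mask falls outside the image bounds."""


class SegmentationError(FlymotorError, ValueError):
    """Branch too short to be divided into segments."""


class FormatError(FlymotorError, ValueError):
    """On-disk file does not match the expected format or metadata schema."""
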