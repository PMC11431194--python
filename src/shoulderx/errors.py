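"""Exception hierarchy.

Every failure mode of the pipeline maps to a distinct exception class so
callers (and the CLI) can categorize errors without string matching.
"""


class ShoulderXError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(ShoulderXError, ValueError):
    """Degenerate geometric input: coincident points, zero-length line."""


class EmptyRegionError(ShoulderXError, ValueError):
    """A required anatomical region mask is empty or below the pixel floor."""

    def __init__(self, region: str, detail: str = ""):
        self.region = region
        msg = f"region '{region}' is empty or too small"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


class AmbiguousLateralityError(ShoulderXError, ValueError):
    """Glenoid and humerus centroids too close in x to infer left/right."""


class DegenerateGlenoidError(ShoulderXError, ValueError):
    """Glenoid mask too short (height <= 2 px) to define superior/inferior poles."""


class UndefinedMetricError(ShoulderXError, ValueError):
    """Metric has no defined value for this input (e.g. two empty masks)."""


class InfeasibleSpecError(ShoulderXError, ValueError):
    """Phantom target triple cannot be realized by the closed-form construction."""


class RenderingError(ShoulderXError, RuntimeError):
    """Rasterized phantom regions overlapped; retry with a larger canvas."""


class FormatError(ShoulderXError, ValueError):
    """Malformed input file (label map with unknown values, bad polygon line)."""


class MissingPredictionError(ShoulderXError, FileNotFoundError):
    """No mask file found for an image in the precomputed-mask backend."""


class MeasurementError(ShoulderXError, ValueError):
    """A measurement failed for a named study; wraps the underlying cause."""

    def __init__(self, source_id: str, cause: Exception):
        self.source_id = source_id
        self.cause = cause
        super().__init__(f"measurement failed for '{source_id}': {cause}")
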