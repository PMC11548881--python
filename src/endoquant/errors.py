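"""Exception types shared across the pipeline.

Every error raised by endoquant derives from :class:`EndoquantError` so
callers can catch pipeline failures without masking programming errors.
"""


class EndoquantError(Exception):
    """Base class for all endoquant errors."""


class ParameterError(EndoquantError, ValueError):
    """An input parameter violates a precondition; names the offending field."""


class CapacityError(EndoquantError):
    """Vesicle placement could not satisfy the request within the retry budget."""

    def __init__(self, requested: int, achieved: int, message: str | None = None):
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            message
            or f"could only place {achieved} of {requested} vesicles "
            "without overlap within the retry budget"
        )


class GeometryError(EndoquantError):
    """A profile or ROI does not fit inside the image or the scene."""


class DegenerateReferenceError(EndoquantError):
    """A plasma-membrane reference or background region carries no signal."""


class UnmeasurableVesicleError(EndoquantError):
    """The reference-dye numerator is non-positive; the vesicle is excluded."""


class InsufficientDataError(EndoquantError):
    """Fewer observations than the summary statistic requires."""


class PairingError(EndoquantError):
    """Treated/control replicate vectors are not matched."""


class WindowError(EndoquantError):
    """A kinetic-trace analysis window is empty or ill-placed."""


class DatasetIOError(EndoquantError):
    """Reading or writing a dataset failed; carries the offending path."""

    def __init__(self, path, message: str):
        self.path = path
        super().__init__(f"{message}: {path}")
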