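"""Exception hierarchy shared across the package."""


class FootKinError(Exception):
    """Base class for all footkin errors."""


class FormatError(FootKinError):
    """A file could not be parsed as the expected format."""


class SchemaError(FootKinError):
    """Parsed data violates the expected tabular schema."""


class EmptyTrialError(FootKinError):
    """A trial contains no frames."""


class ParameterError(FootKinError):
    """An out-of-range or inconsistent parameter value."""


class DegenerateGeometryError(FootKinError):
    """Marker geometry too close to collinear/coincident to define a frame."""


class CalibrationError(FootKinError):
    """The static trial cannot produce the requested calibration product."""


class DataError(FootKinError):
    """Input data violates a physical or logical precondition."""
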