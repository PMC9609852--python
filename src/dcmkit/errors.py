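"""Exception hierarchy shared across dcmkit modules."""


class DcmkitError(Exception):
    """Base class for all dcmkit errors."""


class InvalidGeometryError(DcmkitError):
    """Raised for non-physical geometry inputs (e.g. non-positive areas/volumes)."""


class DegenerateCalibrationError(DcmkitError):
    """Raised when a calibration transform cannot be inverted (zero slope)."""


class MalformedWaveError(DcmkitError):
    """Raised when events tagged as one wave do not form a contiguous wave."""


class ConfigError(DcmkitError):
    """Raised for inconsistent configuration (interval partition, missing constants...)."""


class DataError(DcmkitError):
    """Raised for invalid measurement data (negative concentrations, malformed tables)."""


class FitError(DcmkitError):
    """Raised when a model fit cannot be performed or does not converge."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
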