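"""Exception hierarchy shared across the pipeline."""


class LSBMError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(LSBMError, ValueError):
    """A physical parameter violates its invariant (e.g. non-positive FWHM)."""


class ConfigurationError(LSBMError, ValueError):
    """A spectrometer/geometry configuration is inconsistent or unrealizable."""


class DetectionError(LSBMError, RuntimeError):
    """Peak detection failed; carries the candidate list found so far."""

    def __init__(self, message: str, candidates=None):
        super().__init__(message)
        self.candidates = [] if candidates is None else list(candidates)


class CalibrationInsufficiencyError(LSBMError, ValueError):
    """Too few reference lines or anchors to constrain the dispersion model."""


class RankDeficiencyError(LSBMError, ValueError):
    """Degenerate/collinear calibration input: the fit is under-determined."""


class RangeError(LSBMError, ValueError):
    """A pixel or frequency falls outside the valid range of a mapping."""


class FormatError(LSBMError, IOError):
    """A file does not conform to the expected on-disk layout."""
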