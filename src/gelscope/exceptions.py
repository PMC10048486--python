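"""Exception hierarchy shared by all analysis stages."""


class GelscopeError(Exception):
    """Base class for all gelscope errors."""


class ParameterError(GelscopeError, ValueError):
    """An argument or model field is invalid; the message names the field."""


class ConfigurationError(GelscopeError, ValueError):
    """Mutually inconsistent analysis settings."""


class CalibrationError(GelscopeError):
    """Physical calibration (pixel size, frame interval) is missing."""


class ShapeError(GelscopeError, ValueError):
    """Array shape unsuitable for the requested operation."""


class RangeError(GelscopeError, ValueError):
    """Intensity values do not fit the requested bit depth."""


class BoundsError(GelscopeError, ValueError):
    """A region of interest exceeds the frame bounds."""


class LagError(GelscopeError, ValueError):
    """A requested time lag is not representable on the frame grid."""


class PlateauError(GelscopeError):
    """The long-lag plateau of a variance curve could not be established.

    Carries a ``diagnostic`` dict (window, local slope, threshold) so the
    failure mode — typically insufficient ensemble averaging at long lags —
    is explicit rather than silently absorbed.
    """

    def __init__(self, message, diagnostic=None):
        super().__init__(message)
        self.diagnostic = diagnostic or {}


class AmplitudeError(GelscopeError):
    """No usable scattering amplitude A(q) at the requested wavenumber."""

    def __init__(self, message, diagnostic=None):
        super().__init__(message)
        self.diagnostic = diagnostic or {}


class InsufficientDataError(GelscopeError, ValueError):
    """Too few points for the requested estimate."""


class FitError(GelscopeError):
    """A nonlinear fit failed to converge from every start."""


class DomainError(GelscopeError, ValueError):
    """Input values outside the mathematical domain of the operation."""


class WindowError(GelscopeError, ValueError):
    """An analysis window covers a regime the operation excludes."""


class MethodError(GelscopeError):
    """The requested method is inapplicable to the supplied data."""
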