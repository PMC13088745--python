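"""Exception hierarchy for socmetrics."""


class SocmetricsError(Exception):
    """Base class for all socmetrics errors."""


class GeometryError(SocmetricsError):
    """Requested scene geometry is impossible (e.g. lumen wider than the channel)."""


class DegenerateHistogramError(SocmetricsError):
    """Histogram has fewer than two occupied bins; Otsu threshold undefined."""


class NoProfilesError(SocmetricsError):
    """Margin exclusion left no profile positions on the image."""


class MeasurementError(SocmetricsError):
    """No valid width profile could be extracted from an image."""


class CalibrationError(SocmetricsError):
    """Automatic wall detection failed; manual calibration required."""


class ConvergenceError(SocmetricsError):
    """Iterative model fit did not converge."""


class SingularCovarianceError(SocmetricsError):
    """Estimated covariance matrix is singular; regularization is refused."""


class DegenerateDataError(SocmetricsError):
    """Data admit no rank-based test (e.g. all observations identical)."""


class PackingWarning(UserWarning):
    """Fewer shapes were placed than requested (rejection sampling exhausted)."""
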