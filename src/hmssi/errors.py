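"""Exception hierarchy.

Grouped so the CLI can map classes of failure onto exit codes:
configuration (2), data (3), numerical/calibration (4).
"""


class HmssiError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HmssiError):
    """Invalid or incomplete run/campaign configuration."""


class DataError(HmssiError):
    """Base class for errors caused by the input data."""


class BandMapError(DataError):
    """Band map incomplete, inconsistent, or referencing missing bands."""


class RasterFormatError(DataError):
    """File is not a readable georeferenced raster."""


class ResolutionError(DataError):
    """Resampling factor is not an integer ratio of resolutions."""


class PlotOutOfBoundsError(DataError):
    """A plot's coordinates fall outside the raster extent."""

    def __init__(self, plot_ids):
        self.plot_ids = list(plot_ids)
        super().__init__(f"plots outside raster extent: {', '.join(map(str, self.plot_ids))}")


class SamplingError(DataError):
    """Requested more samples than available cells."""


class AlignmentError(DataError):
    """Raster grids that must share a geometry do not."""


class SchemaError(DataError):
    """Feature layout does not match what a fitted model expects."""


class InputError(DataError):
    """Malformed in-memory input (empty class, length mismatch, ...)."""


class DegenerateLabelsError(DataError):
    """Training table contains fewer than two classes."""


class DomainError(HmssiError, ValueError):
    """Scalar input outside the physical domain (e.g. negative reflectance)."""


class IndexKindError(HmssiError, ValueError):
    """An IndexValue of the wrong kind was supplied."""


class CalibrationError(HmssiError):
    """Generator calibration infeasible or failed to converge."""
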