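"""Exception hierarchy for phenocloud."""


class PhenocloudError(Exception):
    """Base class for all phenocloud errors."""


class EmptyCloudError(PhenocloudError, ValueError):
    """An operation received a point cloud with no points."""


class CloudParseError(PhenocloudError, ValueError):
    """A point-cloud file could not be parsed."""


class DegenerateGeometryError(PhenocloudError, ValueError):
    """The input geometry is degenerate for the requested operation
    (coincident points, collinear surface samples, ...)."""


class FitError(PhenocloudError, RuntimeError):
    """A model fit failed (singular normal matrix, no converging
    RANSAC candidate, ...)."""


class ConfigError(PhenocloudError, ValueError):
    """Mismatched or invalid configuration (e.g. feature dimensions of a
    trained model do not match the supplied histograms)."""
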