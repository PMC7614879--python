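"""Exception hierarchy.

All package-specific failures derive from :class:`MitoshapeError` so callers
can distinguish validation problems from genuine bugs.
"""


class MitoshapeError(Exception):
    """Base class for all mitoshape errors."""


class InvalidGeometryError(MitoshapeError):
    """A polygon/segment input violates a geometric precondition
    (too few vertices, self-intersection, zero area, coincident points)."""


class EmptyOverlapError(MitoshapeError):
    """Jaccard index requested for two empty masks (0/0 is undefined)."""


class MissingFrameError(MitoshapeError):
    """A requested time offset has no frame within tolerance."""


class InsufficientDataError(MitoshapeError):
    """Too few observations for the requested statistic."""


class ConfigurationError(MitoshapeError):
    """Invalid parameter combination or missing required anchor/config."""


class LoadError(MitoshapeError):
    """Malformed input file; message carries file name and line number."""
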