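"""Exception hierarchy for the segmentation and statistics pipeline."""


class MyofatError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(MyofatError, ValueError):
    """A phantom or configuration specification violates one of its constraints."""


class DegenerateInputError(MyofatError, ValueError):
    """Input has too little structure for the requested operation
    (e.g. fewer distinct values than clusters, zero variance)."""


class AmbiguousAssignmentError(MyofatError, ValueError):
    """Cluster centroids cannot be mapped one-to-one onto tissue classes."""


class InvalidParameterError(MyofatError, ValueError):
    """A tunable parameter is outside its admissible range."""


class OutOfBoundsError(MyofatError, ValueError):
    """A contour point lies outside the image frame."""


class SegmentationFailure(MyofatError, RuntimeError):
    """Automatic segmentation could not produce a usable result;
    the slice should be routed to the manual-contour fallback."""


class GeometryError(MyofatError, ValueError):
    """Contours are malformed or incorrectly nested (e.g. limb inside muscle)."""


class UndefinedFractionError(MyofatError, ZeroDivisionError):
    """The fat fraction IMAT/(IMAT+muscle) is undefined because both masks are empty."""


class FormatError(MyofatError, IOError):
    """An input file could not be read or has an ambiguous layout."""
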