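"""Exception hierarchy for spheremark.

Every error raised by the library derives from :class:`SpheremarkError`,
so callers (and the CLI) can catch one base class.
"""


class SpheremarkError(Exception):
    """Base class for all spheremark errors."""


# --- camera model ---------------------------------------------------------

class NonPositiveDepth(SpheremarkError):
    """A world point lies on or behind the camera plane (z_cam <= 0)."""


class NoConvergence(SpheremarkError):
    """The iterative undistortion solver failed to reach tolerance."""


# --- triangulation --------------------------------------------------------

class TooFewRays(SpheremarkError):
    """Triangulation requires at least two rays / observations."""


class DegenerateGeometry(SpheremarkError):
    """Rays are (near-)parallel; the least-squares system is rank deficient."""


class UnknownCamera(SpheremarkError):
    """An observation references a camera id absent from the project."""


# --- measurement ----------------------------------------------------------

class NonPositiveDistance(SpheremarkError):
    """Scale calibration needs strictly positive distances."""


# --- view navigation ------------------------------------------------------

class EmptyProject(SpheremarkError):
    """The project holds no cameras."""


class DegenerateSphere(SpheremarkError):
    """The view sphere cannot be built (e.g. a single camera at the center)."""


class ZeroVectorQuery(SpheremarkError):
    """The query viewing direction is the zero vector."""


class LatitudeOutOfRange(SpheremarkError):
    """Latitude must lie in [-90, 90] degrees."""


# --- project I/O ----------------------------------------------------------

class SchemaError(SpheremarkError):
    """A project document violates the schema; the message names the field."""


class VersionUnsupported(SpheremarkError):
    """The project file declares a schema version this build cannot read."""


class ParseError(SpheremarkError):
    """A calibration file could not be parsed."""


class MissingIntrinsics(SpheremarkError):
    """An extrinsic record references an undefined sensor id."""


class NothingToExport(SpheremarkError):
    """No landmark carries a triangulated 3D position."""


# --- comparison statistics ------------------------------------------------

class MismatchedKeys(SpheremarkError):
    """Two measurement series disagree on specimen/distance/technique keys."""


class TooFewValues(SpheremarkError):
    """The statistic needs more replicate values than were supplied."""


class EmptyInput(SpheremarkError):
    """An aggregation was called on an empty collection."""


# --- synthetic scene ------------------------------------------------------

class InvalidSpec(SpheremarkError):
    """A synthetic scene specification violates its invariants."""
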