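"""Exception hierarchy for the volume-estimation pipeline.

Every failure mode surfaces as a typed exception so that callers (and the
CLI) can attribute a failed estimate to a stage and, where relevant, a beam.
"""


class UrovolError(Exception):
    """Base class for all package errors."""


class ConfigError(UrovolError):
    """Invalid or inconsistent configuration."""


class DataError(UrovolError):
    """Malformed input data (non-finite samples, bad trace files...)."""


class GeometryError(UrovolError):
    """Geometric reconstruction failed."""


class DegenerateTriangleError(GeometryError):
    """The three far-wall points do not form a usable triangle."""


class InconsistentDistancesError(GeometryError):
    """No apex position is compatible with the three measured ranges."""


class DegenerateApexError(GeometryError):
    """Probe position is (numerically) coplanar with the far-wall points."""


class NoSphereError(GeometryError):
    """The sphere closure has no real positive-radius solution."""


class AmbiguousRootError(GeometryError):
    """Two physically admissible spheres; near-wall ranges are needed to pick one."""


class RayMissError(GeometryError):
    """A beam does not intersect the phantom sphere (or is tangent)."""


class EchoDetectionError(UrovolError):
    """Fewer than two qualifying echo peaks in a trace."""

    def __init__(self, message: str, beam_id: int | None = None):
        super().__init__(message)
        self.beam_id = beam_id
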