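"""Closed-form sphere reconstruction from three pulse-echo beam ranges.

The bladder is approximated as a sphere insonified by a fan of three A-mode
beams that share an apex at the probe face ``P``.  Each beam returns two
echoes: one from the near (upper) wall and one from the far (lower) wall.
The far-wall ranges ``h1, h2, h3`` place three points ``A, B, C`` on the
sphere; together with the probe standoff ``h`` (``|OP| = R + h``) they
determine the sphere uniquely:

1. the pairwise beam angles turn the ranges into chord lengths of the base
   triangle ``ABC`` (law of cosines);
2. the triangle is laid flat in the ``z = 0`` plane and the probe apex
   ``P = (xp, yp, zp)`` is trilaterated from the three ranges;
3. the sphere centre lies on the perpendicular to ``ABC`` through its
   circumcentre; eliminating the centre height ``q`` against the constraints
   ``R^2 = r^2 + q^2`` and ``|OP| = R + h`` yields a closed-form quadratic
   in ``R``.

Everything here is pure in-memory geometry in SI units (meters, radians);
volumes are converted to milliliters only at the reporting boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import (
    AmbiguousRootError,
    ConfigError,
    DegenerateApexError,
    DegenerateTriangleError,
    GeometryError,
    InconsistentDistancesError,
    NoSphereError,
    RayMissError,
)

#: absolute tolerance (m^2) for clamping the apex height discriminant
_APEX_TOL = 1e-9
#: degenerate-triangle threshold on sin(theta)
_SIN_TOL = 1e-6

ML_PER_M3 = 1e6


@dataclass(frozen=True)
class BeamGeometry:
    """Pairwise angles of the three-beam fan plus the probe standoff.

    ``alpha``, ``beta``, ``gamma`` are the angles (radians) between beam
    pairs 1-2, 2-3 and 3-1 respectively; ``standoff_h`` is the probe-to-
    bladder-surface distance ``h`` in meters.
    """

    alpha: float
    beta: float
    gamma: float
    standoff_h: float = 0.0

    def __post_init__(self) -> None:
        for name, a in (("alpha", self.alpha), ("beta", self.beta), ("gamma", self.gamma)):
            if not (0.0 <= a < np.pi / 2):
                raise ConfigError(f"beam angle {name}={a!r} rad outside [0, pi/2)")
        if self.standoff_h < 0:
            raise ConfigError("standoff_h must be >= 0")
        if np.linalg.eigvalsh(self.gram_matrix()).min() < -1e-9:
            raise ConfigError("beam angles do not admit a 3D fan (Gram matrix not PSD)")

    def gram_matrix(self) -> np.ndarray:
        """3x3 matrix of pairwise direction cosines."""
        ca, cb, cg = np.cos([self.alpha, self.beta, self.gamma])
        return np.array([[1.0, ca, cg], [ca, 1.0, cb], [cg, cb, 1.0]])

    @property
    def unit_directions(self) -> np.ndarray:
        """Three unit beam vectors realizing the pairwise angles (forward model)."""
        from .phantom import beam_fan  # deferred: phantom imports this module

        return beam_fan(self)


@dataclass(frozen=True)
class BeamDistances:
    """Per-beam one-way ranges: first-echo (near wall) and second-echo (far wall)."""

    near: tuple[float, float, float]
    far: tuple[float, float, float]

    def __post_init__(self) -> None:
        for i, (n, f) in enumerate(zip(self.near, self.far), start=1):
            if n <= 0 or f <= 0:
                raise ConfigError(f"beam {i}: ranges must be positive")
            if f <= n:
                raise ConfigError(f"beam {i}: far range {f} must exceed near range {n}")


@dataclass(frozen=True)
class ChordTriangle:
    """Base triangle ABC of the far-wall reflection points, laid in z = 0.

    Sides ``l = AB``, ``m = BC``, ``n = AC`` (meters); ``theta`` is the angle
    at ``A``; the circumradius/-centre are those of the planar triangle.
    """

    l: float
    m: float
    n: float
    theta: float
    circumradius_r: float
    circumcenter_O1: np.ndarray

    @property
    def vertices(self) -> np.ndarray:
        """A, B, C as rows, in the canonical triangle frame."""
        return np.array(
            [
                [0.0, 0.0, 0.0],
                [self.l, 0.0, 0.0],
                [self.n * np.cos(self.theta), self.n * np.sin(self.theta), 0.0],
            ]
        )


@dataclass(frozen=True)
class ApexSolution:
    """Probe apex P in the triangle frame (zp > 0 by convention)."""

    xp: float
    yp: float
    zp: float

    @property
    def position(self) -> np.ndarray:
        return np.array([self.xp, self.yp, self.zp])


@dataclass(frozen=True)
class SphereSolution:
    """Reconstructed sphere: centre height q, radius R, and closure residual."""

    q: float
    R: float
    center_O: np.ndarray
    residual: float
    n_candidates: int = 1
    root_index: int = 0


@dataclass(frozen=True)
class VolumeEstimate:
    """Final volume in mL plus the diagnostics of how it was obtained."""

    volume_ml: float
    radius_m: float
    diagnostics: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PhantomSpec:
    """A spherical phantom in the probe frame (probe at origin, +z into the body)."""

    center: tuple[float, float, float]
    radius: float
    speed_of_sound: float = 1480.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ConfigError("phantom radius must be positive")
        if self.speed_of_sound <= 0:
            raise ConfigError("speed of sound must be positive")
        if self.center[2] - self.radius <= 0:
            raise ConfigError("phantom must lie entirely below the probe plane")

    @property
    def center_array(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)

    @property
    def standoff(self) -> float:
        """Exact probe-to-surface distance |OP| - R."""
        return float(np.linalg.norm(self.center_array) - self.radius)

    @property
    def volume_ml(self) -> float:
        return sphere_volume(self.radius)


def chord_lengths(far_distances: Sequence[float], angles: BeamGeometry) -> ChordTriangle:
    """Chord lengths of the far-wall triangle from ranges and beam angles.

    Law of cosines per beam pair: ``l^2 = h1^2 + h2^2 - 2 h1 h2 cos(alpha)``
    and cyclically for ``m`` (beams 2,3 / beta) and ``n`` (beams 3,1 / gamma).

    Raises
    ------
    DegenerateTriangleError
        If a side collapses, the triangle inequality fails, or the angle at A
        is numerically 0 or pi.
    """
    h1, h2, h3 = (float(d) for d in far_distances)
    if min(h1, h2, h3) <= 0:
        raise ConfigError("far-wall ranges must be positive")

    l2 = h1 * h1 + h2 * h2 - 2 * h1 * h2 * np.cos(angles.alpha)
    m2 = h2 * h2 + h3 * h3 - 2 * h2 * h3 * np.cos(angles.beta)
    n2 = h3 * h3 + h1 * h1 - 2 * h3 * h1 * np.cos(angles.gamma)
    scale = max(h1, h2, h3)
    sides = {}
    for name, s2 in (("l", l2), ("m", m2), ("n", n2)):
        if s2 <= (_SIN_TOL * scale) ** 2:
            raise DegenerateTriangleError(f"side {name} is degenerate (length ~ 0)")
        sides[name] = float(np.sqrt(s2))
    l, m, n = sides["l"], sides["m"], sides["n"]
    for name, a, b, c in (("l", l, m, n), ("m", m, n, l), ("n", n, l, m)):
        if a >= b + c:
            raise DegenerateTriangleError(
                f"triangle inequality violated: side {name}={a:.6g} >= {b + c:.6g}"
            )

    # angle at A between AB and AC; m is the opposite side
    cos_theta = (l * l + n * n - m * m) / (2 * l * n)
    cos_theta = float(np.clip(cos_theta, -1.0, 1.0))
    theta = float(np.arccos(cos_theta))
    sin_theta = np.sin(theta)
    if sin_theta < _SIN_TOL:
        raise DegenerateTriangleError("triangle is degenerate (sin theta below tolerance)")

    r = m / (2 * sin_theta)
    # circumcentre from |O1 A| = |O1 C| with O1 = (l/2, yc, 0); signed, unlike
    # the +sqrt(r^2 - l^2/4) shortcut, so obtuse-at-C triangles stay correct.
    yc = (n - l * cos_theta) / (2 * sin_theta)
    return ChordTriangle(
        l=l, m=m, n=n, theta=theta, circumradius_r=float(r),
        circumcenter_O1=np.array([l / 2, yc, 0.0]),
    )


def apex_position(triangle: ChordTriangle, far_distances: Sequence[float]) -> ApexSolution:
    """Trilaterate the probe apex P from the three far-wall ranges.

    With ``A=(0,0,0)``, ``B=(l,0,0)``, ``C=(n cos(theta), n sin(theta), 0)``:
    ``xp`` from the A/B equations, ``yp`` from the A/C equations, and
    ``zp = +sqrt(h1^2 - xp^2 - yp^2)`` (positive-z convention; the mirror
    image gives the same sphere radius).
    """
    h1, h2, h3 = (float(d) for d in far_distances)
    l, n, theta = triangle.l, triangle.n, triangle.theta
    xp = (h1 * h1 - h2 * h2 + l * l) / (2 * l)
    yp = (h1 * h1 - h3 * h3 + n * n - 2 * n * np.cos(theta) * xp) / (2 * n * np.sin(theta))
    t = h1 * h1 - xp * xp - yp * yp
    if t < -_APEX_TOL:
        raise InconsistentDistancesError(
            f"ranges are inconsistent with the beam angles (zp^2 = {t:.3e} m^2 < 0)"
        )
    if t <= _APEX_TOL:
        raise DegenerateApexError("probe apex is coplanar with the far-wall points (zp ~ 0)")
    return ApexSolution(xp=float(xp), yp=float(yp), zp=float(np.sqrt(t)))


def solve_sphere(
    apex: ApexSolution,
    triangle: ChordTriangle,
    standoff_h: float,
    near_distances: Sequence[float] | None = None,
) -> SphereSolution:
    """Close the geometry: sphere centre height q and radius R.

    The centre ``O = (l/2, yc, q)`` sits on the perpendicular through the
    circumcentre.  ``|OP|^2 = (R + h)^2`` expands to the affine relation
    ``q = A - B R`` with ``B = h / zp`` and

        ``A = (h1^2 - l xp - 2 yc yp - h^2) / (2 zp)``,

    which substituted into ``R^2 = r^2 + q^2`` gives the quadratic
    ``(1 - B^2) R^2 + 2 A B R - (r^2 + A^2) = 0`` solved in closed form.

    Root policy: keep real roots with ``R > 0`` and centre on the probe side
    of the base plane (``sign(q) = sign(zp)``, since the far-wall cap lies
    beyond the centre).  If two candidates survive, the one whose predicted
    near-wall ranges best match ``near_distances`` wins; without near ranges
    the ambiguity is raised to the caller.
    """
    if standoff_h < 0:
        raise ConfigError("standoff_h must be >= 0")
    xp, yp, zp = apex.xp, apex.yp, apex.zp
    if zp == 0:
        raise DegenerateApexError("apex zp must be nonzero")
    l, r = triangle.l, triangle.circumradius_r
    yc = float(triangle.circumcenter_O1[1])
    h = float(standoff_h)
    h1_sq = xp * xp + yp * yp + zp * zp  # = h1^2 by construction

    A = (h1_sq - l * xp - 2 * yc * yp - h * h) / (2 * zp)
    B = h / zp

    one_m_B2 = 1.0 - B * B
    if abs(one_m_B2) < 1e-14:
        denom = 2 * A * B
        if abs(denom) < 1e-300:
            raise NoSphereError("degenerate closure (B = 1, A = 0)")
        roots = [(r * r + A * A) / denom]
    else:
        disc = (A * B) ** 2 + one_m_B2 * (r * r + A * A)
        if disc < 0:
            raise NoSphereError("no real sphere radius (negative discriminant)")
        sq = np.sqrt(disc)
        roots = [(-A * B + sq) / one_m_B2, (-A * B - sq) / one_m_B2]

    scale = max(r, abs(A), 1e-12)
    candidates: list[tuple[int, float, float]] = []
    for idx, R in enumerate(roots):
        if R <= _SIN_TOL * scale:
            continue
        q = A - B * R
        if q * np.sign(zp) < -1e-12 * scale:
            continue
        candidates.append((idx, float(R), float(q)))

    if not candidates:
        raise NoSphereError("no admissible sphere (all roots unphysical)")
    if len(candidates) > 1:
        if near_distances is None:
            raise AmbiguousRootError(
                "two admissible sphere radii; supply near-wall distances or a root policy"
            )
        near = tuple(float(x) for x in near_distances)
        candidates = [
            min(candidates, key=lambda c: _near_mismatch(c, apex, triangle, yc, near))
        ]

    idx, R, q = candidates[0]
    center = np.array([l / 2, yc, q])
    residual = float(
        max(abs(np.linalg.norm(v - center) - R) for v in triangle.vertices)
    )
    return SphereSolution(
        q=q, R=R, center_O=center, residual=residual,
        n_candidates=len(roots), root_index=idx,
    )


def _near_mismatch(
    candidate: tuple[int, float, float],
    apex: ApexSolution,
    triangle: ChordTriangle,
    yc: float,
    near: tuple[float, ...],
) -> float:
    """Sum-squared error between predicted and measured near-wall ranges."""
    _, R, q = candidate
    sphere = _Sphere(center=np.array([triangle.l / 2, yc, q]), radius=R)
    p = apex.position
    err = 0.0
    for vertex, meas in zip(triangle.vertices, near):
        d = vertex - p
        d = d / np.linalg.norm(d)
        try:
            t_near, _ = ray_sphere_intersections(p, d, sphere)
        except RayMissError:
            return np.inf
        err += (t_near - meas) ** 2
    return err


@dataclass(frozen=True)
class _Sphere:
    # minimal duck-typed sphere for internal ray tests (no probe-plane invariant)
    center: np.ndarray
    radius: float

    @property
    def center_array(self) -> np.ndarray:
        return self.center


def sphere_volume(R: float) -> float:
    """Volume of a sphere of radius ``R`` meters, in milliliters."""
    if R < 0:
        raise ConfigError("radius must be >= 0")
    return (4.0 / 3.0) * np.pi * R ** 3 * ML_PER_M3


def radius_for_volume(volume_ml: float) -> float:
    """Radius (m) of the sphere holding ``volume_ml`` milliliters."""
    if volume_ml < 0:
        raise ConfigError("volume must be >= 0")
    return float((3.0 * volume_ml / ML_PER_M3 / (4.0 * np.pi)) ** (1.0 / 3.0))


StandoffStrategy = Literal["mean", "min", "fixed"]


def estimate_standoff(
    near_distances: Sequence[float] | None,
    strategy: StandoffStrategy = "mean",
    fixed_value: float | None = None,
) -> float:
    """Probe standoff ``h`` from the first-echo ranges.

    ``mean`` averages the three near-wall ranges (default), ``min`` takes the
    smallest (closest to the true surface distance for an on-axis sphere),
    ``fixed`` returns a supplied constant (e.g. a known 2 cm mount).
    """
    if strategy == "fixed":
        if fixed_value is None:
            raise ConfigError("fixed standoff strategy requires fixed_value")
        if fixed_value < 0:
            raise ConfigError("fixed standoff must be >= 0")
        return float(fixed_value)
    if near_distances is None or len(near_distances) == 0:
        raise ConfigError(f"standoff strategy {strategy!r} requires near distances")
    arr = np.asarray(near_distances, dtype=float)
    if np.any(arr <= 0):
        raise ConfigError("near distances must be positive")
    if strategy == "mean":
        return float(arr.mean())
    if strategy == "min":
        return float(arr.min())
    raise ConfigError(f"unknown standoff strategy {strategy!r}")


def ray_sphere_intersections(
    origin: Sequence[float], direction: Sequence[float], phantom
) -> tuple[float, float]:
    """Entry/exit ranges of a ray through a sphere (the forward echo model).

    Returns the two positive roots of ``|origin + t dir - center| = radius``
    sorted ascending.  A miss, a tangency, or a sphere not fully ahead of the
    origin raises :class:`RayMissError`.
    """
    o = np.asarray(origin, dtype=float)
    d = np.asarray(direction, dtype=float)
    nrm = np.linalg.norm(d)
    if abs(nrm - 1.0) > 1e-6:
        raise ConfigError("direction must be a unit vector")
    oc = o - phantom.center_array
    b = float(np.dot(oc, d))
    c = float(np.dot(oc, oc) - phantom.radius ** 2)
    disc = b * b - c
    if disc <= (1e-9 * phantom.radius) ** 2:
        raise RayMissError("ray misses (or is tangent to) the sphere")
    sq = float(np.sqrt(disc))
    t_near, t_far = -b - sq, -b + sq
    if t_near <= 0:
        raise RayMissError("sphere is not fully ahead of the ray origin")
    return t_near, t_far


def fit_sphere_four_points(*points: Sequence[float]) -> tuple[np.ndarray, float]:
    """Unique sphere through four non-coplanar points (independent oracle).

    Subtracting the quadratic constraints pairwise leaves the linear system
    ``2 (p_i - p_0) . c = |p_i|^2 - |p_0|^2`` for the centre ``c``.
    """
    if len(points) != 4:
        raise ConfigError("exactly four points required")
    p = np.asarray(points, dtype=float)
    M = 2.0 * (p[1:] - p[0])
    rhs = np.sum(p[1:] ** 2, axis=1) - np.sum(p[0] ** 2)
    scale = max(np.abs(M).max(), 1e-300)
    if abs(np.linalg.det(M)) < 1e-9 * scale ** 3:
        raise GeometryError("points are coplanar: no unique sphere")
    center = np.linalg.solve(M, rhs)
    radius = float(np.linalg.norm(p[0] - center))
    return center, radius
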