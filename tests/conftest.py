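import numpy as np
import pytest

import urovol as uv

DEG10 = np.deg2rad([10.0, 10.0, 10.0])


@pytest.fixture
def fan10() -> uv.BeamGeometry:
    """The bench fan: 10 degrees between every beam pair."""
    return uv.BeamGeometry(*DEG10)


def random_configuration(rng: np.random.Generator):
    """A random non-degenerate phantom/fan configuration with exact ranges.

    Returns (phantom, geometry, near, far) where near/far are the exact
    ray-sphere ranges of the three beams and geometry carries the exact
    standoff h = |OP| - R.  Rejection-samples until all beams hit.
    """
    while True:
        radius = rng.uniform(0.02, 0.06)
        standoff = rng.uniform(0.01, 0.04)
        angs = rng.uniform(np.deg2rad(6.0), np.deg2rad(14.0), size=3)
        try:
            geometry = uv.BeamGeometry(*angs, standoff_h=standoff)
        except uv.ConfigError:
            continue
        d = standoff + radius
        lateral = rng.uniform(-0.25, 0.25, size=2) * radius
        if np.hypot(*lateral) >= d:
            continue
        cz = np.sqrt(d * d - lateral[0] ** 2 - lateral[1] ** 2)
        if cz <= radius:
            continue
        phantom = uv.PhantomSpec(center=(lateral[0], lateral[1], cz), radius=radius)
        try:
            dirs = uv.beam_fan(geometry)
            pairs = [
                uv.ray_sphere_intersections(np.zeros(3), v, phantom) for v in dirs
            ]
        except (uv.RayMissError, uv.GeometryError):
            continue
        near = tuple(p[0] for p in pairs)
        far = tuple(p[1] for p in pairs)
        return phantom, geometry, near, far


def solve_from_ranges(geometry, near, far, standoff):
    """Run the geometry chain (chords -> apex -> sphere) on exact ranges."""
    tri = uv.chord_lengths(far, geometry)
    apex = uv.apex_position(tri, far)
    sphere = uv.solve_sphere(apex, tri, standoff, near_distances=near)
    return tri, apex, sphere
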