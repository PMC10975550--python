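"""Closed-form sphere reconstruction from exact beam ranges.

Builds a 30 mm-radius sphere 20 mm below the probe, intersects a 10-degree
three-beam fan with it, and runs the geometry chain (chords -> apex ->
sphere) on the exact ranges.  With exact inputs the radius comes back at
machine precision — the geometry itself adds no error.
"""

import numpy as np

import urovol as uv

phantom = uv.PhantomSpec(center=(0.0, 0.0, 0.05), radius=0.03)
geometry = uv.BeamGeometry(*np.deg2rad([10.0, 10.0, 10.0]))

pairs = [
    uv.ray_sphere_intersections(np.zeros(3), d, phantom)
    for d in uv.beam_fan(geometry)
]
near = [p[0] for p in pairs]
far = [p[1] for p in pairs]

triangle = uv.chord_lengths(far, geometry)
apex = uv.apex_position(triangle, far)
sphere = uv.solve_sphere(apex, triangle, phantom.standoff, near_distances=near)

print(f"true radius      : {phantom.radius * 1000:.3f} mm")
print(f"solved radius    : {sphere.R * 1000:.3f} mm")
print(f"relative error   : {abs(sphere.R - phantom.radius) / phantom.radius:.2e}")
print(f"volume           : {uv.sphere_volume(sphere.R):.2f} mL")
print(f"closure residual : {sphere.residual:.2e} m")
# The residual is how far the far-wall points deviate from the fitted sphere;
# ~1e-17 m here means the closed form is exact up to floating point.
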