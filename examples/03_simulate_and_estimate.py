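"""Full pipeline on a simulated 120 mL phantom measurement.

Simulates the three A-mode traces for a 120 mL sphere 2 cm below the probe
(with mild timing jitter and additive noise), then estimates the volume from
the traces alone and compares against ground truth.
"""

import numpy as np

import urovol as uv

phantom = uv.phantom_for_volume(120.0)  # top pole 2 cm below the probe
geometry = uv.BeamGeometry(*np.deg2rad([10.0, 10.0, 10.0]))
noise = uv.NoiseSpec(timing_jitter_sigma=0.25e-3, snr_db=30.0, seed=7)

measurement = uv.simulate_measurement(phantom, geometry, noise=noise)
estimate = uv.estimate_volume(measurement.traces)
stats = uv.error_stats(estimate.volume_ml, phantom.volume_ml)

d = estimate.diagnostics
print(f"true volume      : {phantom.volume_ml:.1f} mL (R = {phantom.radius * 1000:.2f} mm)")
print(f"estimated volume : {estimate.volume_ml:.1f} mL (R = {estimate.radius_m * 1000:.2f} mm)")
print(f"absolute error   : {stats.abs_err_ea:.1f} mL")
print(f"relative error   : {stats.rel_err_er:.2f} %")
print(f"standoff used    : {d['standoff_m'] * 1000:.2f} mm "
      f"({d['standoff_strategy']} of first echoes; exact {phantom.standoff * 1000:.2f} mm)")
# A fraction-of-a-millimeter range jitter maps to a few-percent volume error:
# the radius enters the volume cubed, so relative volume error is ~3x the
# relative radius error.
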