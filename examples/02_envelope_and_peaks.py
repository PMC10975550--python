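"""Hilbert-envelope demodulation and two-echo timing on one beam.

Synthesizes a trace with a near-wall echo at 27 us and a weaker far-wall
echo at 67 us, extracts the envelope, and reads off the two round-trip
times; with the speed of sound they become one-way wall distances.
"""

import numpy as np

import urovol as uv

FS = 100e6  # 100 MHz sampling
SPEED = 1480.0  # m/s (water)

pulse = uv.PulseSpec()  # 3 MHz Gaussian-modulated sinusoid
t = np.arange(int(80e-6 * FS)) / FS
samples = pulse.waveform(t - 27e-6) + 0.6 * pulse.waveform(t - 67e-6)
trace = uv.EchoTrace(samples, FS, beam_id=1)

envelope = uv.hilbert_envelope(trace)
times = uv.detect_two_echoes(envelope)

print(f"near echo : {times.dt_near * 1e6:.3f} us  "
      f"-> {uv.tof_to_distance(times.dt_near, SPEED) * 1000:.3f} mm")
print(f"far echo  : {times.dt_far * 1e6:.3f} us  "
      f"-> {uv.tof_to_distance(times.dt_far, SPEED) * 1000:.3f} mm")
# distance = S * dt / 2: a 27 us round trip in water is a ~20 mm standoff,
# the 67 us echo puts the far wall ~50 mm from the probe.
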