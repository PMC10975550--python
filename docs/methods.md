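# Methods

## Model and assumptions

The estimator treats the bladder as a perfect sphere and the three
ultrasound beams as rays from a common apex P (the probe face). Each ray
contributes two specular echoes — entry (near wall) and exit (far wall) —
and only their *timing* is used; echo amplitude never enters the volume
computation. The method therefore assumes:

- a fully spherical, fluid-filled target (valid for a reasonably full
  bladder; badly wrong for a nearly empty, collapsed one);
- all three beams intersect the sphere (the 10° fan bounds the measurable
  volume range from below for a given standoff);
- a single known speed of sound along the whole path.

## Geometry

With far-wall ranges h₁, h₂, h₃ and pairwise fan angles α, β, γ, the
chord lengths of the reflection triangle follow from the law of cosines.
The triangle is placed canonically (A at the origin, B on +x, C in the
upper half-plane), the apex is trilaterated, and the positive-z solution
is kept — the mirror image yields the same radius, so the convention is
irrelevant to the output.

The closure deserves care. The centre O = (l/2, y_c, q) satisfies both
R² = r² + q² (equidistance from A, B, C) and |OP| = R + h (the standoff
definition). Expanding |OP|² = (R + h)² gives the affine relation
q = A − B·R with

    A = (h₁² − l·x_P − 2·y_c·y_P − h²) / (2·z_P),   B = h / z_P,

and substitution yields (1 − B²)R² + 2ABR − (r² + A²) = 0, solved in
closed form — no iteration, no initialisation. The circumcentre ordinate
y_c is computed with its sign from the equidistance condition,
y_c = (n − l·cosθ) / (2·sinθ), rather than as +√(r² − l²/4); the two
agree for the acute triangles a narrow fan produces but the signed form
also covers obtuse ones.

Root policy: a root must be real, positive, and place the centre on the
probe side of the base plane (sign q = sign z_P — the far-wall cap lies
beyond the centre). For the bench-like regime h < z_P the quadratic has
one positive root and the policy is vacuous; if two roots ever survive,
the one whose predicted first-echo ranges (ray–sphere through P toward
A, B, C) best match the measured ones is kept, and without near ranges
the ambiguity is raised as an error rather than guessed.

Numerical tolerances: triangle rejected when sinθ < 1e−6 or a side
collapses; the apex height discriminant h₁² − x_P² − y_P² is clamped to
zero only within 1e−9 m² (more negative values are an inconsistency
error); solver self-consistency is checked to 1e−9 m and the residual
(max deviation of A, B, C from the fitted sphere) is always reported.

The standoff h is not directly observable. Three strategies are
provided: `mean` of the three first-echo ranges (default), `min`
(smallest first-echo range, an upper bound on h that is tight on-axis),
and `fixed` (a known mount distance, e.g. 2 cm). The mean strategy
overestimates h by ≈ (1 − cos δ)·|OP| for a fan of half-angle δ, because
off-axis beams meet the near wall beyond its top pole; at the bench
geometry this is ~0.2 mm and produces the small negative volume bias
visible in the clean sweep (~0.8 % at 120 mL, shrinking with volume).

## Signal path

The envelope uses the discrete analytic signal (FFT construction). Two
caveats are documented rather than hidden. First, the discrete envelope
of a finite tone shows interior leakage ripple (~1 %) unless the tone
spans whole periods; envelope fidelity statements are therefore made for
whole-period tones and for pulses, which is what the method processes.
Second, peak timing is taken at the envelope maximum and the emission
time is the transmit pulse centre, so round-trip times are
centre-to-centre and pulse width cancels.

Peak picking: local maxima after a dead zone (default 5 µs, covering
transmit ring-down), at least `min_separation` apart (default 2 pulse
lengths ≈ 2.5 µs), above 20 % of the post-dead-zone envelope maximum
(post-dead-zone rather than global, so ring-down amplitude cannot mask
real echoes); the two largest are kept, earlier = near wall. A
three-point parabolic fit refines each peak to sub-sample precision.

Timing precision under additive white noise is limited by information,
not implementation: for the 0.6-amplitude far echo at 20 dB SNR and
100 MHz sampling, the envelope-only Cramér–Rao bound is ≈ 0.8 samples,
so no envelope-peak detector resolves that echo to 1 sample reliably.
Broadband noise makes the naive argmax far worse (the envelope is flat
within the noise over several samples around its peak). An optional
zero-phase Butterworth band-pass around the carrier (off by default, as
bench hardware filters in its analog chain) restores near-bound
performance; the Monte-Carlo suite verifies ≥ 99 % of trials within
4 sample periods at 20 dB and within 1 sample period at 34 dB with the
filter on.

## Phantom simulator

`simulate_measurement` emulates the balloon-in-water-tank bench: a
sphere of known volume, top pole 2 cm below the probe (defaults), a 10°
symmetric fan, 3 MHz Gaussian-modulated pulses (fractional bandwidth
0.6), 100 MHz sampling, 1480 m/s (water at ~20 °C; 1540 m/s is the usual
tissue value). Echo pulses are injected at exactly 2·range/S; the far
pulse at 0.6 relative amplitude (a fixed ratio — no physical attenuation
model, since timing alone drives the estimate). Noise has two knobs:
one-way range-equivalent Gaussian timing jitter per echo, and additive
white noise at a given SNR. All randomness flows from one seed; repeat
runs are byte-identical, and batch sweeps spawn per-run seeds
deterministically from the base seed.

What passing tests show — and don't. The simulator validates the
algorithmic chain: timing extraction, ranging, and the closed-form
geometry, under controlled timing noise. It does not model diffraction,
speckle, wall thickness, refraction, non-spherical bladders or the
abdominal fat layer, so simulated error levels bound real-device
performance only from below.

## Problem sizes and acceptance sweep

The acceptance sweep uses the full bench protocol (10 volumes × 20 reps,
0.5 mm jitter) and runs in seconds; the solver-vs-oracle property uses
1000 random configurations against an independent four-point sphere fit
(linear system), agreeing to 1e−8 relative. Monte-Carlo detection tests
use 300–500 trials per condition. These sizes make the stochastic
assertions stable at the asserted margins while keeping the whole suite
under a minute.

## Known limitations

- Spherical model only; ellipsoidal or partially full bladders bias the
  estimate by construction.
- The standoff strategies assume the first echo truly is the near bladder
  wall; intervening tissue interfaces would need the dead zone and
  thresholds retuned.
- Speed of sound is a single scalar; a fat layer with different S biases
  all ranges multiplicatively.
- Very wide fans or strongly off-axis targets can make a beam miss; the
  pipeline flags rather than extrapolates.
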