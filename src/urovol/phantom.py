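"""In-silico phantom: three-beam A-mode traces for a sphere of known volume.

This module is the synthetic stand-in for a water-tank experiment in which a
water-filled balloon plays the bladder: a sphere of known volume hangs below
the probe, three 3 MHz beams in a narrow fan (10 degrees pairwise by
default) insonify it, and each beam records a near-wall and a far-wall echo.
The simulator injects Gaussian-modulated pulses at the exact round-trip
times given by ray/sphere geometry, optionally perturbed by range-equivalent
timing jitter and additive white noise, and attaches the full ground truth
so every intermediate pipeline quantity can be checked.

What it emulates: pulse-echo timing, echo ordering and amplitude ratio,
measurement noise.  What it does not: diffraction, speckle, frequency-
dependent attenuation, or an abdominal fat layer — timing, not waveform
fidelity, is what the volume estimate consumes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.signal

from .echo import EchoTrace, write_trace
from .errors import ConfigError, GeometryError, RayMissError, UrovolError
from .geometry import (
    BeamGeometry,
    PhantomSpec,
    radius_for_volume,
    ray_sphere_intersections,
)

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "true_volume_ml", "est_volume_ml", "abs_err_ml", "rel_err_pct", "seed", "rep", "ok",
]


@dataclass(frozen=True)
class PulseSpec:
    """Transmit pulse: Gaussian-modulated sinusoid (3 MHz centre by default)."""

    center_frequency: float = 3e6
    fractional_bandwidth: float = 0.6
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.center_frequency <= 0:
            raise ConfigError("center_frequency must be positive")
        if not (0 < self.fractional_bandwidth < 2):
            raise ConfigError("fractional_bandwidth must be in (0, 2)")

    @property
    def duration(self) -> float:
        """Effective pulse length (s): +/-3 sigma of the Gaussian envelope."""
        # scipy.signal.gausspulse envelope is exp(-a t^2) with the -6 dB
        # fractional-bandwidth convention
        ref = 10 ** (-6.0 / 20.0)
        a = -((np.pi * self.center_frequency * self.fractional_bandwidth) ** 2) / (
            4.0 * np.log(ref)
        )
        sigma = 1.0 / np.sqrt(2.0 * a)
        return 6.0 * sigma

    def waveform(self, t: np.ndarray) -> np.ndarray:
        """Pulse samples centred at t = 0."""
        return self.amplitude * scipy.signal.gausspulse(
            t, fc=self.center_frequency, bw=self.fractional_bandwidth
        )


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model.

    timing_jitter_sigma
        One-way range-equivalent Gaussian jitter (m) applied independently
        to every echo; models trigger/clock and speed-of-sound uncertainty.
    snr_db
        Additive white Gaussian noise level relative to the transmit pulse
        amplitude; ``inf`` means a clean trace.
    """

    timing_jitter_sigma: float = 0.0
    snr_db: float = np.inf
    seed: int = 0

    def __post_init__(self) -> None:
        if self.timing_jitter_sigma < 0:
            raise ConfigError("timing_jitter_sigma must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Exact intermediate quantities attached to a simulated measurement."""

    phantom: PhantomSpec
    near_ranges: tuple[float, ...]
    far_ranges: tuple[float, ...]
    standoff_h: float
    volume_ml: float
    missed_beams: tuple[int, ...] = ()


@dataclass(frozen=True)
class SimulatedMeasurement:
    traces: tuple[EchoTrace, ...]
    ground_truth: GroundTruth
    usable: bool = True


FAR_WALL_AMPLITUDE = 0.6  # far echo relative to near echo; fixed, no attenuation model


def beam_fan(angles: BeamGeometry) -> np.ndarray:
    """Three unit beam vectors (rows) realizing the pairwise fan angles.

    The Gram matrix of the requested cosines is factorized (symmetric PSD),
    then the fan is rotated so its mean direction is +z (into the body) and
    the first beam lies in the x-z plane: a deterministic canonical pose.
    For a symmetric fan this is a cone around +z with azimuths 120 deg apart.
    """
    G = angles.gram_matrix()
    w, V = np.linalg.eigh(G)
    if w.min() < -1e-9:
        raise GeometryError("beam angles are not realizable in 3D")
    X = V * np.sqrt(np.clip(w, 0.0, None))  # rows have Gram G
    norms = np.linalg.norm(X, axis=1)
    X = X / norms[:, None]

    axis = X.sum(axis=0)
    axis_norm = np.linalg.norm(axis)
    if axis_norm < 1e-12:
        raise GeometryError("beam fan has no mean direction (angles too wide)")
    axis = axis / axis_norm
    X = X @ _rotation_to_z(axis).T
    # spin about z so beam 1 sits in the x-z half-plane (x >= 0)
    x0, y0 = X[0, 0], X[0, 1]
    if np.hypot(x0, y0) > 1e-12:
        phi = np.arctan2(y0, x0)
        c, s = np.cos(-phi), np.sin(-phi)
        Rz = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        X = X @ Rz.T
    return X


def _rotation_to_z(u: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector u onto +z (Rodrigues)."""
    ez = np.array([0.0, 0.0, 1.0])
    v = np.cross(u, ez)
    s = np.linalg.norm(v)
    c = float(np.dot(u, ez))
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + K + K @ K * ((1 - c) / s ** 2)


def simulate_measurement(
    phantom: PhantomSpec,
    geometry: BeamGeometry,
    pulse: PulseSpec | None = None,
    noise: NoiseSpec | None = None,
    sampling_rate: float = 100e6,
    duration: float | None = None,
) -> SimulatedMeasurement:
    """Generate the three A-mode traces for one phantom measurement.

    Per beam, two pulses are injected at round-trip times ``2 (range +
    jitter) / S`` for the near and far wall (far at reduced amplitude), then
    white noise is added at ``snr_db``.  All randomness comes from
    ``noise.seed``.  A beam that misses the sphere yields a noise-only trace
    and flags the measurement unusable.
    """
    pulse = pulse or PulseSpec()
    noise = noise or NoiseSpec()
    S = phantom.speed_of_sound
    dirs = beam_fan(geometry)

    ranges: list[tuple[float, float] | None] = []
    missed: list[int] = []
    origin = np.zeros(3)
    for i, d in enumerate(dirs, start=1):
        try:
            ranges.append(ray_sphere_intersections(origin, d, phantom))
        except RayMissError:
            ranges.append(None)
            missed.append(i)
            logger.warning("beam %d misses the phantom", i)

    hit_fars = [r[1] for r in ranges if r is not None]
    min_duration = (2.0 * max(hit_fars) / S + pulse.duration) if hit_fars else 0.0
    if duration is None:
        duration = 1.5 * (2.0 * max(hit_fars) / S) if hit_fars else 1e-4
    if hit_fars and duration < min_duration:
        raise ConfigError(
            f"duration {duration:.3e} s shorter than the far round trip {min_duration:.3e} s"
        )

    rng = np.random.default_rng(noise.seed)
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    sigma_n = (
        0.0 if np.isinf(noise.snr_db) else pulse.amplitude * 10 ** (-noise.snr_db / 20.0)
    )

    traces = []
    for i, rr in enumerate(ranges, start=1):
        s = np.zeros(n)
        if rr is not None:
            near, far = rr
            jn, jf = rng.normal(0.0, noise.timing_jitter_sigma, size=2) if (
                noise.timing_jitter_sigma > 0
            ) else (0.0, 0.0)
            s += pulse.waveform(t - 2.0 * (near + jn) / S)
            s += FAR_WALL_AMPLITUDE * pulse.waveform(t - 2.0 * (far + jf) / S)
        if sigma_n > 0:
            s = s + rng.normal(0.0, sigma_n, size=n)
        traces.append(
            EchoTrace(samples=s, sampling_rate=sampling_rate, emission_time=0.0, beam_id=i)
        )

    truth = GroundTruth(
        phantom=phantom,
        near_ranges=tuple(r[0] if r else np.nan for r in ranges),
        far_ranges=tuple(r[1] if r else np.nan for r in ranges),
        standoff_h=phantom.standoff,
        volume_ml=phantom.volume_ml,
        missed_beams=tuple(missed),
    )
    return SimulatedMeasurement(traces=tuple(traces), ground_truth=truth, usable=not missed)


def phantom_for_volume(
    volume_ml: float, standoff: float = 0.02, speed_of_sound: float = 1480.0
) -> PhantomSpec:
    """On-axis sphere of the given volume with its top pole ``standoff`` below the probe."""
    R = radius_for_volume(volume_ml)
    return PhantomSpec(
        center=(0.0, 0.0, standoff + R), radius=R, speed_of_sound=speed_of_sound
    )


def batch_experiment(
    volumes_ml: Sequence[float],
    reps: int,
    geometry: BeamGeometry | None = None,
    pulse: PulseSpec | None = None,
    noise: NoiseSpec | None = None,
    sampling_rate: float = 100e6,
    standoff: float = 0.02,
    speed_of_sound: float = 1480.0,
    standoff_strategy: str = "mean",
    standoff_fixed: float | None = None,
) -> pd.DataFrame:
    """Sweep phantom volumes through the full estimation pipeline.

    For each requested volume a sphere is simulated ``reps`` times (per-run
    seeds spawned deterministically from ``noise.seed``) and estimated from
    its traces.  Rows that fail (beam miss, detection or geometry error) are
    kept with ``ok = False`` and NaN estimates and excluded from summaries.
    """
    from .pipeline import AcquisitionConfig, estimate_volume  # cycle-free at call time

    if reps < 0:
        raise ConfigError("reps must be >= 0")
    if any(v <= 0 for v in volumes_ml):
        raise ConfigError("volumes must be positive")
    geometry = geometry or BeamGeometry(*np.deg2rad([10.0, 10.0, 10.0]))
    noise = noise or NoiseSpec()
    cfg = AcquisitionConfig(
        speed_of_sound=speed_of_sound,
        angles_deg=tuple(np.rad2deg([geometry.alpha, geometry.beta, geometry.gamma])),
        standoff_strategy=standoff_strategy,
        standoff_fixed=standoff_fixed,
    )

    children = np.random.SeedSequence(noise.seed).spawn(len(volumes_ml) * reps)
    rows = []
    n_failed = 0
    k = 0
    for v in volumes_ml:
        spec = phantom_for_volume(v, standoff=standoff, speed_of_sound=speed_of_sound)
        for rep in range(reps):
            run_seed = int(children[k].generate_state(1)[0] & 0x7FFFFFFF)
            k += 1
            run_noise = NoiseSpec(
                timing_jitter_sigma=noise.timing_jitter_sigma,
                snr_db=noise.snr_db,
                seed=run_seed,
            )
            est_v = np.nan
            ok = True
            try:
                meas = simulate_measurement(
                    spec, geometry, pulse, run_noise, sampling_rate=sampling_rate
                )
                if not meas.usable:
                    raise RayMissError(
                        f"beams {meas.ground_truth.missed_beams} missed the phantom"
                    )
                est_v = estimate_volume(meas.traces, cfg).volume_ml
            except UrovolError as exc:
                ok = False
                n_failed += 1
                logger.warning("volume %.0f mL rep %d failed: %s", v, rep, exc)
            rows.append(
                {
                    "true_volume_ml": float(v),
                    "est_volume_ml": est_v,
                    "abs_err_ml": abs(est_v - v) if ok else np.nan,
                    "rel_err_pct": 100.0 * abs(est_v - v) / v if ok else np.nan,
                    "seed": run_seed,
                    "rep": rep,
                    "ok": ok,
                }
            )
    if n_failed:
        logger.warning("%d of %d runs failed and are excluded from summaries",
                       n_failed, len(rows))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_measurement(meas: SimulatedMeasurement, out_dir: str | Path) -> list[Path]:
    """Write trace files plus a JSON ground-truth sidecar; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for tr in meas.traces:
        p = out_dir / f"beam{tr.beam_id}.txt"
        write_trace(tr, p)
        paths.append(p)
    gt = meas.ground_truth
    sidecar = {
        "phantom": {
            "center_m": list(gt.phantom.center),
            "radius_m": gt.phantom.radius,
            "speed_of_sound_m_per_s": gt.phantom.speed_of_sound,
        },
        "near_ranges_m": [x if np.isfinite(x) else None for x in gt.near_ranges],
        "far_ranges_m": [x if np.isfinite(x) else None for x in gt.far_ranges],
        "standoff_h_m": gt.standoff_h,
        "volume_ml": gt.volume_ml,
        "missed_beams": list(gt.missed_beams),
        "usable": meas.usable,
    }
    p = out_dir / "ground_truth.json"
    p.write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    paths.append(p)
    return paths
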