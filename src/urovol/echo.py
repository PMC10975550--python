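"""A-mode echo signal path: envelope demodulation, peak timing, ranging.

A single beam returns a radio-frequency trace ``s(t)`` containing (ideally)
two narrow pulses: the near-wall and far-wall reflections.  The amplitude
envelope ``A(t) = sqrt(s^2 + s_hat^2)`` (``s_hat`` the Hilbert transform of
``s``) strips the 3 MHz carrier so that each echo becomes a smooth hump whose
maximum marks the pulse centre.  Round-trip times of the two largest humps
give the near/far wall ranges via ``distance = S * dt / 2``.

Trace files are plain delimited text with a small comment header, so that a
measurement can be archived and re-estimated bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.signal

from .errors import ConfigError, DataError, EchoDetectionError


@dataclass(frozen=True)
class EchoTrace:
    """Sampled pulse-echo signal from one beam.

    ``emission_time`` is the time of the transmit pulse *centre* on the trace
    clock (sample 0 = time 0); round-trip intervals are measured
    centre-to-centre against it.
    """

    samples: np.ndarray
    sampling_rate: float
    emission_time: float = 0.0
    beam_id: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate must be positive")
        if self.samples.ndim != 1 or self.samples.size < 16:
            raise ConfigError("trace must be a 1-D array of at least 16 samples")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass(frozen=True)
class Envelope:
    """Nonnegative amplitude envelope A(t), same length/clock as its trace."""

    values: np.ndarray
    sampling_rate: float
    emission_time: float = 0.0
    beam_id: int = 1


@dataclass(frozen=True)
class EchoTimes:
    """Round-trip times of the first (near-wall) and second (far-wall) echo."""

    dt_near: float
    dt_far: float
    beam_id: int = 1
    extra_peaks: int = 0  # qualifying candidates beyond the two kept

    def __post_init__(self) -> None:
        if not (0 < self.dt_near < self.dt_far):
            raise DataError("echo times must satisfy 0 < dt_near < dt_far")


@dataclass(frozen=True)
class PeakConfig:
    """Peak-picking policy for the two-echo detector.

    dead_zone
        Initial window (s) excluded from detection; covers transmit
        ring-down on real hardware.
    min_separation
        Minimum time (s) between the two echoes; default spans two 3 MHz
        pulse lengths so the near/far humps cannot merge.
    rel_threshold
        Peaks below this fraction of the post-dead-zone envelope maximum are
        ignored.
    interpolate
        Refine each peak with a three-point parabolic fit (sub-sample).
    """

    dead_zone: float = 5e-6
    min_separation: float = 2e-6
    rel_threshold: float = 0.2
    interpolate: bool = True

    def __post_init__(self) -> None:
        if self.dead_zone < 0:
            raise ConfigError("dead_zone must be >= 0")
        if not (0 < self.rel_threshold < 1):
            raise ConfigError("rel_threshold must be in (0, 1)")
        if self.min_separation <= 0:
            raise ConfigError("min_separation must be positive")


def hilbert_envelope(trace: EchoTrace) -> Envelope:
    """Amplitude envelope via the analytic signal.

    The discrete Hilbert transform is taken through the FFT analytic-signal
    construction (negative frequencies zeroed, positive band doubled), then
    ``A = |s + i s_hat|``.  Deterministic for a fixed input.
    """
    s = trace.samples
    if not np.all(np.isfinite(s)):
        raise DataError("trace contains non-finite samples")
    analytic = scipy.signal.hilbert(s)
    return Envelope(
        values=np.abs(analytic),
        sampling_rate=trace.sampling_rate,
        emission_time=trace.emission_time,
        beam_id=trace.beam_id,
    )


def detect_two_echoes(env: Envelope, cfg: PeakConfig | None = None) -> EchoTimes:
    """Locate the near- and far-wall echo times on one envelope.

    The two largest local maxima after the dead zone, separated by at least
    ``min_separation`` and above ``rel_threshold`` of the post-dead-zone
    maximum, are taken as the pulse centres; the earlier one (minus the
    emission time) is ``dt_near``, the later ``dt_far``.
    """
    cfg = cfg or PeakConfig()
    a = np.asarray(env.values, dtype=float)
    fs = env.sampling_rate
    start = int(np.ceil(cfg.dead_zone * fs))
    if start >= a.size - 2:
        raise EchoDetectionError("dead zone covers the whole trace", beam_id=env.beam_id)
    region = a[start:]
    peak_floor = cfg.rel_threshold * region.max()
    if peak_floor <= 0:
        raise EchoDetectionError("envelope is identically zero", beam_id=env.beam_id)
    idx, props = scipy.signal.find_peaks(
        region,
        height=peak_floor,
        distance=max(1, int(round(cfg.min_separation * fs))),
    )
    if idx.size < 2:
        raise EchoDetectionError(
            f"found {idx.size} qualifying echo peak(s), need 2 "
            "(beam missed the target or SNR too low)",
            beam_id=env.beam_id,
        )
    order = np.argsort(props["peak_heights"])[::-1]
    keep = np.sort(idx[order[:2]]) + start
    times = []
    for i in keep:
        t = i / fs
        if cfg.interpolate and 0 < i < a.size - 1:
            denom = a[i - 1] - 2 * a[i] + a[i + 1]
            if denom < 0:
                t += 0.5 * (a[i - 1] - a[i + 1]) / denom / fs
        times.append(t - env.emission_time)
    return EchoTimes(
        dt_near=times[0],
        dt_far=times[1],
        beam_id=env.beam_id,
        extra_peaks=int(idx.size - 2),
    )


def bandpass_filter(
    trace: EchoTrace,
    center_frequency: float = 3e6,
    half_bandwidth: float = 1.8e6,
    order: int = 4,
) -> EchoTrace:
    """Optional zero-phase band-pass around the pulse carrier.

    Off by default in the pipeline (bench hardware already filters in the
    analog chain); enable it for low-SNR traces — broadband noise otherwise
    dominates the envelope near its flat peak and inflates timing jitter.
    Zero-phase (forward-backward Butterworth), so peak times are unbiased.
    """
    if not (0 < half_bandwidth < center_frequency):
        raise ConfigError("half_bandwidth must be in (0, center_frequency)")
    nyq = trace.sampling_rate / 2.0
    if center_frequency + half_bandwidth >= nyq:
        raise ConfigError("pass band exceeds Nyquist")
    sos = scipy.signal.butter(
        order,
        [center_frequency - half_bandwidth, center_frequency + half_bandwidth],
        btype="bandpass",
        fs=trace.sampling_rate,
        output="sos",
    )
    return EchoTrace(
        samples=scipy.signal.sosfiltfilt(sos, trace.samples),
        sampling_rate=trace.sampling_rate,
        emission_time=trace.emission_time,
        beam_id=trace.beam_id,
    )


def tof_to_distance(dt: float, speed_S: float) -> float:
    """One-way range from a round-trip time: ``S * dt / 2``."""
    if dt < 0:
        raise ConfigError("round-trip time must be >= 0")
    if speed_S <= 0:
        raise ConfigError("speed of sound must be positive")
    return speed_S * dt / 2.0


# ---------------------------------------------------------------------------
# trace file format: '#'-prefixed key=value header, one amplitude per line

def write_trace(trace: EchoTrace, path: str | Path) -> None:
    """Write a trace as delimited text; full float precision (exact round trip)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# sampling_rate_hz={trace.sampling_rate!r}\n")
        fh.write(f"# emission_time_s={trace.emission_time!r}\n")
        fh.write(f"# beam_id={trace.beam_id}\n")
        for x in trace.samples:
            fh.write(f"{float(x)!r}\n")


def read_trace(path: str | Path) -> EchoTrace:
    """Read a trace file written by :func:`write_trace`."""
    path = Path(path)
    header: dict[str, str] = {}
    samples: list[float] = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    header[k.strip()] = v.strip()
            else:
                samples.append(float(line))
    try:
        rate = float(header["sampling_rate_hz"])
    except KeyError:
        raise DataError(f"{path}: missing sampling_rate_hz header") from None
    return EchoTrace(
        samples=np.array(samples),
        sampling_rate=rate,
        emission_time=float(header.get("emission_time_s", 0.0)),
        beam_id=int(header.get("beam_id", 1)),
    )
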