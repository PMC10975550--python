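"""End-to-end orchestration: three echo traces in, a bladder volume out.

``estimate_volume`` chains the whole method — envelope demodulation,
two-echo peak timing, time-of-flight ranging, standoff estimation, chord
triangle, apex trilateration, sphere closure — and attaches per-stage
diagnostics so a failed or suspicious estimate can be traced to a beam.
``run_experiment`` reproduces the balloon-sweep error analysis in silico
and writes a results table plus a JSON summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import geometry as geo
from .echo import (
    EchoTrace,
    PeakConfig,
    bandpass_filter,
    detect_two_echoes,
    hilbert_envelope,
    tof_to_distance,
)
from .errors import ConfigError, EchoDetectionError
from .geometry import VolumeEstimate

logger = logging.getLogger(__name__)

SPEED_RANGE = (1400.0, 1650.0)  # physiological / water-tank plausibility gate, m/s


@dataclass(frozen=True)
class AcquisitionConfig:
    """Everything the estimator needs besides the traces themselves."""

    speed_of_sound: float = 1480.0
    angles_deg: tuple[float, float, float] = (10.0, 10.0, 10.0)
    standoff_strategy: str = "mean"
    standoff_fixed: float | None = None
    peak: PeakConfig = field(default_factory=PeakConfig)
    allow_any_speed: bool = False
    prefilter: bool = False  # zero-phase band-pass around 3 MHz for low-SNR traces

    def __post_init__(self) -> None:
        if not self.allow_any_speed and not (
            SPEED_RANGE[0] <= self.speed_of_sound <= SPEED_RANGE[1]
        ):
            raise ConfigError(
                f"speed of sound {self.speed_of_sound} m/s outside {SPEED_RANGE}; "
                "set allow_any_speed to override"
            )
        for a in self.angles_deg:
            if not (0.0 < a < 90.0):
                raise ConfigError(f"beam angle {a} deg outside (0, 90)")
        if self.standoff_strategy not in ("mean", "min", "fixed"):
            raise ConfigError(f"unknown standoff strategy {self.standoff_strategy!r}")
        if self.standoff_strategy == "fixed" and self.standoff_fixed is None:
            raise ConfigError("fixed standoff strategy requires standoff_fixed")

    @property
    def beam_geometry(self) -> geo.BeamGeometry:
        a, b, c = np.deg2rad(self.angles_deg)
        return geo.BeamGeometry(alpha=float(a), beta=float(b), gamma=float(c))


@dataclass(frozen=True)
class ErrorStats:
    """Absolute and relative error of one measurement against ground truth."""

    measured_x: float
    true_a: float
    abs_err_ea: float
    rel_err_er: float


def error_stats(measured_x: float, true_a: float) -> ErrorStats:
    """Absolute error |x - a| (mL) and relative error 100 |x - a| / a (%)."""
    if true_a <= 0:
        raise ConfigError("true volume must be positive")
    ea = abs(measured_x - true_a)
    return ErrorStats(
        measured_x=float(measured_x),
        true_a=float(true_a),
        abs_err_ea=float(ea),
        rel_err_er=float(100.0 * ea / true_a),
    )


def estimate_volume(
    traces: Sequence[EchoTrace], cfg: AcquisitionConfig | None = None
) -> VolumeEstimate:
    """Estimate the bladder volume from three single-beam echo traces.

    Raises a typed error naming the offending beam/stage on any failure; a
    successful return always carries full per-beam diagnostics.
    """
    cfg = cfg or AcquisitionConfig()
    if len(traces) != 3:
        raise ConfigError(f"exactly three traces required, got {len(traces)}")
    ids = [tr.beam_id for tr in traces]
    if len(set(ids)) != 3:
        raise ConfigError(f"beam_ids must be distinct, got {ids}")
    ordered = sorted(traces, key=lambda tr: tr.beam_id)

    near, far, times = [], [], []
    for tr in ordered:
        if cfg.prefilter:
            tr = bandpass_filter(tr)
        env = hilbert_envelope(tr)
        try:
            et = detect_two_echoes(env, cfg.peak)
        except EchoDetectionError as exc:
            raise EchoDetectionError(
                f"beam {tr.beam_id}: {exc}", beam_id=tr.beam_id
            ) from exc
        times.append(et)
        near.append(tof_to_distance(et.dt_near, cfg.speed_of_sound))
        far.append(tof_to_distance(et.dt_far, cfg.speed_of_sound))

    h = geo.estimate_standoff(near, cfg.standoff_strategy, cfg.standoff_fixed)
    bg = cfg.beam_geometry
    tri = geo.chord_lengths(far, bg)
    apex = geo.apex_position(tri, far)
    sphere = geo.solve_sphere(apex, tri, h, near_distances=near)
    volume = geo.sphere_volume(sphere.R)
    logger.info(
        "estimate: R=%.4f m V=%.1f mL (h=%.4f m, residual=%.2e m)",
        sphere.R, volume, h, sphere.residual,
    )
    return VolumeEstimate(
        volume_ml=volume,
        radius_m=sphere.R,
        diagnostics={
            "near_distances_m": list(near),
            "far_distances_m": list(far),
            "dt_near_s": [t.dt_near for t in times],
            "dt_far_s": [t.dt_far for t in times],
            "extra_peaks": [t.extra_peaks for t in times],
            "standoff_m": h,
            "standoff_strategy": cfg.standoff_strategy,
            "chords_m": [tri.l, tri.m, tri.n],
            "apex_m": [apex.xp, apex.yp, apex.zp],
            "center_O_m": sphere.center_O.tolist(),
            "q_m": sphere.q,
            "root_index": sphere.root_index,
            "n_candidates": sphere.n_candidates,
            "residual_m": sphere.residual,
        },
    )


def summarize(results: pd.DataFrame) -> dict:
    """Per-volume and overall relative-error summary of a sweep table."""
    ok = results[results["ok"].astype(bool)] if len(results) else results
    per_volume = []
    for v, grp in ok.groupby("true_volume_ml", sort=True):
        per_volume.append(
            {
                "true_volume_ml": float(v),
                "n": int(len(grp)),
                "mean_rel_err_pct": float(grp["rel_err_pct"].mean()),
                "max_rel_err_pct": float(grp["rel_err_pct"].max()),
                "mean_est_volume_ml": float(grp["est_volume_ml"].mean()),
            }
        )
    return {
        "n_runs": int(len(results)),
        "n_ok": int(len(ok)),
        "n_failed": int(len(results) - len(ok)),
        "per_volume": per_volume,
        "overall_mean_rel_err_pct": float(ok["rel_err_pct"].mean()) if len(ok) else None,
        "overall_max_rel_err_pct": float(ok["rel_err_pct"].max()) if len(ok) else None,
    }


def run_experiment(
    volumes_ml: Sequence[float],
    reps: int,
    cfg: AcquisitionConfig | None = None,
    jitter_mm: float = 0.0,
    snr_db: float = np.inf,
    seed: int = 0,
    sampling_rate: float = 100e6,
    standoff: float = 0.02,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulated balloon sweep: results table + summary, optionally written out.

    Outputs are byte-deterministic for fixed inputs and seed (hash-equal
    files across runs).
    """
    from .phantom import NoiseSpec, batch_experiment  # deferred: phantom uses pipeline

    cfg = cfg or AcquisitionConfig()
    noise = NoiseSpec(timing_jitter_sigma=jitter_mm * 1e-3, snr_db=snr_db, seed=seed)
    results = batch_experiment(
        list(volumes_ml),
        reps,
        geometry=cfg.beam_geometry,
        noise=noise,
        sampling_rate=sampling_rate,
        standoff=standoff,
        speed_of_sound=cfg.speed_of_sound,
        standoff_strategy=cfg.standoff_strategy,
        standoff_fixed=cfg.standoff_fixed,
    )
    summary = summarize(results)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        results.to_csv(out_dir / "results.csv", index=False, float_format="%.10g")
        (out_dir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
    return results, summary
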