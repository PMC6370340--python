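"""Render ground-truth trajectories into noisy donor/acceptor traces.

The apparent FRET efficiency of the fork falls from ~0.95 (intact
duplex) toward a donor-leakage floor of 0.11 as base pairs are unwound,
following a measured calibration curve.  The renderer converts a
trajectory's piecewise-constant position into per-frame intensities:
the frame's apparent FRET is the exact time-weighted average of the
calibration over the frame (sub-frame steps blur realistically),
acceptor = total*E and donor = total*(1-E), plus per-channel additive
Gaussian camera noise and a constant background.  After strand release
both channels drop to background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np

from .kinetics import Trajectory

__all__ = [
    "CalibrationCurve",
    "NoiseModel",
    "FretTrace",
    "bp_to_fret",
    "render_trace",
    "write_trace",
    "read_trace",
]

#: default calibration anchors: bp unwound -> apparent FRET.  The first five
#: are measured stall levels (0, 4, 7, 10, 13 bp); the curve then runs
#: linearly to the leakage floor at 16 bp and stays flat beyond.
DEFAULT_ANCHORS: Tuple[Tuple[float, float], ...] = (
    (0, 0.95), (4, 0.73), (7, 0.61), (10, 0.48), (13, 0.24), (16, 0.11),
)


@dataclass(frozen=True)
class CalibrationCurve:
    """Monotone map from base pairs unwound to apparent FRET efficiency.

    Leakage of donor emission into the acceptor channel is treated as
    already embedded in the anchor values (they are apparent levels),
    so the floor of the curve *is* the leakage level and no separate
    correction is applied.
    """

    anchors: Tuple[Tuple[float, float], ...] = DEFAULT_ANCHORS
    leakage_floor: float = 0.11

    def __post_init__(self) -> None:
        bp = np.array([a[0] for a in self.anchors], dtype=float)
        ef = np.array([a[1] for a in self.anchors], dtype=float)
        if len(bp) < 2:
            raise ValueError("need at least two calibration anchors")
        if np.any(np.diff(bp) <= 0):
            raise ValueError("anchor bp positions must be strictly increasing")
        if np.any(np.diff(ef) >= 0):
            raise ValueError("anchor FRET values must be strictly decreasing")
        if np.any((ef < 0) | (ef > 1)) or not 0 <= self.leakage_floor <= 1:
            raise ValueError("FRET values must lie in [0, 1]")
        if abs(ef[-1] - self.leakage_floor) > 1e-12 and ef[-1] < self.leakage_floor:
            raise ValueError("anchors fall below the leakage floor")

    @property
    def _bp(self) -> np.ndarray:
        return np.array([a[0] for a in self.anchors], dtype=float)

    @property
    def _ef(self) -> np.ndarray:
        return np.array([a[1] for a in self.anchors], dtype=float)

    def fret_at(self, position) -> np.ndarray:
        """Apparent FRET at ``position`` bp unwound (scalar or array)."""
        pos = np.asarray(position, dtype=float)
        if np.any(pos < 0):
            raise ValueError("position must be non-negative")
        e = np.interp(pos, self._bp, self._ef)
        return np.maximum(e, self.leakage_floor)

    def invert(self, efret) -> np.ndarray:
        """Base pairs unwound at apparent FRET ``efret`` (clipped to the
        calibrated range; the flat floor region maps to the last anchor)."""
        e = np.clip(np.asarray(efret, dtype=float), self._ef[-1], self._ef[0])
        # np.interp needs increasing x
        return np.interp(-e, -self._ef, self._bp)


def bp_to_fret(position, calibration: Optional[CalibrationCurve] = None):
    """Apparent FRET efficiency after unwinding ``position`` base pairs."""
    calibration = calibration or CalibrationCurve()
    out = calibration.fret_at(position)
    return float(out) if np.isscalar(position) else out


@dataclass(frozen=True)
class NoiseModel:
    """Camera model: constant total signal, additive Gaussian channel noise."""

    total_intensity: float = 1000.0   # mean summed counts per frame while bound
    sigma: float = 30.0               # per-channel additive noise s.d. (counts)
    background: float = 100.0         # per-channel offset (counts)

    def __post_init__(self) -> None:
        if self.total_intensity <= 0:
            raise ValueError("total_intensity must be positive")
        if self.sigma < 0 or self.background < 0:
            raise ValueError("sigma and background must be non-negative")


@dataclass
class FretTrace:
    """Per-frame donor/acceptor intensities of one molecule."""

    frame_interval: float            # s
    injection_frame: int
    donor: np.ndarray                # counts
    acceptor: np.ndarray             # counts
    released_frame: Optional[int] = None   # ground truth, when known
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.donor.shape != self.acceptor.shape:
            raise ValueError("donor and acceptor must have equal length")
        if not (np.all(np.isfinite(self.donor)) and np.all(np.isfinite(self.acceptor))):
            raise ValueError("intensities must be finite")

    @property
    def n_frames(self) -> int:
        return len(self.donor)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


def _segment_average(knots: np.ndarray, values: np.ndarray, edges: np.ndarray,
                     end: float) -> np.ndarray:
    """Exact per-frame mean of a piecewise-constant signal.

    ``values[i]`` holds on ``[knots[i], knots[i+1])``; the last value
    holds up to ``end`` and the signal is 0 afterwards.  ``edges`` are
    frame boundaries (length n_frames + 1).
    """
    k = np.append(knots, end)
    # cumulative integral at the knots; piecewise linear in t between them
    seg = np.diff(k) * values
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    integral = np.interp(np.clip(edges, k[0], k[-1]), k, cum)
    return np.diff(integral) / np.diff(edges)


def render_trace(traj: Trajectory, calibration: Optional[CalibrationCurve] = None,
                 noise: Optional[NoiseModel] = None, frame_interval: float = 0.1,
                 seed: int = 0, pre_injection_frames: int = 20) -> FretTrace:
    """Render one trajectory to a camera trace.

    Frames before ``injection_frame`` (and between injection and the
    initiation event) show the intact duplex.  Completion releases the
    donor strand: from that instant both channels contain only
    background and noise, with the release frame itself carrying the
    partial-frame signal.
    """
    if not 0.01 <= frame_interval <= 1.0:
        raise ValueError("frame_interval must lie in [0.01, 1] s")
    if traj.horizon < frame_interval:
        raise ValueError("trajectory horizon shorter than one frame: empty trace")
    calibration = calibration or CalibrationCurve()
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)

    offset = pre_injection_frames * frame_interval
    n_frames = pre_injection_frames + int(np.floor(traj.horizon / frame_interval))
    edges = np.arange(n_frames + 1) * frame_interval
    end = edges[-1]

    knots, pos = traj.position_steps()
    knots = knots + offset
    if knots[0] > 0.0:
        knots = np.concatenate([[0.0], knots])
        pos = np.concatenate([[0], pos])
    efret = calibration.fret_at(pos)

    t_release = traj.completion_time
    released_frame: Optional[int] = None
    if t_release is not None:
        t_release += offset
        released_frame = int(t_release / frame_interval)
    cap = end if t_release is None else min(t_release, end)

    mean_e = _segment_average(knots, efret, edges, cap)          # ∫E·occ / dt
    occ = _segment_average(np.array([0.0]), np.array([1.0]), edges, cap)

    acceptor = noise.total_intensity * mean_e + noise.background
    donor = noise.total_intensity * (occ - mean_e) + noise.background
    if noise.sigma > 0:
        acceptor = acceptor + rng.normal(0.0, noise.sigma, n_frames)
        donor = donor + rng.normal(0.0, noise.sigma, n_frames)

    return FretTrace(
        frame_interval=frame_interval,
        injection_frame=pre_injection_frames,
        donor=donor,
        acceptor=acceptor,
        released_frame=released_frame,
        meta={
            "seed": int(seed),
            "background": noise.background,
            "total_intensity": noise.total_intensity,
            "noise_sigma": noise.sigma,
            "completed": bool(traj.completed),
            "true_slip_count": int(traj.slip_count),
            "t_init_true": float(traj.t_init),
        },
    )


# ---------------------------------------------------------------------------
# trace I/O: TSV with a JSON sidecar

def write_trace(trace: FretTrace, path) -> Tuple[Path, Path]:
    """Write a trace as TSV (frame_index, time_s, donor, acceptor) plus a
    ``.json`` metadata sidecar.  Returns (tsv_path, sidecar_path)."""
    path = Path(path)
    tsv = path if path.suffix == ".tsv" else path.with_suffix(".tsv")
    with open(tsv, "w") as fh:
        fh.write("frame_index\ttime_s\tdonor\tacceptor\n")
        for i, (t, d, a) in enumerate(zip(trace.times, trace.donor, trace.acceptor)):
            fh.write(f"{i}\t{t:.6f}\t{d:.4f}\t{a:.4f}\n")
    sidecar = tsv.with_suffix(".json")
    meta = dict(trace.meta)
    meta.update({
        "frame_interval": trace.frame_interval,
        "injection_frame": trace.injection_frame,
        "released_frame": trace.released_frame,
    })
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    return tsv, sidecar


def read_trace(path) -> FretTrace:
    """Read a TSV trace written by :func:`write_trace` (sidecar optional)."""
    path = Path(path)
    data = np.loadtxt(path, skiprows=1)
    if data.ndim == 1:
        data = data[None, :]
    sidecar = path.with_suffix(".json")
    meta = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
    times = data[:, 1]
    dt = meta.get("frame_interval")
    if dt is None:
        dt = float(np.median(np.diff(times))) if len(times) > 1 else 0.1
    return FretTrace(
        frame_interval=float(dt),
        injection_frame=int(meta.get("injection_frame", 0)),
        donor=data[:, 2],
        acceptor=data[:, 3],
        released_frame=meta.get("released_frame"),
        meta=meta,
    )
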