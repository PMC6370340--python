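"""Deterministic event detection in donor/acceptor traces.

The original trace scoring was done by visual inspection; this module
codifies it into explicit, configurable rules so that simulated and
real traces are scored identically and reproducibly:

* apparent FRET ``E = (A - bA) / ((A - bA) + (D - bD))``, clamped to
  [0, 1]; frames with non-positive total are invalid,
* unwinding onset = first sustained drop of the smoothed E below the
  pre-injection high-state band,
* strand release = collapse of total intensity to background,
* stalls = plateaus of at least five frames at intermediate FRET,
* slippage = hysteresis counting of returns to the high state
  (excursion below 0.70 followed by a recrossing above 0.80) on a
  150-ms box-averaged trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .render import FretTrace

__all__ = [
    "DetectionConfig",
    "StallEvent",
    "EventSet",
    "compute_fret",
    "detect_release",
    "detect_initiation_and_unwinding",
    "detect_stalls",
    "count_slippage",
    "classify_outcome",
    "analyze_trace",
]

COMPLETE = "complete"
INCOMPLETE = "incomplete"
NO_ACTIVITY = "no_activity"


@dataclass(frozen=True)
class DetectionConfig:
    """Thresholds of the codified scoring rules (all FRET values apparent)."""

    onset_smooth: int = 3            # running-mean window for onset detection (frames)
    onset_sigma_mult: float = 3.0    # drop must exceed this many sigma below high state
    onset_hold: int = 3              # frames the drop must persist
    sigma_floor: float = 0.01        # lower bound on the estimated high-state sigma
    fallback_high: float = 0.95      # high-state mean when no pre-injection frames exist
    fallback_sigma: float = 0.02
    stall_tolerance: float = 0.05    # max deviation from the plateau mean
    stall_min_run: int = 5           # minimum plateau length (frames)
    leakage_floor: float = 0.11
    stall_band_margin: float = 0.05  # plateau level must sit this far inside (floor, high)
    slip_low: float = 0.70           # hysteresis thresholds for slippage counting
    slip_high: float = 0.80
    slip_box: float = 0.150          # box-average window (s)
    release_sigma_mult: float = 3.0  # total below this many sigma for release
    release_hold: int = 2            # consecutive frames required


@dataclass(frozen=True)
class StallEvent:
    start_frame: int
    end_frame: int                   # inclusive
    level: float                     # mean apparent FRET over the plateau
    lifetime: float                  # s

    def __post_init__(self) -> None:
        if self.end_frame < self.start_frame:
            raise ValueError("end_frame before start_frame")
        if not 0.0 <= self.level <= 1.0:
            raise ValueError("stall level outside [0, 1]")


@dataclass
class EventSet:
    """Per-trace scored events."""

    t_init: Optional[float]
    t_unw: Optional[float]
    stalls: List[StallEvent] = field(default_factory=list)
    slip_count: int = 0
    outcome: str = NO_ACTIVITY

    def __post_init__(self) -> None:
        if self.outcome not in (COMPLETE, INCOMPLETE, NO_ACTIVITY):
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if (self.outcome == COMPLETE) != (self.t_unw is not None):
            raise ValueError("t_unw must be present iff outcome is complete")


def compute_fret(trace: FretTrace, background: Tuple[float, float]) -> np.ndarray:
    """Per-frame apparent FRET efficiency, NaN where the frame is invalid.

    ``background`` is the per-channel offset ``(donor, acceptor)`` in
    counts.  E is the acceptor fraction of the background-subtracted
    total, clamped to [0, 1]; frames whose total signal is not positive
    carry no molecule information and are flagged invalid (NaN).
    """
    b_d, b_a = background
    if b_d < 0 or b_a < 0:
        raise ValueError("background must be non-negative")
    d = trace.donor - b_d
    a = trace.acceptor - b_a
    total = d + a
    with np.errstate(invalid="ignore", divide="ignore"):
        e = np.where(total > 0, a / total, np.nan)
    return np.clip(e, 0.0, 1.0)


def detect_release(trace: FretTrace, background: Tuple[float, float],
                   config: DetectionConfig = DetectionConfig()) -> Optional[int]:
    """First frame of a sustained total-intensity collapse, or ``None``.

    The noise scale is estimated from pre-injection frames (or from the
    configured fallback when none exist); release requires the
    background-subtracted total to sit below ``release_sigma_mult``
    noise s.d. for ``release_hold`` consecutive frames.
    """
    b_d, b_a = background
    total = (trace.donor - b_d) + (trace.acceptor - b_a)
    pre = total[: trace.injection_frame]
    if len(pre) >= 5:
        sigma = max(float(np.std(pre)), 1e-6)
        high = float(np.mean(pre))
    else:
        sigma = max(float(np.std(total[:10])), 1e-6)
        high = float(np.mean(total[:10]))
    thresh = min(config.release_sigma_mult * sigma, 0.5 * high)
    below = total < thresh
    run = 0
    for i in range(trace.injection_frame, len(total)):
        run = run + 1 if below[i] else 0
        if run >= config.release_hold:
            return i - config.release_hold + 1
    return None


def _first_sustained_drop(smooth: np.ndarray, start: int, threshold: float,
                          hold: int) -> Optional[int]:
    below = smooth < threshold
    for i in range(start, len(smooth) - hold + 1):
        if np.all(below[i:i + hold]):
            return i
    return None


def detect_initiation_and_unwinding(
    E: np.ndarray, injection_frame: int, frame_interval: float,
    config: DetectionConfig = DetectionConfig(),
    release_frame: Optional[int] = None,
) -> Tuple[Optional[float], Optional[float], str]:
    """Score initiation/unwinding times and the trace outcome.

    Returns ``(t_init, t_unw, outcome)``.  ``t_init`` is the delay from
    injection to the unwinding onset; ``t_unw`` runs from the onset to
    strand release and exists only for complete traces.  The onset is
    the first frame where the ``onset_smooth``-frame running mean drops
    more than ``onset_sigma_mult`` estimated noise s.d. below the
    high-state mean and stays below for ``onset_hold`` frames; high
    state and noise are estimated from pre-injection frames.
    """
    E = np.asarray(E, dtype=float)
    if injection_frame >= len(E):
        raise ValueError("no frames after injection: malformed input")
    if injection_frame < 0:
        raise ValueError("injection_frame must be non-negative")

    pre = E[:injection_frame]
    pre = pre[np.isfinite(pre)]
    if len(pre) >= 5:
        high = float(np.mean(pre))
        sigma = max(float(np.std(pre)), config.sigma_floor)
    else:
        high = config.fallback_high
        sigma = config.fallback_sigma

    w = config.onset_smooth
    kernel = np.ones(w) / w
    filled = np.where(np.isfinite(E), E, 0.0)      # invalid frames count as collapsed
    smooth = np.convolve(filled, kernel, mode="same")

    threshold = high - config.onset_sigma_mult * sigma
    onset = _first_sustained_drop(smooth, injection_frame, threshold,
                                  config.onset_hold)
    if onset is None or (release_frame is not None and onset > release_frame):
        return None, None, NO_ACTIVITY

    t_init = (onset - injection_frame) * frame_interval
    if release_frame is not None:
        t_unw = (release_frame - onset) * frame_interval
        return t_init, max(t_unw, 0.0), COMPLETE
    return t_init, None, INCOMPLETE


def detect_stalls(E: np.ndarray, frame_interval: float,
                  tolerance: float = 0.05, min_run: int = 5,
                  config: DetectionConfig = DetectionConfig(),
                  high_level: Optional[float] = None) -> List[StallEvent]:
    """Find intermediate-FRET plateaus of at least ``min_run`` frames.

    A plateau is a maximal run of consecutive valid frames whose every
    member deviates from the run mean by at most ``tolerance``.  Runs
    whose level sits within ``stall_band_margin`` of the leakage floor
    or of the high state are not stalls (they are the unwound and the
    intact duplex, respectively).  Invalid frames break plateaus.
    """
    if min_run < 2:
        raise ValueError("min_run must be at least 2")
    E = np.asarray(E, dtype=float)
    high = config.fallback_high if high_level is None else high_level
    lo = config.leakage_floor + config.stall_band_margin
    hi = high - config.stall_band_margin

    stalls: List[StallEvent] = []
    i = 0
    n = len(E)
    while i < n:
        if not np.isfinite(E[i]):
            i += 1
            continue
        j = i + 1
        # grow the run while every member stays within tolerance of the mean
        while j < n and np.isfinite(E[j]):
            window = E[i:j + 1]
            if np.max(np.abs(window - np.mean(window))) > tolerance:
                break
            j += 1
        run = E[i:j]
        if len(run) >= min_run:
            level = float(np.mean(run))
            if lo < level < hi:
                stalls.append(StallEvent(
                    start_frame=i, end_frame=j - 1,
                    level=level, lifetime=len(run) * frame_interval,
                ))
        i = max(j, i + 1)
    return stalls


def count_slippage(E: np.ndarray, frame_interval: float,
                   box_window: float = 0.150,
                   low_threshold: float = 0.70,
                   high_threshold: float = 0.80) -> int:
    """Count slippage events by threshold hysteresis on a box-averaged trace.

    A slip is an upward recrossing of ``high_threshold`` that follows an
    excursion below ``low_threshold``: the helicase partially unwinds
    the duplex (E drops low) and then slips backwards, rezipping it
    (E returns to the intact-duplex level).  The final, successful
    unwinding run never recrosses upward and is therefore not counted.
    """
    if low_threshold >= high_threshold:
        raise ValueError("low_threshold must be below high_threshold")
    if box_window < frame_interval:
        raise ValueError("box window shorter than the frame interval")
    E = np.asarray(E, dtype=float)
    w = max(int(round(box_window / frame_interval)), 1)
    valid = np.isfinite(E)
    num = np.convolve(np.where(valid, E, 0.0), np.ones(w), mode="same")
    den = np.convolve(valid.astype(float), np.ones(w), mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        box = np.where(den > 0, num / den, np.nan)

    count = 0
    armed = False
    for x in box:
        if not np.isfinite(x):
            continue
        if x < low_threshold:
            armed = True
        elif x > high_threshold and armed:
            count += 1
            armed = False
    return count


def classify_outcome(events: EventSet) -> str:
    """Outcome from a scored event set: ``complete`` iff release followed an
    unwinding onset, ``incomplete`` iff onset without release, else
    ``no_activity``."""
    if events.t_init is None:
        return NO_ACTIVITY
    return COMPLETE if events.t_unw is not None else INCOMPLETE


def analyze_trace(trace: FretTrace,
                  background: Optional[Tuple[float, float]] = None,
                  config: DetectionConfig = DetectionConfig()) -> EventSet:
    """Score one trace end to end: FRET, release, onset, stalls, slips.

    ``background`` defaults to the per-channel value recorded in the
    trace metadata.  Frames after strand release are excluded from
    stall and slippage scoring.
    """
    if background is None:
        b = trace.meta.get("background", 0.0)
        background = (float(b), float(b))
    E = compute_fret(trace, background)
    if not np.any(np.isfinite(E[trace.injection_frame:])):
        # all-background trace: no molecule signal at all
        return EventSet(t_init=None, t_unw=None, stalls=[], slip_count=0,
                        outcome=NO_ACTIVITY)
    release = detect_release(trace, background, config)

    t_init, t_unw, outcome = detect_initiation_and_unwinding(
        E, trace.injection_frame, trace.frame_interval, config,
        release_frame=release,
    )

    if outcome == NO_ACTIVITY:
        return EventSet(t_init=None, t_unw=None, stalls=[], slip_count=0,
                        outcome=NO_ACTIVITY)

    stop = release if release is not None else len(E)
    E_active = E[trace.injection_frame:stop]
    pre = E[:trace.injection_frame]
    pre = pre[np.isfinite(pre)]
    high = float(np.mean(pre)) if len(pre) >= 5 else config.fallback_high

    stalls = detect_stalls(E_active, trace.frame_interval,
                           tolerance=config.stall_tolerance,
                           min_run=config.stall_min_run,
                           config=config, high_level=high)
    stalls = [StallEvent(s.start_frame + trace.injection_frame,
                         s.end_frame + trace.injection_frame,
                         s.level, s.lifetime) for s in stalls]
    slips = count_slippage(E_active, trace.frame_interval,
                           box_window=config.slip_box,
                           low_threshold=config.slip_low,
                           high_threshold=config.slip_high)
    return EventSet(t_init=t_init, t_unw=t_unw, stalls=stalls,
                    slip_count=slips, outcome=outcome)
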