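"""Swim-bout detection, per-bout kinematics, and trajectory segmentation.

Bouts are detected as local maxima of supra-threshold excursions of the
instantaneous speed, where the threshold is a multiple (default 2) of a
dispersion statistic (default standard deviation) of the stream's speed.
Candidates within 0.4 s after an accepted bout are rejected, as are
candidates whose net displacement in a +-0.5 s window falls outside
[0.3, 18] mm. Bout onset is 80 ms before the velocity peak.

Wall-to-wall streams are turned into trajectories only if they last at
least 25 s, contain at least 10 bouts, and include all three bout types
(left turn, right turn, forward).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from . import bout_classification as bc
from . import orientation_markov as om
from .tracking_io import FrameStream

__all__ = [
    "BoutEvent",
    "Trajectory",
    "DetectionParams",
    "TrajectoryFilters",
    "compute_speed",
    "detect_bouts",
    "compute_bout_params",
    "correct_turn_displacement",
    "segment_trajectories",
    "process_streams",
    "bouts_to_dataframe",
]

TURN_DISPLACEMENT_FACTOR = 0.625  # = 1/1.6, turn-bout geometric overshoot


@dataclass(frozen=True)
class DetectionParams:
    """Thresholds of the bout detector; defaults follow the analysis
    conventions described in the module docstring."""

    smooth_window: int = 3  # frames of centered position smoothing (0 = off)
    threshold_mult: float = 2.0
    threshold_stat: str = "std"  # "std" (dimensionally consistent) or "var"
    refractory_s: float = 0.4
    disp_window_s: float = 0.5  # half-width of displacement check window
    min_window_disp: float = 0.3  # mm
    max_window_disp: float = 18.0  # mm
    onset_offset_s: float = 0.080  # onset = peak - 80 ms
    settle_offset_s: float = 0.4  # heading-after window starts here
    settle_frames: int = 2  # frames averaged before/after a bout


@dataclass(frozen=True)
class TrajectoryFilters:
    min_duration: float = 25.0  # s
    min_bouts: int = 10
    require_three_types: bool = True  # >=1 left, >=1 right, >=1 forward


@dataclass
class BoutEvent:
    """One swim bout and its three kinematic scalars."""

    onset_t: float  # s
    peak_t: float  # s
    x: float  # mm at onset
    y: float  # mm at onset
    delta_t: float  # s, interbout interval following the bout (nan for last)
    raw_displacement: float  # mm
    displacement: float  # mm, after turn correction
    delta_theta: float  # rad, signed; >0 left turn
    bout_class: str | None = None  # "forward" | "turn"


@dataclass
class Trajectory:
    """A filtered wall-to-wall bout sequence and its 5 summary parameters."""

    bouts: list[BoutEvent]
    duration: float  # s
    temperature_label: float | None = None
    animal_id: int | None = None
    summary: dict = field(default_factory=dict)


def compute_speed(stream: FrameStream, smooth_window: int = 3) -> np.ndarray:
    """Per-frame instantaneous speed in mm/s (length n_frames - 1).

    Positions are optionally smoothed by a centered moving average before
    finite differencing.
    """
    if len(stream) < 2:
        return np.empty(0)
    x, y = stream.x, stream.y
    if smooth_window and smooth_window > 1:
        x = uniform_filter1d(x, smooth_window, mode="nearest")
        y = uniform_filter1d(y, smooth_window, mode="nearest")
    fps = 1.0 / float(stream.t[1] - stream.t[0])
    return np.hypot(np.diff(x), np.diff(y)) * fps


def detect_bouts(
    speed: np.ndarray, stream: FrameStream, params: DetectionParams | None = None
) -> list[tuple[float, float]]:
    """Detect bouts; returns a list of (peak_t, onset_t) tuples."""
    params = params or DetectionParams()
    if speed.size == 0:
        return []
    if params.threshold_stat == "std":
        dispersion = float(np.std(speed))
    elif params.threshold_stat == "var":
        dispersion = float(np.var(speed))
    else:
        raise ValueError(f"unknown threshold_stat {params.threshold_stat!r}")
    threshold = params.threshold_mult * dispersion
    above = speed > threshold
    if not np.any(above):
        return []
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    stops = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate(([0], starts))
    if above[-1]:
        stops = np.concatenate((stops, [len(above)]))

    t = stream.t
    half_frame = float(t[1] - t[0]) / 2  # speed[i] spans [t_i, t_{i+1}]
    events: list[tuple[float, float]] = []
    last_onset = -np.inf
    for s0, s1 in zip(starts, stops):
        peak_idx = s0 + int(np.argmax(speed[s0:s1]))
        peak_t = float(t[peak_idx]) + half_frame
        onset_t = peak_t - params.onset_offset_s
        if onset_t - last_onset < params.refractory_s:
            continue
        # net displacement in a +-disp_window_s window around the onset
        i0 = int(np.searchsorted(t, onset_t - params.disp_window_s))
        i1 = min(int(np.searchsorted(t, onset_t + params.disp_window_s)), len(t) - 1)
        disp = float(np.hypot(stream.x[i1] - stream.x[i0], stream.y[i1] - stream.y[i0]))
        if not params.min_window_disp <= disp <= params.max_window_disp:
            continue
        events.append((peak_t, onset_t))
        last_onset = onset_t
    return events


def _heading_around(
    stream: FrameStream, onset_t: float, params: DetectionParams, next_onset: float
) -> tuple[float, float]:
    """Mean unwrapped heading just before the onset and after settling."""
    t = stream.t
    i_on = int(np.searchsorted(t, onset_t))
    pre0 = max(i_on - params.settle_frames, 0)
    pre = float(np.mean(stream.heading[pre0:max(i_on, pre0 + 1)]))
    t_post = min(onset_t + params.settle_offset_s, next_onset - 1e-9)
    j = int(np.searchsorted(t, t_post))
    j = min(j, len(t) - 1)
    post = float(np.mean(stream.heading[j : j + params.settle_frames]))
    return pre, post


def compute_bout_params(
    onsets: Sequence[tuple[float, float]],
    stream: FrameStream,
    params: DetectionParams | None = None,
) -> list[BoutEvent]:
    """Per-bout interbout interval, displacement and reorientation angle.

    The last bout has no following interval (delta_t = nan); its
    displacement is measured to the stream end.
    """
    params = params or DetectionParams()
    if len(onsets) < 2:
        return []
    t = stream.t
    events: list[BoutEvent] = []
    onset_times = [o for _, o in onsets]
    for n, (peak_t, onset_t) in enumerate(onsets):
        i0 = int(np.clip(np.searchsorted(t, onset_t), 0, len(t) - 1))
        if n + 1 < len(onsets):
            next_onset = onset_times[n + 1]
            delta_t = next_onset - onset_t
            i1 = int(np.clip(np.searchsorted(t, next_onset), 0, len(t) - 1))
        else:
            next_onset = float(t[-1])
            delta_t = np.nan
            i1 = len(t) - 1
        d_raw = float(np.hypot(stream.x[i1] - stream.x[i0], stream.y[i1] - stream.y[i0]))
        pre, post = _heading_around(stream, onset_t, params, next_onset)
        events.append(
            BoutEvent(
                onset_t=float(onset_t),
                peak_t=float(peak_t),
                x=float(stream.x[i0]),
                y=float(stream.y[i0]),
                delta_t=float(delta_t),
                raw_displacement=d_raw,
                displacement=d_raw,
                delta_theta=post - pre,
            )
        )
    return events


def correct_turn_displacement(
    bouts: list[BoutEvent], factor: float = TURN_DISPLACEMENT_FACTOR
) -> list[BoutEvent]:
    """Scale turn-bout displacements by ``factor``; forwards unchanged."""
    out = []
    for b in bouts:
        if b.bout_class is None:
            raise ValueError("bouts must be classified before displacement correction")
        scaled = b.raw_displacement * factor if b.bout_class == bc.TURN else b.raw_displacement
        out.append(replace(b, displacement=scaled))
    return out


def _summarize(bouts: list[BoutEvent]) -> dict:
    dts = np.array([b.delta_t for b in bouts])
    dts = dts[np.isfinite(dts)]
    classes = np.array([b.bout_class for b in bouts])
    angles = np.array([b.delta_theta for b in bouts])
    turn = classes == bc.TURN
    p_turn = float(np.mean(turn))
    seq = om.ternarize(angles, times=np.array([b.onset_t for b in bouts]))
    try:
        with warnings.catch_warnings():
            # sampling noise routinely clamps short-trajectory estimates
            warnings.simplefilter("ignore", UserWarning)
            p_flip = om.estimate_p_flip(seq, p_turn).p_flip
    except (om.DegenerateSignalError, ValueError):
        p_flip = np.nan
    mean_ibi = float(np.mean(dts)) if dts.size else np.nan
    return {
        "mean_ibi": mean_ibi,
        "mean_disp": float(np.mean([b.displacement for b in bouts])),
        "mean_abs_turn_angle": float(np.mean(np.abs(angles[turn]))) if turn.any() else np.nan,
        "p_turn": p_turn,
        "p_flip": p_flip,
        "k_flip": p_flip / mean_ibi if mean_ibi and np.isfinite(p_flip) else np.nan,
    }


def segment_trajectories(
    streams_with_bouts: Sequence[tuple[FrameStream, list[BoutEvent]]],
    filters: TrajectoryFilters | None = None,
    temperature_label: float | None = None,
) -> list[Trajectory]:
    """Apply the duration / bout-count / bout-type filters and summarize.

    Bouts must already be classified (and displacement-corrected if
    desired); each passing stream yields one :class:`Trajectory` whose
    ``summary`` holds the 5 per-trajectory parameters.
    """
    filters = filters or TrajectoryFilters()
    trajectories: list[Trajectory] = []
    for stream, bouts in streams_with_bouts:
        if any(b.bout_class is None for b in bouts):
            raise ValueError("bouts must be classified before segmentation")
        duration = stream.duration
        if duration < filters.min_duration or len(bouts) < filters.min_bouts:
            continue
        if filters.require_three_types:
            has_left = any(b.bout_class == bc.TURN and b.delta_theta > 0 for b in bouts)
            has_right = any(b.bout_class == bc.TURN and b.delta_theta < 0 for b in bouts)
            has_fwd = any(b.bout_class == bc.FORWARD for b in bouts)
            if not (has_left and has_right and has_fwd):
                continue
        trajectories.append(
            Trajectory(
                bouts=list(bouts),
                duration=duration,
                temperature_label=temperature_label,
                animal_id=stream.animal_id,
                summary=_summarize(bouts),
            )
        )
    return trajectories


def process_streams(
    streams: Sequence[FrameStream],
    detection: DetectionParams | None = None,
    filters: TrajectoryFilters | None = None,
    classification_threshold: float = bc.DEFAULT_THRESHOLD,
    turn_factor: float = TURN_DISPLACEMENT_FACTOR,
    temperature_label: float | None = None,
) -> list[Trajectory]:
    """Full per-stream pipeline: detect, measure, classify, correct, filter."""
    detection = detection or DetectionParams()
    pairs = []
    for stream in streams:
        speed = compute_speed(stream, detection.smooth_window)
        onsets = detect_bouts(speed, stream, detection)
        bouts = compute_bout_params(onsets, stream, detection)
        for b in bouts:
            b.bout_class = bc.classify_bout(b.delta_theta, classification_threshold)
        bouts = correct_turn_displacement(bouts, turn_factor)
        pairs.append((stream, bouts))
    return segment_trajectories(pairs, filters, temperature_label)


def bouts_to_dataframe(trajectories: Sequence[Trajectory]) -> pd.DataFrame:
    """One row per bout with its trajectory index and kinematic scalars."""
    rows = []
    for k, traj in enumerate(trajectories):
        for b in traj.bouts:
            rows.append(
                {
                    "trajectory": k,
                    "animal_id": traj.animal_id,
                    "temperature": traj.temperature_label,
                    "onset_t": b.onset_t,
                    "delta_t": b.delta_t,
                    "raw_displacement": b.raw_displacement,
                    "displacement": b.displacement,
                    "delta_theta": b.delta_theta,
                    "bout_class": b.bout_class,
                }
            )
    return pd.DataFrame(rows)
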