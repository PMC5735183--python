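"""Velocity-threshold saccade detection and per-saccade kinematics.

Saccades are parsed from the gaze speed signal with a single 100 deg/s
criterion: a saccade is a maximal run of samples whose (optionally smoothed)
speed exceeds the threshold.  Nearby runs are merged, very short runs are
discarded, and by default the onset and offset are refined outward to the
surrounding low-speed samples so that start/end positions (and hence
amplitude) reflect the full movement rather than only its suprathreshold
core.

Coordinate convention: direction 0 deg = rightward (contraversive to a
left-hemisphere array), counter-clockwise positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .errors import InvalidArgumentError
from .trace import EyeTrace

__all__ = [
    "compute_speed",
    "detect_saccades",
    "saccade_metrics",
    "SaccadeInterval",
    "SaccadeEvent",
    "DEFAULT_V_THRESHOLD",
]

logger = logging.getLogger(__name__)

#: Detection criterion (deg/s).
DEFAULT_V_THRESHOLD = 100.0
#: Runs separated by less than this gap are merged (ms).
DEFAULT_MERGE_GAP_MS = 10.0
#: Runs shorter than this are discarded as noise (ms).
DEFAULT_MIN_DURATION_MS = 6.0
#: Onset/offset refinement floor, as a fraction of the threshold.
DEFAULT_FLOOR_FRAC = 0.3
#: Maximum refinement walk, in ms, on each side of a run.
MAX_REFINE_MS = 20.0


def _speed_from_xy(
    x: np.ndarray, y: np.ndarray, dt_s: float, smooth_window_samples: int
) -> np.ndarray:
    """Speed (deg/s) from position arrays; trials along axis 0 if 2-D."""
    vx = np.gradient(x, dt_s, axis=-1)
    vy = np.gradient(y, dt_s, axis=-1)
    speed = np.hypot(vx, vy)
    if smooth_window_samples and smooth_window_samples > 1:
        speed = uniform_filter1d(
            speed, size=int(smooth_window_samples), axis=-1, mode="nearest"
        )
    return speed


def compute_speed(trace: EyeTrace, smooth_window_samples: int = 3) -> np.ndarray:
    """Gaze speed (deg/s) by central differences plus optional boxcar smoothing.

    Velocity components come from central differences on x and y (one-sided
    at the endpoints), speed is their Euclidean norm, and a centered boxcar
    of ``smooth_window_samples`` (default 3 samples = 6 ms at 500 Hz) is
    applied when the window exceeds one sample.  Wider windows reject more
    noise but attenuate the velocity peak of short saccades.
    """
    if trace.n_samples < 3:
        raise InvalidArgumentError("need at least 3 samples to compute speed")
    return _speed_from_xy(
        trace.x_deg, trace.y_deg, 1.0 / trace.sample_rate, smooth_window_samples
    )


@dataclass(frozen=True)
class SaccadeInterval:
    """A detected saccade interval, in samples and trial-relative ms.

    ``onset_idx``/``offset_idx`` index the first and last sample of the
    movement; ``offset_ms`` is one sample step past the last sample, so the
    interval covers ``[onset_ms, offset_ms)``.
    """

    onset_idx: int
    offset_idx: int
    onset_ms: float
    offset_ms: float

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


def _threshold_runs(above: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean array, as (first, last) index pairs."""
    if not above.any():
        return []
    padded = np.diff(np.concatenate(([0], above.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def _detect_from_speed(
    speed: np.ndarray,
    t_ms: np.ndarray,
    bad: np.ndarray,
    dt_ms: float,
    v_threshold: float,
    merge_gap_ms: float,
    min_duration_ms: float,
    refine_onset: bool,
    floor_frac: float,
) -> list[SaccadeInterval]:
    n = speed.size
    nan_speed = ~np.isfinite(speed)
    above = np.nan_to_num(speed, nan=0.0) > v_threshold
    runs = _threshold_runs(above)
    if not runs:
        return []

    # merge runs separated by less than the merge gap
    gap_samples = max(int(np.ceil(merge_gap_ms / dt_ms)) - 1, 0)
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] - 1 <= gap_samples:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    min_samples = max(int(np.ceil(min_duration_ms / dt_ms)), 1)
    floor = floor_frac * v_threshold
    max_walk = int(np.ceil(MAX_REFINE_MS / dt_ms))
    out: list[SaccadeInterval] = []
    for s, e in merged:
        if e - s + 1 < min_samples:
            continue
        if (
            bad[max(s - 2, 0): min(e + 3, n)].any()
            or nan_speed[max(s - 1, 0): min(e + 2, n)].any()
        ):
            logger.info(
                "saccade candidate at %.1f-%.1f ms touches missing samples; "
                "excluded", t_ms[s], t_ms[e]
            )
            continue
        i0, i1 = s, e
        if refine_onset:
            j = i0
            while j > 0 and i0 - j < max_walk and not bad[j - 1] and speed[j - 1] >= floor:
                j -= 1
            # include the first sub-floor sample: the eye is at rest there
            if j > 0 and not bad[j - 1]:
                j -= 1
            i0 = j
            k = i1
            while (
                k < n - 1
                and k - i1 < max_walk
                and not bad[k + 1]
                and speed[k + 1] >= floor
            ):
                k += 1
            if k < n - 1 and not bad[k + 1]:
                k += 1
            i1 = k
        if out and i0 <= out[-1].offset_idx:  # keep intervals disjoint
            i0 = out[-1].offset_idx + 1
            if i0 > i1:
                continue
        out.append(
            SaccadeInterval(
                onset_idx=int(i0),
                offset_idx=int(i1),
                onset_ms=float(t_ms[i0]),
                offset_ms=float(t_ms[i1] + dt_ms),
            )
        )
    return out


def detect_saccades(
    trace: EyeTrace,
    v_threshold: float = DEFAULT_V_THRESHOLD,
    smooth_window_samples: int = 3,
    merge_gap_ms: float = DEFAULT_MERGE_GAP_MS,
    min_duration_ms: float = DEFAULT_MIN_DURATION_MS,
    refine_onset: bool = True,
    floor_frac: float = DEFAULT_FLOOR_FRAC,
    speed: np.ndarray | None = None,
) -> list[SaccadeInterval]:
    """Detect saccades as suprathreshold runs of the speed signal.

    A maximal run of samples with speed > ``v_threshold`` marks a saccade;
    runs separated by less than ``merge_gap_ms`` are merged and runs shorter
    than ``min_duration_ms`` are discarded.  With ``refine_onset`` (default)
    each run is extended outward while speed stays above
    ``floor_frac * v_threshold``, which places onset and offset at the actual
    start and landing of the movement instead of at the threshold crossings.
    Candidate runs touching missing (NaN) samples are excluded with a logged
    reason.  Returned intervals are disjoint and time-ordered.
    """
    if speed is None:
        speed = compute_speed(trace, smooth_window_samples)
    bad = ~(np.isfinite(trace.x_deg) & np.isfinite(trace.y_deg))
    return _detect_from_speed(
        speed,
        trace.t_ms,
        bad,
        trace.dt_ms,
        v_threshold,
        merge_gap_ms,
        min_duration_ms,
        refine_onset,
        floor_frac,
    )


@dataclass
class SaccadeEvent:
    """A parsed saccade with its kinematic metrics.

    ``latency_ms`` is onset minus the fixation-point jump time (negative for
    pre-jump movements); ``direction_deg`` is the polar angle of the
    start-to-end displacement with 0 deg = rightward, CCW positive, in
    [0, 360); ``endpoint_error_deg`` is the Euclidean distance from the
    saccade endpoint to the target (NaN when no target is given).
    """

    onset_ms: float
    offset_ms: float
    latency_ms: float
    duration_ms: float
    start_xy: tuple[float, float]
    end_xy: tuple[float, float]
    amplitude_deg: float
    direction_deg: float
    peak_velocity_deg_s: float
    endpoint_error_deg: float


def _endpoint_positions(
    x: np.ndarray, y: np.ndarray, i0: int, i1: int, avg: int = 3
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Start/end gaze positions, averaged over up to ``avg`` samples just
    outside the movement (the eye is at rest there) to suppress sample noise."""
    lo = max(i0 - avg + 1, 0)
    hi = min(i1 + avg, len(x))
    start = (float(np.nanmean(x[lo: i0 + 1])), float(np.nanmean(y[lo: i0 + 1])))
    end = (float(np.nanmean(x[i1: hi])), float(np.nanmean(y[i1: hi])))
    return start, end


def saccade_metrics(
    trace: EyeTrace,
    interval: SaccadeInterval,
    jump_time_ms: float,
    target_xy=None,
    speed: np.ndarray | None = None,
    smooth_window_samples: int = 3,
) -> SaccadeEvent:
    """Kinematic metrics of one detected saccade.

    Peak velocity is the maximum of the speed signal inside the interval;
    amplitude is the Euclidean distance between the start and end positions
    (each averaged over a few resting samples around the interval edges).
    """
    if interval.offset_idx < interval.onset_idx or interval.offset_ms <= interval.onset_ms:
        raise InvalidArgumentError("degenerate interval: offset must follow onset")
    if speed is None:
        speed = compute_speed(trace, smooth_window_samples)
    i0, i1 = interval.onset_idx, interval.offset_idx
    start, end = _endpoint_positions(trace.x_deg, trace.y_deg, i0, i1)
    dx, dy = end[0] - start[0], end[1] - start[1]
    amplitude = float(np.hypot(dx, dy))
    direction = float(np.rad2deg(np.arctan2(dy, dx)) % 360.0)
    peak_v = float(np.nanmax(speed[i0: i1 + 1]))
    if target_xy is None:
        err = float("nan")
    else:
        err = float(np.hypot(end[0] - target_xy[0], end[1] - target_xy[1]))
    return SaccadeEvent(
        onset_ms=interval.onset_ms,
        offset_ms=interval.offset_ms,
        latency_ms=interval.onset_ms - jump_time_ms,
        duration_ms=interval.duration_ms,
        start_xy=start,
        end_xy=end,
        amplitude_deg=amplitude,
        direction_deg=direction,
        peak_velocity_deg_s=peak_v,
        endpoint_error_deg=err,
    )
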