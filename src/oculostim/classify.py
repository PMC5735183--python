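"""Saccade taxonomy, electrode inclusion/exclusion, endpoint ellipses.

Detected saccades fall into three classes relative to the fixation-point
jump (stimulation, when delivered, is concurrent with the jump):

* **evoked** — onset within [0, 100) ms of stimulation onset and duration
  no longer than 75 ms: a movement triggered directly by the current.
* **task** — onset within [100, 400] ms and duration under 75 ms: the
  voluntary saccade to the jumped target.
* **other** — everything else (anticipations, late or long movements).

The evoked window is right-open and the task window left-closed so the two
classes are disjoint and, together with "other", partition all saccades.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .detect import SaccadeEvent
from .errors import DegenerateInputError, InvalidArgumentError

__all__ = [
    "LABEL_EVOKED",
    "LABEL_TASK",
    "LABEL_OTHER",
    "classify_saccade",
    "classify_latency_duration",
    "evoked_inclusion",
    "EvokedSummary",
    "endpoint_ellipse",
    "flag_excluded_electrodes",
]

LABEL_EVOKED = "evoked"
LABEL_TASK = "task"
LABEL_OTHER = "other"

#: Evoked-saccade onset window relative to stimulation onset, [lo, hi) ms.
EVOKED_WINDOW_MS = (0.0, 100.0)
#: Task-saccade onset window relative to the jump, [lo, hi] ms.
TASK_WINDOW_MS = (100.0, 400.0)
#: Maximum saccade duration (ms); evoked uses <=, task uses strict <.
MAX_DURATION_MS = 75.0

#: Minimum proportion of stimulation trials with an evoked saccade for an
#: electrode to count as saccade-evoking (3 of 10 at the standard block size).
EVOKED_INCLUSION_PROPORTION = 0.3
EVOKED_INCLUSION_MIN_TRIALS = 10


def classify_latency_duration(latency_ms: float, duration_ms: float) -> str:
    """Class label from onset latency and duration alone (total function)."""
    if EVOKED_WINDOW_MS[0] <= latency_ms < EVOKED_WINDOW_MS[1] and duration_ms <= MAX_DURATION_MS:
        return LABEL_EVOKED
    if TASK_WINDOW_MS[0] <= latency_ms <= TASK_WINDOW_MS[1] and duration_ms < MAX_DURATION_MS:
        return LABEL_TASK
    return LABEL_OTHER


def classify_saccade(event: SaccadeEvent, reference_onset_ms: float | None = None) -> str:
    """Assign a detected saccade to the evoked / task / other taxonomy.

    ``reference_onset_ms`` is the stimulation (= jump) onset in trial time;
    when omitted, the event's stored latency (already jump-relative) is used.
    """
    if reference_onset_ms is None:
        latency = event.latency_ms
    else:
        latency = event.onset_ms - reference_onset_ms
    return classify_latency_duration(latency, event.duration_ms)


def evoked_inclusion(n_evoked: int, n_stim_trials: int) -> bool:
    """Whether an electrode counts as saccade-evoking.

    True iff evoked saccades occurred on at least 30% of stimulation trials
    and at least 10 stimulation trials were run — i.e. "3 out of 10" at the
    standard block size, generalized proportionally.
    """
    if n_stim_trials < 1:
        raise InvalidArgumentError("n_stim_trials must be >= 1")
    if n_evoked < 0 or n_evoked > n_stim_trials:
        raise InvalidArgumentError("need 0 <= n_evoked <= n_stim_trials")
    return (
        n_stim_trials >= EVOKED_INCLUSION_MIN_TRIALS
        and n_evoked / n_stim_trials >= EVOKED_INCLUSION_PROPORTION
    )


@dataclass
class EvokedSummary:
    """Per-electrode, per-current summary of directly evoked saccades."""

    electrode_id: int
    current_uA: int
    n_stim_trials: int
    n_evoked: int
    included: bool
    mean_direction_deg: float
    mean_amplitude_deg: float
    ellipse: tuple | None  # (center_xy, semi_axes_deg, orientation_deg)


def endpoint_ellipse(points_xy, level: float = 0.95):
    """Confidence ellipse of a bivariate-normal fit to 2-D points.

    Center is the sample mean; axes are the eigenvectors of the sample
    covariance; the semi-axis lengths are ``sqrt(chi2_2(level) * eigenvalue)``
    so that, under normality, the ellipse covers ``level`` of the mass.

    Returns
    -------
    (center, semi_axes, orientation_deg) — semi-axes in descending order,
    orientation is the polar angle of the major axis in [0, 180).
    """
    pts = np.asarray(points_xy, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidArgumentError("points_xy must have shape (n, 2)")
    if not 0 < level < 1:
        raise InvalidArgumentError("level must be in (0, 1)")
    n = pts.shape[0]
    if n < 3:
        raise DegenerateInputError("need at least 3 points for an ellipse")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    scale = max(np.abs(evals).max(), 1.0)
    if evals.min() <= 1e-12 * scale:
        raise DegenerateInputError("singular covariance: points are (near) collinear")
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    q = chi2.ppf(level, df=2)
    semi_axes = np.sqrt(q * evals)
    orientation = float(np.rad2deg(np.arctan2(evecs[1, 0], evecs[0, 0])) % 180.0)
    return center, semi_axes, orientation


def flag_excluded_electrodes(
    evoked_summaries: pd.DataFrame, electrode_map: pd.DataFrame
) -> pd.DataFrame:
    """Electrodes to drop from all behavioral (latency/kinematics/spatial)
    analyses, with reasons.

    An electrode is excluded when it is saccade-evoking (inclusion criterion
    met) at the highest stimulation current, or when its hardware status is
    not ``ok``.

    Parameters
    ----------
    evoked_summaries : DataFrame with columns electrode_id, current_uA,
        n_stim_trials, n_evoked, included (as produced by the pipeline).
    electrode_map : DataFrame with columns electrode_id, status.

    Returns
    -------
    DataFrame with columns ``electrode_id`` and ``reason``.
    """
    records = []
    if len(evoked_summaries):
        top = int(evoked_summaries["current_uA"].max())
        at_top = evoked_summaries[evoked_summaries["current_uA"] == top]
        for eid in sorted(at_top.loc[at_top["included"], "electrode_id"].unique()):
            records.append((int(eid), "evokes-saccades"))
    flagged = {eid for eid, _ in records}
    bad = electrode_map[electrode_map["status"] != "ok"]
    for eid in sorted(bad["electrode_id"].unique()):
        if int(eid) not in flagged:
            records.append((int(eid), "broken"))
    return pd.DataFrame(records, columns=["electrode_id", "reason"])
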