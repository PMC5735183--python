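"""Synthetic eye-trace generator for the stimulated center-out saccade task.

Each trial holds fixation at the screen center for the fixation epoch, after
which the fixation point jumps 7 degrees left or right and the eye follows
with an ex-Gaussian-latency task saccade.  On stimulation trials delivered
through a saccade-evoking electrode, a short-latency evoked saccade toward
the electrode's preferred vector may precede the task saccade.  Saccade
trajectories follow a raised-cosine velocity profile whose duration obeys a
linear main-sequence law, and isotropic Gaussian noise is added to every
sample.  The generator records complete ground truth so detection and
effect-estimation stages can be scored against the injected values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .config import SimConfig
from .errors import InvalidArgumentError
from .trace import EyeTrace

__all__ = [
    "main_sequence_params",
    "synth_saccade_segment",
    "TrialSpec",
    "SessionData",
    "electrode_map_frame",
    "simulate_trial",
    "simulate_session",
]

#: Minimum quiet gap (ms) enforced between the end of an evoked saccade and
#: the onset of the subsequent task saccade, so the two stay separable.
MIN_INTERSACCADE_GAP_MS = 12.0


def main_sequence_params(
    amplitude_deg: float,
    d0_ms: float = 21.0,
    d1_ms_per_deg: float = 2.2,
) -> tuple[float, float]:
    """Main-sequence duration and peak velocity for a saccade of a given size.

    Duration grows linearly with amplitude, ``D = d0 + d1 * A`` (ms), and the
    raised-cosine velocity profile used throughout the simulator then peaks at
    ``2 A / D``.  Both quantities are strictly increasing in amplitude.

    Returns
    -------
    (duration_ms, peak_velocity_deg_s)
    """
    amplitude_deg = float(amplitude_deg)
    if amplitude_deg <= 0:
        raise InvalidArgumentError("amplitude_deg must be positive")
    duration_ms = d0_ms + d1_ms_per_deg * amplitude_deg
    peak_velocity_deg_s = 2.0 * amplitude_deg / (duration_ms / 1000.0)
    return duration_ms, peak_velocity_deg_s


def _profile(phase: np.ndarray) -> np.ndarray:
    """Normalized raised-cosine displacement profile on [0, 1].

    ``sigma(p) = p - sin(2 pi p) / (2 pi)``; its derivative
    ``1 - cos(2 pi p)`` peaks at mid-flight with value 2, giving the
    ``2 A / D`` peak velocity.  The sine is only evaluated inside the
    in-flight window; outside, the profile is exactly 0 or 1.
    """
    phase = np.asarray(phase)
    if not np.issubdtype(phase.dtype, np.floating):
        phase = phase.astype(float)
    out = np.zeros_like(phase)
    out[phase >= 1.0] = 1.0
    m = (phase > 0.0) & (phase < 1.0)
    pm = phase[m]
    out[m] = pm - np.sin(2.0 * np.pi * pm) / (2.0 * np.pi)
    return out


def synth_saccade_segment(
    start_xy,
    end_xy,
    onset_ms: float,
    sample_rate: float,
    d0_ms: float = 21.0,
    d1_ms_per_deg: float = 2.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample one noiseless saccade from ``start_xy`` to ``end_xy``.

    The eye moves along the straight line between the endpoints with
    displacement ``s(t) = A * (t/D - sin(2 pi t / D) / (2 pi))``, so the
    segment starts and ends at rest and instantaneous speed peaks at
    ``2 A / D`` at mid-flight.

    Returns
    -------
    (t_ms, xy) where ``t_ms`` covers ``[onset, onset + duration]`` on the
    sample grid and ``xy`` has shape ``(len(t_ms), 2)``.
    """
    start = np.asarray(start_xy, dtype=float)
    end = np.asarray(end_xy, dtype=float)
    amp = float(np.hypot(*(end - start)))
    if amp == 0.0:
        raise InvalidArgumentError("zero-length saccade: start equals end")
    duration_ms, _ = main_sequence_params(amp, d0_ms, d1_ms_per_deg)
    dt = 1000.0 / sample_rate
    n = int(np.floor(duration_ms / dt)) + 1
    t = onset_ms + np.arange(n + 1) * dt
    t = t[t <= onset_ms + duration_ms + 1e-9]
    if t[-1] < onset_ms + duration_ms - 1e-9:  # ensure the landing sample
        t = np.append(t, onset_ms + duration_ms)
    sigma = _profile((t - onset_ms) / duration_ms)
    xy = start[None, :] + (end - start)[None, :] * sigma[:, None]
    return t, xy


@dataclass(frozen=True)
class TrialSpec:
    """Task/stimulation condition of a single trial to simulate."""

    jump_dir: str                # "contra" (rightward) or "ipsi" (leftward)
    stim: bool
    electrode_id: int
    current_uA: int


@dataclass
class SessionData:
    """A simulated (or loaded) session: traces, metadata and ground truth.

    Traces are stored packed, one row per trial on a shared time grid; use
    :meth:`trace` or :meth:`iter_traces` for per-trial :class:`EyeTrace`
    views.  ``ground_truth`` is ``None`` for sessions loaded from recorded
    files.
    """

    config: Optional[SimConfig]
    t_ms: np.ndarray                     # (n_samples,)
    x: np.ndarray                        # (n_trials, n_samples)
    y: np.ndarray
    trials: pd.DataFrame
    electrode_map: pd.DataFrame
    ground_truth: Optional[pd.DataFrame]
    sample_rate: float

    def trace(self, trial_id: int) -> EyeTrace:
        idx = self._row_of(trial_id)
        return EyeTrace(
            self.t_ms, self.x[idx], self.y[idx], self.sample_rate, trial_id
        )

    def _row_of(self, trial_id: int) -> int:
        ids = self.trials["trial_id"].to_numpy()
        rows = np.flatnonzero(ids == trial_id)
        if rows.size != 1:
            raise InvalidArgumentError(f"unknown trial_id {trial_id}")
        return int(rows[0])

    def iter_traces(self) -> Iterator[EyeTrace]:
        ids = self.trials["trial_id"].to_numpy()
        for i, tid in enumerate(ids):
            yield EyeTrace(self.t_ms, self.x[i], self.y[i], self.sample_rate, int(tid))

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def electrode_map_frame(config: SimConfig) -> pd.DataFrame:
    """Electrode grid table with the rostral/caudal split.

    Electrode ids are row-major on a ``(rows, cols)`` grid whose row axis is
    the rostro-caudal axis; the caudal half (higher rows, nearer the frontal
    eye fields) and rostral half are equal-sized.
    """
    n_rows, n_cols = config.grid_shape
    ids = np.arange(config.n_electrodes)
    rows = ids // n_cols
    cols = ids % n_cols
    group = np.where(rows >= n_rows // 2, "caudal", "rostral")
    status = np.where(np.isin(ids, config.broken_electrodes), "broken", "ok")
    return pd.DataFrame(
        {
            "electrode_id": ids,
            "row": rows,
            "col": cols,
            "group": group,
            "status": status,
        }
    )


def _balanced_block(
    n_trials: int, stim_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Stim flags and jump directions for one block, shuffled.

    Exactly ``n_trials * stim_fraction`` trials are stimulated, and left/right
    jumps are balanced (within one trial) inside both the stimulated and the
    control subsets, mimicking pseudo-random interleaving.
    """
    n_stim = int(round(n_trials * stim_fraction))
    stim = np.zeros(n_trials, dtype=bool)
    stim[:n_stim] = True
    dirs = np.empty(n_trials, dtype=object)
    for subset in (np.flatnonzero(stim), np.flatnonzero(~stim)):
        k = subset.size
        half = k // 2
        d = np.array(["contra"] * half + ["ipsi"] * (k - half), dtype=object)
        if k % 2 == 1 and rng.random() < 0.5:
            d[half] = "contra"
            d[0] = "ipsi"
        dirs[subset] = d
    order = rng.permutation(n_trials)
    return stim[order], dirs[order]


def _build_trial_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """One block of ``trials_per_block`` trials per electrode x current."""
    emap = electrode_map_frame(config)
    group_of = dict(zip(emap["electrode_id"], emap["group"]))
    records = []
    block_id = 0
    trial_id = 0
    for electrode in range(config.n_electrodes):
        for current in config.currents_uA:
            stim, dirs = _balanced_block(
                config.trials_per_block, config.stim_fraction, rng
            )
            for s, d in zip(stim, dirs):
                records.append(
                    (
                        trial_id,
                        block_id,
                        electrode,
                        group_of[electrode],
                        int(current),
                        bool(s),
                        d,
                        config.fixation_ms,
                        "correct",
                    )
                )
                trial_id += 1
            block_id += 1
    return pd.DataFrame.from_records(
        records,
        columns=[
            "trial_id",
            "block_id",
            "electrode_id",
            "group",
            "current_uA",
            "stim",
            "jump_dir",
            "jump_time_ms",
            "outcome",
        ],
    )


def _simulate_from_table(
    config: SimConfig, trials: pd.DataFrame, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.DataFrame]:
    """Generate packed traces and ground truth for a prepared trial table.

    All random draws are made as whole arrays in a fixed order, so a given
    (config, table, seed) yields bit-identical output.
    """
    n = len(trials)
    dt = config.dt_ms
    n_samples = int(round((config.fixation_ms + config.post_jump_ms) / dt))
    t = np.arange(n_samples) * dt
    jump_t = trials["jump_time_ms"].to_numpy(dtype=float)

    contra = (trials["jump_dir"] == "contra").to_numpy()
    stim = trials["stim"].to_numpy(dtype=bool)
    current = trials["current_uA"].to_numpy()
    group = trials["group"].to_numpy()

    # --- task-saccade latency: ex-Gaussian + configured stimulation shift
    mu = np.where(
        contra, config.latency_mu_contra_ms, config.latency_mu_ipsi_ms
    ).astype(float)
    shift = np.zeros(n)
    for i in np.flatnonzero(stim):
        shift[i] = config.require_effect(
            group[i], int(current[i]), "contra" if contra[i] else "ipsi"
        )
    z = rng.standard_normal(n)
    expo = rng.exponential(1.0, n) * config.latency_tau_ms
    latency = mu + shift + config.latency_sigma_ms * z + expo
    latency = np.maximum(latency, 25.0)  # physiological floor

    # --- evoked saccades (stimulation trials on evoking electrodes)
    ev_by_id = {el.electrode_id: el for el in config.evoking_electrodes}
    prob = np.zeros(n)
    pref_dir = np.zeros(n)
    kappa = np.ones(n)
    amp_mean = np.ones(n)
    amp_sd = np.ones(n)
    eids = trials["electrode_id"].to_numpy()
    for i in np.flatnonzero(stim):
        el = ev_by_id.get(int(eids[i]))
        if el is not None:
            c = int(current[i])
            prob[i] = el.prob_by_current[c]
            pref_dir[i] = np.deg2rad(el.preferred_direction_deg)
            kappa[i] = el.direction_kappa
            amp_mean[i] = el.amplitude_mean_by_current[c]
            amp_sd[i] = el.amplitude_sd_deg
    u = rng.random(n)
    lo, hi = config.evoked_onset_window_ms
    ev_onset = rng.uniform(lo, hi, n)
    ev_dir = rng.vonmises(pref_dir, kappa)
    ev_amp = np.maximum(rng.normal(amp_mean, amp_sd), 0.5)
    evoked = u < prob

    ev_dur = config.saccade_d0_ms + config.saccade_d1_ms_per_deg * ev_amp
    ev_end_x = np.where(evoked, ev_amp * np.cos(ev_dir), 0.0)
    ev_end_y = np.where(evoked, ev_amp * np.sin(ev_dir), 0.0)

    # task saccade must start after the evoked one has landed
    min_task = np.where(evoked, ev_onset + ev_dur + MIN_INTERSACCADE_GAP_MS, 0.0)
    latency = np.maximum(latency, min_task)

    # --- geometry: fixation -> (evoked endpoint) -> target
    target_x = np.where(contra, config.jump_amplitude_deg, -config.jump_amplitude_deg)
    task_dx = target_x - ev_end_x
    task_dy = -ev_end_y
    task_amp = np.hypot(task_dx, task_dy)
    task_dur = config.saccade_d0_ms + config.saccade_d1_ms_per_deg * task_amp

    # --- assemble traces (vectorized over trials; single precision is ample
    # for gaze positions with >= 0.01 deg effective resolution)
    t32 = t.astype(np.float32)
    abs_task_onset = (jump_t + latency).astype(np.float32)
    phase2 = (t32[None, :] - abs_task_onset[:, None]) / task_dur.astype(np.float32)[:, None]
    sig2 = _profile(phase2)
    x = task_dx.astype(np.float32)[:, None] * sig2
    y = task_dy.astype(np.float32)[:, None] * sig2
    if evoked.any():
        abs_ev_onset = (jump_t + ev_onset).astype(np.float32)
        phase1 = (t32[None, :] - abs_ev_onset[:, None]) / ev_dur.astype(np.float32)[:, None]
        sig1 = _profile(phase1)
        sig1[~evoked] = 0.0
        x += ev_end_x.astype(np.float32)[:, None] * sig1
        y += ev_end_y.astype(np.float32)[:, None] * sig1
    if config.noise_sd_deg > 0:
        sd = np.float32(config.noise_sd_deg)
        x += sd * rng.standard_normal((n, n_samples), dtype=np.float32)
        y += sd * rng.standard_normal((n, n_samples), dtype=np.float32)

    gt = pd.DataFrame(
        {
            "trial_id": trials["trial_id"].to_numpy(),
            "true_task_latency_ms": latency,
            "true_task_amplitude_deg": task_amp,
            "true_task_direction_deg": np.rad2deg(np.arctan2(task_dy, task_dx)) % 360.0,
            "evoked_present": evoked,
            "evoked_onset_ms": np.where(evoked, ev_onset, np.nan),
            "evoked_direction_deg": np.where(
                evoked, np.rad2deg(ev_dir) % 360.0, np.nan
            ),
            "evoked_amplitude_deg": np.where(evoked, ev_amp, np.nan),
        }
    )
    return t, x, y, gt


def simulate_trial(
    config: SimConfig, trial_spec: TrialSpec, rng: np.random.Generator
) -> tuple[EyeTrace, pd.Series, pd.Series]:
    """Simulate a single trial.

    Returns the eye trace, the trial metadata row and the ground-truth row.
    """
    if trial_spec.jump_dir not in ("contra", "ipsi"):
        raise InvalidArgumentError("jump_dir must be 'contra' or 'ipsi'")
    emap = electrode_map_frame(config)
    group = emap.loc[
        emap["electrode_id"] == trial_spec.electrode_id, "group"
    ]
    if group.empty:
        raise InvalidArgumentError(
            f"electrode_id {trial_spec.electrode_id} outside the grid"
        )
    trials = pd.DataFrame(
        {
            "trial_id": [0],
            "block_id": [0],
            "electrode_id": [trial_spec.electrode_id],
            "group": [group.iloc[0]],
            "current_uA": [int(trial_spec.current_uA)],
            "stim": [bool(trial_spec.stim)],
            "jump_dir": [trial_spec.jump_dir],
            "jump_time_ms": [config.fixation_ms],
            "outcome": ["correct"],
        }
    )
    t, x, y, gt = _simulate_from_table(config, trials, rng)
    trace = EyeTrace(t, x[0], y[0], config.sample_rate, trial_id=0)
    return trace, trials.iloc[0], gt.iloc[0]


def simulate_session(
    config: SimConfig, seed: int | None = None
) -> SessionData:
    """Simulate a full session: one block per electrode x current.

    Within every block exactly ``stim_fraction`` of the trials are stimulated
    and left/right jumps are balanced within one trial; the electrode map
    splits the grid into equal rostral and caudal halves.  Identical
    (config, seed) yields bit-identical data.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    trials = _build_trial_table(config, rng)
    t, x, y, gt = _simulate_from_table(config, trials, rng)
    return SessionData(
        config=config,
        t_ms=t,
        x=x,
        y=y,
        trials=trials,
        electrode_map=electrode_map_frame(config),
        ground_truth=gt,
        sample_rate=config.sample_rate,
    )
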