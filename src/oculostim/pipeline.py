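"""End-to-end analyses: detection, classification, and the four Results
sections (evoked mapping, latency effects, spatial organization,
kinematics), plus report serialization.

The pipeline consumes a :class:`~oculostim.simulate.SessionData` (simulated
or loaded from CSV), parses every trace into saccades, classifies them,
derives electrode exclusions, and then estimates stimulation effects per
direction and current, per rostral/caudal electrode group, and on saccade
kinematics.  Every analysis reports its tests with method tags and sample
sizes, and a filter ledger accounts for every trial.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    LABEL_EVOKED,
    LABEL_TASK,
    classify_latency_duration,
    endpoint_ellipse,
    evoked_inclusion,
    flag_excluded_electrodes,
)
from .config import SimConfig
from .detect import (
    DEFAULT_FLOOR_FRAC,
    DEFAULT_MERGE_GAP_MS,
    DEFAULT_MIN_DURATION_MS,
    DEFAULT_V_THRESHOLD,
    _detect_from_speed,
    _endpoint_positions,
    _speed_from_xy,
)
from .errors import DegenerateInputError, InvalidArgumentError
from .simulate import SessionData, simulate_session
from .stats import (
    bonferroni_alpha,
    circ_descriptives,
    fisher_exact,
    hk_circ_anova,
    latency_test,
    twoway_linear_anova,
)

__all__ = [
    "build_saccade_table",
    "run_evoked_analysis",
    "run_latency_analysis",
    "run_spatial_analysis",
    "run_kinematics_analysis",
    "run_full",
    "report_to_json",
]

SPATIAL_ALPHA = 0.05  # family level for the four group x direction tests
KINEMATIC_MEASURES = ("peak_velocity_deg_s", "amplitude_deg", "endpoint_error_deg")


# ---------------------------------------------------------------------------
# detection + classification over a session
# ---------------------------------------------------------------------------

def build_saccade_table(
    session: SessionData,
    v_threshold: float = DEFAULT_V_THRESHOLD,
    smooth_window_samples: int = 3,
    merge_gap_ms: float = DEFAULT_MERGE_GAP_MS,
    min_duration_ms: float = DEFAULT_MIN_DURATION_MS,
    refine_onset: bool = True,
    floor_frac: float = DEFAULT_FLOOR_FRAC,
) -> pd.DataFrame:
    """Detect and classify every saccade of a session.

    Returns one row per detected saccade with kinematic metrics, the
    evoked/task/other label, and an ``is_first_task`` flag marking the first
    task-classified saccade of each trial (the one entering latency
    analyses).
    """
    dt_ms = 1000.0 / session.sample_rate
    speed = _speed_from_xy(
        session.x, session.y, dt_ms / 1000.0, smooth_window_samples
    )
    bad = ~(np.isfinite(session.x) & np.isfinite(session.y))
    t = session.t_ms
    trials = session.trials
    jump = trials["jump_time_ms"].to_numpy(dtype=float)
    contra = (trials["jump_dir"] == "contra").to_numpy()
    amp = (
        session.config.jump_amplitude_deg
        if session.config is not None
        else 7.0
    )
    target_x = np.where(contra, amp, -amp)
    ids = trials["trial_id"].to_numpy()

    rows = []
    for i in range(len(trials)):
        intervals = _detect_from_speed(
            speed[i], t, bad[i], dt_ms, v_threshold, merge_gap_ms,
            min_duration_ms, refine_onset, floor_frac,
        )
        for iv in intervals:
            i0, i1 = iv.onset_idx, iv.offset_idx
            (sx, sy), (ex, ey) = _endpoint_positions(
                session.x[i], session.y[i], i0, i1
            )
            dx, dy = ex - sx, ey - sy
            amplitude = float(np.hypot(dx, dy))
            latency = iv.onset_ms - jump[i]
            duration = iv.duration_ms
            rows.append(
                (
                    ids[i],
                    iv.onset_ms,
                    iv.offset_ms,
                    latency,
                    duration,
                    float(sx), float(sy), float(ex), float(ey),
                    amplitude,
                    float(np.rad2deg(np.arctan2(dy, dx)) % 360.0),
                    float(np.nanmax(speed[i, i0: i1 + 1])),
                    float(np.hypot(ex - target_x[i], ey - 0.0)),
                    classify_latency_duration(latency, duration),
                )
            )
    sac = pd.DataFrame(
        rows,
        columns=[
            "trial_id", "onset_ms", "offset_ms", "latency_ms", "duration_ms",
            "start_x", "start_y", "end_x", "end_y", "amplitude_deg",
            "direction_deg", "peak_velocity_deg_s", "endpoint_error_deg",
            "label",
        ],
    )
    sac["is_first_task"] = False
    if len(sac):
        task = sac[sac["label"] == LABEL_TASK]
        first_idx = task.groupby("trial_id")["onset_ms"].idxmin()
        sac.loc[first_idx, "is_first_task"] = True
    return sac


def _first_task_table(saccades: pd.DataFrame, trials: pd.DataFrame) -> pd.DataFrame:
    """One row per trial with a task saccade, joined with trial metadata."""
    first = saccades[saccades["is_first_task"]]
    return first.merge(trials, on="trial_id", how="inner", validate="1:1")


# ---------------------------------------------------------------------------
# filter ledger
# ---------------------------------------------------------------------------

def apply_trial_filters(
    trials: pd.DataFrame,
    saccades: pd.DataFrame,
    excluded_electrodes: set,
    broken_electrodes: set,
) -> tuple[pd.DataFrame, dict]:
    """Behavioral-analysis trial filters with an exact accounting ledger.

    Filters, applied in order (a trial is charged to the first one it hits):
    broken electrode, saccade-evoking electrode, incorrect outcome, no
    task-classified saccade in the 100-400 ms window.  The ledger satisfies
    ``trials_in == trials_kept + sum(per-filter exclusions)``.
    """
    ledger = {"trials_in": int(len(trials))}
    cur = trials
    m = cur["electrode_id"].isin(broken_electrodes)
    ledger["excluded_broken_electrode"] = int(m.sum())
    cur = cur[~m]
    m = cur["electrode_id"].isin(excluded_electrodes)
    ledger["excluded_evoking_electrode"] = int(m.sum())
    cur = cur[~m]
    m = cur["outcome"] != "correct"
    ledger["excluded_incorrect"] = int(m.sum())
    cur = cur[~m]
    with_task = set(saccades.loc[saccades["is_first_task"], "trial_id"])
    m = ~cur["trial_id"].isin(with_task)
    ledger["excluded_no_task_saccade"] = int(m.sum())
    cur = cur[~m]
    ledger["trials_kept"] = int(len(cur))
    return cur, ledger


# ---------------------------------------------------------------------------
# evoked-saccade analysis
# ---------------------------------------------------------------------------

def summarize_evoked(
    saccades: pd.DataFrame, trials: pd.DataFrame
) -> pd.DataFrame:
    """Per electrode x current: stimulation-trial counts, evoked counts and
    the inclusion flag."""
    stim = trials[trials["stim"]]
    ev = saccades[saccades["label"] == LABEL_EVOKED]
    ev_trials = set(ev["trial_id"])
    rows = []
    for (eid, cur), grp in stim.groupby(["electrode_id", "current_uA"]):
        n_stim = len(grp)
        n_evoked = int(grp["trial_id"].isin(ev_trials).sum())
        rows.append(
            (
                int(eid), int(cur), n_stim, n_evoked,
                evoked_inclusion(n_evoked, n_stim),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["electrode_id", "current_uA", "n_stim_trials", "n_evoked",
                 "included"],
    )


def _evoked_events(
    saccades: pd.DataFrame, trials: pd.DataFrame
) -> pd.DataFrame:
    """First evoked-classified saccade of each stimulation trial, with
    trial metadata."""
    ev = saccades[saccades["label"] == LABEL_EVOKED]
    if ev.empty:
        return ev.merge(trials, on="trial_id")
    first = ev.loc[ev.groupby("trial_id")["onset_ms"].idxmin()]
    out = first.merge(trials, on="trial_id", validate="1:1")
    return out[out["stim"]]


def run_evoked_analysis(
    saccades: pd.DataFrame,
    trials: pd.DataFrame,
    electrode_map: pd.DataFrame,
    perm_seed: int = 0,
    n_perm: int = 999,
) -> dict:
    """Evoked-saccade section: per-electrode mapping plus the frequency,
    direction and amplitude analyses.

    Restricted to electrodes whose stimulation evokes saccades at *every*
    current tested, this runs (i) a Fisher exact test of evoked frequency
    against current, (ii) a two-way circular ANOVA of evoked direction on
    electrode x current, (iii) a two-way linear ANOVA of evoked amplitude,
    and (iv) the same three analyses with currents pooled and the
    task-instructed jump direction as the second factor (a control: the
    instructed direction should not shape directly evoked movements).
    """
    summaries = summarize_evoked(saccades, trials)
    currents = sorted(trials.loc[trials["stim"], "current_uA"].unique())
    out: dict = {"summaries": summaries, "currents_uA": [int(c) for c in currents]}

    events = _evoked_events(saccades, trials)

    # endpoint summaries per included electrode x current
    vec_rows = []
    for _, row in summaries[summaries["included"]].iterrows():
        sel = events[
            (events["electrode_id"] == row["electrode_id"])
            & (events["current_uA"] == row["current_uA"])
        ]
        if sel.empty:
            continue
        cd = circ_descriptives(sel["direction_deg"])
        try:
            center, axes, orient = endpoint_ellipse(sel[["end_x", "end_y"]].to_numpy())
            ellipse = {
                "center": [float(center[0]), float(center[1])],
                "semi_axes": [float(axes[0]), float(axes[1])],
                "orientation_deg": orient,
            }
        except DegenerateInputError:
            ellipse = None
        vec_rows.append(
            {
                "electrode_id": int(row["electrode_id"]),
                "current_uA": int(row["current_uA"]),
                "n": int(len(sel)),
                "mean_direction_deg": cd.mean_direction_deg,
                "resultant_length": cd.resultant_length,
                "mean_amplitude_deg": float(sel["amplitude_deg"].mean()),
                "ellipse": ellipse,
            }
        )
    out["mean_vectors"] = vec_rows

    if len(currents) < 2:
        out["empty"] = True
        return out
    inc_by_cur = {
        c: set(
            summaries.loc[
                (summaries["current_uA"] == c) & summaries["included"],
                "electrode_id",
            ]
        )
        for c in currents
    }
    both = sorted(set.intersection(*inc_by_cur.values())) if inc_by_cur else []
    out["electrodes_included_at_all_currents"] = [int(e) for e in both]
    if not both:
        out["empty"] = True
        return out
    out["empty"] = False

    def _safe_fisher(table):
        try:
            return {"table": table, "test": fisher_exact(table)}
        except InvalidArgumentError as exc:
            return {"table": table, "test": None, "note": str(exc)}

    lo, hi = int(currents[0]), int(currents[-1])
    sub = summaries[summaries["electrode_id"].isin(both)]
    a = int(sub.loc[sub["current_uA"] == lo, "n_evoked"].sum())
    na = int(sub.loc[sub["current_uA"] == lo, "n_stim_trials"].sum())
    b = int(sub.loc[sub["current_uA"] == hi, "n_evoked"].sum())
    nb = int(sub.loc[sub["current_uA"] == hi, "n_stim_trials"].sum())
    out["frequency_vs_current"] = _safe_fisher([[a, na - a], [b, nb - b]])

    ev_both = events[events["electrode_id"].isin(both)]

    def _factorial(frame, factor_b_col, tag):
        res = {}
        counts = frame.groupby(["electrode_id", factor_b_col]).size()
        complete = (
            len(counts) == len(both) * frame[factor_b_col].nunique()
            and counts.min() >= 2
        )
        if not complete:
            res["direction_anova"] = None
            res["amplitude_anova"] = None
            res["note"] = "insufficient evoked saccades per design cell"
            return res
        res["direction_anova"] = hk_circ_anova(
            frame["direction_deg"].to_numpy(),
            frame["electrode_id"].to_numpy(),
            frame[factor_b_col].to_numpy(),
            n_perm=n_perm,
            seed=perm_seed,
        )
        res["amplitude_anova"] = twoway_linear_anova(
            frame["amplitude_deg"].to_numpy(),
            frame["electrode_id"].to_numpy(),
            frame[factor_b_col].to_numpy(),
        )
        return res

    out["by_current"] = _factorial(ev_both, "current_uA", "current")

    # instructed-direction control (currents pooled)
    stim_both = trials[trials["stim"] & trials["electrode_id"].isin(both)]
    ev_ids = set(ev_both["trial_id"])
    fa = int(stim_both.loc[stim_both["jump_dir"] == "contra", "trial_id"].isin(ev_ids).sum())
    nfa = int((stim_both["jump_dir"] == "contra").sum())
    fb = int(stim_both.loc[stim_both["jump_dir"] == "ipsi", "trial_id"].isin(ev_ids).sum())
    nfb = int((stim_both["jump_dir"] == "ipsi").sum())
    out["frequency_vs_instructed_direction"] = _safe_fisher(
        [[fa, nfa - fa], [fb, nfb - fb]]
    )
    out["by_instructed_direction"] = _factorial(ev_both, "jump_dir", "jump_dir")
    return out


# ---------------------------------------------------------------------------
# latency analysis
# ---------------------------------------------------------------------------

def _condition_tests(stim_lat, ctrl_lat) -> dict:
    if len(stim_lat) < 2 or len(ctrl_lat) < 2:
        return {
            "insufficient_data": True,
            "n_stim": int(len(stim_lat)),
            "n_control": int(len(ctrl_lat)),
        }
    return {
        "insufficient_data": False,
        "n_stim": int(len(stim_lat)),
        "n_control": int(len(ctrl_lat)),
        "mean_diff_ms": float(np.mean(stim_lat) - np.mean(ctrl_lat)),
        "median_diff_ms": float(np.median(stim_lat) - np.median(ctrl_lat)),
        "test_transformed": latency_test(stim_lat, ctrl_lat, "t", transform=True),
        "test_raw": latency_test(stim_lat, ctrl_lat, "t", transform=False),
        "test_ranksum": latency_test(stim_lat, ctrl_lat, "ranksum", transform=False),
    }


def run_latency_analysis(
    kept_trials: pd.DataFrame, saccades: pd.DataFrame
) -> dict:
    """Latency section: baseline direction asymmetry and stimulation
    effects per direction x current.

    The baseline comparison uses control (non-stimulated) trials only and
    asks whether contraversive saccades lead ipsiversive ones.  Stimulation
    effects compare stimulated against interleaved control trials of the
    same direction and block current; the primary test runs on
    reciprocal-transformed latencies with raw-t and rank-sum companions,
    and mean/median differences are reported in milliseconds.
    """
    ft = _first_task_table(saccades, kept_trials)
    ctrl = ft[~ft["stim"]]
    out: dict = {}
    c_lat = ctrl.loc[ctrl["jump_dir"] == "contra", "latency_ms"].to_numpy()
    i_lat = ctrl.loc[ctrl["jump_dir"] == "ipsi", "latency_ms"].to_numpy()
    if len(c_lat) >= 2 and len(i_lat) >= 2:
        out["baseline"] = {
            "n_contra": int(len(c_lat)),
            "n_ipsi": int(len(i_lat)),
            # positive advantage = contraversive saccades are faster
            "contra_advantage_ms": float(np.mean(i_lat) - np.mean(c_lat)),
            "contra_advantage_median_ms": float(np.median(i_lat) - np.median(c_lat)),
            "test_transformed": latency_test(c_lat, i_lat, "t", transform=True),
            "test_raw": latency_test(c_lat, i_lat, "t", transform=False),
            "test_ranksum": latency_test(c_lat, i_lat, "ranksum", transform=False),
        }
    else:
        out["baseline"] = {"insufficient_data": True}

    conditions = {}
    for direction in ("contra", "ipsi"):
        for current in sorted(ft["current_uA"].unique()):
            sel = ft[(ft["jump_dir"] == direction) & (ft["current_uA"] == current)]
            stim_lat = sel.loc[sel["stim"], "latency_ms"].to_numpy()
            ctrl_lat = sel.loc[~sel["stim"], "latency_ms"].to_numpy()
            conditions[f"{direction}:{int(current)}"] = _condition_tests(
                stim_lat, ctrl_lat
            )
    out["conditions"] = conditions
    return out


# ---------------------------------------------------------------------------
# spatial (rostral/caudal) analysis
# ---------------------------------------------------------------------------

def run_spatial_analysis(
    kept_trials: pd.DataFrame,
    saccades: pd.DataFrame,
    electrode_map: pd.DataFrame,
    current_uA: int = 250,
) -> dict:
    """Spatial section: latency effects by rostral/caudal electrode group.

    Restricted to blocks of the given current (the strong current by
    default), each electrode contributes its mean stimulated-trial latency
    and the mean of its own interleaved control trials, per direction.
    Within each group x direction the two are compared with a paired t test
    across electrodes (Bonferroni over the four tests); per direction, the
    per-electrode effects of the two groups are compared with a two-sample
    t test.
    """
    ft = _first_task_table(saccades, kept_trials)
    ft = ft[ft["current_uA"] == current_uA]
    group_of = dict(zip(electrode_map["electrode_id"], electrode_map["group"]))
    rows = []
    for (eid, direction), grp in ft.groupby(["electrode_id", "jump_dir"]):
        s = grp.loc[grp["stim"], "latency_ms"]
        c = grp.loc[~grp["stim"], "latency_ms"]
        if len(s) < 1 or len(c) < 1:
            continue
        rows.append(
            (
                int(eid), group_of[int(eid)], direction,
                int(len(s)), int(len(c)),
                float(s.mean()), float(c.mean()), float(s.mean() - c.mean()),
            )
        )
    per_electrode = pd.DataFrame(
        rows,
        columns=["electrode_id", "group", "jump_dir", "n_stim", "n_control",
                 "mean_stim_ms", "mean_control_ms", "effect_ms"],
    )
    out: dict = {"current_uA": int(current_uA), "per_electrode": per_electrode}

    n_paired_tests = 4
    alpha_adj = bonferroni_alpha(SPATIAL_ALPHA, n_paired_tests)
    out["alpha_adjusted"] = alpha_adj
    group_tests = {}
    for group in ("caudal", "rostral"):
        for direction in ("contra", "ipsi"):
            sel = per_electrode[
                (per_electrode["group"] == group)
                & (per_electrode["jump_dir"] == direction)
            ]
            key = f"{group}:{direction}"
            if len(sel) < 2:
                group_tests[key] = {"insufficient_data": True, "n_electrodes": int(len(sel))}
                continue
            res = latency_test(
                sel["mean_stim_ms"].to_numpy(),
                sel["mean_control_ms"].to_numpy(),
                method="t",
                paired=True,
                transform=False,
            )
            group_tests[key] = {
                "insufficient_data": False,
                "n_electrodes": int(len(sel)),
                "mean_effect_ms": float(sel["effect_ms"].mean()),
                "test": res,
                "significant": bool(res.p_value < alpha_adj),
            }
    out["group_tests"] = group_tests

    between = {}
    for direction in ("contra", "ipsi"):
        caud = per_electrode[
            (per_electrode["group"] == "caudal")
            & (per_electrode["jump_dir"] == direction)
        ]["effect_ms"].to_numpy()
        rost = per_electrode[
            (per_electrode["group"] == "rostral")
            & (per_electrode["jump_dir"] == direction)
        ]["effect_ms"].to_numpy()
        if len(caud) < 2 or len(rost) < 2:
            between[direction] = {"insufficient_data": True}
            continue
        res = latency_test(caud, rost, method="t", transform=False)
        between[direction] = {
            "insufficient_data": False,
            "n_caudal": int(len(caud)),
            "n_rostral": int(len(rost)),
            "caudal_minus_rostral_ms": float(np.mean(caud) - np.mean(rost)),
            "test": res,
            "significant": bool(res.p_value < 0.05),
        }
    out["between_groups"] = between
    return out


# ---------------------------------------------------------------------------
# kinematics analysis
# ---------------------------------------------------------------------------

def run_kinematics_analysis(
    kept_trials: pd.DataFrame, saccades: pd.DataFrame
) -> dict:
    """Kinematics section: stimulation effects on peak velocity, amplitude
    and endpoint accuracy.

    For each measure and each direction x current combination, stimulated
    and control task saccades are compared with a two-sample t test; pooled
    per-direction comparisons (across currents) are reported as companions.
    The Bonferroni adjustment spans every per-combination comparison across
    the three measures in one family.
    """
    ft = _first_task_table(saccades, kept_trials)
    currents = sorted(ft["current_uA"].unique())
    combos = [(d, int(c)) for d in ("contra", "ipsi") for c in currents]
    n_family = len(combos) * len(KINEMATIC_MEASURES)
    alpha_adj = bonferroni_alpha(0.05, max(n_family, 1))
    out: dict = {
        "alpha_adjusted": alpha_adj,
        "n_comparisons": n_family,
        "measures": {},
    }
    for measure in KINEMATIC_MEASURES:
        mres: dict = {"per_combination": {}, "pooled_by_direction": {}}
        for direction, current in combos:
            sel = ft[(ft["jump_dir"] == direction) & (ft["current_uA"] == current)]
            s = sel.loc[sel["stim"], measure].to_numpy()
            c = sel.loc[~sel["stim"], measure].to_numpy()
            key = f"{direction}:{current}"
            if len(s) < 2 or len(c) < 2:
                mres["per_combination"][key] = {"insufficient_data": True}
                continue
            res = latency_test(s, c, method="t", transform=False)
            mres["per_combination"][key] = {
                "insufficient_data": False,
                "n_stim": int(len(s)),
                "n_control": int(len(c)),
                "mean_diff": float(np.mean(s) - np.mean(c)),
                "test": res,
                "significant_adjusted": bool(res.p_value < alpha_adj),
            }
        for direction in ("contra", "ipsi"):
            sel = ft[ft["jump_dir"] == direction]
            s = sel.loc[sel["stim"], measure].to_numpy()
            c = sel.loc[~sel["stim"], measure].to_numpy()
            if len(s) < 2 or len(c) < 2:
                mres["pooled_by_direction"][direction] = {"insufficient_data": True}
                continue
            res = latency_test(s, c, method="t", transform=False)
            mres["pooled_by_direction"][direction] = {
                "insufficient_data": False,
                "n_stim": int(len(s)),
                "n_control": int(len(c)),
                "mean_diff": float(np.mean(s) - np.mean(c)),
                "test": res,
            }
        out["measures"][measure] = mres
    return out


# ---------------------------------------------------------------------------
# full run + serialization
# ---------------------------------------------------------------------------

def run_full(
    config: SimConfig | None = None,
    session: SessionData | None = None,
    seed: int | None = None,
    v_threshold: float = DEFAULT_V_THRESHOLD,
    smooth_window_samples: int = 3,
    perm_seed: int = 0,
    n_perm: int = 999,
    spatial_current_uA: int | None = None,
    out_dir=None,
) -> dict:
    """Simulate (or take) a session and run every analysis stage.

    Exactly one of ``config`` / ``session`` must be given; with ``config``
    the session is simulated first (``seed`` overrides the config seed).
    Returns the full report as a nested dict; when ``out_dir`` is given the
    report JSON and per-table CSVs are written there.
    """
    if (config is None) == (session is None):
        raise InvalidArgumentError("provide exactly one of config or session")
    if session is None:
        session = simulate_session(config, seed=seed)
    trials = session.trials
    emap = session.electrode_map

    saccades = build_saccade_table(
        session,
        v_threshold=v_threshold,
        smooth_window_samples=smooth_window_samples,
    )
    evoked = run_evoked_analysis(
        saccades, trials, emap, perm_seed=perm_seed, n_perm=n_perm
    )
    exclusions = flag_excluded_electrodes(evoked["summaries"], emap)
    excluded_evoking = set(
        exclusions.loc[exclusions["reason"] == "evokes-saccades", "electrode_id"]
    )
    broken = set(exclusions.loc[exclusions["reason"] == "broken", "electrode_id"])
    kept, ledger = apply_trial_filters(trials, saccades, excluded_evoking, broken)

    latency = run_latency_analysis(kept, saccades)
    if spatial_current_uA is None:
        spatial_current_uA = int(max(trials.loc[trials["stim"], "current_uA"],
                                     default=250))
    spatial = run_spatial_analysis(kept, saccades, emap, spatial_current_uA)
    kinematics = run_kinematics_analysis(kept, saccades)

    report = {
        "manifest": {
            "package": "oculostim",
            "version": __version__,
            "seed": seed if seed is not None else (
                config.seed if config is not None else None
            ),
            "detection": {
                "v_threshold_deg_s": v_threshold,
                "smooth_window_samples": smooth_window_samples,
            },
            "n_trials": int(len(trials)),
            "config": config.to_dict() if config is not None else None,
        },
        "filter_ledger": ledger,
        "exclusions": exclusions.to_dict(orient="records"),
        "evoked": evoked,
        "latency": latency,
        "spatial": spatial,
        "kinematics": kinematics,
    }
    if out_dir is not None:
        _write_report(report, saccades, out_dir)
    report["_saccades"] = saccades  # in-memory convenience; not serialized
    return report


def _jsonify(obj):
    if is_dataclass(obj) and hasattr(obj, "to_dict"):
        return _jsonify(obj.to_dict())
    if is_dataclass(obj):
        return _jsonify(asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.to_dict(orient="records"))
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating,)):
        obj = float(obj)
    if isinstance(obj, float) and (np.isnan(obj) or np.isinf(obj)):
        return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
    return obj


def report_to_json(report: dict) -> str:
    """Deterministic JSON serialization of a report (sorted keys; identical
    inputs yield byte-identical output)."""
    clean = {k: v for k, v in report.items() if not k.startswith("_")}
    return json.dumps(_jsonify(clean), sort_keys=True, indent=2)


def _write_report(report: dict, saccades: pd.DataFrame, out_dir) -> None:
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report_to_json(report))
    saccades.to_csv(out / "saccades.csv", index=False)
    report["evoked"]["summaries"].to_csv(out / "evoked_summary.csv", index=False)
    pd.DataFrame(report["exclusions"]).to_csv(out / "exclusions.csv", index=False)
    report["spatial"]["per_electrode"].to_csv(
        out / "spatial_per_electrode.csv", index=False
    )
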