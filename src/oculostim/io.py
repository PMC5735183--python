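"""CSV input/output for traces, trial metadata and electrode maps.

File formats (all plain CSV):

* traces:       trial_id, t_ms, x_deg, y_deg   (long format, 500 Hz grid)
* trials:       trial_id, jump_time_ms, jump_dir, stim, electrode_id,
                current_uA [, block_id, group, outcome]
* electrodes:   electrode_id, row, col, group, status
* ground truth: as produced by the simulator (optional)
"""

from __future__ import annotations

import json
import pathlib

import numpy as np
import pandas as pd

from .config import SimConfig
from .errors import SchemaError
from .simulate import SessionData, electrode_map_frame

__all__ = ["write_session", "read_session", "read_traces_frame"]

TRACE_COLUMNS = ["trial_id", "t_ms", "x_deg", "y_deg"]
TRIAL_COLUMNS = [
    "trial_id", "jump_time_ms", "jump_dir", "stim", "electrode_id", "current_uA",
]
ELECTRODE_COLUMNS = ["electrode_id", "row", "col", "group", "status"]


def _require(df: pd.DataFrame, columns, what: str) -> None:
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"{what} table is missing required column {col!r}")


def write_session(session: SessionData, out_dir, write_traces: bool = True) -> dict:
    """Write a session to ``out_dir`` as CSV tables plus a run manifest.

    Returns the mapping of table names to file paths.  The traces table is
    by far the largest and can be skipped with ``write_traces=False``.
    """
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    if write_traces:
        n_trials, n_samples = session.x.shape
        ids = np.repeat(session.trials["trial_id"].to_numpy(), n_samples)
        frame = pd.DataFrame(
            {
                "trial_id": ids,
                "t_ms": np.tile(session.t_ms, n_trials),
                "x_deg": session.x.ravel(),
                "y_deg": session.y.ravel(),
            }
        )
        paths["traces"] = out / "traces.csv"
        frame.to_csv(paths["traces"], index=False, float_format="%.5f")
    paths["trials"] = out / "trials.csv"
    trials = session.trials.copy()
    trials["stim"] = trials["stim"].astype(int)
    trials.to_csv(paths["trials"], index=False)
    paths["electrodes"] = out / "electrodes.csv"
    session.electrode_map.to_csv(paths["electrodes"], index=False)
    if session.ground_truth is not None:
        paths["ground_truth"] = out / "ground_truth.csv"
        session.ground_truth.to_csv(paths["ground_truth"], index=False)
    if session.config is not None:
        paths["config"] = out / "config.yaml"
        session.config.to_yaml(paths["config"])
    manifest = {
        "seed": session.config.seed if session.config is not None else None,
        "n_trials": int(session.n_trials),
        "sample_rate": session.sample_rate,
        "files": {k: str(v.name) for k, v in paths.items()},
    }
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, sort_keys=True, indent=2))
    return paths


def read_traces_frame(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, TRACE_COLUMNS, "traces")
    return df


def read_session(
    traces_path, trials_path, electrodes_path=None, config: SimConfig | None = None
) -> SessionData:
    """Assemble a :class:`SessionData` from CSV files.

    All trials must share one uniform time grid (as written by
    :func:`write_session`); missing samples may be encoded as empty fields
    or NaN.
    """
    traces = read_traces_frame(traces_path)
    trials = pd.read_csv(trials_path)
    _require(trials, TRIAL_COLUMNS, "trials")
    trials = trials.copy()
    trials["stim"] = trials["stim"].astype(bool)
    if "outcome" not in trials.columns:
        trials["outcome"] = "correct"
    bad_dir = set(trials["jump_dir"].unique()) - {"contra", "ipsi"}
    if bad_dir:
        raise SchemaError(
            f"trials column 'jump_dir' contains invalid values {sorted(bad_dir)}"
        )

    if electrodes_path is not None:
        emap = pd.read_csv(electrodes_path)
        _require(emap, ELECTRODE_COLUMNS, "electrodes")
    elif config is not None:
        emap = electrode_map_frame(config)
    else:
        raise SchemaError("an electrode map (or a config) is required")
    if "group" in emap.columns:
        bad_grp = set(emap["group"].unique()) - {"rostral", "caudal"}
        if bad_grp:
            raise SchemaError(
                f"electrodes column 'group' contains invalid values {sorted(bad_grp)}"
            )
    missing = set(trials["electrode_id"]) - set(emap["electrode_id"])
    if missing:
        raise SchemaError(
            f"trials reference electrode ids not in the map: {sorted(missing)[:5]}"
        )

    ids_in_order = trials["trial_id"].to_numpy()
    grouped = {tid: g for tid, g in traces.groupby("trial_id", sort=False)}
    missing_traces = [tid for tid in ids_in_order if tid not in grouped]
    if missing_traces:
        raise SchemaError(
            f"traces missing for trial_id {missing_traces[:5]}"
        )
    first = grouped[ids_in_order[0]]
    t = first["t_ms"].to_numpy(dtype=float)
    if t.size < 2:
        raise SchemaError("traces must contain at least 2 samples per trial")
    steps = np.diff(t)
    if steps.min() <= 0 or not np.allclose(steps, steps[0], rtol=0, atol=1e-6):
        raise SchemaError("traces column 't_ms' must be uniform and increasing")
    sample_rate = 1000.0 / steps[0]
    n_samples = t.size
    x = np.empty((len(ids_in_order), n_samples))
    y = np.empty_like(x)
    for i, tid in enumerate(ids_in_order):
        g = grouped[tid]
        if len(g) != n_samples:
            raise SchemaError(
                f"trial {tid}: expected {n_samples} samples, found {len(g)}"
            )
        x[i] = g["x_deg"].to_numpy(dtype=float)
        y[i] = g["y_deg"].to_numpy(dtype=float)

    if "group" not in trials.columns:
        trials = trials.merge(
            emap[["electrode_id", "group"]], on="electrode_id", how="left"
        )
    return SessionData(
        config=config,
        t_ms=t,
        x=x,
        y=y,
        trials=trials,
        electrode_map=emap,
        ground_truth=None,
        sample_rate=sample_rate,
    )
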