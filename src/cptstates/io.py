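"""Delimited-text readers/writers for traces, centroids, events and results.

All on-disk formats are plain text so that sessions round-trip through
version control and external touchscreen/miniscope exports can be adapted by
simple column renaming:

* traces:    CSV, rows = frames, columns = cell IDs, header row
* centroids: CSV with columns cell_id, x_um, y_um
* events:    CSV with columns time_s, event_type, correction_flag where
             event_type ∈ {stim_on_splus, stim_on_sminus, hit, false_alarm,
             miss, correct_rejection, reward_collect}
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import BehaviorSession
from .core import CalciumTraceSet

EVENT_TYPES = (
    "stim_on_splus",
    "stim_on_sminus",
    "hit",
    "false_alarm",
    "miss",
    "correct_rejection",
    "reward_collect",
)

_OUTCOME_TO_EVENT = {
    "hit": "hit",
    "FA": "false_alarm",
    "miss": "miss",
    "CR": "correct_rejection",
}
_EVENT_TO_OUTCOME = {v: k for k, v in _OUTCOME_TO_EVENT.items()}


def write_traces(ts: CalciumTraceSet, path: str | Path) -> None:
    df = pd.DataFrame(ts.traces.T, columns=ts.neuron_ids)
    df.to_csv(path, index=False, float_format="%.6g")


def read_traces(path: str | Path, frame_rate_hz: float = 10.0) -> CalciumTraceSet:
    df = pd.read_csv(path)
    return CalciumTraceSet(
        traces=df.to_numpy(float).T,
        frame_rate_hz=frame_rate_hz,
        neuron_ids=np.asarray(df.columns, dtype=object),
    )


def write_centroids(ts: CalciumTraceSet, path: str | Path) -> None:
    if ts.centroids_um is None:
        raise ValueError("trace set has no centroids")
    pd.DataFrame(
        {
            "cell_id": ts.neuron_ids,
            "x_um": ts.centroids_um[:, 0],
            "y_um": ts.centroids_um[:, 1],
        }
    ).to_csv(path, index=False, float_format="%.4f")


def read_centroids(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"cell_id", "x_um", "y_um"}
    if not need.issubset(df.columns):
        raise ValueError(f"centroid table must have columns {sorted(need)}")
    return df


def attach_centroids(ts: CalciumTraceSet, centroids: pd.DataFrame) -> CalciumTraceSet:
    """Join a centroid table onto a trace set by cell_id (order-aligned)."""
    lookup = centroids.set_index("cell_id")
    try:
        xy = lookup.loc[list(ts.neuron_ids), ["x_um", "y_um"]].to_numpy(float)
    except KeyError as e:
        raise ValueError(f"centroid table missing cell ids: {e}") from e
    return CalciumTraceSet(ts.traces, ts.frame_rate_hz, xy, ts.neuron_ids)


def session_to_events(
    session: BehaviorSession, window_s: float = 4.5, extra_events: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Flatten a trial table into the on-disk event stream.

    Misses/CRs are stamped at the end of the response window (onset +
    ``window_s``); hits/FAs at the touch time.  ``extra_events`` (e.g.
    reward_collect rows) are merged in time order.
    """
    rows = []
    for _, tr in session.trials.iterrows():
        stim = "stim_on_splus" if tr["stimulus"] == "S+" else "stim_on_sminus"
        corr = bool(tr["correction"])
        rows.append((tr["onset_s"], stim, corr))
        if tr["outcome"] in ("hit", "FA"):
            rows.append((tr["response_s"], _OUTCOME_TO_EVENT[tr["outcome"]], corr))
        else:
            rows.append((tr["onset_s"] + window_s, _OUTCOME_TO_EVENT[tr["outcome"]], corr))
    df = pd.DataFrame(rows, columns=["time_s", "event_type", "correction_flag"])
    if extra_events is not None:
        df = pd.concat([df, extra_events], ignore_index=True)
    return df.sort_values("time_s", kind="stable").reset_index(drop=True)


def events_to_session(
    events: pd.DataFrame, session_length_s: float, stage: str = "stage3"
) -> BehaviorSession:
    """Reconstruct the trial table from an event stream.

    Each stim_on row opens a trial; the first outcome row before the next
    stim_on closes it.  reward_collect rows are ignored here.
    """
    bad = set(events["event_type"]) - set(EVENT_TYPES)
    if bad:
        raise ValueError(f"unknown event types: {sorted(bad)}")
    ev = events.sort_values("time_s", kind="stable")
    trials = []
    current = None
    for _, row in ev.iterrows():
        etype = row["event_type"]
        if etype.startswith("stim_on"):
            current = {
                "trial_index": len(trials),
                "stimulus": "S+" if etype == "stim_on_splus" else "S-",
                "onset_s": float(row["time_s"]),
                "response_s": np.nan,
                "outcome": None,
                "correction": bool(row["correction_flag"]),
            }
        elif etype in _EVENT_TO_OUTCOME:
            if current is None or current["outcome"] is not None:
                raise ValueError(f"outcome event at t={row['time_s']} without open trial")
            current["outcome"] = _EVENT_TO_OUTCOME[etype]
            if etype in ("hit", "false_alarm"):
                current["response_s"] = float(row["time_s"])
            trials.append(current)
            current = None
    df = pd.DataFrame(trials)
    return BehaviorSession(trials=df, session_length_s=session_length_s, stage=stage)


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, index=False, float_format="%.4f")


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"time_s", "event_type", "correction_flag"}
    if not need.issubset(df.columns):
        raise ValueError(f"event table must have columns {sorted(need)}")
    return df


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
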