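"""Schema-validated CSV ingestion and export for trial tables and spike data.

Trial tables are delimited text (UTF-8, header row) with one row per trial;
times are float seconds for behavior and float ms (relative to cue onset) for
events and spikes.  Spike exports split into a spikes CSV (one row per spike)
and an events CSV (one row per trial).
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .spikes import SpikeData

TRIAL_COLUMNS = [
    "session_id", "trial_index", "reward_size", "delay_class", "delay_mean_s",
    "outcome", "is_repeat", "cum_reward_drops", "rcum", "treatment",
]
OUTCOMES = ("correct", "early", "late")
TREATMENTS = ("baseline", "control", "inactivation")
SPIKE_COLUMNS = ["neuron_id", "session_id", "trial_index", "spike_time_ms"]
EVENT_COLUMNS = ["session_id", "trial_index", "cue_ms", "go_ms", "release_ms", "reward_ms"]


class SchemaError(ValueError):
    """A file violates the expected schema; the message names the offender."""


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _first_bad(mask: pd.Series) -> int:
    return int(np.flatnonzero(mask.to_numpy())[0])


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial table CSV."""
    df = pd.read_csv(path)
    _require_columns(df, TRIAL_COLUMNS, path)
    bad = ~df["outcome"].isin(OUTCOMES)
    if bad.any():
        i = _first_bad(bad)
        raise SchemaError(f"{path}: row {i}: invalid outcome {df['outcome'].iloc[i]!r}")
    bad = ~df["is_repeat"].isin([0, 1])
    if bad.any():
        i = _first_bad(bad)
        raise SchemaError(f"{path}: row {i}: is_repeat must be 0 or 1")
    bad = ~df["treatment"].isin(TREATMENTS)
    if bad.any():
        i = _first_bad(bad)
        raise SchemaError(f"{path}: row {i}: invalid treatment {df['treatment'].iloc[i]!r}")
    rc = df["rcum"].to_numpy(dtype=float)
    bad = pd.Series((rc < 0) | (rc > 1), index=df.index)
    if bad.any():
        i = _first_bad(bad)
        raise SchemaError(f"{path}: row {i}: rcum {rc[i]} outside [0, 1]")
    return df


def write_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def write_spikes(population, spikes_path, events_path) -> None:
    """Write spike and event CSVs for a collection of neurons.

    ``population`` is an iterable of :class:`SpikeData` or of
    ``(SpikeData, label)`` pairs.
    """
    spike_rows = []
    event_frames = {}
    for item in population:
        sd = item[0] if isinstance(item, tuple) else item
        sid = sd.trials["session_id"].iloc[0] if len(sd.trials) else ""
        for ti, s in zip(sd.trials["trial_index"], sd.spikes):
            for t in s:
                spike_rows.append((sd.neuron_id, sid, int(ti), float(t)))
        ev = sd.trials[["session_id", "trial_index", "go_ms", "release_ms", "reward_ms"]].copy()
        ev.insert(2, "cue_ms", 0.0)
        event_frames[sid] = ev
    pd.DataFrame(spike_rows, columns=SPIKE_COLUMNS).to_csv(spikes_path, index=False)
    pd.concat(event_frames.values(), ignore_index=True).drop_duplicates(
        subset=["session_id", "trial_index"]
    ).to_csv(events_path, index=False)


def read_spikes(spikes_path, events_path, trials: pd.DataFrame) -> dict[str, SpikeData]:
    """Rebuild per-neuron :class:`SpikeData` from spike/event CSVs.

    ``trials`` supplies the per-trial condition metadata; events are merged
    on (session_id, trial_index).  Spike times must be sorted within trial.
    """
    sp = pd.read_csv(spikes_path)
    _require_columns(sp, SPIKE_COLUMNS, spikes_path)
    ev = pd.read_csv(events_path)
    _require_columns(ev, EVENT_COLUMNS, events_path)

    meta = trials.drop(columns=["go_ms", "release_ms", "reward_ms"], errors="ignore")
    merged = meta[meta["outcome"] == "correct"].merge(
        ev, on=["session_id", "trial_index"], how="inner", validate="one_to_one"
    )
    out: dict[str, SpikeData] = {}
    for nid, grp in sp.groupby("neuron_id", sort=True):
        sid = grp["session_id"].iloc[0]
        tmeta = merged[merged["session_id"] == sid].sort_values("trial_index").reset_index(drop=True)
        if tmeta.empty:
            raise SchemaError(f"{spikes_path}: neuron {nid}: no events for session {sid!r}")
        by_trial = {int(t): g["spike_time_ms"].to_numpy(dtype=float) for t, g in grp.groupby("trial_index")}
        spikes = []
        for _, tr in tmeta.iterrows():
            arr = by_trial.get(int(tr["trial_index"]), np.empty(0))
            if arr.size and np.any(np.diff(arr) < 0):
                raise SchemaError(
                    f"{spikes_path}: neuron {nid} trial {int(tr['trial_index'])}: "
                    "unsorted spike times"
                )
            spikes.append(arr)
        out[str(nid)] = SpikeData(neuron_id=str(nid), trials=tmeta, spikes=spikes)
    return out
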