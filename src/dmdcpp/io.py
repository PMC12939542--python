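"""Recording container and BIDS-style events-table I/O.

Recordings travel as ``.npz`` archives (signal matrix plus scalar
attributes); stimulus events use tab-separated tables with ``onset``,
``duration`` and ``trial_type`` columns.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .segmentation import Recording


def save_recording(rec: Recording, path) -> None:
    np.savez_compressed(
        path,
        signal=rec.signal,
        fs=rec.fs,
        stim_onset=rec.stim_onset,
        stim_offset=rec.stim_offset,
        subject_id=np.array(rec.subject_id),
        label=np.array(rec.label),
        channel_names=np.array(rec.channel_names),
    )


def load_recording(path) -> Recording:
    with np.load(path, allow_pickle=False) as z:
        return Recording(
            subject_id=str(z["subject_id"]),
            label=str(z["label"]),
            signal=z["signal"],
            fs=float(z["fs"]),
            stim_onset=float(z["stim_onset"]),
            stim_offset=float(z["stim_offset"]),
            channel_names=[str(c) for c in z["channel_names"]],
        )


def write_events(rec: Recording, path) -> None:
    pd.DataFrame([{
        "onset": rec.stim_onset,
        "duration": rec.stim_offset - rec.stim_onset,
        "trial_type": "photic_stimulation",
    }]).to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"events table not found: {path}")
    df = pd.read_csv(path, sep="\t")
    missing = {"onset", "duration", "trial_type"} - set(df.columns)
    if missing:
        raise ValueError(f"events table {path} missing columns: {sorted(missing)}")
    return df


def stim_interval_from_events(events: pd.DataFrame,
                              trial_type: str = "photic_stimulation"):
    """(onset, offset) spanning the rows of the given trial type."""
    sel = events[events["trial_type"] == trial_type]
    if sel.empty:
        raise ValueError(f"no events of trial_type {trial_type!r}")
    onset = float(sel["onset"].min())
    offset = float((sel["onset"] + sel["duration"]).max())
    return onset, offset
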