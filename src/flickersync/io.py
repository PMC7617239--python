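"""Plain-text serialization for spike tables, LFPs and event tables.

Formats:

* spike tables -- tab-separated text with a schema-version header comment:
  columns ``unit_id, spike_time_s, trial_id`` plus optional label columns;
* LFP -- flat binary float32, channel-major, with a JSON sidecar holding
  ``fs``, ``n_channels``, ``spacing_um`` and ``t0``;
* event tables -- tab-separated text.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .core import ContinuousSignal, LaminarRecording, SpikeTrain

__all__ = [
    "SCHEMA_VERSION",
    "save_spike_table",
    "load_spike_table",
    "save_lfp",
    "load_lfp",
    "save_events",
    "load_events",
]

SCHEMA_VERSION = 1
_HEADER = f"# flickersync table v{SCHEMA_VERSION}"


def save_spike_table(path: str | Path, trains: Sequence[SpikeTrain]) -> None:
    rows = []
    for tr in trains:
        tid = tr.trial_ids if tr.trial_ids is not None else np.full(tr.n_spikes, -1)
        for t, k in zip(tr.spike_times, tid):
            rows.append(
                {
                    "unit_id": tr.unit_id,
                    "spike_time_s": t,
                    "trial_id": k,
                    "area": tr.area or "",
                    "layer": tr.layer or "",
                    "cell_class": tr.cell_class or "",
                }
            )
    df = pd.DataFrame(rows)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_HEADER + "\n")
        df.to_csv(fh, sep="\t", index=False)


def load_spike_table(path: str | Path) -> List[SpikeTrain]:
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    trains = []
    for uid, grp in df.groupby("unit_id", sort=True):
        grp = grp.sort_values("spike_time_s")
        tid = grp["trial_id"].to_numpy()
        trains.append(
            SpikeTrain(
                unit_id=uid,
                spike_times=grp["spike_time_s"].to_numpy(dtype=float),
                trial_ids=None if (tid < 0).all() else tid,
                area=str(grp["area"].iloc[0]) or None,
                layer=str(grp["layer"].iloc[0]) or None,
                cell_class=str(grp["cell_class"].iloc[0]) or None,
            )
        )
    return trains


def save_lfp(prefix: str | Path, rec: LaminarRecording | ContinuousSignal) -> None:
    """Write ``<prefix>.bin`` (float32 channel-major) and ``<prefix>.json``."""
    prefix = Path(prefix)
    if isinstance(rec, ContinuousSignal):
        data = rec.samples[None, :]
        meta = {"fs": rec.fs, "n_channels": 1, "spacing_um": 0.0, "t0": rec.t0}
    else:
        data = rec.data
        meta = {
            "fs": rec.fs,
            "n_channels": rec.n_channels,
            "spacing_um": rec.spacing_um,
            "t0": rec.t0,
        }
    meta["schema_version"] = SCHEMA_VERSION
    data.astype(np.float32).tofile(prefix.with_suffix(".bin"))
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_lfp(prefix: str | Path) -> LaminarRecording | ContinuousSignal:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    flat = np.fromfile(prefix.with_suffix(".bin"), dtype=np.float32)
    data = flat.reshape(meta["n_channels"], -1).astype(float)
    if meta["n_channels"] == 1:
        return ContinuousSignal(data[0], fs=meta["fs"], t0=meta["t0"])
    return LaminarRecording(
        data, fs=meta["fs"], spacing_um=meta["spacing_um"], t0=meta["t0"]
    )


def save_events(path: str | Path, events: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write(_HEADER + "\n")
        events.to_csv(fh, sep="\t", index=False)


def load_events(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
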