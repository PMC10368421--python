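"""Session serialization: HDF5 bundles, TSV exports, JSON summaries."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .behavior import BeelineTrial, PositionTrace
from .synth import GroundTruthCell, Session, SessionEvents
from .tuning import ActivityRaster, PlaceCellLabel

__all__ = [
    "write_session_h5",
    "read_session_h5",
    "write_ground_truth_json",
    "write_position_tsv",
    "write_registry_tsv",
    "write_trials_tsv",
    "write_place_cell_tsv",
]


def write_session_h5(path: str | Path, session: Session) -> None:
    """Write a session to HDF5 (datasets /position/t, /position/x, /spikes,
    /events/*)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("position/t", data=session.trace.t)
        f.create_dataset("position/x", data=session.trace.x)
        f["position"].attrs["frame_rate"] = session.trace.frame_rate
        f["position"].attrs["track_length"] = session.trace.track_length
        f.create_dataset("spikes", data=session.raster.spikes)
        ev = f.create_group("events")
        ev.attrs["condition"] = session.events.condition
        ev.create_dataset("reward_zones", data=np.asarray(session.events.reward_zones))
        ev.create_dataset("shock_zone", data=np.asarray(session.events.shock_zone))
        if session.events.shock_on_time is not None:
            ev.attrs["shock_on_time"] = session.events.shock_on_time
        if session.trial_table:
            starts, ends, dirs = zip(*session.trial_table)
            tt = f.create_group("trials")
            tt.create_dataset("start_frame", data=np.asarray(starts))
            tt.create_dataset("end_frame", data=np.asarray(ends))
            tt.create_dataset(
                "direction", data=np.array([d.encode() for d in dirs])
            )


def read_session_h5(path: str | Path) -> Session:
    """Read a session bundle written by :func:`write_session_h5`.

    The ground-truth cell list lives in the JSON sidecar (if present) and is
    not reloaded here; ``cells`` is empty.
    """
    with h5py.File(path, "r") as f:
        trace = PositionTrace(
            t=f["position/t"][:],
            x=f["position/x"][:],
            frame_rate=float(f["position"].attrs["frame_rate"]),
            track_length=float(f["position"].attrs["track_length"]),
        )
        raster = ActivityRaster(
            spikes=f["spikes"][:], frame_rate=trace.frame_rate
        )
        ev = f["events"]
        rz = ev["reward_zones"][:]
        events = SessionEvents(
            reward_zones=((rz[0][0], rz[0][1]), (rz[1][0], rz[1][1])),
            shock_zone=tuple(ev["shock_zone"][:]),
            shock_on_time=float(ev.attrs["shock_on_time"])
            if "shock_on_time" in ev.attrs
            else None,
            condition=str(ev.attrs["condition"]),
        )
        trial_table = []
        if "trials" in f:
            tt = f["trials"]
            trial_table = [
                (int(s), int(e), d.decode())
                for s, e, d in zip(
                    tt["start_frame"][:], tt["end_frame"][:], tt["direction"][:]
                )
            ]
    return Session(trace=trace, raster=raster, events=events, cells=[],
                   trial_table=trial_table)


def write_ground_truth_json(path: str | Path, cells: list[GroundTruthCell]) -> None:
    """Ground-truth sidecar for a simulated session."""
    Path(path).write_text(
        json.dumps([dataclasses.asdict(c) for c in cells], indent=1)
    )


def write_position_tsv(path: str | Path, trace: PositionTrace) -> None:
    pd.DataFrame({"t": trace.t, "x": trace.x}).to_csv(path, sep="\t", index=False)


def write_registry_tsv(path: str | Path, registry) -> None:
    """Long-form cell registry: global_id, session, local_index."""
    long = (
        registry.table.reset_index()
        .melt(id_vars=registry.table.index.name or "index",
              var_name="session", value_name="local_index")
    )
    long.columns = ["global_id", "session", "local_index"]
    long.to_csv(path, sep="\t", index=False)


def write_trials_tsv(
    path: str | Path, trials: list[BeelineTrial], trace: PositionTrace,
    kept: set[int] | None = None,
) -> None:
    rows = [
        {
            "trial_id": i,
            "direction": tr.direction,
            "start_t": trace.t[tr.start_frame],
            "end_t": trace.t[tr.end_frame],
            "mean_speed": tr.mean_speed,
            "kept_flag": (kept is None) or (i in kept),
        }
        for i, tr in enumerate(trials)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_place_cell_tsv(path: str | Path, labels: list[PlaceCellLabel]) -> None:
    rows = [
        {
            "cell_id": lab.cell_id,
            "median_p_LR": lab.median_p_LR,
            "median_p_RL": lab.median_p_RL,
            "is_place_LR": lab.is_place_LR,
            "is_place_RL": lab.is_place_RL,
            "spikes_per_trial": lab.spikes_per_trial,
            "interneuron_flag": lab.interneuron_flag,
            "is_place_cell": lab.is_place_cell,
        }
        for lab in labels
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
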