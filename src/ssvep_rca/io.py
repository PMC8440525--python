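"""On-disk containers: HDF5 recordings with JSON sidecars for the montage
and the stimulus schedule."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from ssvep_rca.synth import RawRecording, SensorMontage, StimulusSchedule

__all__ = ["save_recordings", "load_recordings", "save_montage", "load_montage",
           "save_schedule", "load_schedule"]


def save_montage(path: Path, montage: SensorMontage) -> None:
    payload = [
        {
            "sensor": s,
            "x": float(montage.positions[s, 0]),
            "y": float(montage.positions[s, 1]),
            "z": float(montage.positions[s, 2]),
            "neighbors": list(montage.adjacency[s]),
        }
        for s in range(montage.n_sensors)
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def load_montage(path: Path) -> SensorMontage:
    payload = json.loads(Path(path).read_text())
    pos = np.array([[row["x"], row["y"], row["z"]] for row in payload])
    adj = tuple(tuple(int(n) for n in row["neighbors"]) for row in payload)
    return SensorMontage(positions=pos, adjacency=adj)


def save_schedule(path: Path, schedule: StimulusSchedule) -> None:
    Path(path).write_text(json.dumps({
        "base_hz": schedule.base_hz,
        "deviant_hz": schedule.deviant_hz,
        "items_per_deviant": schedule.items_per_deviant,
        "trial_duration_s": schedule.trial_duration_s,
        "n_trials": schedule.n_trials,
        "item_labels": list(schedule.item_labels),
    }, indent=1))


def load_schedule(path: Path) -> StimulusSchedule:
    d = json.loads(Path(path).read_text())
    return StimulusSchedule(
        base_hz=d["base_hz"],
        deviant_hz=d["deviant_hz"],
        items_per_deviant=d["items_per_deviant"],
        trial_duration_s=d["trial_duration_s"],
        n_trials=d["n_trials"],
        item_labels=tuple(d["item_labels"]),
    )


def save_recordings(out_dir: Path, recordings: list[RawRecording]) -> None:
    """One HDF5 file per condition holding per-subject datasets, plus JSON
    sidecars for montage and schedules."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_condition: dict[str, list[RawRecording]] = {}
    for rec in recordings:
        by_condition.setdefault(rec.condition_id, []).append(rec)
    save_montage(out_dir / "montage.json", recordings[0].montage)
    for cond, recs in by_condition.items():
        save_schedule(out_dir / f"schedule_{cond}.json", recs[0].schedule)
        with h5py.File(out_dir / f"eeg_{cond}.h5", "w") as h5:
            h5.attrs["condition_id"] = cond
            for rec in recs:
                ds = h5.create_dataset(rec.subject_id, data=rec.data,
                                       compression="gzip")
                ds.attrs["fs"] = rec.fs
                ds.attrs["units"] = "uV"


def load_recordings(data_dir: Path, condition_id: str) -> list[RawRecording]:
    data_dir = Path(data_dir)
    montage = load_montage(data_dir / "montage.json")
    schedule = load_schedule(data_dir / f"schedule_{condition_id}.json")
    recordings: list[RawRecording] = []
    with h5py.File(data_dir / f"eeg_{condition_id}.h5", "r") as h5:
        for subject_id in sorted(h5.keys()):
            ds = h5[subject_id]
            recordings.append(RawRecording(
                data=ds[()],
                fs=float(ds.attrs["fs"]),
                montage=montage,
                schedule=schedule,
                condition_id=condition_id,
                subject_id=subject_id,
            ))
    return recordings
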