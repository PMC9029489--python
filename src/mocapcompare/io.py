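"""Plain-text file formats for streams, angle series, events, and configs.

Directory layout of a study::

    study/
      manifest.json                      # subjects/tasks/trials, rates
      truth_ledger.json                  # injected parameters (synthetic only)
      joints.json                        # joint definitions + placements
      <subject>_<task>_<trial>/
        sensor_<placement>.csv           # time,w,x,y,z (scalar-first), header
        <system>_<joint>_<dof>.csv       # time,value_deg,valid
        <system>_<joint>_<dof>.meta.json # joint, dof, system, rate, t0
        events.csv                       # trial_id,start_index,end_index

All files are delimited text or JSON; indices are 0-based on the 100 Hz
reference timeline and windows are closed on both ends.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .kinematics import (
    JointAngleSeries,
    JointDefinition,
    OrientationStream,
    SensorPlacement,
    default_joint_definitions,
    default_placements,
)
from .segment import SegmentEventSet, validate_events
from .trial import TrialRecord


# ---------------------------------------------------------------------------
# orientation streams
# ---------------------------------------------------------------------------

def write_orientation_stream(stream: OrientationStream, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "time": stream.times,
            "w": stream.quats[:, 0],
            "x": stream.quats[:, 1],
            "y": stream.quats[:, 2],
            "z": stream.quats[:, 3],
        }
    )
    df.to_csv(path, index=False)


def read_orientation_stream(path: str | Path, sensor_id: str) -> OrientationStream:
    df = pd.read_csv(path)
    required = {"time", "w", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ConfigurationError(
            f"{path}: expected header columns {sorted(required)}"
        )
    t = df["time"].to_numpy(dtype=float)
    if len(t) < 2:
        rate = 100.0
    else:
        rate = 1.0 / float(np.median(np.diff(t)))
    return OrientationStream(
        sensor_id=sensor_id,
        rate=rate,
        quats=df[["w", "x", "y", "z"]].to_numpy(dtype=float),
        t0=float(t[0]),
    )


# ---------------------------------------------------------------------------
# joint-angle series
# ---------------------------------------------------------------------------

def write_angle_series(series: JointAngleSeries, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(
        {
            "time": series.times,
            "value_deg": series.values,
            "valid": series.quality_mask.astype(int),
        }
    ).to_csv(path, index=False)
    meta = {
        "joint": series.joint,
        "dof": series.dof,
        "system": series.system,
        "rate": series.rate,
        "t0": series.t0,
    }
    path.with_suffix(".meta.json").write_text(json.dumps(meta, sort_keys=True))


def read_angle_series(path: str | Path) -> JointAngleSeries:
    path = Path(path)
    meta = json.loads(path.with_suffix(".meta.json").read_text())
    df = pd.read_csv(path)
    return JointAngleSeries(
        joint=meta["joint"],
        dof=meta["dof"],
        system=meta["system"],
        rate=float(meta["rate"]),
        values=df["value_deg"].to_numpy(dtype=float),
        quality_mask=df["valid"].to_numpy(dtype=bool),
        t0=float(meta.get("t0", 0.0)),
    )


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

def write_events(events: SegmentEventSet, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"trial_id": events.trial_id, "start_index": s, "end_index": e}
            for s, e in events.segments
        ]
    ).to_csv(path, index=False)


def read_events(path: str | Path) -> SegmentEventSet:
    df = pd.read_csv(path)
    trial_id = str(df["trial_id"].iloc[0]) if len(df) else "trial"
    return validate_events(
        df[["start_index", "end_index"]].itertuples(index=False), trial_id=trial_id
    )


# ---------------------------------------------------------------------------
# joint/placement config
# ---------------------------------------------------------------------------

def write_joint_config(path: str | Path, joints=None, placements=None) -> None:
    joints = joints or default_joint_definitions()
    placements = placements or default_placements()
    payload = {
        "joints": {
            name: {
                "parent_sensor": jd.parent_sensor,
                "child_sensor": jd.child_sensor,
                "euler_order": jd.euler_order,
                "dof_labels": list(jd.dof_labels),
                "sign_flips": list(jd.sign_flips),
                "anatomical_limits": [list(l) for l in jd.anatomical_limits],
            }
            for name, jd in joints.items()
        },
        "placements": {
            sid: {"segment": p.segment, "si_axis": list(p.si_axis)}
            for sid, p in placements.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_joint_config(path: str | Path):
    payload = json.loads(Path(path).read_text())
    joints = {
        name: JointDefinition(
            joint=name,
            parent_sensor=d["parent_sensor"],
            child_sensor=d["child_sensor"],
            euler_order=d["euler_order"],
            dof_labels=tuple(d["dof_labels"]),
            sign_flips=tuple(d["sign_flips"]),
            anatomical_limits=tuple(tuple(l) for l in d["anatomical_limits"]),
        )
        for name, d in payload["joints"].items()
    }
    placements = {
        sid: SensorPlacement(sensor_id=sid, segment=d["segment"], si_axis=d["si_axis"])
        for sid, d in payload["placements"].items()
    }
    return joints, placements


# ---------------------------------------------------------------------------
# study directories
# ---------------------------------------------------------------------------

def write_study(
    trials: list[TrialRecord],
    outdir: str | Path,
    ledger: dict | None = None,
    joints=None,
    placements=None,
) -> None:
    """Write a full study directory in the documented text layout."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"trials": []}
    for trial in trials:
        tdir = outdir / trial.trial_id
        tdir.mkdir(exist_ok=True)
        for sid, stream in trial.sensors.items():
            write_orientation_stream(stream, tdir / f"sensor_{sid}.csv")
        for system, chans in trial.series.items():
            for (joint, dof), s in chans.items():
                write_angle_series(s, tdir / f"{system}_{joint}_{dof}.csv")
        if trial.events is not None:
            write_events(trial.events, tdir / "events.csv")
        manifest["trials"].append(
            {
                "trial_id": trial.trial_id,
                "subject": trial.subject,
                "task": trial.task,
                "trial": trial.trial,
            }
        )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    write_joint_config(outdir / "joints.json", joints, placements)
    if ledger is not None:
        (outdir / "truth_ledger.json").write_text(
            json.dumps(ledger, indent=1, sort_keys=True, default=float)
        )


def load_study(indir: str | Path) -> list[TrialRecord]:
    """Load a study directory written by :func:`write_study`."""
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    trials: list[TrialRecord] = []
    for entry in manifest["trials"]:
        tdir = indir / entry["trial_id"]
        sensors = {}
        series: dict[str, dict] = {}
        for f in sorted(tdir.glob("sensor_*.csv")):
            sid = f.stem[len("sensor_") :]
            sensors[sid] = read_orientation_stream(f, sensor_id=sid)
        for f in sorted(tdir.glob("*.meta.json")):
            s = read_angle_series(f.with_suffix("").with_suffix(".csv"))
            series.setdefault(s.system, {})[(s.joint, s.dof)] = s
        events = None
        if (tdir / "events.csv").exists():
            events = read_events(tdir / "events.csv")
        trials.append(
            TrialRecord(
                subject=entry["subject"],
                task=entry["task"],
                trial=int(entry["trial"]),
                series=series,
                sensors=sensors,
                events=events,
            )
        )
    return trials
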