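"""Reading and writing the package's file formats.

Two recording container layouts are supported:

* **csv** — a directory per session: ``session.json`` with the session
  metadata, then one sub-directory per passage (``passage_00`` ...)
  holding one RFC-4180 CSV per sensor with columns
  ``t, ax, ay, az, gx, gy, gz, qw, qx, qy, qz``
  (time in s; acceleration m/s^2; angular velocity rad/s; scalar-first
  unit quaternion, sensor-to-global).  Floats are written with 17
  significant digits, so a round trip is bit-exact for float64.
* **hdf5** — a single file mirroring the same hierarchy
  (``/passage_00/ST/{acc,gyro,quat}``) with metadata in attributes.

Indicator tables are plain CSV with the fixed column order
``horse, gait, sensor, side, channel, indicator, scope, run, value``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .datamodel import (
    Gait,
    Run,
    SensorLocation,
    SensorRecording,
    Session,
    ValidationError,
)

RECORDING_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz", "qw", "qx", "qy", "qz"]
INDICATOR_COLUMNS = [
    "horse", "gait", "sensor", "side", "channel", "indicator", "scope", "run", "value",
]
_FLOAT_FMT = "%.17g"

__all__ = [
    "load_recording",
    "write_recording",
    "write_indicator_table",
    "read_indicator_table",
    "RECORDING_COLUMNS",
    "INDICATOR_COLUMNS",
]


def _passage_name(i: int) -> str:
    return f"passage_{i:02d}"


# ---------------------------------------------------------------------------
# recording containers


def write_recording(session: Session, path, format: str = "csv",
                    write_truth: bool = False) -> None:
    """Write a :class:`Session` to a recording container.

    ``write_truth`` additionally stores the generator ground truth
    (stride onset times) when present; the sidecar is for oracle tests
    only and is ignored by :func:`load_recording`.
    """
    path = Path(path)
    if format == "csv":
        _write_csv(session, path, write_truth)
    elif format in ("hdf5", "h5", "hdf5-container"):
        _write_hdf5(session, path, write_truth)
    else:
        raise ValueError(f"unknown container format {format!r}")


def load_recording(path, format: str | None = None) -> Session:
    """Load a recording container written by :func:`write_recording`."""
    path = Path(path)
    if format is None:
        format = "csv" if path.is_dir() else "hdf5"
    if format == "csv":
        return _load_csv(path)
    if format in ("hdf5", "h5", "hdf5-container"):
        return _load_hdf5(path)
    raise ValueError(f"unknown container format {format!r}")


def _write_csv(session: Session, root: Path, write_truth: bool) -> None:
    root.mkdir(parents=True, exist_ok=True)
    meta = {
        "horse_id": session.horse_id,
        "gait": session.gait.value,
        "run": session.run.value,
        "fs": session.fs,
        "n_passages": len(session.passages),
        "sensors": session.sensor_keys(),
    }
    (root / "session.json").write_text(json.dumps(meta, indent=1) + "\n")
    for i, passage in enumerate(session.passages):
        pdir = root / _passage_name(i)
        pdir.mkdir(exist_ok=True)
        for key, rec in passage.items():
            t = np.arange(rec.n_samples) / rec.fs
            data = np.column_stack([t, rec.acc, rec.gyro, rec.quat])
            header = ",".join(RECORDING_COLUMNS)
            np.savetxt(pdir / f"{key}.csv", data, fmt=_FLOAT_FMT,
                       delimiter=",", header=header, comments="")
    if write_truth and session.truth is not None:
        truth = {"stride_onsets": [list(map(float, o))
                                   for o in session.truth["stride_onsets"]]}
        (root / "truth.json").write_text(json.dumps(truth) + "\n")
        # generating global accelerations, one sidecar per sensor (test use)
        for i, passage_truth in enumerate(session.truth.get("a_global", [])):
            pdir = root / _passage_name(i)
            for key, a_global in passage_truth.items():
                np.savetxt(pdir / f"{key}.truth.csv", a_global, fmt=_FLOAT_FMT,
                           delimiter=",", header="agx,agy,agz", comments="")


def _load_csv(root: Path) -> Session:
    meta_path = root / "session.json"
    if not meta_path.exists():
        raise ValidationError(f"{root}: missing session.json")
    meta = json.loads(meta_path.read_text())
    passages = []
    for i in range(int(meta["n_passages"])):
        pdir = root / _passage_name(i)
        passage = {}
        for key in meta["sensors"]:
            fpath = pdir / f"{key}.csv"
            if not fpath.exists():
                raise ValidationError(f"sensor {key}: missing stream file {fpath}")
            df = pd.read_csv(fpath, float_precision="round_trip")
            missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
            if missing:
                raise ValidationError(f"sensor {key}: missing columns {missing}")
            passage[key] = _make_recording(key, float(meta["fs"]), df)
        passages.append(passage)
    return Session(
        horse_id=meta["horse_id"], gait=Gait(meta["gait"]), run=Run(meta["run"]),
        passages=passages,
    )


def _make_recording(key: str, fs: float, df: pd.DataFrame) -> SensorRecording:
    loc = SensorLocation.from_key(key)
    acc = df[["ax", "ay", "az"]].to_numpy(float)
    gyro = df[["gx", "gy", "gz"]].to_numpy(float)
    quat = df[["qw", "qx", "qy", "qz"]].to_numpy(float)
    try:
        return SensorRecording(location=loc, fs=fs, acc=acc, gyro=gyro, quat=quat)
    except ValidationError:
        raise


def _write_hdf5(session: Session, path: Path, write_truth: bool) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["horse_id"] = session.horse_id
        f.attrs["gait"] = session.gait.value
        f.attrs["run"] = session.run.value
        f.attrs["fs"] = session.fs
        for i, passage in enumerate(session.passages):
            g = f.create_group(_passage_name(i))
            for key, rec in passage.items():
                sg = g.create_group(key)
                sg.create_dataset("acc", data=rec.acc)
                sg.create_dataset("gyro", data=rec.gyro)
                sg.create_dataset("quat", data=rec.quat)
        if write_truth and session.truth is not None:
            tg = f.create_group("truth")
            for i, onsets in enumerate(session.truth["stride_onsets"]):
                tg.create_dataset(f"stride_onsets_{i:02d}", data=np.asarray(onsets))


def _load_hdf5(path: Path) -> Session:
    if not Path(path).exists():
        raise ValidationError(f"no such container: {path}")
    with h5py.File(path, "r") as f:
        fs = float(f.attrs["fs"])
        passages = []
        names = sorted(k for k in f.keys() if k.startswith("passage_"))
        for name in names:
            g = f[name]
            passage = {}
            for key in sorted(g.keys()):
                sg = g[key]
                for stream in ("acc", "gyro", "quat"):
                    if stream not in sg:
                        raise ValidationError(f"sensor {key}: missing stream {stream!r}")
                loc = SensorLocation.from_key(key)
                passage[key] = SensorRecording(
                    location=loc, fs=fs,
                    acc=sg["acc"][()], gyro=sg["gyro"][()], quat=sg["quat"][()],
                )
            passages.append(passage)
        return Session(
            horse_id=str(f.attrs["horse_id"]), gait=Gait(str(f.attrs["gait"])),
            run=Run(str(f.attrs["run"])), passages=passages,
        )


# ---------------------------------------------------------------------------
# indicator tables


def _record_key(r) -> tuple:
    return (r.horse, str(r.gait), str(r.sensor), str(r.side), r.channel,
            str(r.indicator), str(r.scope), str(r.run))


def write_indicator_table(records, path) -> None:
    """Write indicator records to CSV (fixed column order, lossless floats).

    Records must be unique on (horse, gait, sensor, side, channel,
    indicator, scope, run).
    """
    records = list(records)
    if not records:
        raise ValueError("no indicator records to write")
    seen: dict = {}
    for r in records:
        k = _record_key(r)
        if k in seen:
            raise ValueError(f"duplicate indicator record key: {k}")
        seen[k] = r
    df = pd.DataFrame(
        [
            {
                "horse": r.horse, "gait": str(r.gait), "sensor": str(r.sensor),
                "side": str(r.side), "channel": r.channel,
                "indicator": str(r.indicator), "scope": str(r.scope),
                "run": str(r.run), "value": r.value,
            }
            for r in records
        ],
        columns=INDICATOR_COLUMNS,
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_indicator_table(path):
    """Read an indicator CSV back into a list of IndicatorRecord."""
    from .strides import IndicatorRecord

    df = pd.read_csv(path, keep_default_na=False, na_values=["nan", ""],
                     float_precision="round_trip")
    missing = [c for c in INDICATOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"indicator table missing columns {missing}")
    return [
        IndicatorRecord(
            horse=str(row.horse), gait=str(row.gait), sensor=str(row.sensor),
            side=str(row.side), channel=str(row.channel),
            indicator=str(row.indicator), scope=str(row.scope),
            run=str(row.run), value=float(row.value),
        )
        for row in df.itertuples()
    ]
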