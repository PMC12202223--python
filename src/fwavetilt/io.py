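"""Plain-text readers and writers for records, truth, beats and results.

Formats are deliberately simple and self-describing:

* ECG records: tab-separated text, one ``time_s`` column plus one column per
  lead, with ``# key=value`` header comments (fs, leads) and the phase
  timeline in a JSON sidecar (``<stem>.timeline.json``).
* Ground truth: a JSON sidecar.
* Activation sets: two-column CSV (``point_id, activation_time_s``) or JSON.
* Beat annotations: CSV (sample index, label N/V).
* Results: CSV with snake_case columns, units in a header comment.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import BeatSet, ECGRecord
from .synthetic import ActivationSet, GroundTruth

__all__ = [
    "write_record", "read_record",
    "write_ground_truth", "read_ground_truth",
    "write_activation_set", "read_activation_set",
    "write_beats", "write_results", "read_results",
]


def write_record(record: ECGRecord, path) -> Path:
    """Write an ECG record as delimited text plus a timeline JSON sidecar."""
    path = Path(path)
    t = np.arange(record.samples.shape[1]) / record.fs
    with open(path, "w") as fh:
        fh.write(f"# fs={record.fs}\n")
        fh.write(f"# leads={','.join(record.lead_names)}\n")
        fh.write("time_s\t" + "\t".join(record.lead_names) + "\n")
        np.savetxt(fh, np.column_stack([t, record.samples.T]), fmt="%.6f",
                   delimiter="\t")
    sidecar = path.with_suffix(path.suffix + ".timeline.json")
    with open(sidecar, "w") as fh:
        json.dump([list(p) for p in record.timeline], fh)
    return path


def read_record(path, timeline: list | None = None) -> ECGRecord:
    """Read a delimited-text ECG record (tab or comma separated).

    The phase timeline is taken from the JSON sidecar when present, else
    from the ``timeline`` argument.
    """
    path = Path(path)
    fs = None
    leads: list[str] | None = None
    header_rows = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                header_rows += 1
                body = line[1:].strip()
                if body.startswith("fs="):
                    fs = float(body[3:])
                elif body.startswith("leads="):
                    leads = body[6:].split(",")
            else:
                break
    sep = "\t" if "\t" in line else ","
    df = pd.read_csv(path, sep=sep, skiprows=header_rows)
    cols = list(df.columns)
    if cols[0].lower() not in ("time_s", "time", "t"):
        raise ValueError(f"first column of {path} must be time_s")
    tcol = df[cols[0]].to_numpy()
    if fs is None:
        dt = np.median(np.diff(tcol))
        fs = float(round(1.0 / dt))
    if leads is None:
        leads = cols[1:]
    sidecar = path.with_suffix(path.suffix + ".timeline.json")
    if timeline is None and sidecar.exists():
        with open(sidecar) as fh:
            timeline = [tuple(p) for p in json.load(fh)]
    if timeline is None:
        raise ValueError("no phase timeline: provide a sidecar or the timeline argument")
    samples = df[cols[1:]].to_numpy().T
    return ECGRecord(samples=samples, fs=fs, lead_names=leads,
                     timeline=[tuple(p) for p in timeline])


def write_ground_truth(truth: GroundTruth, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh)
    return path


def read_ground_truth(path) -> GroundTruth:
    with open(path) as fh:
        return GroundTruth.from_dict(json.load(fh))


def write_activation_set(aset: ActivationSet, path) -> Path:
    """Two-column CSV: point_id, activation_time_s."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("point_id,activation_time_s\n")
        for pid in sorted(aset.times):
            for t in aset.times[pid]:
                fh.write(f"{pid},{t:.6f}\n")
    return path


def read_activation_set(path) -> ActivationSet:
    """Read an activation set from CSV (point_id, activation_time_s) or JSON."""
    path = Path(path)
    if path.suffix == ".json":
        with open(path) as fh:
            d = json.load(fh)
        times = {k: np.asarray(v, dtype=float) for k, v in d["times"].items()}
        return ActivationSet(times=times, duration=float(d["duration"]),
                             truth=d.get("truth"))
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"empty activation file: {path}")
    if not {"point_id", "activation_time_s"} <= set(df.columns):
        raise ValueError(f"{path}: need columns point_id, activation_time_s")
    times = {
        str(pid): np.sort(g["activation_time_s"].to_numpy(dtype=float))
        for pid, g in df.groupby("point_id")
    }
    duration = float(df["activation_time_s"].max())
    return ActivationSet(times=times, duration=duration)


def write_beats(beats: BeatSet, path) -> Path:
    """Beat annotations as CSV: sample index, label (N normal / V ectopic)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("sample,label\n")
        for r, e in zip(beats.r_peaks, beats.ectopic):
            fh.write(f"{int(r)},{'V' if e else 'N'}\n")
    return path


RESULT_UNITS = ("# units: ff=Hz fhr=bpm frr=Hz delta_ff=Hz pr=percent\n")


def write_results(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(RESULT_UNITS)
        table.to_csv(fh, index=False)
    return path


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
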