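"""On-disk formats: the epoch container, rating tables, RDMs, timecourses.

The epoch container is a directory with three files:

* ``epochs.bin``  — 32-bit little-endian floats, C order,
  trials x channels x timepoints;
* ``meta.json``   — dimensions, channel labels, ``sample_rate_hz`` and
  ``time_zero_index`` (the sample at stimulus onset);
* ``events.csv``  — one row per trial: ``trial,sequence,block,stimulus_id``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EVENT_COLUMNS, EpochSet


class FormatError(ValueError):
    """Raised when an on-disk container is inconsistent with its sidecar."""


def write_epochs(epochs: EpochSet, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    data = np.ascontiguousarray(epochs.data, dtype="<f4")
    data.tofile(path / "epochs.bin")
    meta = {
        "n_trials": epochs.n_trials,
        "n_channels": epochs.n_channels,
        "n_times": epochs.n_times,
        "channels": list(epochs.channels),
        "sample_rate_hz": float(epochs.sample_rate),
        "time_zero_index": int(round(-epochs.times[0] / (1000.0 / epochs.sample_rate))),
        "bad_channels": sorted(epochs.bad_channels),
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    epochs.events[EVENT_COLUMNS].to_csv(path / "events.csv", index=False)
    return path


def read_epochs(path: str | Path) -> EpochSet:
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    shape = (meta["n_trials"], meta["n_channels"], meta["n_times"])
    expected = int(np.prod(shape))
    raw = np.fromfile(path / "epochs.bin", dtype="<f4")
    if raw.size != expected:
        raise FormatError(
            f"epochs.bin holds {raw.size} samples, meta.json promises {expected} "
            f"(trials x channels x timepoints = {shape})"
        )
    events = pd.read_csv(path / "events.csv")
    if len(events) != meta["n_trials"]:
        raise FormatError(
            f"events.csv has {len(events)} rows, meta.json promises {meta['n_trials']} trials"
        )
    period = 1000.0 / meta["sample_rate_hz"]
    times = (np.arange(meta["n_times"]) - meta["time_zero_index"]) * period
    return EpochSet(
        data=raw.reshape(shape).astype(np.float32),
        times=times,
        sample_rate=meta["sample_rate_hz"],
        channels=list(meta["channels"]),
        events=events,
        bad_channels=set(meta.get("bad_channels", [])),
    )


def write_ratings(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table[["stimulus_id", "rater_id", "attribute", "rating"]].to_csv(path, index=False)
    return path


def read_ratings(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    required = {"stimulus_id", "rater_id", "attribute", "rating"}
    missing = required - set(table.columns)
    if missing:
        raise FormatError(f"ratings table missing columns {sorted(missing)}")
    return table


def write_rdm(rdm, path: str | Path) -> Path:
    """Condensed CSV: a header line with the condition-id order, then values."""
    from .containers import RDM  # local to avoid cycle in type-only use

    assert isinstance(rdm, RDM)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# ids=" + ",".join(str(i) for i in rdm.condition_ids.tolist()))
        fh.write(f" metric={rdm.metric}\n")
        fh.write("dissimilarity\n")
        np.savetxt(fh, rdm.condensed, fmt="%.8g")
    return path


def read_rdm(path: str | Path):
    from .containers import RDM

    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# ids="):
            raise FormatError("condensed RDM file must start with '# ids=' header")
        body, _, metric = header[len("# ids=") :].partition(" metric=")
        ids = np.array([int(x) for x in body.split(",")])
        fh.readline()  # column name
        values = np.loadtxt(fh, ndmin=1)
    return RDM(ids, values, metric or "unspecified")


def write_timecourse(times: np.ndarray, values: np.ndarray, path: str | Path,
                     value_name: str = "accuracy") -> Path:
    """Long-format CSV (time_ms, subject, value) for per-subject stacks."""
    values = np.atleast_2d(values)
    frames = []
    for s, row in enumerate(values):
        frames.append(pd.DataFrame({"time_ms": times, "subject": s, value_name: row}))
    out = pd.concat(frames, ignore_index=True)
    path = Path(path)
    out.to_csv(path, index=False)
    return path


def read_timecourse(path: str | Path, value_name: str = "accuracy"):
    df = pd.read_csv(path)
    times = np.sort(df["time_ms"].unique())
    subjects = np.sort(df["subject"].unique())
    stack = np.full((len(subjects), len(times)), np.nan)
    t_idx = {t: i for i, t in enumerate(times)}
    s_idx = {s: i for i, s in enumerate(subjects)}
    for _, row in df.iterrows():
        stack[s_idx[row["subject"]], t_idx[row["time_ms"]]] = row[value_name]
    if np.isnan(stack).any():
        raise FormatError("timecourse CSV does not cover the full subject x time grid")
    return times, stack
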