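"""Plain-text readers and writers for spike trains, current traces and tables.

Formats (all diffable text):

* spike-train CSV — columns ``unit_id,spike_time_s[,spike_duration_ms]``,
  one row per spike, plus a JSON sidecar keyed by unit_id carrying
  ``epoch_duration_s``, ``group``, ``condition`` and ``setting``;
* trace CSV — ``# key=value`` header lines (``sampling_rate_hz``,
  ``holding_potential_mv``, ``protocol``, optionally ``cell_id``, ``group``
  and ``stimulus_marks`` as JSON) followed by a single ``current_pa``
  column;
* summary CSV — one row per cell, written/read via pandas with a stable
  column order.

Round trips are lossless at double precision (floats are serialized with
``repr``-level precision).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CurrentTrace, SpikeTrain
from .errors import FormatError, ValidationError

_FLOAT_FMT = "%.17g"


def write_spike_trains(trains: list[SpikeTrain], csv_path, meta_path=None) -> None:
    """Write spike trains to CSV + JSON metadata sidecar.

    If ``meta_path`` is None it defaults to ``csv_path`` with a
    ``.meta.json`` suffix.
    """
    csv_path = Path(csv_path)
    meta_path = Path(meta_path) if meta_path else csv_path.with_suffix(".meta.json")
    frames = []
    meta: dict[str, dict] = {}
    for tr in trains:
        df = pd.DataFrame({"unit_id": tr.unit_id, "spike_time_s": tr.spike_times})
        if tr.spike_durations is not None:
            df["spike_duration_ms"] = tr.spike_durations
        frames.append(df)
        meta[tr.unit_id] = {
            "epoch_duration_s": tr.epoch_duration,
            "group": tr.group,
            "condition": tr.condition,
            "setting": tr.setting,
        }
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=["unit_id", "spike_time_s"])
    out.to_csv(csv_path, index=False, float_format=_FLOAT_FMT)
    meta_path.write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_spike_trains(csv_path, meta_path=None) -> list[SpikeTrain]:
    """Read spike trains written by :func:`write_spike_trains`.

    Raises
    ------
    FormatError
        Missing required columns or missing/unreadable metadata sidecar.
    ValidationError
        Spike times not strictly increasing within a unit (names the unit).
    """
    csv_path = Path(csv_path)
    meta_path = Path(meta_path) if meta_path else csv_path.with_suffix(".meta.json")
    if not meta_path.exists():
        raise FormatError(f"metadata sidecar not found: {meta_path}")
    meta = json.loads(meta_path.read_text())
    df = pd.read_csv(csv_path, float_precision="round_trip")
    required = {"unit_id", "spike_time_s"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{csv_path}: missing columns {sorted(required - set(df.columns))}"
        )
    trains = []
    # preserve first-appearance order of units, plus units with zero spikes
    seen = list(dict.fromkeys(df["unit_id"].astype(str)))
    for uid in seen + [u for u in meta if u not in seen]:
        sub = df[df["unit_id"].astype(str) == uid]
        if uid not in meta:
            raise FormatError(f"unit {uid}: no metadata entry in {meta_path}")
        m = meta[uid]
        durations = None
        if "spike_duration_ms" in sub.columns and sub["spike_duration_ms"].notna().all():
            durations = sub["spike_duration_ms"].to_numpy()
        times = sub["spike_time_s"].to_numpy()
        if times.size and np.any(np.diff(times) <= 0):
            raise ValidationError(f"unit {uid}: spike times not strictly increasing")
        trains.append(
            SpikeTrain(
                unit_id=uid,
                spike_times=times,
                epoch_duration=float(m["epoch_duration_s"]),
                spike_durations=durations,
                group=m.get("group", ""),
                condition=m.get("condition", ""),
                setting=m.get("setting", "in_vivo"),
            )
        )
    return trains


def write_current_trace(trace: CurrentTrace, path) -> None:
    """Write a trace as ``# key=value`` header lines + one current_pa column."""
    path = Path(path)
    lines = [
        f"# sampling_rate_hz={trace.sampling_rate!r}",
        f"# holding_potential_mv={trace.holding_potential!r}",
        f"# protocol={trace.protocol}",
        f"# cell_id={trace.cell_id}",
        f"# group={trace.group}",
        f"# stimulus_marks={json.dumps(trace.stimulus_marks)}",
        "current_pa",
    ]
    body = "\n".join(_FLOAT_FMT % x for x in trace.current)
    path.write_text("\n".join(lines) + "\n" + body + "\n")


def read_current_trace(path) -> CurrentTrace:
    """Read a trace written by :func:`write_current_trace`.

    Raises
    ------
    FormatError
        Missing ``sampling_rate_hz`` header or malformed file.
    ValidationError
        NaN/Inf samples (via the CurrentTrace invariant).
    """
    path = Path(path)
    header: dict[str, str] = {}
    samples: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                header[key.strip()] = val.strip()
            elif line != "current_pa":
                samples.append(line)
    if "sampling_rate_hz" not in header:
        raise FormatError(f"{path}: missing sampling_rate_hz header")
    marks = [
        (float(t), str(d))
        for t, d in json.loads(header.get("stimulus_marks", "[]"))
    ]
    current = np.asarray(samples, dtype=float)
    return CurrentTrace(
        cell_id=header.get("cell_id", path.stem),
        sampling_rate=float(header["sampling_rate_hz"]),
        current=current,
        holding_potential=float(header.get("holding_potential_mv", "nan")),
        group=header.get("group", ""),
        protocol=header.get("protocol", "mipsc"),
        stimulus_marks=marks,
    )


def write_summary_table(records: list, path, record_type=None) -> pd.DataFrame:
    """Write homogeneous dataclass records as a one-row-per-cell CSV.

    Column order follows the dataclass field order. An empty list writes a
    header-only CSV when ``record_type`` names the dataclass.

    Raises
    ------
    TypeError
        Records of mixed types, or an empty list without ``record_type``.
    """
    t0 = type(records[0]) if records else record_type
    if t0 is None:
        raise TypeError("empty record list requires record_type for the header")
    if any(type(r) is not t0 for r in records):
        raise TypeError("write_summary_table requires homogeneous records")
    if not dataclasses.is_dataclass(t0):
        raise TypeError("records must be dataclasses")
    cols = [f.name for f in dataclasses.fields(t0)]
    df = pd.DataFrame([dataclasses.asdict(r) for r in records], columns=cols)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return df


def read_summary_table(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")
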