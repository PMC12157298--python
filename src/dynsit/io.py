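"""File formats: frame tables (CSV), classification streams (JSON-lines or
CSV), reminder events (JSON-lines) and scaler parameters (JSON)."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .engine import ReminderEvent
from .postures import CHANNELS, Posture
from .simulate import FRAME_COLUMNS, ClassificationStream


def write_frames(frames: pd.DataFrame, path: str | Path) -> None:
    frames.to_csv(path, index=False, columns=FRAME_COLUMNS)


def read_frames(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(FRAME_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"frame table missing columns: {sorted(missing)}")
    return df


def write_stream(stream: ClassificationStream, path: str | Path) -> None:
    """JSON-lines (`{"t": ..., "posture": ...}`) or CSV by file suffix."""
    path = Path(path)
    if path.suffix == ".csv":
        stream.to_frame().to_csv(path, index=False)
        return
    with open(path, "w", encoding="utf-8") as fh:
        for t, p in stream.ticks:
            fh.write(json.dumps({"t": int(t), "posture": int(p)}) + "\n")


def read_stream(path: str | Path) -> ClassificationStream:
    path = Path(path)
    if path.suffix == ".csv":
        return ClassificationStream.from_frame(pd.read_csv(path))
    ticks = []
    for line in path.read_text(encoding="utf-8").splitlines():
        if line.strip():
            d = json.loads(line)
            ticks.append((int(d["t"]), Posture(int(d["posture"]))))
    return ClassificationStream(ticks)


def write_events(events: Sequence[ReminderEvent], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for e in events:
            fh.write(json.dumps(e.to_dict()) + "\n")


def read_events(path: str | Path) -> list[ReminderEvent]:
    events = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if line.strip():
            d = json.loads(line)
            posture = None if d["posture"] is None else Posture(int(d["posture"]))
            events.append(
                ReminderEvent(d["kind"], int(d["t"]), posture,
                              (d["freq_hz"], d["dur_s"]))
            )
    return events


def write_scaler_params(
    params: Mapping[str, tuple[float, float]], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({c: list(params[c]) for c in CHANNELS}, fh, indent=2)


def read_scaler_params(path: str | Path) -> dict[str, tuple[float, float]]:
    d = json.loads(Path(path).read_text(encoding="utf-8"))
    return {c: (float(d[c][0]), float(d[c][1])) for c in CHANNELS}
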