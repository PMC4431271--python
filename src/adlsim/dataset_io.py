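"""CSV input/output for labelled sensor-event datasets.

The native dialect is a four-column RFC-4180 style CSV with header
``timestamp,sensor,label,marker``: ISO-8601 timestamps at second
resolution, the literal label ``None`` for noise events, and marker one of
``""``, ``start``, ``end`` or ``start+end`` (the last for an activity
instance reduced to a single surviving activation).

External event logs for comparison need only ``timestamp,sensor`` columns;
an optional ``label`` column is preserved and missing labels become the
placeholder ``unlabelled``.
"""

from __future__ import annotations

import csv
from datetime import datetime
from pathlib import Path

import pandas as pd

from .simulator import (
    MARKER_BOTH,
    MARKER_END,
    MARKER_NONE,
    MARKER_START,
    LabelledDataset,
    SensorEvent,
)

__all__ = ["write_dataset_csv", "read_dataset_csv", "read_external_events"]

HEADER = ["timestamp", "sensor", "label", "marker"]
_MARKERS = {MARKER_NONE, MARKER_START, MARKER_END, MARKER_BOTH}

#: label given to events of an external log that carries no label column
UNLABELLED = "unlabelled"


class DatasetFormatError(ValueError):
    """Malformed dataset file; carries the offending line number."""


def write_dataset_csv(ds: LabelledDataset, path: str | Path) -> None:
    """Write ``ds`` in the native dialect; re-reading reproduces the events."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(HEADER)
        for ev in ds.events:
            label = "None" if ev.label is None else ev.label
            writer.writerow([ev.timestamp.isoformat(), ev.sensor_name, label, ev.marker])


def read_dataset_csv(path: str | Path) -> LabelledDataset:
    """Read a native-dialect file back into a :class:`LabelledDataset`.

    The inverse of :func:`write_dataset_csv` on the event list; activity
    instances are not persisted in CSV, so ``instances`` comes back empty
    and the span is inferred from the first/last event days.
    """
    events: list[SensorEvent] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise DatasetFormatError(f"{path}: empty file (missing header)")
        if header != HEADER:
            raise DatasetFormatError(f"{path}: line 1: expected header {','.join(HEADER)}")
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 4:
                raise DatasetFormatError(f"{path}: line {line_no}: expected 4 fields, got {len(row)}")
            ts_txt, sensor, label, marker = row
            try:
                ts = datetime.fromisoformat(ts_txt)
            except ValueError:
                raise DatasetFormatError(f"{path}: line {line_no}: malformed timestamp {ts_txt!r}")
            if marker not in _MARKERS:
                raise DatasetFormatError(f"{path}: line {line_no}: unknown marker {marker!r}")
            events.append(
                SensorEvent(ts, sensor, None if label == "None" else label, marker)
            )
    if events:
        span = (min(e.timestamp for e in events).date(), max(e.timestamp for e in events).date())
    else:
        span = (datetime.min.date(), datetime.min.date())
    return LabelledDataset(events=events, instances=[], span=span)


def read_external_events(path: str | Path) -> LabelledDataset:
    """Read a minimal external event log (``timestamp,sensor[,label]``).

    Events are returned sorted by timestamp regardless of file order; an
    absent label column yields the ``unlabelled`` placeholder.
    """
    df = pd.read_csv(path)
    for col in ("timestamp", "sensor"):
        if col not in df.columns:
            raise DatasetFormatError(f"{path}: missing required column {col!r}")
    try:
        stamps = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise DatasetFormatError(f"{path}: malformed timestamp ({exc})")
    labels = df["label"] if "label" in df.columns else pd.Series([UNLABELLED] * len(df))
    events = [
        SensorEvent(ts.to_pydatetime(), str(sensor), str(label))
        for ts, sensor, label in zip(stamps, df["sensor"], labels.fillna(UNLABELLED))
    ]
    events.sort(key=lambda e: e.timestamp)
    if events:
        span = (events[0].timestamp.date(), events[-1].timestamp.date())
    else:
        span = (datetime.min.date(), datetime.min.date())
    return LabelledDataset(events=events, instances=[], span=span)
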