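"""Directory-of-CSV behavior database: schema, readers, writers, summaries.

The database is a folder per behavior class, one CSV per labeled event.
Each CSV carries 26 columns: a calendar timestamp plus 25 numeric channels
from two collar IMUs (BNO055: world- and body-frame acceleration, gyroscope,
magnetometer, orientation quaternion; MPU9250: body-frame acceleration,
gyroscope, magnetometer). Sampling rate is 10 Hz.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SAMPLE_RATE_HZ = 10.0

#: canonical behavior labels (snake_case) in database order
BEHAVIORS = ("active_mounting", "walking", "resting", "grazing", "head_nodding")

#: positive class of the binary detection task
POSITIVE_BEHAVIOR = "active_mounting"

_TOKEN_TO_BEHAVIOR = {
    "ActiveMounting": "active_mounting",
    "Walking": "walking",
    "Resting": "resting",
    "Grazing": "grazing",
    "HeadNodding": "head_nodding",
}
_BEHAVIOR_TO_TOKEN = {v: k for k, v in _TOKEN_TO_BEHAVIOR.items()}

#: default filename grammar; configurable so other conventions can be matched
FILENAME_REGEX = re.compile(
    r"^(?P<behavior>[A-Za-z]+)_(?P<cow_id>[A-Za-z0-9]+)_"
    r"(?P<date>\d{4}-\d{2}-\d{2})_(?P<time>\d{2}-\d{2}-\d{2})\.csv$"
)

TIME_COLUMN = "time"

#: the 25 numeric channels, in fixed column order (timestamp first in file)
NUMERIC_COLUMNS = (
    "bno_ax_world", "bno_ay_world", "bno_az_world",
    "bno_ax_body", "bno_ay_body", "bno_az_body",
    "bno_gx", "bno_gy", "bno_gz",
    "bno_mx", "bno_my", "bno_mz",
    "q1", "q2", "q3", "q4",
    "mpu_ax_body", "mpu_ay_body", "mpu_az_body",
    "mpu_gx", "mpu_gy", "mpu_gz",
    "mpu_mx", "mpu_my", "mpu_mz",
)

#: physical units per numeric channel
COLUMN_UNITS = dict(
    **{c: "m/s^2" for c in NUMERIC_COLUMNS if "_a" in c},
    **{c: "deg/s" for c in NUMERIC_COLUMNS if "_g" in c},
    **{c: "" for c in NUMERIC_COLUMNS if "_m" in c or c.startswith("q")},
)


class SchemaError(ValueError):
    """Event file violates the database schema or filename convention."""


@dataclass(frozen=True)
class ColumnSchema:
    """Ordered 26-column layout of an event CSV.

    ``rename_map`` lets the reader accept files whose headers use a
    different spelling (maps *file* header -> canonical name).
    """

    columns: tuple = (TIME_COLUMN,) + NUMERIC_COLUMNS
    rename_map: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.columns) != 26:
            raise SchemaError(f"schema must have 26 columns, got {len(self.columns)}")


DEFAULT_SCHEMA = ColumnSchema()


@dataclass
class EventRecording:
    """One labeled event: multichannel 10 Hz time series plus metadata."""

    behavior: str
    cow_id: str
    start: datetime
    data: pd.DataFrame  # 25 numeric channels, canonical names
    fs: float = SAMPLE_RATE_HZ

    def __post_init__(self):
        if self.behavior not in BEHAVIORS:
            raise SchemaError(f"unknown behavior {self.behavior!r}")
        if self.fs <= 0:
            raise ValueError("sample rate must be positive")
        missing = set(NUMERIC_COLUMNS) - set(self.data.columns)
        if missing:
            raise SchemaError(f"recording missing channels: {sorted(missing)}")
        if len(self.data) < 2:
            raise SchemaError("recording must hold at least 2 samples")

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def sample_times(self) -> pd.DatetimeIndex:
        """Per-row timestamps reconstructed from row index / fs."""
        offsets = pd.to_timedelta(np.arange(self.n_samples) / self.fs, unit="s")
        return pd.DatetimeIndex(pd.Timestamp(self.start) + offsets)


@dataclass(frozen=True)
class DatabaseSummary:
    """Per-behavior archive counts and durations (seconds)."""

    counts: Mapping[str, int]
    total_duration_s: Mapping[str, float]

    def average_duration_s(self, behavior: str) -> float:
        n = self.counts.get(behavior, 0)
        return self.total_duration_s.get(behavior, 0.0) / n if n else 0.0

    @property
    def grand_total_s(self) -> float:
        return float(sum(self.total_duration_s.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b in BEHAVIORS:
            n = self.counts.get(b, 0)
            tot = self.total_duration_s.get(b, 0.0)
            rows.append({
                "behavior": b,
                "n_archives": n,
                "total_duration": format_hms(tot),
                "average_duration": format_hms(tot / n) if n else format_hms(0),
            })
        return pd.DataFrame(rows)


def format_hms(seconds: float) -> str:
    s = int(round(seconds))
    return f"{s // 3600:02d}:{s % 3600 // 60:02d}:{s % 60:02d}"


def behavior_token(behavior: str) -> str:
    """snake_case behavior -> CamelCase filename token."""
    try:
        return _BEHAVIOR_TO_TOKEN[behavior]
    except KeyError:
        raise SchemaError(f"unknown behavior {behavior!r}") from None


def parse_event_filename(name: str, pattern: re.Pattern = FILENAME_REGEX):
    """Parse ``<Behavior>_<cowID>_<YYYY-MM-DD>_<hh-mm-ss>.csv``.

    Returns ``(behavior, cow_id, start_timestamp)``; inverse of
    :func:`format_event_filename`.
    """
    m = pattern.match(Path(name).name)
    if m is None:
        raise SchemaError(f"filename {name!r} does not match event convention")
    token = m.group("behavior")
    if token not in _TOKEN_TO_BEHAVIOR:
        raise SchemaError(f"filename {name!r}: unknown behavior token {token!r}")
    start = datetime.strptime(
        m.group("date") + " " + m.group("time"), "%Y-%m-%d %H-%M-%S"
    )
    return _TOKEN_TO_BEHAVIOR[token], m.group("cow_id"), start


def format_event_filename(behavior: str, cow_id: str, start: datetime) -> str:
    return (
        f"{behavior_token(behavior)}_{cow_id}_"
        f"{start.strftime('%Y-%m-%d_%H-%M-%S')}.csv"
    )


def read_event_csv(
    path, schema: ColumnSchema = DEFAULT_SCHEMA,
    behavior: str | None = None,
) -> EventRecording:
    """Read one event CSV into an :class:`EventRecording`.

    Metadata comes from the filename; pass ``behavior`` to override the
    parsed label. Headers are matched by name (whitespace-stripped), with
    ``schema.rename_map`` applied first, so column order in the file is
    not significant.
    """
    path = Path(path)
    parsed_behavior, cow_id, start = parse_event_filename(path.name)
    df = pd.read_csv(path)
    df.columns = [schema.rename_map.get(c.strip(), c.strip()) for c in df.columns]
    expected = set(schema.columns)
    got = set(df.columns)
    if got != expected:
        missing, extra = sorted(expected - got), sorted(got - expected)
        raise SchemaError(f"{path.name}: missing columns {missing}, extra {extra}")
    df = df[list(schema.columns)]
    numeric = df[list(NUMERIC_COLUMNS)].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df[list(NUMERIC_COLUMNS)].notna()
    if numeric.isna().any().any():
        row = int(numeric.isna().any(axis=1).idxmax())
        raise SchemaError(f"{path.name}: non-numeric or missing cell at data row {row}")
    del bad
    if len(numeric) < 2:
        raise SchemaError(f"{path.name}: too short ({len(numeric)} samples)")
    return EventRecording(
        behavior=behavior or parsed_behavior,
        cow_id=cow_id,
        start=start,
        data=numeric.reset_index(drop=True),
    )


def write_event_csv(rec: EventRecording, directory) -> Path:
    """Write an event CSV under ``directory`` using the filename convention.

    Round-trips through :func:`read_event_csv` to an equal recording
    (values to float round-trip precision).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = directory / format_event_filename(rec.behavior, rec.cow_id, rec.start)
    df = pd.DataFrame({TIME_COLUMN: rec.sample_times().strftime("%Y-%m-%d %H:%M:%S")})
    for c in NUMERIC_COLUMNS:
        df[c] = np.asarray(rec.data[c], dtype=float)
    df.to_csv(out, index=False, float_format="%.9g")
    return out


def iter_database(root, schema: ColumnSchema = DEFAULT_SCHEMA):
    """Yield EventRecordings from a ``<root>/<Behavior>/*.csv`` layout.

    Unknown behavior folders are skipped with a logged warning.
    """
    root = Path(root)
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        if sub.name not in _TOKEN_TO_BEHAVIOR:
            logger.warning("skipping unknown behavior folder %s", sub.name)
            continue
        behavior = _TOKEN_TO_BEHAVIOR[sub.name]
        for f in sorted(sub.glob("*.csv")):
            yield read_event_csv(f, schema=schema, behavior=behavior)


def load_database(root, schema: ColumnSchema = DEFAULT_SCHEMA) -> list[EventRecording]:
    return list(iter_database(root, schema=schema))


def summarize_database(root) -> DatabaseSummary:
    """Per-behavior archive counts and total durations (Fig.-5-style layout)."""
    root = Path(root)
    counts = {b: 0 for b in BEHAVIORS}
    totals = {b: 0.0 for b in BEHAVIORS}
    if root.exists():
        for sub in sorted(p for p in root.iterdir() if p.is_dir()):
            if sub.name not in _TOKEN_TO_BEHAVIOR:
                logger.warning("skipping unknown behavior folder %s", sub.name)
                continue
            b = _TOKEN_TO_BEHAVIOR[sub.name]
            for f in sorted(sub.glob("*.csv")):
                n_rows = sum(1 for _ in open(f)) - 1  # minus header
                counts[b] += 1
                totals[b] += n_rows / SAMPLE_RATE_HZ
    return DatabaseSummary(counts=counts, total_duration_s=totals)


def event_id(rec: EventRecording) -> str:
    return format_event_filename(rec.behavior, rec.cow_id, rec.start)[:-4]
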