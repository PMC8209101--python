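"""Sample event logs: core data types and delimited-text I/O.

A clinical laboratory records three timestamps per sample: *Receipt 1*
(``x``, arrival at the laboratory), *Receipt 2* (``y``, the pre-treated
sample is loaded into the analyzer) and *report* (``z``, the result is
transmitted to the hospital information system).  All downstream analysis
works on real-valued minutes measured on a single monotone clock; wall-clock
datetimes are converted on ingest, keeping the earliest arrival as the
origin and retaining the origin only so duty/shift labels can be recovered.

Derived phase durations:

* pre-analytical phase       ``y - x``  (centrifugation, de-capping, racking)
* analytical + post phase    ``z - y``  (instrument run and result transfer)
* overall turnaround time    ``z - x``  (the TAT judged against a guideline)

The TAT guideline is inclusive: a sample with TAT exactly equal to the limit
counts as compliant ("one hour or less").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleRecord",
    "DerivedDurations",
    "EventLog",
    "ColumnMap",
    "EventLogError",
    "ConfigurationError",
    "ValidationError",
    "EmptyLogError",
    "read_event_log",
    "write_event_log",
    "durations",
]

#: absolute tolerance (minutes) under which two timestamps compare equal;
#: also the precision guaranteed by the CSV round-trip.
TIME_ATOL = 1e-6

DEFAULT_TAT_LIMIT = 60.0


class EventLogError(Exception):
    """Base class for event-log errors."""


class ConfigurationError(EventLogError):
    """A required column is missing or the dialect is unusable."""


class ValidationError(EventLogError):
    """One or more records violate the x <= y <= z timeline.

    ``rows`` holds the offending 0-based data-row indices with messages.
    """

    def __init__(self, rows: Sequence[tuple[int, str]]):
        self.rows = list(rows)
        detail = "; ".join(f"row {i}: {msg}" for i, msg in self.rows)
        super().__init__(f"{len(self.rows)} invalid record(s): {detail}")


class EmptyLogError(EventLogError):
    """The input contains no usable records."""


class SampleRecord(NamedTuple):
    """One sample's timestamps (minutes): arrival, analyzer load, report."""

    sample_id: str
    x: float
    y: float
    z: float


class DerivedDurations(NamedTuple):
    """Per-sample phase durations in minutes (computed view, never stored)."""

    pre_analytical: float
    analytical_post: float
    overall_tat: float


@dataclass
class EventLog:
    """An ordered collection of sample records.

    Records are kept sorted ascending by arrival time ``x`` (ties broken by
    ``y``, then ``sample_id``) and are stored column-wise as numpy arrays for
    efficiency; :meth:`records` reconstructs the row view.

    Parameters
    ----------
    ids, x, y, z
        Parallel sequences; timestamps in minutes.
    tat_limit
        TAT guideline in minutes (default 60, inclusive comparison).
    origin
        Optional wall-clock datetime corresponding to minute 0, kept only
        so duty/shift labels can be attached to records later.
    n_missing_receipt1
        Tally of input rows excluded because Receipt 1 was absent.
    """

    ids: list[str]
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    tat_limit: float = DEFAULT_TAT_LIMIT
    origin: pd.Timestamp | None = None
    n_missing_receipt1: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (len(self.ids) == self.x.size == self.y.size == self.z.size):
            raise ValueError("ids, x, y, z must have equal length")
        if self.tat_limit <= 0:
            raise ValueError("tat_limit must be positive")
        if len(self.ids) != len(set(self.ids)):
            raise ValidationError([(0, "duplicate sample_ids")])
        bad = self._invalid_rows()
        if bad:
            raise ValidationError(bad)
        self._sort()

    def _invalid_rows(self) -> list[tuple[int, str]]:
        rows: list[tuple[int, str]] = []
        for i in range(len(self.ids)):
            x, y, z = self.x[i], self.y[i], self.z[i]
            if not (np.isfinite(x) and np.isfinite(y) and np.isfinite(z)):
                rows.append((i, f"non-finite timestamp in {self.ids[i]}"))
            elif x < 0:
                rows.append((i, f"negative Receipt-1 time in {self.ids[i]}"))
            elif x > y + TIME_ATOL:
                rows.append((i, f"Receipt 1 after Receipt 2 ({x} > {y})"))
            elif y > z + TIME_ATOL:
                rows.append((i, f"Receipt 2 after report ({y} > {z})"))
        return rows

    def _sort(self) -> None:
        order = sorted(range(len(self.ids)),
                       key=lambda i: (self.x[i], self.y[i], self.ids[i]))
        self.ids = [self.ids[i] for i in order]
        self.x = self.x[order]
        self.y = self.y[order]
        self.z = self.z[order]

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self) -> Iterator[SampleRecord]:
        return iter(self.records())

    def records(self) -> list[SampleRecord]:
        return [SampleRecord(i, float(a), float(b), float(c))
                for i, a, b, c in zip(self.ids, self.x, self.y, self.z)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventLog):
            return NotImplemented
        return (self.ids == other.ids
                and self.tat_limit == other.tat_limit
                and np.allclose(self.x, other.x, atol=TIME_ATOL, rtol=0)
                and np.allclose(self.y, other.y, atol=TIME_ATOL, rtol=0)
                and np.allclose(self.z, other.z, atol=TIME_ATOL, rtol=0))

    @classmethod
    def from_records(cls, records: Sequence[SampleRecord | tuple],
                     tat_limit: float = DEFAULT_TAT_LIMIT,
                     origin: pd.Timestamp | None = None) -> "EventLog":
        recs = [SampleRecord(*r) for r in records]
        return cls(ids=[r.sample_id for r in recs],
                   x=np.array([r.x for r in recs], dtype=float),
                   y=np.array([r.y for r in recs], dtype=float),
                   z=np.array([r.z for r in recs], dtype=float),
                   tat_limit=tat_limit, origin=origin)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.ids, "x": self.x,
                             "y": self.y, "z": self.z})

    def compliance_rate(self) -> float:
        """Fraction of samples with overall TAT <= tat_limit (1.0 if empty)."""
        if len(self) == 0:
            return 1.0
        return float(np.mean(self.z - self.x <= self.tat_limit + TIME_ATOL))


@dataclass(frozen=True)
class ColumnMap:
    """CSV dialect: column names and how timestamps are encoded.

    ``timestamps`` is ``"minutes"`` (real-valued minutes on the log's clock)
    or ``"iso8601"`` (wall-clock datetimes, converted to minutes from the
    earliest Receipt 1 on ingest).
    """

    sample_id: str = "sample_id"
    x: str = "x"
    y: str = "y"
    z: str = "z"
    timestamps: str = "minutes"
    delimiter: str = ","

    def __post_init__(self) -> None:
        if self.timestamps not in ("minutes", "iso8601"):
            raise ConfigurationError(
                f"unknown timestamp dialect {self.timestamps!r}")


def read_event_log(path, dialect: ColumnMap | None = None,
                   tat_limit: float = DEFAULT_TAT_LIMIT) -> EventLog:
    """Read a delimited-text event log into a sorted, validated :class:`EventLog`.

    Rows whose Receipt 1 is missing are excluded (and tallied on the returned
    log's ``n_missing_receipt1``) rather than imputed: ``x`` anchors both TAT
    and batching, so inventing it would invent data.  Rows violating
    ``x <= y <= z`` or with unparseable timestamps raise a single
    :class:`ValidationError` naming every offending row.
    """
    dialect = dialect or ColumnMap()
    try:
        df = pd.read_csv(path, sep=dialect.delimiter, dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyLogError(f"{path}: file is empty") from None
    missing = [c for c in (dialect.sample_id, dialect.x, dialect.y, dialect.z)
               if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    if df.empty:
        raise EmptyLogError(f"{path}: no data rows")

    raw = df[[dialect.sample_id, dialect.x, dialect.y, dialect.z]].copy()
    raw.columns = ["sample_id", "x", "y", "z"]

    n_missing = int(raw["x"].isna().sum())
    raw = raw[raw["x"].notna()].reset_index(drop=False)
    if raw.empty:
        raise EmptyLogError(f"{path}: every row lacks Receipt 1")

    origin: pd.Timestamp | None = None
    errors: list[tuple[int, str]] = []
    if dialect.timestamps == "iso8601":
        cols = {}
        for c in ("x", "y", "z"):
            parsed = pd.to_datetime(raw[c], errors="coerce", format="ISO8601")
            for i in np.flatnonzero(parsed.isna().to_numpy()):
                errors.append((int(raw["index"][i]),
                               f"unparseable datetime {raw[c][i]!r} in {c}"))
            cols[c] = parsed
        if errors:
            raise ValidationError(errors)
        origin = cols["x"].min()
        vals = {c: (cols[c] - origin).dt.total_seconds().to_numpy() / 60.0
                for c in ("x", "y", "z")}
    else:
        vals = {}
        for c in ("x", "y", "z"):
            num = pd.to_numeric(raw[c], errors="coerce")
            for i in np.flatnonzero(num.isna().to_numpy()):
                errors.append((int(raw["index"][i]),
                               f"unparseable timestamp {raw[c][i]!r} in {c}"))
            vals[c] = num.to_numpy(dtype=float)
        if errors:
            raise ValidationError(errors)

    x, y, z = vals["x"], vals["y"], vals["z"]
    for i in range(len(raw)):
        if x[i] > y[i] + TIME_ATOL:
            errors.append((int(raw["index"][i]),
                           f"Receipt 1 after Receipt 2 ({x[i]} > {y[i]})"))
        elif y[i] > z[i] + TIME_ATOL:
            errors.append((int(raw["index"][i]),
                           f"Receipt 2 after report ({y[i]} > {z[i]})"))
    if errors:
        raise ValidationError(errors)

    return EventLog(ids=list(raw["sample_id"]), x=x, y=y, z=z,
                    tat_limit=tat_limit, origin=origin,
                    n_missing_receipt1=n_missing)


def write_event_log(log: EventLog, path) -> None:
    """Write an event log as CSV (minutes dialect, 1e-6 min round-trip)."""
    # 13 significant digits keep sub-1e-6 min precision out to years of log
    log.to_frame().to_csv(path, index=False, float_format="%.13g")


def durations(log: EventLog) -> list[DerivedDurations]:
    """Per-record phase durations, in record order.

    Each element is ``(y - x, z - y, z - x)``; the first two always sum to
    the third, and all are invariant under shifting the log's time origin.
    """
    return [DerivedDurations(float(b - a), float(c - b), float(c - a))
            for a, b, c in zip(log.x, log.y, log.z)]
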