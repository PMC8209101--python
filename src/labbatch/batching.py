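"""Batch-waiting transformation of an event log and its two objectives.

The method under study: instead of loading each pre-treated sample into the
analyzer as it becomes ready, the technician waits.  Given a waiting
interval ``M`` (minutes), samples are accumulated and loaded together as a
single Receipt-2 task.  Formally, on the log sorted by arrival time, repeat
until every record is assigned:

1. let ``k`` be the earliest-arriving unassigned record (the *anchor*) and
   ``x_k + M`` its *batch deadline*;
2. the batch consists of ``k`` plus every unassigned later record ``i``
   whose original Receipt-2 time satisfies ``y_i <= x_k + M``;
3. every batch member whose original ``y`` is at or before the deadline is
   retimed to ``y' = x_k + M`` (this is all non-anchor members by
   construction, and the anchor iff ``y_k <= x_k + M``; an anchor already
   past the deadline keeps ``y' = y_k`` — waiting can delay work, never
   retroactively speed it up);
4. report times carry the analytical + post-analytical duration over
   unchanged: ``z' = y' + (z - y)``.

Two quantities summarise the consequence of a given ``M``:

* ``l_M`` — the number of batches, i.e. of distinct Receipt-2 tasks.  Fewer
  tasks means fewer occasions to switch away from other duties.
* ``r_M`` — the fraction of samples whose modified TAT ``z' - x`` still
  meets the guideline.

Sweeping ``M`` over a grid yields the trade-off curve between the two.

Membership normally tests the original ``y_i`` against the deadline, exactly
as the rule above is written.  ``membership="arrival"`` is an alternative
reading that tests the arrival time ``x_i`` instead (a sample arriving
within the window joins the batch even if its own pre-treatment would have
finished later); it is provided for comparison and is not the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .event_model import TIME_ATOL, EventLog

__all__ = ["BatchedLog", "ObjectivePoint", "batch_receipts", "count_tasks",
           "tat_satisfaction", "tradeoff_curve"]


class ObjectivePoint(NamedTuple):
    """Objective pair for one waiting interval: M, l_M (tasks), r_M (rate)."""

    M: float
    l: int
    r: float


@dataclass
class BatchedLog:
    """An event log after the batch-waiting transformation at interval ``M``.

    Arrays are parallel to the source log's (sorted) records.  ``batch_index``
    maps each record to its batch (contiguous from 0 in anchor order);
    ``anchor_ids``/``anchor_x`` identify each batch's anchor and
    ``batch_deadline[b] = anchor_x[b] + M``.
    """

    M: float
    ids: list[str]
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    y_prime: np.ndarray
    z_prime: np.ndarray
    batch_index: np.ndarray
    anchor_ids: list[str]
    anchor_x: np.ndarray
    tat_limit: float

    @property
    def n_batches(self) -> int:
        return len(self.anchor_ids)

    @property
    def batch_deadline(self) -> np.ndarray:
        return self.anchor_x + self.M

    def batch_of(self, sample_id: str) -> int:
        return int(self.batch_index[self.ids.index(sample_id)])

    def members(self, b: int) -> list[str]:
        return [i for i, bi in zip(self.ids, self.batch_index) if bi == b]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample_id": self.ids, "x": self.x, "y": self.y, "z": self.z,
            "y_prime": self.y_prime, "z_prime": self.z_prime,
            "batch_index": self.batch_index,
            "batch_deadline": self.batch_deadline[self.batch_index],
        })


def batch_receipts(log: EventLog, M: float,
                   membership: str = "receipt2") -> BatchedLog:
    """Apply the greedy batch-waiting transformation at interval ``M``.

    Anchors are taken greedily in arrival order over still-unassigned
    records; a record with ``y`` exactly at the deadline is in the batch.
    ``M = 0`` is the identity whenever every ``y_i`` exceeds every earlier
    arrival ``x_k``.
    """
    if M < 0:
        raise ValueError(f"waiting interval M must be >= 0, got {M}")
    if membership not in ("receipt2", "arrival"):
        raise ValueError(f"unknown membership mode {membership!r}")
    n = len(log)
    x, y, z = log.x, log.y, log.z
    key = y if membership == "receipt2" else x

    batch_index = np.full(n, -1, dtype=int)
    y_prime = np.empty(n, dtype=float)
    anchor_idx: list[int] = []

    b = 0
    for k in range(n):
        if batch_index[k] >= 0:
            continue
        deadline = x[k] + M
        # later candidates are bounded by x_i <= deadline (x <= y <= key bound)
        hi = int(np.searchsorted(x, deadline + TIME_ATOL, side="right"))
        later = k + 1 + np.flatnonzero(
            (batch_index[k + 1:hi] < 0) & (key[k + 1:hi] <= deadline + TIME_ATOL))
        members = np.concatenate(([k], later))
        batch_index[members] = b
        # waiting only delays Receipt 2; equals the deadline for every
        # member whose original y is at or before it
        y_prime[members] = np.maximum(y[members], deadline)
        anchor_idx.append(k)
        b += 1

    z_prime = y_prime + (z - y)
    return BatchedLog(M=float(M), ids=list(log.ids), x=x.copy(), y=y.copy(),
                      z=z.copy(), y_prime=y_prime, z_prime=z_prime,
                      batch_index=batch_index,
                      anchor_ids=[log.ids[k] for k in anchor_idx],
                      anchor_x=x[anchor_idx] if anchor_idx else np.empty(0),
                      tat_limit=log.tat_limit)


def count_tasks(batched: BatchedLog) -> int:
    """Number of Receipt-2 tasks (batches) — the objective ``l_M``."""
    return batched.n_batches


def tat_satisfaction(batched: BatchedLog, limit: float) -> float:
    """Fraction of samples with modified TAT ``z' - x <= limit`` (``r_M``).

    The comparison is inclusive; an empty log is fully compliant (1.0).
    """
    if limit <= 0:
        raise ValueError(f"TAT limit must be positive, got {limit}")
    if len(batched.ids) == 0:
        return 1.0
    return float(np.mean(batched.z_prime - batched.x <= limit + TIME_ATOL))


def tradeoff_curve(log: EventLog,
                   M_grid: Sequence[float]) -> list[ObjectivePoint]:
    """Evaluate ``(l_M, r_M)`` over a strictly increasing grid of intervals."""
    grid = np.asarray(list(M_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("M_grid must be non-empty")
    if np.any(grid < 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("M_grid must be strictly increasing and >= 0")
    points = []
    for M in grid:
        batched = batch_receipts(log, float(M))
        points.append(ObjectivePoint(float(M), count_tasks(batched),
                                     tat_satisfaction(batched, log.tat_limit)))
    return points
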