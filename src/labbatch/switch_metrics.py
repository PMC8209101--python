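"""Counting task switches in labelled task sequences, and duty labelling.

A technician's workday is a sequence of task types — e.g. pre-treatment
``P`` and analytical ``A`` steps, or "Receipt 2" versus any other duty.  A
*switch* is any adjacent change of task type; the first task is not a
switch.  Interleaved processing such as P-A-PP-AA-P-A costs five switches
where the fully batched ordering PPPP-AAAA costs one.

Duty labelling supports the two partitions of the day used in shift
reporting: analysis duties (day 07-15, evening 15-23, night 23-07) and
staffing windows (day 07-17 with 4 workers, evening 17-22 with 3, night
22-07 with 2).  Windows are half-open [start, end) so they partition every
24-hour day exactly.
"""

from __future__ import annotations

import datetime as _dt
from typing import Hashable, Sequence

__all__ = ["count_switches", "switches_per_100", "label_duty",
           "DUTY", "STAFFING", "DUTY_SCHEMES"]

#: scheme name -> list of (label, start hour, end hour); end < start wraps
#: past midnight.
DUTY = [("day", 7, 15), ("evening", 15, 23), ("night", 23, 7)]
STAFFING = [("day (4 workers)", 7, 17), ("evening (3 workers)", 17, 22),
            ("night (2 workers)", 22, 7)]
DUTY_SCHEMES: dict[str, list[tuple[str, int, int]]] = {
    "DUTY": DUTY, "STAFFING": STAFFING}


def count_switches(seq: Sequence[Hashable]) -> int:
    """Number of adjacent positions whose task types differ.

    Equivalently (number of maximal runs of equal labels) - 1; invariant
    under any relabelling bijection.  Sample indices play no role — only
    the type matters.
    """
    labels = list(seq)
    if not labels:
        raise ValueError("task sequence must be non-empty")
    return sum(1 for a, b in zip(labels, labels[1:]) if a != b)


def switches_per_100(total_works: int, switched: int) -> float:
    """Switch rate per 100 works: ``100 * switched / total_works``."""
    if total_works <= 0:
        raise ValueError(f"total_works must be positive, got {total_works}")
    if not 0 <= switched <= total_works:
        raise ValueError(
            f"switched must lie in [0, total_works], got {switched}")
    return 100.0 * switched / total_works


def _hour_of_day(t) -> float:
    if isinstance(t, _dt.datetime):
        return t.hour + t.minute / 60 + t.second / 3600
    if isinstance(t, _dt.time):
        return t.hour + t.minute / 60 + t.second / 3600
    return float(t) % 24.0


def label_duty(timestamp, scheme="DUTY") -> str:
    """Duty label of the half-open window containing ``timestamp``.

    ``timestamp`` may be a datetime, a time, or an hour-of-day float;
    ``scheme`` is ``"DUTY"``, ``"STAFFING"`` or an explicit window list.
    The windows cover the whole day, so every timestamp gets a label.
    """
    windows = DUTY_SCHEMES[scheme] if isinstance(scheme, str) else scheme
    h = _hour_of_day(timestamp)
    for label, start, end in windows:
        if start < end:
            if start <= h < end:
                return label
        else:  # wraps midnight
            if h >= start or h < end:
                return label
    raise ValueError(f"duty windows do not cover hour {h}")  # pragma: no cover
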