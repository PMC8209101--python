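"""Evaluation outputs: phase summaries, boxplot statistics, duty breakdowns
and the batch-deadline alert schedule.

These reproduce the standard reporting views a laboratory uses to evaluate
a workflow change: per-phase mean +/- SD split by TAT compliance, boxplot
five-number summaries of the TAT distribution, switch rates per 100 works
by duty with period-over-period deltas, and the alert schedule a monitoring
system would emit ("process the accumulated batch now").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .batching import BatchedLog
from .event_model import TIME_ATOL, EventLog
from .switch_metrics import switches_per_100

__all__ = ["StratumStats", "PhaseSummary", "BoxplotStats", "Alert",
           "phase_summary", "boxplot_stats", "duty_switch_report",
           "monitor_alerts"]


class StratumStats(NamedTuple):
    """n, share of total, and per-phase mean/SD (minutes) for one stratum."""

    n: int
    percent: float
    pre_mean: float | None
    pre_sd: float | None
    post_mean: float | None
    post_sd: float | None
    tat_mean: float | None
    tat_sd: float | None


@dataclass
class PhaseSummary:
    """Phase statistics overall and split at the TAT limit.

    Strata: ``overall``, ``within_limit`` (TAT <= limit, inclusive) and
    ``after_limit``.  SDs are sample (n-1) standard deviations; a stratum
    with n < 2 has undefined SDs (None), and an empty stratum has all
    moments undefined.
    """

    tat_limit: float
    strata: dict[str, StratumStats]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame.from_dict(
            {k: v._asdict() for k, v in self.strata.items()}, orient="index")
        df.index.name = "stratum"
        return df

    def to_text(self) -> str:
        """Plain-text table with percentages printed to two decimals."""
        lines = [f"TAT limit: {self.tat_limit:g} min"]
        hdr = (f"{'stratum':<14}{'n':>8}{'%':>9}{'pre':>16}"
               f"{'anal+post':>16}{'overall TAT':>16}")
        lines.append(hdr)
        for name, s in self.strata.items():
            def ms(m, sd):
                if m is None:
                    return "-"
                return f"{m:.2f} ± {sd:.2f}" if sd is not None else f"{m:.2f}"
            lines.append(f"{name:<14}{s.n:>8}{s.percent:>8.2f}%"
                         f"{ms(s.pre_mean, s.pre_sd):>16}"
                         f"{ms(s.post_mean, s.post_sd):>16}"
                         f"{ms(s.tat_mean, s.tat_sd):>16}")
        return "\n".join(lines)


class BoxplotStats(NamedTuple):
    """Five-number boxplot summary with 1.5*IQR whiskers and outliers.

    Quartiles use linear interpolation between order statistics; whiskers
    sit at the most extreme data points within 1.5*IQR of the box edges and
    every value beyond the fences is listed as an outlier.
    """

    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


class Alert(NamedTuple):
    """One monitoring alert: fire at ``time``, process batch ``batch``."""

    time: float
    batch: int
    sample_ids: tuple[str, ...]


def _stratum(pre: np.ndarray, post: np.ndarray, tat: np.ndarray,
             total: int) -> StratumStats:
    n = tat.size
    if n == 0:
        return StratumStats(0, 0.0, None, None, None, None, None, None)

    def sd(v):
        return float(np.std(v, ddof=1)) if n >= 2 else None

    return StratumStats(n, 100.0 * n / total,
                        float(pre.mean()), sd(pre),
                        float(post.mean()), sd(post),
                        float(tat.mean()), sd(tat))


def phase_summary(log: EventLog) -> PhaseSummary:
    """Per-phase mean +/- SD overall and split by TAT compliance."""
    if len(log) == 0:
        raise ValueError("phase_summary requires a non-empty log")
    pre = log.y - log.x
    post = log.z - log.y
    tat = log.z - log.x
    within = tat <= log.tat_limit + TIME_ATOL
    total = len(log)
    strata = {
        "overall": _stratum(pre, post, tat, total),
        "within_limit": _stratum(pre[within], post[within], tat[within],
                                 total),
        "after_limit": _stratum(pre[~within], post[~within], tat[~within],
                                total),
    }
    return PhaseSummary(tat_limit=log.tat_limit, strata=strata)


def boxplot_stats(values: Sequence[float]) -> BoxplotStats:
    """Quartiles (linear interpolation), 1.5*IQR whiskers, and outliers."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("boxplot_stats requires a non-empty sequence")
    q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = np.sort(v[(v < lo_fence) | (v > hi_fence)])
    return BoxplotStats(float(q1), float(med), float(q3),
                        float(inside.min()), float(inside.max()),
                        tuple(float(o) for o in outliers))


def duty_switch_report(
    counts: Mapping[str, Mapping[str, tuple[int, int]]],
) -> pd.DataFrame:
    """Switches per 100 works by duty and period, with deltas.

    ``counts`` maps period label -> duty label -> (total works, switched
    works).  Periods are compared in insertion order; with more than one
    period the table carries, per consecutive pair, the change in the rate
    and the percentage reduction in switched works (e.g. 20,000 fewer
    switched tasks on 50,000 total is a 40% efficiency gain).
    """
    periods = list(counts)
    duties: list[str] = []
    for p in periods:
        for d in counts[p]:
            if d not in duties:
                duties.append(d)
    rows = []
    for d in duties:
        row: dict[str, object] = {"duty": d}
        for p in periods:
            total, switched = counts[p][d]
            row[f"total_{p}"] = total
            row[f"switched_{p}"] = switched
            row[f"per100_{p}"] = switches_per_100(total, switched)
        for prev, cur in zip(periods, periods[1:]):
            row[f"delta_per100_{prev}_to_{cur}"] = (
                row[f"per100_{cur}"] - row[f"per100_{prev}"])  # type: ignore
            reduction = counts[prev][d][1] - counts[cur][d][1]
            row[f"efficiency_gain_pct_{prev}_to_{cur}"] = switches_per_100(
                counts[cur][d][0], abs(reduction)) * np.sign(reduction)
        rows.append(row)
    return pd.DataFrame(rows).set_index("duty")


def monitor_alerts(batched: BatchedLog) -> list[Alert]:
    """Alert schedule: one alert per batch, ordered by firing time.

    An alert tells the technician to load the accumulated batch.  It fires
    at the batch's actual Receipt-2 time, ``max(x_k + M, y_k)`` — the
    deadline, unless the anchor's own pre-treatment finishes later (at
    M = 0 this is simply each sample's original ``y``).  The number of
    alerts always equals the task count ``l_M``.
    """
    alerts = []
    for b in range(batched.n_batches):
        mask = batched.batch_index == b
        anchor_pos = int(np.flatnonzero(mask)[0])
        fire = float(batched.y_prime[anchor_pos])
        members = tuple(i for i, m in zip(batched.ids, mask) if m)
        alerts.append(Alert(fire, b, members))
    alerts.sort(key=lambda a: (a.time, a.batch))
    return alerts
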