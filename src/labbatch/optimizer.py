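"""Normalisation, weighted scalarization and selection of the interval M0.

The two objectives pull in opposite directions: a longer waiting interval
``M`` means fewer Receipt-2 tasks (``l_M`` falls) but later reports (the
dissatisfaction rate ``1 - r_M`` rises).  To make the printed weights
meaningful the objectives are first min-max normalised over the evaluated
grid —

    f1(M) = ((1 - r_M) - min) / (max - min)      TAT dissatisfaction
    f2(M) = (l_M - min) / (max - min)            task count

(a constant objective maps to all-zeros) — and then collapsed with weights
on the unit simplex:

    g(M) = w_tat * f1(M) + w_switch * f2(M),   M0 = argmin_M g(M),

ties broken toward the smallest M (favouring TAT compliance when
indifferent).  The Pareto-optimal grid intervals — those whose (f1, f2)
pair no other interval dominates — are reported alongside; for strictly
positive weights the selected M0 always lies in that set.

Raising ``w_switch`` never lowers M0: with f1 weakly increasing and f2
weakly decreasing in M, the smallest-tie-break argmin is weakly increasing
in the task-switching weight.  Sweeping weight pairs therefore yields an
interval of recommendations rather than a single point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .batching import ObjectivePoint, tradeoff_curve
from .event_model import EventLog

__all__ = ["NormalizedCurve", "OptimizationResult", "RecommendationSummary",
           "normalize_curve", "scalarize", "recommend_interval",
           "default_grid", "curve_frame", "plot_tradeoff"]

WEIGHT_TOL = 1e-9

#: the standard weight sweep: TAT-leaning, balanced, switching-leaning
DEFAULT_WEIGHT_PAIRS: tuple[tuple[float, float], ...] = (
    (0.6, 0.4), (0.5, 0.5), (0.4, 0.6))


def default_grid(stop: float = 60.0, step: float = 1.0) -> np.ndarray:
    """Integer-minute grid 0..stop; the data's resolution and the TAT limit
    bound the useful range of M."""
    return np.arange(0.0, stop + step / 2, step)


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = float(v.min()), float(v.max())
    if hi - lo < 1e-12:
        return np.zeros_like(v, dtype=float)
    return (v - lo) / (hi - lo)


@dataclass
class NormalizedCurve:
    """Min-max normalised trade-off curve over a grid of intervals."""

    M: np.ndarray
    f1: np.ndarray  # normalised TAT dissatisfaction, in [0, 1]
    f2: np.ndarray  # normalised task count, in [0, 1]
    source: list[ObjectivePoint]


@dataclass
class OptimizationResult:
    """Outcome of scalarizing a normalised curve with one weight pair."""

    w_tat: float
    w_switch: float
    M: np.ndarray
    objective: np.ndarray
    M0: float
    pareto_set: list[float]


@dataclass
class RecommendationSummary:
    """Per-weight-pair optima and the interval they span."""

    results: list[OptimizationResult]
    curve: NormalizedCurve

    @property
    def interval(self) -> tuple[float, float]:
        opts = [r.M0 for r in self.results]
        return (min(opts), max(opts))


def normalize_curve(curve: Sequence[ObjectivePoint]) -> NormalizedCurve:
    """Min-max normalise (1 - r_M) and l_M over the evaluated grid."""
    pts = list(curve)
    if not pts:
        raise ValueError("trade-off curve must be non-empty")
    M = np.array([p.M for p in pts], dtype=float)
    dissat = np.array([1.0 - p.r for p in pts], dtype=float)
    tasks = np.array([p.l for p in pts], dtype=float)
    return NormalizedCurve(M=M, f1=_minmax(dissat), f2=_minmax(tasks),
                           source=pts)


def _pareto_mask(f1: np.ndarray, f2: np.ndarray) -> np.ndarray:
    """Non-domination mask: i is dominated if some j is <= in both
    objectives and < in at least one."""
    n = f1.size
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        dominated = ((f1 <= f1[i]) & (f2 <= f2[i])
                     & ((f1 < f1[i]) | (f2 < f2[i])))
        if dominated.any():
            keep[i] = False
    return keep


def scalarize(norm: NormalizedCurve, w_tat: float,
              w_switch: float) -> OptimizationResult:
    """Weighted-sum scalarization g = w_tat*f1 + w_switch*f2; pick M0.

    Weights must be non-negative and sum to 1.  The argmin tie-break is the
    smallest grid M; ``np.argmin`` returns the first minimiser of the
    (increasing-M) grid, which is exactly that.
    """
    if w_tat < 0 or w_switch < 0 or abs(w_tat + w_switch - 1.0) > WEIGHT_TOL:
        raise ValueError(
            f"weights must be >= 0 and sum to 1, got ({w_tat}, {w_switch})")
    g = w_tat * norm.f1 + w_switch * norm.f2
    M0 = float(norm.M[int(np.argmin(g))])
    pareto = [float(m) for m in norm.M[_pareto_mask(norm.f1, norm.f2)]]
    return OptimizationResult(w_tat=w_tat, w_switch=w_switch, M=norm.M,
                              objective=g, M0=M0, pareto_set=pareto)


def recommend_interval(
    log: EventLog,
    M_grid: Sequence[float] | None = None,
    weight_pairs: Sequence[tuple[float, float]] = DEFAULT_WEIGHT_PAIRS,
) -> RecommendationSummary:
    """Full pipeline: trade-off curve -> normalise -> scalarize per weights.

    Returns each weight pair's M0 and the spanned recommendation interval;
    heavier weight on task switching never shortens the interval.
    """
    grid = default_grid() if M_grid is None else M_grid
    if not list(weight_pairs):
        raise ValueError("at least one weight pair is required")
    norm = normalize_curve(tradeoff_curve(log, grid))
    results = [scalarize(norm, wt, ws) for wt, ws in weight_pairs]
    return RecommendationSummary(results=results, curve=norm)


def curve_frame(summary: RecommendationSummary) -> pd.DataFrame:
    """Tabulate the curve and each weight pair's objective (CSV-ready)."""
    norm = summary.curve
    df = pd.DataFrame({
        "M": norm.M,
        "l": [p.l for p in norm.source],
        "r": [p.r for p in norm.source],
        "f1": norm.f1,
        "f2": norm.f2,
    })
    for res in summary.results:
        df[f"g_{res.w_tat:g}_{res.w_switch:g}"] = res.objective
    return df


def plot_tradeoff(summary: RecommendationSummary, path) -> None:
    """Two-panel figure: normalised objectives vs M, and the scalarized
    objectives with each selected M0 marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    norm = summary.curve
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    ax1.plot(norm.M, norm.f2, "r-", label="normalised task count $f_2$")
    ax1.plot(norm.M, norm.f1, "b-", label="normalised TAT dissatisfaction $f_1$")
    ax1.set_xlabel("waiting interval M (min)")
    ax1.set_ylabel("normalised objective")
    ax1.legend()
    for res in summary.results:
        (line,) = ax2.plot(norm.M, res.objective,
                           label=f"w=({res.w_tat:g}, {res.w_switch:g})")
        ax2.axvline(res.M0, color=line.get_color(), ls=":", lw=1)
    ax2.set_xlabel("waiting interval M (min)")
    ax2.set_ylabel("weighted objective g(M)")
    ax2.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
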