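"""Per-cycle exposure metrics and population summaries.

For each dosing cycle the non-compartmental metrics are:

* Cmax — maximum concentration over the cycle window;
* Cmin — the trough, i.e. the concentration at the window end, immediately
  before the next dose (the popPK Ctrough convention);
* weekly AUC — trapezoidal AUC over the window rescaled to a 7-day week,
  ``AUC_window * 7 / window_days``, the only AUC scale comparable across
  regimens whose intervals differ (14/21/28/42 days).

Population summaries report geometric means with the 90% prediction
interval as the 5th–95th percentiles (linear-interpolation quantiles, so
bands are bit-reproducible), plus mean, median and SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dosing import CycleWindow
from .engine import ConcProfile, SimulationResult

__all__ = [
    "CycleMetrics",
    "cycle_metrics",
    "geometric_mean",
    "percentiles",
    "population_metrics",
    "summarize_exposure",
    "SUMMARY_COLUMNS",
]

METRIC_NAMES = ("cmax", "cmin", "weekly_auc")
SUMMARY_COLUMNS = ["regimen", "cycle", "metric", "geo_mean", "p5", "p50", "p95", "mean", "sd"]


@dataclass(frozen=True)
class CycleMetrics:
    """One subject's exposure in one cycle (µg/mL; weekly AUC in µg·day/mL)."""

    subject_id: int
    regimen: str
    cycle: int
    cmax: float
    cmin: float
    weekly_auc: float


def cycle_metrics(profile: ConcProfile, window: CycleWindow, regimen: str = "") -> CycleMetrics:
    """Cmax / Cmin / weekly AUC of one profile over one cycle window.

    The profile grid must cover [start, end] including the end point (the
    trough time).
    """
    t = profile.times
    mask = (t >= window.start) & (t <= window.end)
    if not np.any(mask) or t[mask].min() > window.start or t[mask].max() < window.end:
        raise ValueError(f"profile grid does not cover cycle {window.index} "
                         f"[{window.start}, {window.end}]")
    tw, cw = t[mask], profile.conc[mask]
    order = np.argsort(tw, kind="stable")
    tw, cw = tw[order], cw[order]
    auc = np.trapezoid(cw, tw)
    return CycleMetrics(
        subject_id=profile.subject_id,
        regimen=regimen,
        cycle=window.index,
        cmax=float(cw.max()),
        cmin=float(cw[-1]),
        weekly_auc=float(auc * 7.0 / window.length),
    )


def geometric_mean(values) -> float:
    """exp(mean(ln values)); rejects nonpositive input rather than dropping it."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("geometric mean of empty input")
    if np.any(v <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(v))))


def percentiles(values, probs=(0.05, 0.50, 0.95)) -> np.ndarray:
    """Linear-interpolation quantiles (numpy's default rule); p50 is the median."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("percentiles of empty input")
    return np.percentile(v, np.asarray(probs) * 100.0, method="linear")


def population_metrics(result: SimulationResult, cycles=None) -> pd.DataFrame:
    """Per-subject per-cycle metrics for a whole simulated population.

    ``cycles`` restricts to a subset of cycle indices (default: all).
    Vectorized over subjects; one row per subject x cycle.
    """
    rows = []
    for w in result.windows:
        if cycles is not None and w.index not in cycles:
            continue
        mask = (result.grid.times >= w.start) & (result.grid.times <= w.end)
        tw = result.grid.times[mask]
        order = np.argsort(tw, kind="stable")
        tw = tw[order]
        cw = result.conc[:, mask][:, order]
        auc = np.trapezoid(cw, tw, axis=1)
        rows.append(pd.DataFrame({
            "subject_id": result.subject_ids,
            "regimen": result.regimen.name,
            "cycle": w.index,
            "cmax": cw.max(axis=1),
            "cmin": cw[:, -1],
            "weekly_auc": auc * 7.0 / w.length,
        }))
    return pd.concat(rows, ignore_index=True)


def summarize_exposure(metrics: pd.DataFrame) -> pd.DataFrame:
    """Population summary per regimen x cycle x metric.

    Columns: geo_mean, p5, p50, p95 (the 90% PI is [p5, p95]), mean, sd.
    """
    if metrics.empty:
        raise ValueError("no metrics to summarize")
    rows = []
    for (regimen, cycle), grp in metrics.groupby(["regimen", "cycle"], sort=True):
        for metric in METRIC_NAMES:
            v = grp[metric].to_numpy()
            p5, p50, p95 = percentiles(v)
            rows.append({
                "regimen": regimen, "cycle": cycle, "metric": metric,
                "geo_mean": geometric_mean(v),
                "p5": p5, "p50": p50, "p95": p95,
                "mean": float(np.mean(v)),
                "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
            })
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
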