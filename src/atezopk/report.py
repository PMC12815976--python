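"""Figures, exports, throughput benchmark and pipeline orchestration.

Figures follow the study's presentation: for each regimen and for cycles 1
and 7, the population median concentration-time curve with the 90%
prediction interval (5th–95th percentile band) shaded, and a horizontal
reference line at the 6 µg/mL minimum effective concentration.
"""

from __future__ import annotations

import re
import time
from dataclasses import dataclass
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .config import RunConfig
from .dosing import CycleWindow, DoseEvent, Regimen, expand_regimen
from .engine import SimulationResult, TimeGrid, simulate_population
from .exposure import population_metrics, summarize_exposure
from .population import generate_population, write_population

__all__ = [
    "BenchmarkResult",
    "plot_cycle_ribbon",
    "export_nonmem_dataset",
    "write_nonmem_dataset",
    "events_from_nonmem",
    "benchmark_throughput",
    "run_pipeline",
    "slug",
]

NONMEM_COLUMNS = ["ID", "TIME", "AMT", "RATE", "EVID", "CMT", "DV",
                  "WT", "ALB", "TUM", "ADA", "SEXF"]


@dataclass(frozen=True)
class BenchmarkResult:
    """Throughput of one simulation run (hardware-dependent, non-normative)."""

    n_observations: int
    wall_seconds: float

    @property
    def obs_per_sec(self) -> float:
        return self.n_observations / self.wall_seconds


def slug(name: str) -> str:
    return re.sub(r"[^a-z0-9]+", "-", name.lower()).strip("-")


def plot_cycle_ribbon(result: SimulationResult, window: CycleWindow, mec: float,
                      path) -> Path:
    """Median + 90% PI ribbon for one cycle, MEC reference line included.

    x is time after the cycle's dose in days; writes both raster (.png)
    and vector (.svg) files and returns the raster path.
    """
    if result.conc.size == 0:
        raise ValueError("empty profile set")
    mask = (result.grid.times >= window.start) & (result.grid.times <= window.end)
    if not np.any(mask):
        raise ValueError(f"profiles do not cover cycle {window.index}")
    t = result.grid.times[mask]
    order = np.argsort(t, kind="stable")
    t = t[order] - window.start
    band = np.percentile(result.conc[:, mask][:, order], [5, 50, 95], axis=0)

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(t, band[0], band[2], alpha=0.3, color="#4878cf", label="90% PI")
    ax.plot(t, band[1], color="#1f3b73", lw=1.8, label="median")
    ax.axhline(mec, color="#c44e52", ls="--", lw=1.2, label=f"MEC = {mec:g} µg/mL")
    ax.set_xlabel("Time after dose (days)")
    ax.set_ylabel("Atezolizumab concentration (µg/mL)")
    ax.set_title(f"{result.regimen.name} — cycle {window.index}")
    ax.set_xlim(0, window.length)
    ax.set_ylim(bottom=0)
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    fig.savefig(path.with_suffix(".svg"))
    plt.close(fig)
    return path


def export_nonmem_dataset(population: pd.DataFrame, regimen: Regimen, grid: TimeGrid,
                          infusion_duration: float) -> pd.DataFrame:
    """NONMEM-style rectangular event dataset.

    Dose rows: EVID=1, CMT=1, RATE=AMT/duration; observation rows: EVID=0
    with missing DV.  Sorted by ID then TIME, dose rows before same-time
    observations.  Covariates: WT (kg), ALB (g/L), TUM (mm), ADA (0/1),
    SEXF (1=female).
    """
    events, _ = expand_regimen(regimen, infusion_duration)
    frames = []
    for row in population.itertuples(index=False):
        cov = {"WT": row.weight, "ALB": row.albumin, "TUM": row.tumor_size,
               "ADA": int(row.ada), "SEXF": int(row.sex == "female")}
        dose = pd.DataFrame({
            "ID": int(row.subject_id),
            "TIME": [ev.time for ev in events],
            "AMT": [ev.amount for ev in events],
            "RATE": [ev.amount / ev.duration if ev.duration > 0 else 0.0 for ev in events],
            "EVID": 1, "CMT": 1, "DV": np.nan, "_prio": 0, **cov,
        })
        obs = pd.DataFrame({
            "ID": int(row.subject_id),
            "TIME": grid.times,
            "AMT": 0.0, "RATE": 0.0, "EVID": 0, "CMT": 1, "DV": np.nan, "_prio": 1, **cov,
        })
        frames.append(pd.concat([dose, obs], ignore_index=True))
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["ID", "TIME", "_prio"], kind="stable").drop(columns="_prio")
    return out[NONMEM_COLUMNS].reset_index(drop=True)


def write_nonmem_dataset(df: pd.DataFrame, path) -> None:
    """Comma-delimited with a header row; '.' marks missing DV."""
    df.to_csv(path, index=False, na_rep=".")


def events_from_nonmem(df: pd.DataFrame, subject_id: int,
                       ) -> list[DoseEvent]:
    """Reconstruct dose events for one subject from an exported dataset."""
    rows = df[(df["ID"] == subject_id) & (df["EVID"] == 1)]
    return [DoseEvent(time=float(r.TIME), amount=float(r.AMT),
                      duration=float(r.AMT) / float(r.RATE) if r.RATE > 0 else 0.0)
            for r in rows.itertuples(index=False)]


def benchmark_throughput(run) -> BenchmarkResult:
    """Time a deterministic run closure returning an observation count.

    The absolute rate is hardware-dependent and reported for information
    only; no cross-software claim is made.
    """
    t0 = time.perf_counter()
    n_obs = int(run())
    wall = time.perf_counter() - t0
    if wall <= 0:
        raise RuntimeError("zero-duration benchmark run")
    return BenchmarkResult(n_observations=n_obs, wall_seconds=wall)


def run_pipeline(config: RunConfig, output_dir=None, report_cycles=(1, 7)) -> dict:
    """Full study pipeline: population → simulate → summarize → plot.

    Writes the population table, one exposure summary table per regimen, a
    combined summary, and one ribbon figure per regimen x reported cycle.
    Returns a manifest with the in-memory objects and written paths.
    """
    outdir = Path(output_dir if output_dir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    population = generate_population(config.population)
    write_population(population, outdir / "population.csv")

    results, tables, figures, summaries = {}, [], [], []
    for i, regimen in enumerate(config.regimens):
        # independent deterministic IIV seed per regimen
        sim_seed = (config.seed * 1000003 + i) % (2**31)
        res = simulate_population(population, config.model, regimen,
                                  resolution=config.resolution, seed=sim_seed,
                                  infusion_duration=config.infusion_duration)
        results[regimen.name] = res
        metrics = population_metrics(res, cycles=report_cycles)
        summary = summarize_exposure(metrics)
        summaries.append(summary)
        tpath = outdir / f"summary_{slug(regimen.name)}.csv"
        summary.to_csv(tpath, index=False, float_format="%.6g")
        tables.append(tpath)
        for w in res.windows:
            if w.index in report_cycles:
                figures.append(plot_cycle_ribbon(
                    res, w, config.mec,
                    outdir / f"fig_{slug(regimen.name)}_cycle{w.index}.png"))
    combined = pd.concat(summaries, ignore_index=True)
    combined.to_csv(outdir / "summary_all.csv", index=False, float_format="%.6g")
    return {
        "population": population,
        "results": results,
        "summary": combined,
        "population_path": outdir / "population.csv",
        "tables": tables,
        "figures": figures,
        "n_observations": {name: r.n_observations for name, r in results.items()},
    }
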