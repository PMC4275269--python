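"""High-level pipeline runs mirroring the two analysis approaches.

Each ``run_*`` function is a pure function of (input files, config, seed):
it reads profiles and/or the event catalog, executes one analysis stage and
writes tables (CSV), figures (PNG) and a run log into the output directory.
The thin command-line layer in :mod:`medheat.cli` wraps these directly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import climatology as clim
from .catalog import read_catalog, write_catalog
from .interp import BAND_0_50, LAYERS, DepthLayer
from .profiles import ProfileSet, read_profiles, write_profiles
from .qc import QCConfig, apply_qc
from .trends import GridSpec, TrendCellResult, trend_map, trend_table

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_simulate", "run_qc", "run_trends",
           "run_local", "run_associate"]

_LAYER_BY_LABEL = {ly.label: ly for ly in (*LAYERS, BAND_0_50)}


class PipelineError(RuntimeError):
    """A pipeline stage cannot proceed (e.g. nothing survived QC)."""


@dataclass
class RunConfig:
    """Wiring for a pipeline run; echoed verbatim into the output dir."""

    profiles_path: str = "profiles.csv"
    catalog_path: str = "catalog.csv"
    out_dir: str = "out"
    cell_size: float = 1.0
    months: tuple[int, ...] = (7, 8, 9, 10, 11)
    confidence: float = 0.90
    min_years: int = 10
    layer_policy: str = "band_0_50"
    restrict_to_significant: bool = True
    n_bins: int = 5
    seed: int = 0
    qc: QCConfig = field(default_factory=QCConfig)

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.cell_size)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        qc_raw = raw.pop("qc", {})
        for key in ("months",):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        if qc_raw:
            for k in ("region_bounds", "temp_range", "duplicate_tolerance",
                      "date_window"):
                if k in qc_raw:
                    qc_raw[k] = tuple(qc_raw[k])
            if "months" in qc_raw:
                qc_raw["months"] = frozenset(qc_raw["months"])
            cfg.qc = QCConfig(**qc_raw)
        return cfg

    def echo(self, out_dir: Path) -> None:
        d = dataclasses.asdict(self)
        d["qc"]["months"] = sorted(d["qc"]["months"])
        (out_dir / "config_echo.yaml").write_text(
            yaml.safe_dump(d, sort_keys=True))


def _prepare(config: RunConfig) -> tuple[ProfileSet, Path]:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.echo(out)
    pset = read_profiles(config.profiles_path)
    passed, report = apply_qc(pset, config.qc)
    for line in report.log_lines():
        log.info(line)
    report.to_table().to_csv(out / "qc_report.csv", index=False)
    return passed, out


def run_simulate(syn_config, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete synthetic dataset into a directory.

    Produces the profiles file, event catalog, the two truth sidecars and
    a config echo; returns the paths.
    """
    from .synthetic import SyntheticConfig, generate_events, sample_profiles

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pset, profile_truth = sample_profiles(syn_config)
    events, event_truth = generate_events(syn_config)
    paths = {
        "profiles": out / "profiles.csv",
        "catalog": out / "catalog.csv",
        "profile_truth": out / "profile_truth.csv",
        "event_truth": out / "event_truth.csv",
        "config": out / "synthetic_config.json",
    }
    write_profiles(pset, paths["profiles"])
    write_catalog(events, paths["catalog"])
    profile_truth.to_csv(paths["profile_truth"], index=False)
    event_truth.to_csv(paths["event_truth"], index=False)
    cfg = dataclasses.asdict(syn_config)
    cfg["trend_field"] = {
        "cell_size": syn_config.trend_field.grid.cell_size,
        "betas": {f"{i},{j}": b
                  for (i, j), b in sorted(syn_config.trend_field.betas.items())},
    }
    cfg.pop("year_weight", None)
    paths["config"].write_text(json.dumps(cfg, indent=1, default=str))
    return paths


def run_qc(config: RunConfig) -> Path:
    """QC a profile file and write the passed subset plus the report."""
    passed, out = _prepare(config)
    write_profiles(passed, out / "profiles_passed.csv")
    return out


def run_trends(config: RunConfig,
               make_plot: bool = True) -> list[TrendCellResult]:
    """Approach 1: gridded yearly trends with significance, table + map."""
    passed, out = _prepare(config)
    if not len(passed):
        raise PipelineError("no profiles passed QC")
    results = trend_map(passed, config.grid, months=config.months,
                        confidence=config.confidence,
                        min_years=config.min_years)
    if not results:
        raise PipelineError("no cell had enough data for a trend")
    table = trend_table(results, config.grid)
    table.to_csv(out / "trend_table.csv", index=False)
    if make_plot:
        from .plots import plot_trend_map
        for layer in (*LAYERS, BAND_0_50):
            sub = [r for r in results if r.layer.label == layer.label]
            if sub:
                plot_trend_map(sub, config.grid,
                               path=out / f"trend_map_{layer.label}.png")
    log.info("trends: %d cell-layer results", len(results))
    return results


def run_local(config: RunConfig,
              boxes: Sequence[clim.RegionBox] = clim.DEFAULT_BOXES,
              make_plots: bool = True) -> dict[str, pd.DataFrame]:
    """Approach 2: two-period climatologies, event anomalies, extremes."""
    passed, out = _prepare(config)
    events, _ = read_catalog(config.catalog_path)
    anomaly_rows = []
    n_plots = 0
    for box in boxes:
        box_events = [e for e in events
                      if box.contains(e.latitude, e.longitude)
                      and e.month is not None]
        if not any(box.contains(p.latitude, p.longitude) for p in passed):
            log.warning("box %s has no profiles; skipped", box.name)
            continue
        for month in config.months:
            clims = {per.label: clim.monthly_climatology(passed, box, month, per)
                     for per in (clim.P1945_1982, clim.P1983_2011)}
            if all(c.empty for c in clims.values()):
                continue
            month_events = [e for e in box_events if e.month == month]
            anomalies = [clim.event_anomaly(passed, box, e.year, e.month)
                         for e in month_events]
            if make_plots:
                from .plots import plot_climatology
                plot_climatology(
                    list(clims.values()),
                    [a for a in anomalies if not a.no_data],
                    path=out / f"climatology_{box.name.replace(' ', '_')}"
                               f"_{month:02d}.png")
                n_plots += 1
            for e, a in zip(month_events, anomalies):
                for per_label, ma in a.max_anomaly.items():
                    anomaly_rows.append({
                        "box": box.name, "event_id": e.event_id,
                        "year": e.year, "month": e.month,
                        "reference": per_label,
                        "n_event_profiles": a.n_event_profiles,
                        "max_anomaly_c": None if ma is None else ma[0],
                        "max_anomaly_depth_m": None if ma is None else ma[1],
                    })
    anomaly_table = pd.DataFrame(anomaly_rows, columns=[
        "box", "event_id", "year", "month", "reference",
        "n_event_profiles", "max_anomaly_c", "max_anomaly_depth_m"])
    freq_table = clim.extreme_frequency(passed, boxes, months=config.months)
    anomaly_table.to_csv(out / "anomaly_table.csv", index=False)
    freq_table.to_csv(out / "extreme_frequency.csv", index=False)
    log.info("local: %d plots, %d anomaly rows", n_plots, len(anomaly_table))
    return {"anomalies": anomaly_table, "extremes": freq_table}


def load_trend_table(path: str | Path,
                     grid: GridSpec | None = None) -> list[TrendCellResult]:
    """Rebuild TrendCellResult objects from an exported trend table."""
    grid = grid or GridSpec()
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        cell = (round(r["cell_lon_edge"] / grid.cell_size),
                round(r["cell_lat_edge"] / grid.cell_size))
        out.append(TrendCellResult(
            cell=(int(cell[0]), int(cell[1])),
            layer=_LAYER_BY_LABEL[r["layer"]],
            slope=float(r["slope"]), intercept=float(r["intercept"]),
            p_value=float(r["p_value"]), n_years=int(r["n_years"]),
            significant=bool(r["significant"])))
    return out


def run_associate(config: RunConfig,
                  make_plot: bool = True) -> assoc.AssociationResult:
    """Match catalog events to the trend map and run the association stats.

    Uses ``<out_dir>/trend_table.csv`` when present (as written by
    :func:`run_trends`); otherwise recomputes the map from the profiles.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trend_file = out / "trend_table.csv"
    if trend_file.exists():
        results = load_trend_table(trend_file, config.grid)
    else:
        results = run_trends(config, make_plot=False)
    events, rejects = read_catalog(config.catalog_path)
    if len(rejects):
        log.warning("catalog: %d rejected rows", len(rejects))
    res = assoc.associate(
        events, results, config.grid,
        layer_policy=config.layer_policy,
        restrict_to_significant=config.restrict_to_significant,
        n_bins=config.n_bins)
    report = {
        "n_events": len(events),
        "n_assigned": len(res.assignments),
        "n_unmatched": len(res.unmatched),
        "n_neg": res.sign.n_neg,
        "n_pos": res.sign.n_pos,
        "cells_neg": res.sign.cells_neg,
        "cells_pos": res.sign.cells_pos,
        "event_ratio": list(res.sign.event_ratio),
        "area_ratio": list(res.sign.area_ratio),
        "bin_edges": [float(x) for x in res.bin_edges],
        "histogram": [float(x) for x in res.histogram],
        "ks_D": res.ks.D,
        "ks_p": res.ks.p,
        "ks_two_sample_D": res.ks.two_sample_D,
        "ks_two_sample_p": res.ks.two_sample_p,
        "ks_underpowered": res.ks.underpowered,
        "restricted_to_significant": res.restricted_to_significant,
    }
    (out / "association_report.json").write_text(json.dumps(report, indent=1))
    pd.DataFrame([{
        "event_id": a.event_id, "cell_i": a.cell[0], "cell_j": a.cell[1],
        "layer": a.layer.label, "slope": a.slope, "p_value": a.p_value,
        "significant": a.significant, "weight": a.weight,
    } for a in res.assignments]).to_csv(out / "assignments.csv", index=False)
    if make_plot and len(res.histogram):
        from .plots import plot_association_histogram
        plot_association_histogram(res, path=out / "association_hist.png")
    return res
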