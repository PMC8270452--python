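"""End-to-end orchestration: ingest (or simulate) -> day-level tests ->
smoothing and trend -> machine-readable report."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from . import daily_tests, ingest, simulate, smoothing

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One reproducible analysis run.

    Exactly one of ``posts_csv`` (a labelled post stream on disk) or
    ``scenario`` (a synthetic scenario) provides the input.
    """

    out_dir: str
    posts_csv: str | None = None
    scenario: simulate.ScenarioConfig | None = None
    start: date | None = None
    end: date | None = None
    window: int = 15
    sensitivity_windows: tuple[int, ...] = ()
    alphas: tuple[float, ...] = (0.10, 0.05, 0.01)
    h_grid: tuple[float, ...] = tuple(np.geomspace(0.005, 0.2, 25))
    max_degree: int = 5
    delta_r2: float = 0.01
    min_volume: int = 1
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = json.load(fh)
        if "scenario" in d and d["scenario"] is not None:
            d["scenario"] = simulate.ScenarioConfig(**d["scenario"])
        for key in ("start", "end"):
            if d.get(key):
                d[key] = date.fromisoformat(d[key])
        for key in ("sensitivity_windows", "alphas", "h_grid"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class AnalysisReport:
    summary: dict
    test_summaries: dict[str, dict]
    trend: dict
    bandwidth: float
    config_echo: dict
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "polarity_summary": self.summary,
            "tests": self.test_summaries,
            "smoothing": {"bandwidth": self.bandwidth,
                          "kernel": "discrete_beta"},
            "trend": self.trend,
            "config": self.config_echo,
        }


class StageError(RuntimeError):
    """An analysis stage failed; the stage name prefixes the message."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"[{stage}] {original}")
        self.stage = stage


def run_analysis(config: RunConfig) -> AnalysisReport:
    """Execute the whole pipeline and write CSV/JSON artifacts to out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"disorient {__version__} seed={config.seed}"]

    # --- stage: input -----------------------------------------------------
    try:
        if config.scenario is not None:
            series, truth = simulate.generate_series(config.scenario,
                                                     seed=config.seed)
            truth.to_json(out / "truth.json")
            log_lines.append(
                f"simulate: {config.scenario.n_days} days, "
                f"total volume {int(series.volume.sum())}")
        elif config.posts_csv is not None:
            records = ingest.read_posts_csv(config.posts_csv)
            n_raw = len(records)
            records = ingest.deduplicate(records)
            if config.start is None or config.end is None:
                stamps = [r.timestamp for r in records]
                start = min(stamps).date()
                end = max(stamps).date()
            else:
                start, end = config.start, config.end
            series = ingest.aggregate_daily(records, start, end)
            log_lines.append(
                f"ingest: {n_raw} records read, "
                f"{len(records)} retained after dedup/OOC, "
                f"{int(series.volume.sum())} in range")
        else:
            raise ValueError("config needs posts_csv or scenario")
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError("input", exc) from exc
    series.to_csv(out / "daily.csv")

    # --- stage: summary ---------------------------------------------------
    try:
        summary = ingest.polarity_summary(series, seed=config.seed)
    except Exception as exc:
        raise StageError("summary", exc) from exc

    # --- stage: tests -----------------------------------------------------
    test_summaries: dict[str, dict] = {}
    try:
        runs = {
            "basic": daily_tests.basic_daily_test(
                series, min_volume=config.min_volume, seed=config.seed),
            "running": daily_tests.running_daily_test(
                series, window=config.window, min_volume=config.min_volume,
                seed=config.seed),
            "variance": daily_tests.running_variance_test(
                series, window=max(config.window, 3)),
        }
        for name, res in runs.items():
            res.to_csv(out / f"tests_{name}.csv", index=False)
            summ = daily_tests.rejection_summary(res, config.alphas)
            test_summaries[name] = summ.to_dict()
            log_lines.append(
                f"test {name}: tested {summ.tested_days}, rejected "
                f"{dict(zip(summ.alphas, summ.rejected_days))}")
        if config.sensitivity_windows:
            sens = daily_tests.window_sensitivity(
                series, config.sensitivity_windows, config.alphas,
                seed=config.seed)
            sens.to_csv(out / "window_sensitivity.csv", index=False)
    except Exception as exc:
        raise StageError("tests", exc) from exc

    # --- stage: smoothing + trend ----------------------------------------
    try:
        props = series.proportions()
        h_star, cv_table = smoothing.cv_bandwidth(props, config.h_grid)
        cv_table.to_csv(out / "cv_bandwidth.csv", index=False)
        smoothed = smoothing.smooth_series(props, h_star)
        sm_out = pd.concat(
            [props.add_prefix("raw_"), smoothed.values.add_prefix("smooth_")],
            axis=1)
        sm_out.insert(0, "date", sm_out.index.strftime("%Y-%m-%d"))
        sm_out.to_csv(out / "smoothed.csv", index=False)
        fit = smoothing.fit_polynomial_trend(
            smoothed.values["p_F"].to_numpy(),
            max_degree=config.max_degree, delta_r2=config.delta_r2)
        trend = fit.to_dict()
        with open(out / "trend.json", "w") as fh:
            json.dump(trend, fh, indent=2)
        log_lines.append(
            f"smoothing: h*={h_star:.4g}; trend degree {fit.selected_degree}, "
            f"R2 {fit.r2_by_degree[fit.selected_degree]:.4f}")
    except Exception as exc:
        raise StageError("smoothing", exc) from exc

    config_echo = {
        "window": config.window, "alphas": list(config.alphas),
        "max_degree": config.max_degree, "delta_r2": config.delta_r2,
        "seed": config.seed,
        "input": "scenario" if config.scenario is not None else config.posts_csv,
    }
    report = AnalysisReport(summary=summary.to_dict(),
                            test_summaries=test_summaries,
                            trend=trend, bandwidth=h_star,
                            config_echo=config_echo)
    with open(out / "summary.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return report
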