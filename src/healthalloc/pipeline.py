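"""One-call orchestration of the full equity-and-efficiency analysis.

``run_all`` takes a panel (or a CSV path) and writes the complete report
bundle: the by-year Gini table, the region-level W table, the two DEA
reports (years as DMUs on province totals; regions as DMUs per year),
per-region density data for bar summaries, Lorenz plots, and a metadata
JSON.  Display tables round to the conventional precision (2 decimals for
Gini and W, 3 for efficiencies); the ``*_full.csv`` companions keep machine
precision, and every displayed number is a pure rounding of its
machine-precision counterpart.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import version
from pathlib import Path

from .panel import RESOURCES, Panel, read_panel
from . import density, dea, equity

logger = logging.getLogger("healthalloc")


@dataclass
class AnalysisConfig:
    input_path: str | Path | None = None
    output_dir: str | Path = "healthalloc_report"
    resources: tuple[str, ...] = RESOURCES
    dea_tol: float = dea.DEFAULT_TOL
    dea_slack_frontier: str = "crs"
    w_standard: str = "aggregate"
    make_plots: bool = True
    lorenz_years: tuple[int, ...] | None = None  # default: first and last year
    log_level: str = "INFO"


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def _write_pair(df, out_dir: Path, name: str, decimals: int, index=False) -> None:
    df.to_csv(out_dir / f"{name}_full.csv", index=index)
    df.round(decimals).to_csv(out_dir / f"{name}.csv", index=index)


def run_all(config: AnalysisConfig, panel: Panel | None = None) -> dict:
    """Run every analysis stage and write the report bundle.

    Returns a dict mapping artifact names to paths.  Any stage failure
    aborts with the stage name attached.
    """
    logging.basicConfig(level=config.log_level)
    if panel is None:
        if config.input_path is None:
            raise ValueError("either a panel or config.input_path is required")
        panel = read_panel(config.input_path)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    logger.info(
        "panel: %d regions × %d years, complete=%s",
        len(panel.regions), len(panel.years), panel.is_complete,
    )

    gt = _stage("gini_table")(equity.gini_table)(panel, config.resources)
    flat = gt.copy()
    flat.columns = [f"{b}_{r}" for b, r in gt.columns]
    _write_pair(flat, out, "gini_table", 2, index=True)
    artifacts["gini_table"] = out / "gini_table.csv"

    w_long = _stage("w_table")(density.w_table)(
        panel, config.resources, standard=config.w_standard
    )
    w_long.to_csv(out / "w_table_full.csv", index=False)
    grid = density.w_grid(w_long)
    grid.columns = [f"{res}_{yr}" for res, yr in grid.columns]
    grid.round(2).to_csv(out / "w_table.csv")
    density.flag_w_extremes(w_long).to_csv(out / "w_flags.csv")
    artifacts["w_table"] = out / "w_table.csv"

    dens = _stage("density_table")(density.density_table)(panel, config.resources)
    _write_pair(dens, out, "density_by_region", 2)
    artifacts["density_by_region"] = out / "density_by_region.csv"

    by_year = _stage("dea_by_year")(dea.dea_by_year_table)(
        panel, tol=config.dea_tol, slack_frontier=config.dea_slack_frontier
    )
    _write_pair(by_year, out, "dea_by_year", 3)
    artifacts["dea_by_year"] = out / "dea_by_year.csv"

    by_region = _stage("dea_by_region")(dea.dea_by_region_table)(
        panel, tol=config.dea_tol, slack_frontier=config.dea_slack_frontier
    )
    _write_pair(by_region, out, "dea_by_region", 3)
    artifacts["dea_by_region"] = out / "dea_by_region.csv"

    if config.make_plots:
        years = config.lorenz_years or (panel.years[0], panel.years[-1])
        _stage("lorenz_plot")(equity.plot_lorenz)(
            panel, years=years, resources=config.resources, path=out / "lorenz.png"
        )
        artifacts["lorenz_plot"] = out / "lorenz.png"

    meta = {
        "package": "healthalloc",
        "version": version("healthalloc"),
        "n_regions": len(panel.regions),
        "years": panel.years,
        "complete": panel.is_complete,
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in vars(config).items()
        },
        "panel_sha256": hashlib.sha256(
            panel.frame.to_csv(index=False).encode()
        ).hexdigest(),
    }
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=2, default=str))
    artifacts["run_metadata"] = out / "run_metadata.json"
    logger.info("report bundle written to %s", out)
    return artifacts
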