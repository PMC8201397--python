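"""File-based pipeline steps tying the analysis stages together.

Steps communicate only through files in the run's output directory, so each
stage can be rerun, inspected or replaced independently:

    simulate      -> index_*.tif, layout.geojson, sample_points.geojson,
                     samples.csv, traits.csv, truth.json
    indices       -> stack.json  (candidate layers after exclusions)
    extract       -> covariates.csv, modeling_table.csv, join_report.json
    select        -> selection_table.csv, best_model.txt
    predict       -> prediction.tif
    grid          -> cells.csv, cell_predictions.csv, plot_summary.csv,
                     grid_summary.json
    test-cultivar -> cultivar_contrasts.csv, cultivar_lrt.json,
                     variance_components.csv
    test-traits   -> trait_lrts.csv, marginal_effects.csv
    report        -> report.json

Every step writes ``manifest_<step>.json`` recording its inputs, parameters,
package version, seed and the configuration hash; ``report`` refuses to
summarize a run whose artifacts were produced under different hashes.
"""

from __future__ import annotations

import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .geometry import (
    build_grid,
    classify_cells,
    extract_point_covariates,
    join_samples,
    layout_from_geojson,
    points_from_geojson,
)
from .imagery import build_index_stack
from .mixedmodels import cultivar_analysis, marginal_effects, trait_analysis
from .prediction import aggregate_cells, predict_pixels, summarize_plots
from .raster import read_geotiff, write_geotiff
from .selection import best_model, fit_all_subsets, load_best_model, save_best_model
from .synthetic import SyntheticConfig, write_experiment

__all__ = ["run_step", "run_all", "PipelineError", "STEPS"]

log = logging.getLogger(__name__)

STEPS = (
    "simulate", "indices", "extract", "select", "predict", "grid",
    "test-cultivar", "test-traits", "report",
)


class PipelineError(RuntimeError):
    """A step cannot run (missing prerequisites or inconsistent artifacts)."""


def _require(outdir: Path, filename: str, producer: str) -> Path:
    path = outdir / filename
    if not path.exists():
        raise PipelineError(
            f"missing prerequisite {filename!r}; run the {producer!r} step first"
        )
    return path


def _write_manifest(outdir: Path, step: str, config: PipelineConfig,
                    inputs: list[str], outputs: list[str]) -> None:
    manifest = {
        "step": step,
        "inputs": inputs,
        "outputs": outputs,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    with open(outdir / f"manifest_{step}.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def _load_stack(outdir: Path, config: PipelineConfig):
    spec_path = _require(outdir, "stack.json", "indices")
    with open(spec_path) as fh:
        stack_spec = json.load(fh)
    layers = {
        name: read_geotiff(outdir / fname)
        for name, fname in stack_spec["layers"].items()
    }
    return build_index_stack(layers)


def _cell_observations(outdir: Path) -> pd.DataFrame:
    cells = pd.read_csv(_require(outdir, "cell_predictions.csv", "grid"))
    layout = layout_from_geojson(_require(outdir, "layout.geojson", "simulate"))
    meta = layout.plot_table()
    obs = cells.merge(meta, on="plot_id", how="left")
    obs["cell_id"] = obs["cell_i"].astype(str) + "_" + obs["cell_j"].astype(str)
    return obs


# ---------------------------------------------------------------------------
# individual steps
# ---------------------------------------------------------------------------

def _step_simulate(outdir: Path, config: PipelineConfig) -> list[str]:
    syn = dict(config.synthetic)
    syn.setdefault("random_seed", config.seed)
    syn.setdefault("quadrat_size_m", config.quadrat_size_m)
    manifest = write_experiment(outdir, SyntheticConfig(**syn))
    with open(outdir / "experiment.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return ["experiment.json", *manifest["index_files"].values(),
            "layout.geojson", "sample_points.geojson", "samples.csv",
            "traits.csv", "truth.json"]


def _step_indices(outdir: Path, config: PipelineConfig) -> list[str]:
    """Collect candidate index layers and apply configured exclusions.

    Synthetic runs (and pre-processed real surveys) provide ready-made
    ``index_<name>.tif`` files; raw-product workflows can point
    ``raster_dir`` at externally computed index GeoTIFFs with the same
    naming convention.
    """
    src = Path(config.raster_dir) if config.raster_dir else outdir
    layers = {}
    for name in config.candidates:
        path = src / f"index_{name}.tif"
        if not path.exists():
            raise PipelineError(
                f"missing index raster {path.name!r}; run 'simulate' or point "
                "raster_dir at precomputed index GeoTIFFs"
            )
        layers[name] = path
    kept = [n for n in config.candidates if n not in set(config.exclusions)]
    # validate co-registration before committing the stack manifest
    stack = build_index_stack({n: read_geotiff(layers[n]) for n in kept})
    spec = {
        "layers": {n: str(layers[n].name) if layers[n].parent == outdir
                   else str(layers[n]) for n in kept},
        "m": stack.m,
        "excluded": list(config.exclusions),
    }
    with open(outdir / "stack.json", "w") as fh:
        json.dump(spec, fh, indent=1)
    return ["stack.json"]


def _step_extract(outdir: Path, config: PipelineConfig) -> list[str]:
    stack = _load_stack(outdir, config)
    points = points_from_geojson(_require(outdir, "sample_points.geojson", "simulate"))
    for pt in points:
        pt.quadrat_size = config.quadrat_size_m
    samples = pd.read_csv(_require(outdir, "samples.csv", "simulate"))
    covariates = extract_point_covariates(stack, points)
    covariates.to_csv(outdir / "covariates.csv")
    harvest = samples.drop(columns=["x", "y", "plot_id"], errors="ignore")
    joined, report = join_samples(covariates, harvest,
                                  exclude_ids=config.sample_exclude_ids)
    joined.to_csv(outdir / "modeling_table.csv")
    with open(outdir / "join_report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return ["covariates.csv", "modeling_table.csv", "join_report.json"]


def _step_select(outdir: Path, config: PipelineConfig) -> list[str]:
    data = pd.read_csv(_require(outdir, "modeling_table.csv", "extract"))
    with open(_require(outdir, "stack.json", "indices")) as fh:
        names = list(json.load(fh)["layers"])
    table = fit_all_subsets(data, names, config.response,
                            max_candidates=config.max_candidates)
    table.to_csv(outdir / "selection_table.csv")
    save_best_model(best_model(table), outdir / "best_model.txt")
    return ["selection_table.csv", "best_model.txt"]


def _step_predict(outdir: Path, config: PipelineConfig) -> list[str]:
    fit = load_best_model(_require(outdir, "best_model.txt", "select"))
    stack = _load_stack(outdir, config)
    pred = predict_pixels(fit, stack)
    write_geotiff(outdir / "prediction.tif", pred)
    return ["prediction.tif"]


def _step_grid(outdir: Path, config: PipelineConfig) -> list[str]:
    layout = layout_from_geojson(_require(outdir, "layout.geojson", "simulate"))
    pred = read_geotiff(_require(outdir, "prediction.tif", "predict"))
    grid = build_grid(layout.field, config.cell_size_m)
    cells = classify_cells(grid, layout)
    cells.to_csv(outdir / "cells.csv", index=False)
    cellset = aggregate_cells(pred, cells, grid)
    cellset.to_csv(outdir / "cell_predictions.csv", index=False)

    samples = pd.read_csv(_require(outdir, "samples.csv", "simulate"))
    meta = layout.plot_table()
    # the quartile comparison excludes destructive-sampling plots
    roles = dict(zip(meta["plot_id"], meta["role"]))
    manual = samples[samples["plot_id"].notna()].copy()
    manual = manual[manual["plot_id"].map(roles) != "destructive"]
    summary, pct = summarize_plots(
        cellset[cellset["plot_id"].map(roles) != "destructive"],
        manual[["plot_id", config.response]], config.response,
    )
    summary.to_csv(outdir / "plot_summary.csv", index=False)
    info = {
        "n_cells_total": int(grid.n_cells),
        "n_cells_retained": int(len(cellset)),
        "mean_cells_per_plot": float(len(cellset) / cellset["plot_id"].nunique()),
        "retained_area_m2": float(len(cellset) * config.cell_size_m ** 2),
        "n_plots_summarized": int(len(summary)),
        "n_outside_iqr": int(summary["outside_iqr"].sum()),
        "pct_outside_iqr": pct,
    }
    with open(outdir / "grid_summary.json", "w") as fh:
        json.dump(info, fh, indent=1)
    return ["cells.csv", "cell_predictions.csv", "plot_summary.csv",
            "grid_summary.json"]


def _step_test_cultivar(outdir: Path, config: PipelineConfig) -> list[str]:
    obs = _cell_observations(outdir)
    obs = obs[obs["cultivar"].notna()]
    res = cultivar_analysis(obs, response="y_hat", p_adjust=config.p_adjust)
    res.contrasts.to_csv(outdir / "cultivar_contrasts.csv", index=False)
    res.fit.variance_components().rename("variance").to_csv(
        outdir / "variance_components.csv"
    )
    out = {
        "reference_cultivar": res.reference,
        "emm": {str(k): float(v) for k, v in res.emm.items()},
        "lrt_cultivar": {"statistic": res.lrt_cultivar.statistic,
                         "df": res.lrt_cultivar.df,
                         "p_value": res.lrt_cultivar.p_value},
        "lrt_sowing_date": {"statistic": res.lrt_sowing.statistic,
                            "df": res.lrt_sowing.df,
                            "p_value": res.lrt_sowing.p_value},
    }
    with open(outdir / "cultivar_lrt.json", "w") as fh:
        json.dump(out, fh, indent=1)
    return ["cultivar_contrasts.csv", "variance_components.csv",
            "cultivar_lrt.json"]


def _step_test_traits(outdir: Path, config: PipelineConfig) -> list[str]:
    obs = _cell_observations(outdir)
    traits = pd.read_csv(_require(outdir, "traits.csv", "simulate"))
    obs = obs[obs["role"] == "cultivar"].merge(
        traits.drop(columns=["cultivar"], errors="ignore"), on="plot_id"
    )
    res = trait_analysis(obs, response="y_hat")
    res.lrts.to_csv(outdir / "trait_lrts.csv", index=False)
    # marginal-effect surface for the two stem/above-ground terms
    grids = {}
    for col in ("agb_dw", "stem_dw"):
        v = res.data[col]
        grids[col] = list(np.linspace(v.min(), v.max(), config.marginal_grid_points))
    surface = marginal_effects(res.fit, "agb_dw", "stem_dw",
                               grids["agb_dw"], grids["stem_dw"])
    surface.to_csv(outdir / "marginal_effects.csv", index=False)
    return ["trait_lrts.csv", "marginal_effects.csv"]


def _step_report(outdir: Path, config: PipelineConfig) -> list[str]:
    manifests = sorted(outdir.glob("manifest_*.json"))
    if not manifests:
        raise PipelineError("no step manifests found; nothing to report")
    hashes = {}
    steps_run = []
    for path in manifests:
        with open(path) as fh:
            man = json.load(fh)
        hashes[man["step"]] = man["config_hash"]
        steps_run.append(man["step"])
    if len(set(hashes.values())) > 1:
        raise PipelineError(
            f"inconsistent config hashes across artifacts: {hashes}"
        )
    report: dict = {"steps_run": steps_run, "config_hash": config.config_hash(),
                    "version": __version__}
    for name in ("grid_summary.json", "cultivar_lrt.json", "join_report.json"):
        path = outdir / name
        if path.exists():
            with open(path) as fh:
                report[name.replace(".json", "")] = json.load(fh)
    sel = outdir / "selection_table.csv"
    if sel.exists():
        top = pd.read_csv(sel).iloc[0]
        report["best_model"] = {"spec": top["spec"],
                                "r_squared": float(top["r_squared"]),
                                "df": int(top["df"])}
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return ["report.json"]


_STEP_FUNCS = {
    "simulate": _step_simulate,
    "indices": _step_indices,
    "extract": _step_extract,
    "select": _step_select,
    "predict": _step_predict,
    "grid": _step_grid,
    "test-cultivar": _step_test_cultivar,
    "test-traits": _step_test_traits,
    "report": _step_report,
}


def run_step(step: str, config: PipelineConfig) -> list[str]:
    """Run one named pipeline step; returns the artifact filenames written."""
    if step not in _STEP_FUNCS:
        raise ValueError(f"unknown step {step!r}; choose from {STEPS}")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("running step %s -> %s", step, outdir)
    inputs = []  # filled from _require calls implicitly; recorded coarsely
    outputs = _STEP_FUNCS[step](outdir, config)
    _write_manifest(outdir, step, config, inputs, outputs)
    log.info("step %s wrote: %s", step, ", ".join(outputs))
    return outputs


def run_all(config: PipelineConfig, steps=STEPS) -> dict[str, list[str]]:
    """Run steps in order; returns the artifacts per step."""
    return {step: run_step(step, config) for step in steps}
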