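"""Pixel-wise prediction, cell aggregation, and plot-level comparison.

The fitted yield model is applied to every pixel of the index stack,
predictions are averaged within each retained 25-cm grid cell,

    yhat_{c_i} = sum_{p in c_i} yhat_p / n_{c_i},

and the per-plot distribution of cell predictions is compared against the
manually harvested quadrat value for that plot (is the manual value inside
the predicted inter-quartile range?).

Point predictions are conditional means: the residual term of the yield
model is *not* added.  Pass ``simulate_residual=True`` (with an rng) to add
N(0, sigma^2) noise for uncertainty propagation experiments.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .geometry import Grid
from .raster import IndexStack, RasterLayer
from .selection import FitResult

__all__ = [
    "predict_pixels",
    "aggregate_cells",
    "summarize_plots",
]

log = logging.getLogger(__name__)


def predict_pixels(
    best: FitResult,
    stack: IndexStack,
    simulate_residual: bool = False,
    rng: np.random.Generator | None = None,
) -> RasterLayer:
    """Apply the fitted model at every pixel where all covariates are valid."""
    missing = [name for name in best.spec if name not in stack]
    if missing:
        raise KeyError(f"index stack lacks model covariates: {missing}")
    ref = stack.grid
    mask = stack.common_mask(best.spec) if best.spec else ref.mask.copy()
    yhat = np.full(ref.shape, best.intercept, dtype=float)
    for name, slope in best.slopes.items():
        yhat += slope * stack[name].values
    if simulate_residual:
        if rng is None:
            raise ValueError("simulate_residual=True requires an rng")
        yhat = yhat + rng.normal(0.0, np.sqrt(best.sigma2), size=yhat.shape)
    yhat[~mask] = np.nan
    return RasterLayer(
        values=yhat,
        x_origin=ref.x_origin,
        y_origin=ref.y_origin,
        pixel_size=ref.pixel_size,
        kind="index",
        mask=mask,
    )


def aggregate_cells(
    pred_map: RasterLayer,
    cells: pd.DataFrame,
    grid: Grid,
) -> pd.DataFrame:
    """Mean pixel prediction per retained grid cell.

    ``cells`` is the classification frame from
    :func:`uavfield.geometry.classify_cells`; only ``retained`` rows are
    aggregated.  Pixel membership is pixel-center-in-cell with half-open
    cells.  Retained cells with zero unmasked pixels are dropped with a
    warning.  Returns one row per surviving cell: cell_i, cell_j, plot_id,
    y_hat, n_pixels.
    """
    retained = cells[cells["status"] == "retained"]
    if retained.empty:
        raise ValueError("no retained cells to aggregate")
    xs, ys = pred_map.pixel_center_coords()
    X, Y = np.meshgrid(xs, ys)
    valid = pred_map.mask & np.isfinite(pred_map.values)
    ci, cj = grid.cell_of(X[valid], Y[valid])
    vals = pred_map.values[valid]

    inside = (ci >= 0) & (ci < grid.n_rows) & (cj >= 0) & (cj < grid.n_cols)
    ci, cj, vals = ci[inside], cj[inside], vals[inside]
    flat = ci * grid.n_cols + cj
    sums = np.bincount(flat, weights=vals, minlength=grid.n_cells)
    counts = np.bincount(flat, minlength=grid.n_cells)

    key = retained["cell_i"].to_numpy() * grid.n_cols + retained["cell_j"].to_numpy()
    n_pix = counts[key]
    empty = n_pix == 0
    if empty.any():
        log.warning("%d retained cells contain no unmasked pixels; dropped",
                    int(empty.sum()))
    with np.errstate(invalid="ignore"):
        means = np.where(n_pix > 0, sums[key] / np.maximum(n_pix, 1), np.nan)
    out = pd.DataFrame(
        {
            "cell_i": retained["cell_i"].to_numpy(),
            "cell_j": retained["cell_j"].to_numpy(),
            "plot_id": retained["plot_id"].to_numpy(),
            "y_hat": means,
            "n_pixels": n_pix,
        }
    )
    return out[~empty].reset_index(drop=True)


def summarize_plots(
    cellset: pd.DataFrame,
    manual: pd.DataFrame,
    value_col: str = "manual_value",
) -> tuple[pd.DataFrame, float]:
    """Per-plot quartile comparison of predicted cells vs. the manual sample.

    ``manual`` maps plot_id -> manual quadrat value (column ``value_col`` or
    the first non-id column).  Quartiles use the linear-interpolation
    definition.  A plot is *flagged* when its manual value falls strictly
    outside [q25, q75].  Returns the per-plot summary and the flagged
    percentage (to 0.1 %).  Plots without a manual sample are skipped with a
    warning.
    """
    man = manual.copy()
    if "plot_id" in man.columns:
        man = man.set_index("plot_id")
    if value_col not in man.columns:
        value_col = man.columns[0]
    rows = []
    for plot_id, grp in cellset.groupby("plot_id"):
        if plot_id not in man.index:
            log.warning("plot %s has no manual sample; skipped", plot_id)
            continue
        q25, q50, q75 = np.percentile(grp["y_hat"], [25, 50, 75])
        value = float(man.loc[plot_id, value_col])
        outside = value < q25 or value > q75
        rows.append(
            {
                "plot_id": plot_id,
                "n_cells": int(len(grp)),
                "q25": q25,
                "median": q50,
                "q75": q75,
                "manual_value": value,
                "outside_iqr": outside,
                "direction": "below" if value < q25 else ("above" if value > q75 else "inside"),
            }
        )
    summary = pd.DataFrame(rows)
    if summary.empty:
        raise ValueError("no plots could be summarized")
    pct = outside_fraction_pct(int(summary["outside_iqr"].sum()), len(summary))
    return summary, pct


def outside_fraction_pct(n_flagged: int, n_plots: int) -> float:
    """Percentage of flagged plots, reported to one decimal place."""
    if n_plots <= 0:
        raise ValueError("n_plots must be positive")
    return round(100.0 * n_flagged / n_plots, 1)
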