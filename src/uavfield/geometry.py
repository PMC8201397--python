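"""Experimental layout, analysis grid, and per-quadrat covariate extraction.

The field layout is a set of rectangular (in general, polygonal) treatment
plots arranged in sowing rows inside a field polygon, with everything that is
not a plot treated as corridor.  The analysis grid tiles the field bounding
box with square cells (default 0.25 m).  Cells are classified so that every
retained cell belongs to exactly one plot:

* ``retained``            — fully inside exactly one plot,
* ``eliminated_two_plots``— overlaps two or more plots,
* ``eliminated_corridor_mix`` — overlaps one plot but also corridor,
* ``outside``             — touches no plot.

All coordinates are local projected meters; no geographic math anywhere.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, box, mapping, shape
from shapely.strtree import STRtree

from .raster import IndexStack

__all__ = [
    "PlotRecord",
    "FieldLayout",
    "Grid",
    "SamplePoint",
    "LayoutError",
    "build_grid",
    "classify_cells",
    "extract_point_covariates",
    "join_samples",
    "layout_to_geojson",
    "layout_from_geojson",
    "points_to_geojson",
    "points_from_geojson",
]

CELL_STATUSES = (
    "retained",
    "eliminated_two_plots",
    "eliminated_corridor_mix",
    "outside",
)

#: areas below this (m^2) are treated as boundary-touching, not overlap
_AREA_EPS = 1e-9


class LayoutError(ValueError):
    """Raised for invalid field layouts (overlaps, out-of-bounds plots)."""


@dataclass
class PlotRecord:
    plot_id: str
    polygon: Polygon
    row_id: str
    cultivar: str | None = None
    sowing_date: str | None = None
    role: str = "cultivar"  # cultivar | weedy | sheet | destructive


@dataclass
class FieldLayout:
    """Field polygon plus plot records; corridor is field minus plots."""

    field: Polygon
    plots: list[PlotRecord]
    crs_note: str = "local projected Cartesian frame, meters"

    def __post_init__(self) -> None:
        if self.field.is_empty or self.field.area <= 0:
            raise LayoutError("field polygon is degenerate")
        seen: set[str] = set()
        for rec in self.plots:
            if rec.plot_id in seen:
                raise LayoutError(f"duplicate plot id {rec.plot_id!r}")
            seen.add(rec.plot_id)
            if not self.field.covers(rec.polygon):
                raise LayoutError(f"plot {rec.plot_id!r} extends outside the field")
            if not rec.row_id:
                raise LayoutError(f"plot {rec.plot_id!r} lacks a row id")
        polys = [rec.polygon for rec in self.plots]
        tree = STRtree(polys)
        for i, poly in enumerate(polys):
            for j in tree.query(poly, predicate="intersects"):
                if j <= i:
                    continue
                if poly.intersection(polys[j]).area > _AREA_EPS:
                    raise LayoutError(
                        f"plots {self.plots[i].plot_id!r} and "
                        f"{self.plots[j].plot_id!r} overlap"
                    )

    @property
    def corridor(self):
        return self.field.difference(shapely.union_all([p.polygon for p in self.plots]))

    def plot(self, plot_id: str) -> PlotRecord:
        for rec in self.plots:
            if rec.plot_id == plot_id:
                return rec
        raise KeyError(plot_id)

    def plot_table(self) -> pd.DataFrame:
        """Per-plot metadata (no geometry) as a data frame."""
        return pd.DataFrame(
            {
                "plot_id": [p.plot_id for p in self.plots],
                "row_id": [p.row_id for p in self.plots],
                "cultivar": [p.cultivar for p in self.plots],
                "sowing_date": [p.sowing_date for p in self.plots],
                "role": [p.role for p in self.plots],
                "area_m2": [p.polygon.area for p in self.plots],
            }
        )


@dataclass
class Grid:
    """Square-cell tiling of the field bounding box.

    Cells are half-open: cell (i, j) spans
    ``[x_min + j*s, x_min + (j+1)*s) x [y_min + i*s, y_min + (i+1)*s)``,
    with i counted upward from the minimum-y edge.
    """

    x_min: float
    y_min: float
    cell_size: float
    n_cols: int
    n_rows: int

    @property
    def n_cells(self) -> int:
        return self.n_cols * self.n_rows

    def cell_polygon(self, i: int, j: int) -> Polygon:
        s = self.cell_size
        x0 = self.x_min + j * s
        y0 = self.y_min + i * s
        return box(x0, y0, x0 + s, y0 + s)

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Cell indices (i, j) containing map points; half-open convention.

        Coordinates are snapped to nanometer precision before the floor so
        that points sitting numerically on a cell boundary resolve the same
        way as the polygon-based membership test.
        """
        j = np.floor(np.round((np.asarray(x) - self.x_min) / self.cell_size, 9)).astype(int)
        i = np.floor(np.round((np.asarray(y) - self.y_min) / self.cell_size, 9)).astype(int)
        return i, j


@dataclass
class SamplePoint:
    """A ground-truth harvest location with its 1 m x 1 m quadrat."""

    sample_id: str
    x: float
    y: float
    plot_id: str | None = None  # None -> adjacent-area point
    quadrat_size: float = 1.0

    @property
    def quadrat(self) -> Polygon:
        h = self.quadrat_size / 2.0
        return box(self.x - h, self.y - h, self.x + h, self.y + h)


# ---------------------------------------------------------------------------
# grid construction and cell classification
# ---------------------------------------------------------------------------

def build_grid(field: Polygon, cell_size: float = 0.25) -> Grid:
    """Tile the field bounding box with square cells (ceiling rule)."""
    if field.is_empty or field.area <= 0:
        raise LayoutError("field polygon is degenerate")
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    x_min, y_min, x_max, y_max = field.bounds
    # round before ceil so widths that are exact multiples of the cell size
    # do not gain a spurious extra column from float representation
    n_cols = math.ceil(round((x_max - x_min) / cell_size, 9))
    n_rows = math.ceil(round((y_max - y_min) / cell_size, 9))
    return Grid(x_min=x_min, y_min=y_min, cell_size=cell_size,
                n_cols=max(n_cols, 1), n_rows=max(n_rows, 1))


def classify_cells(grid: Grid, layout: FieldLayout) -> pd.DataFrame:
    """Classify every grid cell against the plot layout.

    Returns a frame with one row per cell: ``cell_i``, ``cell_j``,
    ``status`` and ``plot_id`` (non-null iff retained).  Boundary-touching
    intersections with zero area do not count as overlap, so a cell that
    merely shares an edge with a plot is still ``outside``.
    """
    s = grid.cell_size
    jj, ii = np.meshgrid(np.arange(grid.n_cols), np.arange(grid.n_rows))
    ii = ii.ravel()
    jj = jj.ravel()
    x0 = grid.x_min + jj * s
    y0 = grid.y_min + ii * s
    cells = shapely.box(x0, y0, x0 + s, y0 + s)

    plot_polys = [p.polygon for p in layout.plots]
    plot_ids = [p.plot_id for p in layout.plots]
    tree = STRtree(plot_polys)
    cell_idx, plot_idx = tree.query(cells, predicate="intersects")
    # keep only true areal overlaps
    if len(cell_idx):
        inter_area = shapely.area(
            shapely.intersection(cells[cell_idx], np.array(plot_polys, dtype=object)[plot_idx])
        )
        keep = inter_area > _AREA_EPS
        cell_idx, plot_idx = cell_idx[keep], plot_idx[keep]

    n = len(cells)
    n_plots_hit = np.bincount(cell_idx, minlength=n)
    status = np.full(n, "outside", dtype=object)
    owner = np.full(n, None, dtype=object)

    status[n_plots_hit >= 2] = "eliminated_two_plots"
    single = np.where(n_plots_hit == 1)[0]
    if len(single):
        pos = np.isin(cell_idx, single)
        one_cell = cell_idx[pos]
        one_plot = plot_idx[pos]
        covered = shapely.contains_properly(
            np.array(plot_polys, dtype=object)[one_plot], cells[one_cell]
        ) | shapely.covers(np.array(plot_polys, dtype=object)[one_plot], cells[one_cell])
        status[one_cell[covered]] = "retained"
        for c, p in zip(one_cell[covered], one_plot[covered]):
            owner[c] = plot_ids[p]
        status[one_cell[~covered]] = "eliminated_corridor_mix"

    return pd.DataFrame(
        {"cell_i": ii, "cell_j": jj, "status": status, "plot_id": owner}
    )


# ---------------------------------------------------------------------------
# covariate extraction and sample joining
# ---------------------------------------------------------------------------

def extract_point_covariates(
    stack: IndexStack,
    points: Sequence[SamplePoint],
) -> pd.DataFrame:
    """Quadrat-mean covariates for every sample point.

    For each point and each index layer, the arithmetic mean of unmasked
    pixel values whose centers fall inside the (half-open) quadrat.  Points
    whose quadrat contains no unmasked pixel are flagged ``valid=False``
    rather than raising, so a single bad point cannot sink a survey.
    """
    ref = stack.grid
    xs, ys = ref.pixel_center_coords()
    records = []
    for pt in points:
        h = pt.quadrat_size / 2.0
        in_x = (xs >= pt.x - h) & (xs < pt.x + h)
        in_y = (ys >= pt.y - h) & (ys < pt.y + h)
        rows = np.where(in_y)[0]
        cols = np.where(in_x)[0]
        rec: dict = {"sample_id": pt.sample_id, "plot_id": pt.plot_id}
        if len(rows) == 0 or len(cols) == 0:
            for name in stack.names:
                rec[name] = np.nan
            rec["n_pixels"] = 0
            rec["valid"] = False
        else:
            sub = np.ix_(rows, cols)
            n_any = 0
            for name in stack.names:
                layer = stack[name]
                vals = layer.values[sub]
                mask = layer.mask[sub]
                n = int(mask.sum())
                rec[name] = float(vals[mask].mean()) if n else np.nan
                n_any = max(n_any, n)
            rec["n_pixels"] = n_any
            rec["valid"] = n_any > 0
        records.append(rec)
    return pd.DataFrame(records).set_index("sample_id")


def join_samples(
    covariates: pd.DataFrame,
    harvest: pd.DataFrame,
    exclude_ids: Iterable[str] = (),
) -> tuple[pd.DataFrame, dict]:
    """Inner-join quadrat covariates with harvest measurements.

    ``harvest`` must carry a ``sample_id`` column (or index) and the response
    column(s).  Sample ids in ``exclude_ids`` are dropped after the join; the
    returned report lists unmatched and excluded ids so that every row that
    leaves the analysis is accounted for.
    """
    cov = covariates.copy()
    if "sample_id" in cov.columns:
        cov = cov.set_index("sample_id")
    har = harvest.copy()
    if "sample_id" in har.columns:
        har = har.set_index("sample_id")
    for name, df in (("covariate", cov), ("harvest", har)):
        if df.index.duplicated().any():
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise ValueError(f"duplicate {name} sample ids: {dups}")
    joined = cov.join(har, how="inner")
    unmatched_cov = sorted(cov.index.difference(har.index))
    unmatched_har = sorted(har.index.difference(cov.index))
    excluded = sorted(set(exclude_ids) & set(joined.index))
    joined = joined.drop(index=excluded)
    if "valid" in joined.columns:
        invalid = sorted(joined.index[~joined["valid"].astype(bool)])
        joined = joined[joined["valid"].astype(bool)]
    else:
        invalid = []
    report = {
        "unmatched_covariate_ids": unmatched_cov,
        "unmatched_harvest_ids": unmatched_har,
        "excluded_ids": excluded,
        "invalid_quadrat_ids": invalid,
        "n_rows": int(len(joined)),
    }
    return joined, report


# ---------------------------------------------------------------------------
# GeoJSON serialization (plain dict/json; local projected coordinates)
# ---------------------------------------------------------------------------

def layout_to_geojson(layout: FieldLayout, path=None) -> dict:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(layout.field),
            "properties": {"role": "field", "crs_note": layout.crs_note},
        }
    ]
    for rec in layout.plots:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(rec.polygon),
                "properties": {
                    "plot_id": rec.plot_id,
                    "row_id": rec.row_id,
                    "cultivar": rec.cultivar,
                    "sowing_date": rec.sowing_date,
                    "role": rec.role,
                },
            }
        )
    fc = {"type": "FeatureCollection", "features": features}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(fc, fh)
    return fc


def layout_from_geojson(source) -> FieldLayout:
    if isinstance(source, dict):
        fc = source
    else:
        with open(source) as fh:
            fc = json.load(fh)
    field_poly = None
    crs_note = "local projected Cartesian frame, meters"
    plots: list[PlotRecord] = []
    for feat in fc["features"]:
        props = feat.get("properties") or {}
        geom = shape(feat["geometry"])
        if props.get("role") == "field":
            field_poly = geom
            crs_note = props.get("crs_note", crs_note)
        else:
            plots.append(
                PlotRecord(
                    plot_id=str(props["plot_id"]),
                    polygon=geom,
                    row_id=str(props["row_id"]),
                    cultivar=props.get("cultivar"),
                    sowing_date=props.get("sowing_date"),
                    role=props.get("role", "cultivar"),
                )
            )
    if field_poly is None:
        raise LayoutError("GeoJSON lacks a feature with role='field'")
    return FieldLayout(field=field_poly, plots=plots, crs_note=crs_note)


def points_to_geojson(points: Sequence[SamplePoint], path=None) -> dict:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [pt.x, pt.y]},
            "properties": {
                "sample_id": pt.sample_id,
                "plot_id": pt.plot_id,
                "quadrat_size": pt.quadrat_size,
            },
        }
        for pt in points
    ]
    fc = {"type": "FeatureCollection", "features": features}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(fc, fh)
    return fc


def points_from_geojson(source) -> list[SamplePoint]:
    if isinstance(source, dict):
        fc = source
    else:
        with open(source) as fh:
            fc = json.load(fh)
    points = []
    for feat in fc["features"]:
        props = feat.get("properties") or {}
        x, y = feat["geometry"]["coordinates"]
        points.append(
            SamplePoint(
                sample_id=str(props["sample_id"]),
                x=float(x),
                y=float(y),
                plot_id=props.get("plot_id"),
                quadrat_size=float(props.get("quadrat_size", 1.0)),
            )
        )
    return points
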