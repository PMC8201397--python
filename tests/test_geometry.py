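"""Grid construction, cell classification, covariate extraction, joins."""

import math

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from uavfield.geometry import (
    FieldLayout,
    LayoutError,
    PlotRecord,
    SamplePoint,
    build_grid,
    classify_cells,
    extract_point_covariates,
    join_samples,
    layout_from_geojson,
    layout_to_geojson,
    points_from_geojson,
    points_to_geojson,
)
from uavfield.raster import IndexStack
from uavfield.synthetic import full_scale_config, generate_experiment

from conftest import make_layer


class TestBuildGrid:
    @pytest.mark.parametrize(
        "w,h,s,expected",
        [(1.0, 1.0, 0.25, 16), (40.0, 50.0, 0.25, 32_000), (1.1, 1.0, 0.25, 20)],
    )
    def test_cell_counts(self, w, h, s, expected):
        grid = build_grid(box(0, 0, w, h), s)
        assert grid.n_cells == expected
        # brute-force tiling oracle: cells laid until the bbox is covered
        n_cols = 0
        while n_cols * s < w - 1e-9:
            n_cols += 1
        n_rows = 0
        while n_rows * s < h - 1e-9:
            n_rows += 1
        assert grid.n_cells == n_cols * n_rows

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(LayoutError):
            build_grid(box(0, 0, 0, 0), 0.25)


class TestClassifyCells:
    def test_statuses(self, two_plot_layout):
        grid = build_grid(two_plot_layout.field, 0.5)
        cells = classify_cells(grid, two_plot_layout)
        by_idx = cells.set_index(["cell_i", "cell_j"])

        def status(x, y):
            i, j = grid.cell_of(np.array([x]), np.array([y]))
            return by_idx.loc[(i[0], j[0]), "status"]

        assert status(1.75, 2.25) == "retained"            # interior of P1
        assert status(3.1, 2.25) == "retained"             # interior of P2
        # cell [2.5,3.0)x[2,2.5) straddles the P1|P2 boundary at x=3? no:
        # boundary is x=3.0; the cell [2.75..] -- use a cell crossing x=3
        assert status(7.0, 7.0) == "outside"

    def test_two_plot_and_corridor_elimination(self):
        # plots offset by a quarter cell so cells straddle boundaries
        field = box(0, 0, 6, 6)
        layout = FieldLayout(
            field=field,
            plots=[
                PlotRecord("P1", box(0.9, 1.0, 2.9, 5.0), row_id="R1"),
                PlotRecord("P2", box(2.9, 1.0, 4.9, 5.0), row_id="R1"),
            ],
        )
        grid = build_grid(field, 0.5)
        cells = classify_cells(grid, layout)
        counts = cells["status"].value_counts()
        # cells crossing x=2.9 overlap both plots
        assert counts.get("eliminated_two_plots", 0) > 0
        # cells crossing the outer plot edges mix plot and corridor
        assert counts.get("eliminated_corridor_mix", 0) > 0
        retained = cells[cells["status"] == "retained"]
        assert set(retained["plot_id"]) == {"P1", "P2"}

    def test_partition_property(self, two_plot_layout):
        grid = build_grid(two_plot_layout.field, 0.25)
        cells = classify_cells(grid, two_plot_layout)
        assert len(cells) == grid.n_cells
        assert cells.groupby("status").size().sum() == grid.n_cells
        retained = cells[cells["status"] == "retained"]
        assert retained["plot_id"].notna().all()

    def test_shrinking_a_plot_never_gains_cells(self, two_plot_layout):
        grid = build_grid(two_plot_layout.field, 0.25)
        n_before = (classify_cells(grid, two_plot_layout)["plot_id"] == "P1").sum()
        shrunk = FieldLayout(
            field=two_plot_layout.field,
            plots=[
                PlotRecord("P1", box(1.3, 1.3, 2.8, 4.6), row_id="R1"),
                two_plot_layout.plots[1],
            ],
        )
        n_after = (classify_cells(grid, shrunk)["plot_id"] == "P1").sum()
        assert n_after <= n_before

    def test_overlapping_plots_rejected(self):
        with pytest.raises(LayoutError):
            FieldLayout(
                field=box(0, 0, 10, 10),
                plots=[
                    PlotRecord("P1", box(1, 1, 4, 5), row_id="R1"),
                    PlotRecord("P2", box(3, 1, 6, 5), row_id="R1"),
                ],
            )

    def test_full_scale_retained_cells_per_plot(self):
        """2.4 m x 4.2 m plots on a 25-cm grid keep 100-144 cells each."""
        cfg = full_scale_config()
        layout, _, _, _ = generate_experiment(cfg)
        grid = build_grid(layout.field, 0.25)
        cells = classify_cells(grid, layout)
        per_plot = cells[cells["status"] == "retained"].groupby("plot_id").size()
        assert len(per_plot) == 70
        cap = math.floor(2.4 / 0.25) * math.floor(4.2 / 0.25)
        assert cap == 144
        assert per_plot.max() <= cap
        assert per_plot.min() >= 100


class TestExtractCovariates:
    def test_uniform_layer_gives_uniform_means(self, uniform_layer):
        stack = IndexStack({"A": uniform_layer(7.5, shape=(20, 20), pixel_size=0.25)})
        pts = [SamplePoint("s1", 2.0, 2.0), SamplePoint("s2", 3.6, 1.2)]
        out = extract_point_covariates(stack, pts)
        assert (out["A"] == 7.5).all()
        assert out["valid"].all()

    def test_half_and_half_quadrat_mean(self):
        # 1 m quadrat over a layer where x < 2 has value a and x >= 2 has b
        values = np.zeros((8, 8))
        values[:, :4] = 10.0
        values[:, 4:] = 30.0
        stack = IndexStack({"A": make_layer(values, pixel_size=0.5)})
        pt = SamplePoint("s", 2.0, 2.0)  # quadrat spans x in [1.5, 2.5)
        out = extract_point_covariates(stack, [pt])
        # oracle by explicit pixel enumeration
        xs = (np.arange(8) + 0.5) * 0.5
        ys = 4.0 - (np.arange(8) + 0.5) * 0.5
        sel = np.ix_((ys >= 1.5) & (ys < 2.5), (xs >= 1.5) & (xs < 2.5))
        assert out.loc["s", "A"] == pytest.approx(values[sel].mean())
        assert out.loc["s", "A"] == pytest.approx(20.0)

    def test_quadrat_outside_extent_flagged_not_fatal(self, uniform_layer):
        stack = IndexStack({"A": uniform_layer(1.0, shape=(4, 4))})
        out = extract_point_covariates(
            stack, [SamplePoint("in", 2.0, 2.0), SamplePoint("out", 50.0, 50.0)]
        )
        assert out.loc["in", "valid"]
        assert not out.loc["out", "valid"]
        assert out.loc["out", "n_pixels"] == 0


class TestJoinSamples:
    def _tables(self, n, n_harvest=None):
        ids = [f"s{i}" for i in range(n)]
        cov = pd.DataFrame({"sample_id": ids, "A": np.arange(n, dtype=float),
                            "valid": True}).set_index("sample_id")
        hids = ids if n_harvest is None else [f"s{i}" for i in range(n_harvest)]
        har = pd.DataFrame({"sample_id": hids,
                            "ear_dry_weight_g": np.ones(len(hids))})
        return cov, har

    def test_exclusion_list_reduces_modeling_rows(self):
        cov, har = self._tables(154)
        excluded = [f"s{i}" for i in range(11)]
        joined, report = join_samples(cov, har, exclude_ids=excluded)
        assert report["n_rows"] == 143
        assert report["excluded_ids"] == sorted(excluded)

    def test_equal_ids_no_exclusions_preserves_rows(self):
        cov, har = self._tables(20)
        joined, report = join_samples(cov, har)
        assert len(joined) == 20
        assert report["unmatched_harvest_ids"] == []

    def test_unmatched_harvest_rows_reported(self):
        cov, har = self._tables(5, n_harvest=8)
        _, report = join_samples(cov, har)
        assert report["unmatched_harvest_ids"] == ["s5", "s6", "s7"]

    def test_duplicate_ids_rejected(self):
        cov, har = self._tables(3)
        har = pd.concat([har, har.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicate"):
            join_samples(cov, har)


class TestGeoJsonRoundTrip:
    def test_layout(self, tmp_path, two_plot_layout):
        path = tmp_path / "layout.geojson"
        layout_to_geojson(two_plot_layout, path)
        back = layout_from_geojson(path)
        assert len(back.plots) == 2
        assert back.plots[0].polygon.equals(two_plot_layout.plots[0].polygon)
        assert back.field.equals(two_plot_layout.field)

    def test_points(self, tmp_path):
        pts = [SamplePoint("s1", 1.5, 2.5, plot_id="P1"),
               SamplePoint("a1", 9.0, 9.0)]
        path = tmp_path / "pts.geojson"
        points_to_geojson(pts, path)
        back = points_from_geojson(path)
        assert [p.sample_id for p in back] == ["s1", "a1"]
        assert back[0].plot_id == "P1" and back[1].plot_id is None
        assert back[0].quadrat.area == pytest.approx(1.0)
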