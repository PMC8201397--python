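"""Raster containers for co-registered UAV survey products.

All geometry lives in a local projected Cartesian frame with meter units.
A :class:`RasterLayer` is a north-up, axis-aligned grid: the map x coordinate
increases with column index and y decreases with row index (image convention).
Georeferencing is the minimal GeoTIFF model — a pixel scale plus the map
coordinates of the top-left raster corner — which is all a single-field UAV
survey needs; rotated or sheared grids are out of scope.

GeoTIFF files are written with the standard ModelPixelScale / ModelTiepoint
tags plus GDAL's nodata tag, so other GIS software can open them; NaN marks
masked pixels in floating-point layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import tifffile

__all__ = [
    "RasterLayer",
    "IndexStack",
    "CoRegistrationError",
    "read_geotiff",
    "write_geotiff",
]

# GeoTIFF / GDAL tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

#: recognised band semantics
BAND_KINDS = ("reflectance", "rgb", "elevation", "index", "cover")


class CoRegistrationError(ValueError):
    """Raised when layers that must share a grid do not."""


@dataclass
class RasterLayer:
    """A single-band (2-D) or multi-band (rows x cols x bands) raster.

    Parameters
    ----------
    values:
        Float array of pixel values, shape ``(rows, cols)`` or
        ``(rows, cols, bands)``.
    mask:
        Boolean array, shape ``(rows, cols)``; ``True`` marks valid pixels.
    x_origin, y_origin:
        Map coordinates (m) of the *top-left corner* of pixel (0, 0).
        y decreases down the rows.
    pixel_size:
        Ground sampling distance in meters per pixel (square pixels).
    kind:
        Band semantics, one of ``reflectance | rgb | elevation | index | cover``.
    """

    values: np.ndarray
    x_origin: float
    y_origin: float
    pixel_size: float
    kind: str = "index"
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim not in (2, 3):
            raise ValueError("values must be 2-D or 3-D (rows, cols[, bands])")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.kind not in BAND_KINDS:
            raise ValueError(f"unknown band kind {self.kind!r}")
        if self.mask is None:
            finite = np.isfinite(self.values)
            self.mask = finite if self.values.ndim == 2 else finite.all(axis=2)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape[:2]:
            raise ValueError("mask shape must match the pixel grid")

    # -- grid helpers -----------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[:2]

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def same_grid(self, other: "RasterLayer") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.pixel_size, other.pixel_size)
            and np.isclose(self.x_origin, other.x_origin)
            and np.isclose(self.y_origin, other.y_origin)
        )

    def pixel_center_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates of every pixel center as 1-D (x_cols, y_rows)."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.x_origin + (cols + 0.5) * self.pixel_size
        y = self.y_origin - (rows + 0.5) * self.pixel_size
        return x, y

    def masked(self) -> np.ma.MaskedArray:
        """View as a numpy masked array (mask convention inverted)."""
        m = ~self.mask
        if self.values.ndim == 3:
            m = np.broadcast_to(m[:, :, None], self.values.shape)
        return np.ma.MaskedArray(self.values, mask=m)

    def with_values(self, values: np.ndarray, kind: str | None = None,
                    mask: np.ndarray | None = None) -> "RasterLayer":
        """New layer on the same grid with different pixel values."""
        return replace(
            self,
            values=values,
            kind=self.kind if kind is None else kind,
            mask=self.mask.copy() if mask is None else mask,
        )


def _require_same_grid(*layers: RasterLayer) -> None:
    first = layers[0]
    for other in layers[1:]:
        if not first.same_grid(other):
            raise CoRegistrationError(
                "layers are not co-registered (shape/transform mismatch)"
            )


class IndexStack:
    """Named, co-registered candidate-index layers.

    Layer names follow ``<K>_<Mon.DD>`` with K in {C, H, N} for canopy cover,
    plant height and NDVI respectively (e.g. ``C_Mar.14``); ``m`` is the
    number of candidate indices available to the yield model.
    """

    def __init__(self, layers: Mapping[str, RasterLayer]):
        if not layers:
            raise ValueError("IndexStack needs at least one layer")
        names = list(layers)
        if len(set(names)) != len(names):
            raise ValueError("duplicate layer names")
        _require_same_grid(*layers.values())
        self._layers: dict[str, RasterLayer] = dict(layers)

    @property
    def names(self) -> list[str]:
        return list(self._layers)

    @property
    def m(self) -> int:
        return len(self._layers)

    @property
    def grid(self) -> RasterLayer:
        """An arbitrary member layer, used as the grid reference."""
        return next(iter(self._layers.values()))

    def __getitem__(self, name: str) -> RasterLayer:
        return self._layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self._layers

    def __iter__(self) -> Iterator[str]:
        return iter(self._layers)

    def __len__(self) -> int:
        return len(self._layers)

    def subset(self, names: Sequence[str]) -> "IndexStack":
        missing = [n for n in names if n not in self._layers]
        if missing:
            raise KeyError(f"layers not in stack: {missing}")
        return IndexStack({n: self._layers[n] for n in names})

    def common_mask(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Pixels valid in every one of the requested layers."""
        names = self.names if names is None else list(names)
        mask = np.ones(self.grid.shape, dtype=bool)
        for n in names:
            mask &= self[n].mask
        return mask


# ---------------------------------------------------------------------------
# GeoTIFF I/O (tifffile + standard georeferencing tags)
# ---------------------------------------------------------------------------

def write_geotiff(path, layer: RasterLayer) -> None:
    """Write a layer as a GeoTIFF with pixel-scale/tiepoint georeferencing.

    Masked pixels are stored as NaN and declared via the GDAL nodata tag.
    """
    values = np.asarray(layer.values, dtype=np.float32).copy()
    if values.ndim == 2:
        values[~layer.mask] = np.nan
    else:
        values[~layer.mask, :] = np.nan
    scale = (float(layer.pixel_size), float(layer.pixel_size), 0.0)
    tiepoint = (0.0, 0.0, 0.0, float(layer.x_origin), float(layer.y_origin), 0.0)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, scale, True),
        (_TAG_MODEL_TIEPOINT, "d", 6, tiepoint, True),
        (_TAG_GDAL_NODATA, "s", 0, "nan", True),
    ]
    tifffile.imwrite(
        str(path),
        values,
        extratags=extratags,
        metadata={"kind": layer.kind},
    )


def read_geotiff(path, kind: str | None = None) -> RasterLayer:
    """Read a GeoTIFF written by :func:`write_geotiff` (or compatible)."""
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(float)
        tags = page.tags
        try:
            scale = tags[_TAG_MODEL_PIXEL_SCALE].value
            tiepoint = tags[_TAG_MODEL_TIEPOINT].value
        except KeyError as exc:  # pragma: no cover - malformed input
            raise ValueError(f"{path}: missing GeoTIFF georeferencing tags") from exc
        if kind is None:
            kind = "index"
            meta = tif.shaped_metadata or tif.imagej_metadata
            if meta:
                entry = meta[0] if isinstance(meta, (list, tuple)) else meta
                kind = entry.get("kind", "index")
    if abs(scale[0] - scale[1]) > 1e-9:
        raise ValueError("non-square pixels are not supported")
    # tiepoint maps raster (col=tp[0], row=tp[1]) to map (tp[3], tp[4])
    x_origin = tiepoint[3] - tiepoint[0] * scale[0]
    y_origin = tiepoint[4] + tiepoint[1] * scale[1]
    return RasterLayer(
        values=values,
        x_origin=float(x_origin),
        y_origin=float(y_origin),
        pixel_size=float(scale[0]),
        kind=kind,
    )
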