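"""Candidate-index layers from raw UAV raster products.

Three per-pixel indices are supported as yield-model covariates:

* canopy **cover** — binary vegetation mask from the RGB orthomosaic via
  excess-green (ExG = 2G - R - B) thresholding; its mean over a quadrat or
  grid cell is the cover fraction,
* plant **height** — digital surface model minus a ground-elevation layer,
  clamped at zero (negative canopy height is physically meaningless),
* **NDVI** — (NIR - Red)/(NIR + Red) from calibrated reflectance bands.

Multispectral bands are calibrated against a reflectance panel of known
albedo imaged immediately before and after the flight.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from skimage.filters import threshold_otsu

from .raster import CoRegistrationError, IndexStack, RasterLayer

__all__ = [
    "CalibrationError",
    "calibrate_reflectance",
    "compute_ndvi",
    "segment_vegetation",
    "compute_height",
    "build_index_stack",
]


class CalibrationError(ValueError):
    """Raised for unusable reflectance-panel observations."""


def calibrate_reflectance(
    band: RasterLayer,
    panel_known_reflectance: float,
    panel_observed_pre: float,
    panel_observed_post: float,
) -> RasterLayer:
    """Scale a raw band by the panel gain; result clipped to [0, 1].

    The gain is ``known / mean(observed_pre, observed_post)``, averaging the
    pre- and post-flight panel captures to absorb illumination drift.
    """
    if panel_observed_pre <= 0 or panel_observed_post <= 0:
        raise CalibrationError("panel observations must be positive")
    if not (0 < panel_known_reflectance <= 1):
        raise CalibrationError("panel known reflectance must lie in (0, 1]")
    gain = panel_known_reflectance / ((panel_observed_pre + panel_observed_post) / 2.0)
    calibrated = np.clip(band.values * gain, 0.0, 1.0)
    return band.with_values(calibrated, kind="reflectance")


def compute_ndvi(red: RasterLayer, nir: RasterLayer) -> RasterLayer:
    """Normalized difference vegetation index, masked where NIR + Red = 0."""
    if not red.same_grid(nir):
        raise CoRegistrationError("red and nir bands are not co-registered")
    total = nir.values + red.values
    valid = red.mask & nir.mask & (total != 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = np.where(valid, (nir.values - red.values) / total, np.nan)
    return RasterLayer(
        values=ndvi,
        x_origin=red.x_origin,
        y_origin=red.y_origin,
        pixel_size=red.pixel_size,
        kind="index",
        mask=valid,
    )


def excess_green(rgb: RasterLayer) -> np.ndarray:
    """Per-pixel ExG = 2G - R - B score from an RGB orthomosaic."""
    if rgb.values.ndim != 3 or rgb.values.shape[2] != 3:
        raise ValueError("orthomosaic must have three bands (R, G, B)")
    r, g, b = (rgb.values[:, :, i] for i in range(3))
    return 2.0 * g - r - b


def segment_vegetation(rgb: RasterLayer, method: str = "fixed_threshold") -> RasterLayer:
    """Binary vegetation cover from RGB via excess-green thresholding.

    ``fixed_threshold`` labels a pixel vegetation iff ExG > 0; ``automatic``
    picks the threshold by a bimodal histogram split (Otsu) over the unmasked
    pixels.  The output is 1 (vegetation) / 0 (background) with the input
    mask preserved.
    """
    if not rgb.mask.any():
        raise ValueError("cannot segment a fully masked image")
    exg = excess_green(rgb)
    if method == "fixed_threshold":
        t = 0.0
    elif method == "automatic":
        t = float(threshold_otsu(exg[rgb.mask]))
    else:
        raise ValueError(f"unknown segmentation method {method!r}")
    cover = (exg > t).astype(float)
    cover[~rgb.mask] = np.nan
    return RasterLayer(
        values=cover,
        x_origin=rgb.x_origin,
        y_origin=rgb.y_origin,
        pixel_size=rgb.pixel_size,
        kind="cover",
        mask=rgb.mask.copy(),
    )


def compute_height(dsm: RasterLayer, ground: RasterLayer) -> RasterLayer:
    """Canopy height = max(DSM - ground, 0); mask is the union of inputs."""
    if not dsm.same_grid(ground):
        raise CoRegistrationError("DSM and ground layers are not co-registered")
    valid = dsm.mask & ground.mask
    height = np.where(valid, np.maximum(dsm.values - ground.values, 0.0), np.nan)
    return RasterLayer(
        values=height,
        x_origin=dsm.x_origin,
        y_origin=dsm.y_origin,
        pixel_size=dsm.pixel_size,
        kind="index",
        mask=valid,
    )


def build_index_stack(
    layers: Mapping[str, RasterLayer] | Sequence[tuple[str, RasterLayer]],
    exclusions: Sequence[str] = (),
) -> IndexStack:
    """Assemble the candidate-covariate stack, dropping excluded layers.

    ``layers`` is a name->layer mapping or a sequence of (name, layer) pairs;
    duplicate names are an error.  Exclusion supports the survey-screening
    step in which an index measured too early in the season (e.g. plant
    height under 10 cm) is removed from the candidate set before model
    selection.
    """
    if not isinstance(layers, Mapping):
        pairs = list(layers)
        names = [n for n, _ in pairs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate layer names")
        layers = dict(pairs)
    excluded = set(exclusions)
    unknown = excluded - set(layers)
    if unknown:
        raise KeyError(f"exclusions not present in layers: {sorted(unknown)}")
    kept = {name: layer for name, layer in layers.items() if name not in excluded}
    return IndexStack(kept)
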