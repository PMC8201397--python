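"""Synthetic UAV field experiments with known ground truth.

Real UAV field-trial datasets of this kind are rarely public, so this module
generates complete experiments — layout, per-index rasters, quadrat harvest
samples and per-plot treatment covariates — from a known generative model,
letting every downstream stage (extraction, model selection, gridding,
mixed-model testing) be verified by parameter recovery.

Generative model
----------------
The latent yield surface (g per m^2-quadrat equivalent) is

    L(x, y) = mu + trend(x, y) + u_row + u_plot + e_pixel,

where ``trend`` is a sum of deterministic smooth basis fields (linear
gradients and fixed-wavelength sinusoids) scaled by
``spatial_trend_amplitude``; ``u_row`` is a per-sowing-row N(0, row_sd^2)
offset applied over the row's band; ``u_plot`` is applied inside each plot
and sums the cultivar effect, the sowing-date effect, the configured trait
contribution and a N(0, plot_sd^2) residual; ``e_pixel`` is white noise.

Each *true* candidate index is an affine image of a distinct additive
component of L (the components — mean, trend basis fields, row field, plot
field, pixel-noise field — are partitioned round-robin among the true
indices) plus index noise:

    x_i = a_i + (component_i + e_index) / beta_i.

Summing beta_i * (x_i - a_i) over the true subset reconstructs L exactly
when the noise terms are zero, so the latent yield is an exact linear
function of the *full* true subset and of no proper subset: noiseless runs
must recover exactly the true index set, and every index carries signal.
The remaining candidates are pure nuisance fields (smooth random surface
plus white noise), statistically independent of L.

Quadrat samples are means of L over the 1 m x 1 m quadrat's pixel centers
plus N(0, sample_sd^2) harvest noise.  A single integer seed drives one
root ``SeedSequence``; every sub-stage draws from its own spawned child
stream, so adding a stage never perturbs earlier stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import box

from .geometry import FieldLayout, LayoutError, PlotRecord, SamplePoint
from .raster import IndexStack, RasterLayer, write_geotiff

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_experiment",
    "generate_trait_table",
    "simulate_cell_observations",
    "write_experiment",
    "full_scale_config",
    "noiseless_config",
]

#: the default candidate set: cover (C), height (H) and NDVI (N) layers from
#: three survey dates, February height excluded (crop too short to measure)
DEFAULT_CANDIDATES = (
    "C_Feb.15", "C_Mar.14", "C_Apr.12",
    "H_Mar.14", "H_Apr.12",
    "N_Mar.14", "N_Apr.12",
)

#: true generating subset and effect sizes (yield units per index unit)
DEFAULT_TRUE_COEFFICIENTS = {
    "C_Mar.14": 600.0,
    "H_Mar.14": 400.0,
    "C_Apr.12": 500.0,
    "N_Apr.12": 800.0,
}

#: plausible index-scale offsets per layer kind
_DEFAULT_INTERCEPTS = {"C": 0.35, "H": 0.25, "N": 0.30}

TRAIT_NAMES = ("stem_dw", "seed_dw", "agb_dw", "seed100_w")


@dataclass
class SyntheticConfig:
    """Configuration of a synthetic experiment.

    The default is a quarter-size field (20 m x 25 m, 20 plots in 4 sowing
    rows) that keeps a full-pipeline run under a minute;
    :func:`full_scale_config` returns the full 40 m x 50 m, 70-plot preset.
    Distances in meters, effects and noise SDs in yield units (g/quadrat).
    """

    field_width_m: float = 20.0
    field_height_m: float = 25.0
    plot_rows: int = 4
    plots_per_row: int = 5
    plot_width_m: float = 2.4
    plot_height_m: float = 4.2
    corridor_m: float = 0.8
    n_cultivars: int = 4
    sowing_dates: tuple[str, str] = ("Jun.20", "Jul.20")
    n_weedy: int = 0
    n_sheet: int = 0
    n_destructive: int = 0
    pixel_size_m: float = 0.1
    quadrat_size_m: float = 1.0
    n_adjacent_points: int = 16
    mean_yield: float = 500.0
    candidate_indices: tuple[str, ...] = DEFAULT_CANDIDATES
    true_coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_COEFFICIENTS)
    )
    index_noise_sd: float = 10.0
    pixel_noise_sd: float = 20.0
    sample_noise_sd: float = 20.0
    spatial_trend_amplitude: float = 40.0
    row_effect_sd: float = 25.0
    plot_effect_sd: float = 15.0
    cultivar_effects: tuple[float, ...] | None = None
    sowing_date_effect: float = 0.0
    trait_effect_spec: Mapping[tuple[str, ...], float] = field(default_factory=dict)
    trait_base_means: Mapping[str, float] = field(
        default_factory=lambda: {
            "stem_dw": 400.0, "other_dw": 300.0, "seed_dw": 250.0,
            "seed100_w": 25.0,
        }
    )
    trait_between_sd: float = 60.0
    trait_within_sd: float = 25.0
    random_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("field_width_m", "field_height_m", "plot_width_m",
                     "plot_height_m", "pixel_size_m", "quadrat_size_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.corridor_m < 0:
            raise ValueError("corridor_m must be non-negative")
        if self.pixel_size_m > 0.25 / 2:
            raise ValueError(
                "pixel_size_m must be <= 0.125 m so every 25-cm cell holds "
                ">= 4 pixel centers"
            )
        if len(self.sowing_dates) != 2:
            raise ValueError("exactly two sowing dates are supported")
        span_x = (self.plots_per_row * self.plot_width_m
                  + (self.plots_per_row - 1) * self.corridor_m)
        span_y = (self.plot_rows * self.plot_height_m
                  + (self.plot_rows - 1) * self.corridor_m)
        if span_x > self.field_width_m or span_y > self.field_height_m:
            raise LayoutError("plots (with corridors) do not fit inside the field")
        unknown = set(self.true_coefficients) - set(self.candidate_indices)
        if unknown:
            raise ValueError(f"true_coefficients not in candidates: {sorted(unknown)}")
        if any(b == 0 for b in self.true_coefficients.values()):
            raise ValueError("true coefficients must be nonzero")
        if self.cultivar_effects is not None and \
                len(self.cultivar_effects) != self.n_cultivars:
            raise ValueError("cultivar_effects length must equal n_cultivars")
        for key, mean in self.trait_base_means.items():
            if mean < 0:
                raise ValueError(f"trait base mean {key!r} must be non-negative")
        n_special = self.n_weedy + self.n_sheet + self.n_destructive
        if n_special >= self.plot_rows * self.plots_per_row:
            raise ValueError("special-role plots leave no cultivar plots")
        # normalize trait-effect keys: "stem_dw:agb_dw" == ("stem_dw", "agb_dw")
        spec = {}
        for key, coef in self.trait_effect_spec.items():
            if isinstance(key, str):
                key = tuple(key.split(":"))
            spec[tuple(key)] = float(coef)
        self.trait_effect_spec = spec

    @property
    def n_plots(self) -> int:
        return self.plot_rows * self.plots_per_row

    @property
    def true_subset(self) -> tuple[str, ...]:
        return tuple(n for n in self.candidate_indices if n in self.true_coefficients)

    def resolved_cultivar_effects(self) -> dict[str, float]:
        effs = self.cultivar_effects or tuple(0.0 for _ in range(self.n_cultivars))
        return {f"v{i + 1}": float(e) for i, e in enumerate(effs)}


@dataclass
class SyntheticTruth:
    """Everything needed to verify recovery of the generative model."""

    latent: RasterLayer
    true_model_subset: tuple[str, ...]
    true_fixed_effects: dict
    row_effects: pd.Series
    plot_effects: pd.Series          # random (non-treatment) part, per plot
    assignment: pd.DataFrame         # plot_id, row_id, cultivar, sowing_date, role
    trait_table: pd.DataFrame
    index_transforms: dict           # name -> (offset a_i, slope beta_i)


def _spawn_streams(seed: int) -> dict[str, np.random.Generator]:
    names = ("layout", "traits", "row", "plot", "pixel", "index_noise",
             "nuisance", "samples", "aux")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


# ---------------------------------------------------------------------------
# layout and treatment assignment
# ---------------------------------------------------------------------------

def _build_layout(config: SyntheticConfig, rng: np.random.Generator
                  ) -> tuple[FieldLayout, pd.DataFrame]:
    W, H = config.field_width_m, config.field_height_m
    pw, ph, cor = config.plot_width_m, config.plot_height_m, config.corridor_m
    span_x = config.plots_per_row * pw + (config.plots_per_row - 1) * cor
    span_y = config.plot_rows * ph + (config.plot_rows - 1) * cor
    mx, my = (W - span_x) / 2.0, (H - span_y) / 2.0

    n = config.n_plots
    roles = np.array(["cultivar"] * n, dtype=object)
    special = (["weedy"] * config.n_weedy + ["sheet"] * config.n_sheet
               + ["destructive"] * config.n_destructive)
    if special:
        pos = rng.choice(n, size=len(special), replace=False)
        roles[pos] = special

    cultivar_names = [f"v{i + 1}" for i in range(config.n_cultivars)]
    n_cult_plots = int((roles == "cultivar").sum())
    labels = [cultivar_names[i % config.n_cultivars] for i in range(n_cult_plots)]
    rng.shuffle(labels)
    sowing = [config.sowing_dates[i % 2] for i in range(n)]
    rng.shuffle(sowing)

    plots: list[PlotRecord] = []
    rows_meta = []
    it_labels = iter(labels)
    k = 0
    for r in range(config.plot_rows):
        y0 = my + r * (ph + cor)
        for j in range(config.plots_per_row):
            x0 = mx + j * (pw + cor)
            role = roles[k]
            if role == "cultivar":
                cultivar = next(it_labels)
            elif role in ("weedy", "sheet"):
                cultivar = role  # analysed as an extra treatment level
            else:
                cultivar = None  # destructive sampling plot
            rec = PlotRecord(
                plot_id=f"P{k + 1}",
                polygon=box(x0, y0, x0 + pw, y0 + ph),
                row_id=f"R{r + 1}",
                cultivar=cultivar,
                sowing_date=sowing[k],
                role=str(role),
            )
            plots.append(rec)
            rows_meta.append({"plot_id": rec.plot_id, "row_id": rec.row_id,
                              "cultivar": cultivar, "sowing_date": sowing[k],
                              "role": str(role)})
            k += 1
    layout = FieldLayout(field=box(0.0, 0.0, W, H), plots=plots)
    return layout, pd.DataFrame(rows_meta)


# ---------------------------------------------------------------------------
# trait table
# ---------------------------------------------------------------------------

def generate_trait_table(
    config: SyntheticConfig,
    assignment: Sequence[str] | pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-plot preceding-crop traits drawn around cultivar-specific means.

    ``assignment`` is one cultivar label per plot (or a frame with plot_id /
    cultivar columns).  Stem and the remaining above-ground mass are drawn
    separately and summed, so above-ground dry weight >= stem dry weight
    holds for every plot by construction.  Plots without a cultivar label
    (destructive role) get traits drawn around the base means.
    """
    if rng is None:
        rng = _spawn_streams(config.random_seed)["traits"]
    if isinstance(assignment, pd.DataFrame):
        plot_ids = list(assignment["plot_id"])
        labels = list(assignment["cultivar"])
    else:
        labels = list(assignment)
        plot_ids = [f"P{i + 1}" for i in range(len(labels))]

    base = config.trait_base_means
    levels = sorted({l for l in labels if l is not None})
    means = {
        lv: {
            "stem_dw": base["stem_dw"] + rng.normal(0, config.trait_between_sd),
            "other_dw": base["other_dw"] + rng.normal(0, config.trait_between_sd),
            "seed_dw": base["seed_dw"] + rng.normal(0, config.trait_between_sd / 2),
            "seed100_w": base["seed100_w"] + rng.normal(0, config.trait_between_sd / 15),
        }
        for lv in levels
    }
    rows = []
    for pid, lv in zip(plot_ids, labels):
        m = means.get(lv, base)
        stem = max(rng.normal(m["stem_dw"], config.trait_within_sd), 1.0)
        other = max(rng.normal(m["other_dw"], config.trait_within_sd), 0.0)
        seed = max(rng.normal(m["seed_dw"], config.trait_within_sd / 2), 1.0)
        s100 = max(rng.normal(m["seed100_w"], config.trait_within_sd / 15), 1.0)
        rows.append({
            "plot_id": pid, "cultivar": lv,
            "stem_dw": stem, "seed_dw": seed,
            "agb_dw": stem + other, "seed100_w": s100,
        })
    return pd.DataFrame(rows)


def _trait_contribution(
    trait_table: pd.DataFrame,
    spec: Mapping[tuple[str, ...], float],
) -> pd.Series:
    """Per-plot yield contribution of the configured trait effects.

    Keys are 1-tuples (main effects) or 2-tuples (pairwise interactions) of
    trait names; traits are centered across plots before products.
    """
    contrib = pd.Series(0.0, index=trait_table["plot_id"])
    if not spec:
        return contrib
    centered = trait_table.set_index("plot_id")[list(TRAIT_NAMES)]
    centered = centered - centered.mean()
    for key, coef in spec.items():
        terms = (key,) if isinstance(key, str) else tuple(key)
        prod = pd.Series(1.0, index=centered.index)
        for t in terms:
            if t not in centered.columns:
                raise KeyError(f"unknown trait {t!r} in trait_effect_spec")
            prod = prod * centered[t]
        contrib = contrib + coef * prod
    return contrib


# ---------------------------------------------------------------------------
# raster surfaces
# ---------------------------------------------------------------------------

def _trend_basis(xn: np.ndarray, yn: np.ndarray, k: int) -> np.ndarray:
    """k-th smooth deterministic basis field on normalized coords in [0, 1]."""
    if k == 0:
        return 2.0 * xn - 1.0
    if k == 1:
        return 2.0 * yn - 1.0
    if k == 2:
        return np.sin(2 * np.pi * xn) * np.sin(2 * np.pi * yn)
    if k == 3:
        return np.sin(4 * np.pi * xn)
    if k == 4:
        return np.cos(4 * np.pi * yn)
    if k == 5:
        return np.sin(2 * np.pi * (xn + yn))
    return np.cos(2 * np.pi * (xn - yn) * (k - 4))


def _smooth_random_field(shape: tuple[int, int], xn, yn,
                         rng: np.random.Generator) -> np.ndarray:
    """Unit-scale smooth nuisance surface: random-phase sinusoid mixture."""
    out = np.zeros(shape)
    for _ in range(4):
        fx, fy = rng.uniform(0.5, 3.0, size=2)
        phase = rng.uniform(0, 2 * np.pi)
        out += rng.normal(0, 0.5) * np.sin(2 * np.pi * (fx * xn + fy * yn) + phase)
    return out


def generate_experiment(
    config: SyntheticConfig,
) -> tuple[FieldLayout, IndexStack, pd.DataFrame, SyntheticTruth]:
    """Generate a complete synthetic experiment.

    Returns the field layout, the combined candidate-index stack (layer
    names carry the survey date), the harvest-sample table (sample_id, x, y,
    plot_id, ear_dry_weight_g, straw_dry_weight_g, mature_ear_count) and the
    ground truth.  Identical configs (same seed) give bit-identical output.
    """
    streams = _spawn_streams(config.random_seed)
    layout, assignment = _build_layout(config, streams["layout"])
    trait_table = generate_trait_table(config, assignment, streams["traits"])

    W, H = config.field_width_m, config.field_height_m
    px = config.pixel_size_m
    n_cols = int(round(W / px))
    n_rows = int(round(H / px))
    cols = (np.arange(n_cols) + 0.5) * px
    rows_y = H - (np.arange(n_rows) + 0.5) * px      # y decreases down rows
    X, Y = np.meshgrid(cols, rows_y)
    xn, yn = X / W, Y / H

    true_subset = config.true_subset
    k_true = len(true_subset)
    if k_true == 0:
        raise ValueError("at least one true index is required")

    # latent components -----------------------------------------------------
    mu_field = np.full(X.shape, config.mean_yield)
    trend_fields = [
        config.spatial_trend_amplitude * _trend_basis(xn, yn, k)
        for k in range(k_true)
    ]

    row_effects = pd.Series(
        streams["row"].normal(0.0, config.row_effect_sd, config.plot_rows),
        index=[f"R{r + 1}" for r in range(config.plot_rows)],
    )
    row_field = np.zeros(X.shape)
    ph, cor = config.plot_height_m, config.corridor_m
    span_y = config.plot_rows * ph + (config.plot_rows - 1) * cor
    my = (H - span_y) / 2.0
    for r in range(config.plot_rows):
        y_lo = my + r * (ph + cor) - cor / 2.0
        y_hi = y_lo + ph + cor
        band = (Y >= max(y_lo, 0.0)) & (Y < min(y_hi, H))
        row_field[band] += row_effects.iloc[r]

    cultivar_effects = config.resolved_cultivar_effects()
    trait_contrib = _trait_contribution(trait_table, config.trait_effect_spec)
    plot_random = pd.Series(
        streams["plot"].normal(0.0, config.plot_effect_sd, config.n_plots),
        index=assignment["plot_id"],
    )
    plot_field = np.zeros(X.shape)
    plot_total = {}
    second_date = config.sowing_dates[1]
    for rec in layout.plots:
        eff = plot_random[rec.plot_id] + trait_contrib[rec.plot_id]
        eff += cultivar_effects.get(rec.cultivar, 0.0)
        if rec.sowing_date == second_date:
            eff += config.sowing_date_effect
        plot_total[rec.plot_id] = eff
        x0, y0, x1, y1 = rec.polygon.bounds
        inside = (X >= x0) & (X < x1) & (Y >= y0) & (Y < y1)
        plot_field[inside] += eff

    pixel_field = streams["pixel"].normal(0.0, config.pixel_noise_sd, X.shape) \
        if config.pixel_noise_sd > 0 else np.zeros(X.shape)

    latent_values = mu_field + sum(trend_fields) + row_field + plot_field + pixel_field
    latent = RasterLayer(values=latent_values, x_origin=0.0, y_origin=H,
                         pixel_size=px, kind="index")

    # candidate index layers ------------------------------------------------
    components = [mu_field, *trend_fields, row_field, plot_field, pixel_field]
    shares: dict[str, np.ndarray] = {name: np.zeros(X.shape) for name in true_subset}
    for i, comp in enumerate(components):
        shares[true_subset[i % k_true]] += comp

    layers: dict[str, RasterLayer] = {}
    transforms: dict[str, tuple[float, float]] = {}
    for name in config.candidate_indices:
        kind_letter = name.split("_")[0]
        a = _DEFAULT_INTERCEPTS.get(kind_letter, 0.0)
        if name in config.true_coefficients:
            beta = float(config.true_coefficients[name])
            noise = (streams["index_noise"].normal(0, config.index_noise_sd, X.shape)
                     if config.index_noise_sd > 0 else 0.0)
            values = a + (shares[name] + noise) / beta
            transforms[name] = (a, beta)
        else:
            beta_ref = float(np.mean(list(config.true_coefficients.values())))
            surface = config.spatial_trend_amplitude * _smooth_random_field(
                X.shape, xn, yn, streams["nuisance"]
            )
            noise = (streams["nuisance"].normal(0, config.index_noise_sd, X.shape)
                     if config.index_noise_sd > 0 else 0.0)
            values = a + (surface + noise) / beta_ref
        layers[name] = RasterLayer(values=values, x_origin=0.0, y_origin=H,
                                   pixel_size=px, kind="index")
    stack = IndexStack(layers)

    # harvest samples -------------------------------------------------------
    points = _sample_points(config, layout, streams["samples"])
    rng_s = streams["samples"]
    rng_aux = streams["aux"]
    sample_rows = []
    for pt in points:
        h = config.quadrat_size_m / 2.0
        in_x = (cols >= pt.x - h) & (cols < pt.x + h)
        in_y = (rows_y >= pt.y - h) & (rows_y < pt.y + h)
        quad = latent_values[np.ix_(np.where(in_y)[0], np.where(in_x)[0])]
        y_true = float(quad.mean()) if quad.size else np.nan
        noise = rng_s.normal(0.0, config.sample_noise_sd) \
            if config.sample_noise_sd > 0 else 0.0
        y_obs = max(y_true + noise, 0.0)
        straw = max(0.8 * y_obs + rng_aux.normal(0, 10.0), 0.0)
        ears = max(int(round(y_obs / 1.5 + rng_aux.normal(0, 5.0))), 0)
        sample_rows.append({
            "sample_id": pt.sample_id, "x": pt.x, "y": pt.y,
            "plot_id": pt.plot_id,
            "ear_dry_weight_g": y_obs,
            "straw_dry_weight_g": straw,
            "mature_ear_count": ears,
        })
    samples = pd.DataFrame(sample_rows)

    truth = SyntheticTruth(
        latent=latent,
        true_model_subset=true_subset,
        true_fixed_effects={
            "mean_yield": config.mean_yield,
            "cultivar_effects": cultivar_effects,
            "sowing_date_effect": config.sowing_date_effect,
            "trait_effect_spec": dict(config.trait_effect_spec),
            "plot_total_effects": plot_total,
        },
        row_effects=row_effects,
        plot_effects=plot_random,
        assignment=assignment,
        trait_table=trait_table,
        index_transforms=transforms,
    )
    return layout, stack, samples, truth


def _sample_points(config: SyntheticConfig, layout: FieldLayout,
                   rng: np.random.Generator) -> list[SamplePoint]:
    """One quadrat at every plot center plus adjacent-area points."""
    points = [
        SamplePoint(
            sample_id=f"S_{rec.plot_id}",
            x=rec.polygon.centroid.x,
            y=rec.polygon.centroid.y,
            plot_id=rec.plot_id,
            quadrat_size=config.quadrat_size_m,
        )
        for rec in layout.plots
    ]
    # candidate adjacent positions on a coarse lattice, quadrat clear of plots
    W, H = config.field_width_m, config.field_height_m
    q = config.quadrat_size_m
    step = 2.5
    candidates = []
    for cx in np.arange(q, W - q / 2, step):
        for cy in np.arange(q, H - q / 2, step):
            quad = box(cx - q / 2, cy - q / 2, cx + q / 2, cy + q / 2)
            if all(not quad.intersects(rec.polygon) for rec in layout.plots):
                candidates.append((float(cx), float(cy)))
    n_extra = min(config.n_adjacent_points, len(candidates))
    if n_extra:
        chosen = rng.choice(len(candidates), size=n_extra, replace=False)
        for i, ci in enumerate(sorted(chosen)):
            cx, cy = candidates[ci]
            points.append(SamplePoint(sample_id=f"A{i + 1}", x=cx, y=cy,
                                      plot_id=None,
                                      quadrat_size=config.quadrat_size_m))
    return points


def sample_points_from_table(samples: pd.DataFrame,
                             quadrat_size: float = 1.0) -> list[SamplePoint]:
    """Rebuild SamplePoint objects from a harvest-sample table."""
    return [
        SamplePoint(sample_id=str(r.sample_id), x=float(r.x), y=float(r.y),
                    plot_id=None if pd.isna(r.plot_id) else str(r.plot_id),
                    quadrat_size=quadrat_size)
        for r in samples.itertuples()
    ]


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def full_scale_config(**overrides) -> SyntheticConfig:
    """The full-scale layout: 40 m x 50 m, 70 plots (7 rows x 10), 14
    cultivars, 4 weedy + 4 sheet + 6 destructive plots, 2.4 m x 4.2 m plots."""
    base = dict(
        field_width_m=40.0, field_height_m=50.0,
        plot_rows=7, plots_per_row=10,
        corridor_m=1.0,
        n_cultivars=14,
        n_weedy=4, n_sheet=4, n_destructive=6,
        n_adjacent_points=84,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


def calibration_scale_config(**overrides) -> SyntheticConfig:
    """A 28 m x 42 m field with 64 plots (8 rows x 8) and 4 cultivars.

    The layout used for end-to-end calibration runs: it matches the plot
    count of a full-scale analysis (the quantity that governs how well the
    chi-square reference of the cultivar LRT holds) while staying cheap
    enough to rerun dozens of times.
    """
    base = dict(
        field_width_m=28.0, field_height_m=42.0,
        plot_rows=8, plots_per_row=8,
        n_cultivars=4,
        n_adjacent_points=20,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


def detection_config(effect: float = 60.0, **overrides) -> SyntheticConfig:
    """Full-scale layout with one cultivar (v5) elevated by ``effect`` g.

    The default elevation is twice the 30 g cell-scale residual SD used
    throughout the calibration studies.  Spatial trend amplitude and the
    plot random SD are set to 10 g so that, with 4 replicate plots per
    cultivar, the planted contrast has a prior standard error of about
    8 g — a design in which a 2-sigma-residual treatment effect is
    detectable at p < 0.001 by a power calculation, so a non-detection
    indicts the pipeline rather than the design.
    """
    effects = [0.0] * 14
    effects[4] = effect  # cultivar v5
    base = dict(
        spatial_trend_amplitude=10.0,
        plot_effect_sd=10.0,
        cultivar_effects=tuple(effects),
    )
    base.update(overrides)
    return full_scale_config(**base)


def noiseless_config(**overrides) -> SyntheticConfig:
    """Quarter-scale preset with every stochastic term switched off.

    The latent surface reduces to mean + deterministic trend, so the
    quadrat response is an exact linear function of the true index subset:
    model selection must recover exactly that subset with zero residual.
    """
    base = dict(
        index_noise_sd=0.0, pixel_noise_sd=0.0, sample_noise_sd=0.0,
        row_effect_sd=0.0, plot_effect_sd=0.0,
        cultivar_effects=None, sowing_date_effect=0.0,
        trait_effect_spec={},
    )
    base.update(overrides)
    return SyntheticConfig(**base)


# ---------------------------------------------------------------------------
# direct cell-table simulation (for mixed-model calibration studies)
# ---------------------------------------------------------------------------

def simulate_cell_observations(
    rng: np.random.Generator,
    n_rows: int = 6,
    plots_per_row: int = 4,
    cells_per_plot: int = 12,
    grand_mean: float = 500.0,
    n_cultivars: int = 4,
    cultivar_effects: Mapping[str, float] | None = None,
    sowing_date_effect: float = 0.0,
    row_sd: float = 25.0,
    plot_sd: float = 15.0,
    resid_sd: float = 30.0,
    trait_table: pd.DataFrame | None = None,
    trait_effect_spec: Mapping[tuple[str, ...], float] | None = None,
    trait_within_sd: float = 25.0,
) -> pd.DataFrame:
    """Draw a cell-observation table straight from the mixed-model family.

    This bypasses the raster pipeline and generates the response at the cell
    level — exactly the generative family the inference module assumes —
    which is what calibration studies (type-I error, parameter recovery)
    need, at a fraction of the cost of full raster runs.
    """
    n_plots = n_rows * plots_per_row
    plot_ids = [f"P{i + 1}" for i in range(n_plots)]
    row_ids = [f"R{i // plots_per_row + 1}" for i in range(n_plots)]
    labels = [f"v{i % n_cultivars + 1}" for i in range(n_plots)]
    rng.shuffle(labels)
    sowing = ["d1" if i % 2 == 0 else "d2" for i in range(n_plots)]
    rng.shuffle(sowing)

    cultivar_effects = cultivar_effects or {}
    u_row = {f"R{r + 1}": rng.normal(0, row_sd) for r in range(n_rows)}
    u_plot = rng.normal(0, plot_sd, n_plots)

    if trait_effect_spec and trait_table is None:
        base = {"stem_dw": 400.0, "other": 300.0, "seed_dw": 250.0,
                "seed100_w": 25.0}
        trait_table = pd.DataFrame({
            "plot_id": plot_ids,
            "stem_dw": rng.normal(base["stem_dw"], trait_within_sd * 2, n_plots),
            "seed_dw": rng.normal(base["seed_dw"], trait_within_sd, n_plots),
            "seed100_w": rng.normal(base["seed100_w"], trait_within_sd / 10, n_plots),
        })
        trait_table["agb_dw"] = trait_table["stem_dw"] + np.abs(
            rng.normal(base["other"], trait_within_sd * 2, n_plots)
        )
    contrib = (
        _trait_contribution(trait_table, trait_effect_spec)
        if trait_effect_spec and trait_table is not None
        else pd.Series(0.0, index=plot_ids)
    )

    frames = []
    for i, pid in enumerate(plot_ids):
        mean = (grand_mean + u_row[row_ids[i]] + u_plot[i]
                + cultivar_effects.get(labels[i], 0.0)
                + (sowing_date_effect if sowing[i] == "d2" else 0.0)
                + contrib.get(pid, 0.0))
        y = mean + rng.normal(0, resid_sd, cells_per_plot)
        df = pd.DataFrame({
            "cell_id": [f"{pid}_c{c}" for c in range(cells_per_plot)],
            "plot_id": pid, "row_id": row_ids[i],
            "cultivar": labels[i], "sowing_date": sowing[i],
            "y_hat": y,
        })
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    if trait_table is not None:
        out = out.merge(trait_table.drop(columns=["cultivar"], errors="ignore"),
                        on="plot_id", how="left")
    return out


# ---------------------------------------------------------------------------
# on-disk experiment (GeoTIFF / GeoJSON / CSV)
# ---------------------------------------------------------------------------

def write_experiment(outdir, config: SyntheticConfig) -> dict:
    """Generate and write a full experiment; returns a manifest dict."""
    from .geometry import layout_to_geojson, points_to_geojson

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout, stack, samples, truth = generate_experiment(config)

    index_files = {}
    for name in stack.names:
        fname = f"index_{name}.tif"
        write_geotiff(outdir / fname, stack[name])
        index_files[name] = fname
    write_geotiff(outdir / "latent_yield.tif", truth.latent)
    layout_to_geojson(layout, outdir / "layout.geojson")
    points_to_geojson(sample_points_from_table(samples, config.quadrat_size_m),
                      outdir / "sample_points.geojson")
    samples.to_csv(outdir / "samples.csv", index=False)
    truth.trait_table.to_csv(outdir / "traits.csv", index=False)
    truth.assignment.to_csv(outdir / "assignment.csv", index=False)
    truth_meta = {
        "true_model_subset": list(truth.true_model_subset),
        "true_fixed_effects": {
            k: v for k, v in truth.true_fixed_effects.items()
            if k != "trait_effect_spec"
        },
        "index_transforms": {k: list(v) for k, v in truth.index_transforms.items()},
        "row_effects": truth.row_effects.to_dict(),
        "plot_effects": truth.plot_effects.to_dict(),
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth_meta, fh, indent=1, default=str)
    return {
        "index_files": index_files,
        "layout": "layout.geojson",
        "points": "sample_points.geojson",
        "samples": "samples.csv",
        "traits": "traits.csv",
        "truth": "truth.json",
        "candidates": list(config.candidate_indices),
    }
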