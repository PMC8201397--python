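"""Simulation-based calibration studies for the mixed-model stage.

These routines quantify, by Monte Carlo over the generative family of
:func:`uavfield.synthetic.simulate_cell_observations`, how the inference
machinery behaves when the truth is known:

* type-I error of the cultivar likelihood-ratio test under the null, with
  the correct row + plot-in-row random structure and — as a deliberate
  contrast — with the plot intercept omitted (pseudo-replication, which
  treats within-plot cells as independent and inflates the test);
* recovery of fixed effects and variance components;
* power against a cultivar shifted by a multiple of the residual SD.

The default calibration design is 8 sowing rows x 8 plots x 8 cells — the
same number of plots as a full-scale analysis but an order of magnitude
fewer cells — with row/plot/residual SDs of 25/15/30 yield units.  The
design is large enough for the chi-square reference of the LRT to hold at
the nominal level; much smaller plot counts make the ML-based LRT visibly
anticonservative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mixedmodels import LmmConvergenceError, fit_lmm, lrt_fixed_effect
from .synthetic import simulate_cell_observations

__all__ = [
    "CalibrationDesign",
    "lrt_rejection_rate",
    "variance_recovery",
    "DEFAULT_DESIGN",
]

_CULTIVAR_TERMS = ["C(sowing_date)", "C(cultivar)"]
_REDUCED_TERMS = ["C(sowing_date)"]


@dataclass(frozen=True)
class CalibrationDesign:
    """Reduced-scale simulated experiment for Monte Carlo calibration."""

    n_rows: int = 8
    plots_per_row: int = 8
    cells_per_plot: int = 8
    n_cultivars: int = 4
    grand_mean: float = 500.0
    row_sd: float = 25.0
    plot_sd: float = 15.0
    resid_sd: float = 30.0
    cultivar_effects: dict = field(default_factory=dict)

    def draw(self, rng: np.random.Generator) -> pd.DataFrame:
        return simulate_cell_observations(
            rng,
            n_rows=self.n_rows,
            plots_per_row=self.plots_per_row,
            cells_per_plot=self.cells_per_plot,
            grand_mean=self.grand_mean,
            n_cultivars=self.n_cultivars,
            cultivar_effects=self.cultivar_effects,
            row_sd=self.row_sd,
            plot_sd=self.plot_sd,
            resid_sd=self.resid_sd,
        )


DEFAULT_DESIGN = CalibrationDesign()


def lrt_rejection_rate(
    n_replicates: int,
    seed: int,
    design: CalibrationDesign = DEFAULT_DESIGN,
    include_plot: bool = True,
    alpha: float = 0.05,
) -> dict:
    """Monte Carlo rejection rate of the cultivar LRT at level ``alpha``.

    With ``design.cultivar_effects`` empty this is the type-I error; with
    effects set it is power.  ``include_plot=False`` drops the plot random
    intercept (the pseudo-replication demonstration).  Replicates whose fit
    fails to converge are counted separately, not silently dropped.
    """
    streams = np.random.SeedSequence(seed).spawn(n_replicates)
    rejections = 0
    failures = 0
    for child in streams:
        data = design.draw(np.random.default_rng(child))
        try:
            res = lrt_fixed_effect(
                data, _CULTIVAR_TERMS, _REDUCED_TERMS, include_plot=include_plot
            )
        except LmmConvergenceError:
            failures += 1
            continue
        rejections += res.p_value < alpha
    n_ok = n_replicates - failures
    return {
        "rate": rejections / n_ok if n_ok else float("nan"),
        "n_replicates": n_replicates,
        "n_converged": n_ok,
        "alpha": alpha,
    }


def variance_recovery(
    n_replicates: int,
    seed: int,
    design: CalibrationDesign = DEFAULT_DESIGN,
) -> pd.DataFrame:
    """Recover variance components and the grand mean over many replicates.

    Returns one row per parameter with the truth, the Monte Carlo mean of
    the REML estimates, the Monte Carlo standard error of that mean, and
    the absolute z-score |mean - truth| / SE.
    """
    streams = np.random.SeedSequence(seed).spawn(n_replicates)
    rows = []
    for child in streams:
        data = design.draw(np.random.default_rng(child))
        try:
            fit = fit_lmm(data, _CULTIVAR_TERMS, "REML")
        except LmmConvergenceError:
            continue
        rows.append(
            {
                "intercept": float(fit.fe_params.iloc[0]),
                "var_row": fit.var_row,
                "var_plot": fit.var_plot,
                "var_resid": fit.var_resid,
            }
        )
    est = pd.DataFrame(rows)
    # the model intercept is the reference cell (first cultivar/sowing
    # levels); with zero effects that is the grand mean
    truth = {
        "intercept": design.grand_mean,
        "var_row": design.row_sd ** 2,
        "var_plot": design.plot_sd ** 2,
        "var_resid": design.resid_sd ** 2,
    }
    out = []
    for name, true_value in truth.items():
        mean = est[name].mean()
        se = est[name].std(ddof=1) / np.sqrt(len(est))
        out.append(
            {
                "parameter": name,
                "truth": true_value,
                "mc_mean": mean,
                "mc_se": se,
                "z": abs(mean - true_value) / se if se > 0 else np.inf,
                "n": len(est),
            }
        )
    return pd.DataFrame(out)
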