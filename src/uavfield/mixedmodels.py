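"""Linear mixed models on cell-level predictions with nested random effects.

Treatment effects are tested on the dense grid of per-cell predicted yields
rather than on the handful of manual quadrats.  Because the ~125 cells of a
plot are repeated observations of the same experimental unit, and because
the field carries systematic spatial variation, the model includes random
intercepts for the sowing **row** and for the **plot nested in the row**:

    y_cell = X beta + u_row + u_plot(row) + eps,
    u_row ~ N(0, s2_row),  u_plot ~ N(0, s2_plot),  eps ~ N(0, s2_e).

Omitting the plot intercept would treat within-plot cells as independent
replicates (pseudo-replication) and grossly inflate type-I error; the
``include_plot=False`` switch exists precisely to demonstrate that.

Fixed effects are tested with likelihood-ratio tests on ML fits (chi-square
reference); reported coefficient tables come from REML fits.  Pairwise
cultivar contrasts are Wald z tests against the lowest-mean cultivar,
uncorrected by default (a Holm correction is available).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import patsy
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "LmmFit",
    "LrtResult",
    "CultivarAnalysis",
    "TraitAnalysis",
    "LmmConvergenceError",
    "fit_lmm",
    "lrt_fixed_effect",
    "cultivar_analysis",
    "trait_analysis",
    "marginal_effects",
    "significance_mark",
]

log = logging.getLogger(__name__)

TRAIT_COLUMNS = ("stem_dw", "seed_dw", "agb_dw", "seed100_w")


class LmmConvergenceError(RuntimeError):
    """Optimizer failed to converge; message carries the optimizer trace."""


@dataclass
class LmmFit:
    """A fitted linear mixed model with row / plot-in-row intercepts."""

    formula: str
    criterion: str                      # "ML" | "REML"
    fe_params: pd.Series
    fe_bse: pd.Series
    var_row: float
    var_plot: float
    var_resid: float
    loglik: float
    n_obs: int
    converged: bool
    include_plot: bool
    result: object = field(repr=False, default=None)  # statsmodels results

    @property
    def n_fixed(self) -> int:
        return len(self.fe_params)

    def variance_components(self) -> pd.Series:
        return pd.Series(
            {"row": self.var_row, "plot_in_row": self.var_plot,
             "residual": self.var_resid}
        )


@dataclass
class LrtResult:
    """Likelihood-ratio test between nested ML fits."""

    statistic: float
    df: int
    p_value: float
    term: str | None = None


def _formula(response: str, terms: list[str]) -> str:
    rhs = " + ".join(terms) if terms else "1"
    return f"{response} ~ {rhs}"


def fit_lmm(
    data: pd.DataFrame,
    fixed: list[str],
    criterion: str = "REML",
    response: str = "y_hat",
    include_plot: bool = True,
) -> LmmFit:
    """Fit the Gaussian mixed model with row and plot-in-row intercepts.

    ``fixed`` is a list of formula terms (e.g. ``["C(sowing_date)",
    "C(cultivar)"]`` or ``["stem_dw", "stem_dw:agb_dw"]``); the intercept is
    implicit.  Variance components may land on the boundary (0); that is
    reported, not an error.  Non-convergence raises
    :class:`LmmConvergenceError`.
    """
    if criterion not in ("ML", "REML"):
        raise ValueError("criterion must be 'ML' or 'REML'")
    if data["row_id"].nunique() < 2:
        raise ValueError("need at least two rows for the row random effect")
    formula = _formula(response, fixed)
    vc = {"plot": "0 + C(plot_id)"} if include_plot else None
    model = smf.mixedlm(
        formula, data, groups=data["row_id"], re_formula="1", vc_formula=vc
    )
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise np.linalg.LinAlgError(
            f"collinear fixed-effect design for formula {formula!r}"
        )
    result = None
    errors: list[str] = []
    with warnings.catch_warnings():
        # boundary variance estimates are permitted; keep the output quiet
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        for method in ("lbfgs", "cg", "powell", "nm"):
            try:
                result = model.fit(reml=(criterion == "REML"), method=method,
                                   disp=False)
            except (np.linalg.LinAlgError, ValueError) as exc:
                errors.append(f"{method}: {exc}")
                result = None
                continue
            if not np.isfinite(result.llf):
                # a degenerate optimum (e.g. scale -> 0) can report
                # convergence with an unbounded likelihood; reject it
                errors.append(f"{method}: non-finite log-likelihood")
                result = None
                continue
            if result.converged:
                break
    if result is None or not result.converged:
        trace = errors or getattr(result, "hist", None)
        raise LmmConvergenceError(
            f"mixed-model fit did not converge for {formula!r}; trace: {trace}"
        )
    k_fe = model.exog.shape[1]
    fe = result.params.iloc[:k_fe]
    bse = result.bse.iloc[:k_fe]
    var_plot = float(result.vcomp[0]) if include_plot else 0.0
    return LmmFit(
        formula=formula,
        criterion=criterion,
        fe_params=fe,
        fe_bse=bse,
        var_row=float(np.asarray(result.cov_re)[0, 0]),
        var_plot=var_plot,
        var_resid=float(result.scale),
        loglik=float(result.llf),
        n_obs=int(model.nobs),
        converged=bool(result.converged),
        include_plot=include_plot,
        result=result,
    )


def lrt_fixed_effect(
    data: pd.DataFrame,
    full: list[str],
    reduced: list[str],
    response: str = "y_hat",
    include_plot: bool = True,
    term: str | None = None,
) -> LrtResult:
    """LRT between nested fixed-effect structures (both fitted with ML).

    The degrees of freedom are the difference in fixed-effect design
    columns (a categorical term contributes its level count minus one).
    """
    if not set(reduced) <= set(full):
        raise ValueError("reduced terms must be a subset of the full terms")
    fit_full = fit_lmm(data, full, "ML", response, include_plot)
    fit_red = fit_lmm(data, reduced, "ML", response, include_plot)
    df = fit_full.n_fixed - fit_red.n_fixed
    stat = max(0.0, 2.0 * (fit_full.loglik - fit_red.loglik))
    if df < 1:
        return LrtResult(statistic=0.0, df=0, p_value=1.0, term=term)
    p = float(stats.chi2.sf(stat, df))
    return LrtResult(statistic=stat, df=df, p_value=p, term=term)


def significance_mark(p: float) -> str:
    """Raw-p asterisk convention: ** < 0.01, * < 0.05."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# cultivar analysis (treatment testing)
# ---------------------------------------------------------------------------

@dataclass
class CultivarAnalysis:
    fit: LmmFit                      # REML fit with the reference recoding
    lrt_cultivar: LrtResult
    lrt_sowing: LrtResult
    emm: pd.Series                   # estimated marginal mean per cultivar
    reference: str
    contrasts: pd.DataFrame          # cultivar, estimate, se, z, p, mark


def _marginal_means(fit: LmmFit, data: pd.DataFrame,
                    factor: str = "cultivar") -> pd.Series:
    """Estimated marginal mean per factor level, averaging over the other
    factor's levels with equal weight (random effects at zero)."""
    design_info = fit.result.model.data.design_info
    levels = sorted(data[factor].dropna().unique())
    others = sorted(data["sowing_date"].dropna().unique())
    grid = pd.DataFrame(
        [{factor: lv, "sowing_date": sd} for lv in levels for sd in others]
    )
    X = np.asarray(patsy.dmatrix(design_info, grid))
    pred = X @ fit.fe_params.to_numpy()
    return pd.Series(pred, index=pd.MultiIndex.from_frame(grid)).groupby(level=0).mean()


def cultivar_analysis(
    data: pd.DataFrame,
    response: str = "y_hat",
    p_adjust: str = "none",
) -> CultivarAnalysis:
    """Test treatment (cultivar, sowing date) effects on cell predictions.

    Fits ``response ~ sowing_date + cultivar`` with the nested random
    intercepts, runs LRTs for each treatment term, re-codes the cultivar
    factor so the level with the lowest estimated marginal mean is the
    reference, and reports Wald z contrasts of every other level against it.
    """
    if data["cultivar"].nunique() < 2:
        raise ValueError("need at least two cultivar levels")
    plots_per_cultivar = data.groupby("cultivar")["plot_id"].nunique()
    singles = plots_per_cultivar[plots_per_cultivar < 2]
    if not singles.empty:
        log.warning(
            "cultivar(s) with a single plot (contrast SEs inflated): %s",
            ", ".join(singles.index.astype(str)),
        )
    terms = ["C(sowing_date)", "C(cultivar)"]
    lrt_cult = lrt_fixed_effect(data, terms, ["C(sowing_date)"], response,
                                term="cultivar")
    lrt_sow = lrt_fixed_effect(data, terms, ["C(cultivar)"], response,
                               term="sowing_date")
    base_fit = fit_lmm(data, terms, "REML", response)
    emm = _marginal_means(base_fit, data)
    reference = str(emm.idxmin())

    ref_terms = ["C(sowing_date)", f"C(cultivar, Treatment(reference={reference!r}))"]
    fit = fit_lmm(data, ref_terms, "REML", response)
    prefix = f"C(cultivar, Treatment(reference={reference!r}))[T."
    rows = []
    for name, est in fit.fe_params.items():
        if not name.startswith(prefix):
            continue
        level = name[len(prefix):-1]
        se = float(fit.fe_bse[name])
        z = est / se
        p = 2.0 * float(stats.norm.sf(abs(z)))
        rows.append({"cultivar": level, "estimate": float(est), "se": se,
                     "z": z, "p": p})
    contrasts = pd.DataFrame(rows).sort_values("cultivar").reset_index(drop=True)
    if p_adjust == "holm":
        from statsmodels.stats.multitest import multipletests

        contrasts["p_adjusted"] = multipletests(contrasts["p"], method="holm")[1]
        contrasts["mark"] = contrasts["p_adjusted"].map(significance_mark)
    elif p_adjust == "none":
        contrasts["mark"] = contrasts["p"].map(significance_mark)
    else:
        raise ValueError("p_adjust must be 'none' or 'holm'")
    return CultivarAnalysis(
        fit=fit,
        lrt_cultivar=lrt_cult,
        lrt_sowing=lrt_sow,
        emm=emm,
        reference=reference,
        contrasts=contrasts,
    )


# ---------------------------------------------------------------------------
# trait analysis (which preceding-crop traits drive the response)
# ---------------------------------------------------------------------------

@dataclass
class TraitAnalysis:
    fit: LmmFit                      # REML fit of the full trait model
    lrts: pd.DataFrame               # term, statistic, df, p, mark
    terms: list[str]
    data: pd.DataFrame = field(repr=False, default=None)


def trait_terms(traits: tuple[str, ...] = TRAIT_COLUMNS) -> list[str]:
    """Main effects plus all pairwise interactions (1 + 4 + 6 columns)."""
    mains = list(traits)
    inters = [f"{a}:{b}" for a, b in combinations(traits, 2)]
    return mains + inters


def trait_analysis(
    data: pd.DataFrame,
    traits: tuple[str, ...] = TRAIT_COLUMNS,
    response: str = "y_hat",
) -> TraitAnalysis:
    """Regress cell predictions on preceding-crop traits and interactions.

    Fixed part: the four trait main effects and their six pairwise
    interactions (11 coefficients with the intercept); random part as in
    :func:`fit_lmm`.  Each term is tested by single-term deletion under ML.
    Traits are centered (per-plot values) before products are formed, which
    leaves the LRTs unchanged but decorrelates mains from interactions.
    """
    work = data.copy()
    for t in traits:
        col = work[t].astype(float)
        if col.std() == 0:
            raise np.linalg.LinAlgError(f"trait {t!r} is constant across plots")
        work[t] = col - col.mean()
    terms = trait_terms(traits)
    full_fit = fit_lmm(work, terms, "REML", response)
    rows = []
    for term in terms:
        reduced = [t for t in terms if t != term]
        res = lrt_fixed_effect(work, terms, reduced, response, term=term)
        rows.append({"term": term, "statistic": res.statistic, "df": res.df,
                     "p": res.p_value, "mark": significance_mark(res.p_value)})
    lrts = pd.DataFrame(rows)
    return TraitAnalysis(fit=full_fit, lrts=lrts, terms=terms, data=work)


def marginal_effects(
    fit: LmmFit,
    focal: str,
    moderator: str,
    focal_values,
    moderator_values,
) -> pd.DataFrame:
    """Fixed-effect predictions over a focal x moderator grid.

    All other covariates are held at their training-data means and random
    effects at zero, so with centered traits the prediction at (0, 0) is the
    fitted population mean.  Values far outside the observed range trigger
    an extrapolation warning, not an error.
    """
    model = fit.result.model
    frame = model.data.frame
    design_info = model.data.design_info
    numeric = frame.select_dtypes(include=[np.number])
    base = {c: float(numeric[c].mean()) for c in numeric.columns}
    for col in (focal, moderator):
        if col not in frame.columns:
            raise KeyError(f"{col!r} is not a model covariate")
        lo, hi = frame[col].min(), frame[col].max()
        values = focal_values if col == focal else moderator_values
        span = hi - lo if hi > lo else 1.0
        if min(values) < lo - 0.5 * span or max(values) > hi + 0.5 * span:
            log.warning("%s grid extends far outside the data range", col)
    grid = pd.DataFrame(
        [
            {**base, focal: fv, moderator: mv}
            for fv in focal_values
            for mv in moderator_values
        ]
    )
    X = np.asarray(patsy.dmatrix(design_info, grid))
    pred = X @ fit.fe_params.to_numpy()
    out = grid[[focal, moderator]].copy()
    out["prediction"] = pred
    return out
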