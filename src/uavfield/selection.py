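"""All-subsets Gaussian linear model search scored by AIC.

The predictive model is an ordinary Gaussian linear model (identity link)
relating the ground-sampled response y_p at quadrat p to the quadrat-mean
imagery indices x_{i,p}:

    y_p = b0 + sum_i b_i x_{i,p} + eps,   eps ~ N(0, sigma^2)

Every subset of the m candidate indices (2^m models, intercept always
included) is fitted and ranked by AIC = -2 logLik + 2k, where the parameter
count k includes the intercept, the slopes and the residual variance, and
the log-likelihood is the full Gaussian one:

    logLik = -(n/2) [ln(2 pi) + ln(RSS/n) + 1]

Akaike weights w_i = exp(-dAIC_i/2) / sum_j exp(-dAIC_j/2) quantify relative
support over the candidate set.  A fit with RSS = 0 has unbounded Gaussian
likelihood; such degenerate fits are ranked ahead of all finite-AIC fits
(smaller k first, then lexicographic subset) and share the weight uniformly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ModelSpec",
    "FitResult",
    "SelectionTable",
    "SingularityError",
    "DegenerateFitError",
    "fit_gaussian_glm",
    "aic",
    "enumerate_models",
    "rank_models",
    "best_model",
    "save_best_model",
    "load_best_model",
]

#: RSS below this (relative to total sum of squares, floored absolutely)
#: marks an exact fit whose Gaussian log-likelihood is unbounded.
_DEGENERATE_RTOL = 1e-10


class SingularityError(ValueError):
    """Design matrix is rank deficient (collinear predictors)."""


class DegenerateFitError(ValueError):
    """RSS = 0: the Gaussian log-likelihood (and AIC) is unbounded."""


ModelSpec = tuple[str, ...]


@dataclass(frozen=True)
class FitResult:
    """One fitted candidate model (intercept always included)."""

    spec: ModelSpec
    params: np.ndarray          # intercept first, then slopes in spec order
    rss: float
    tss: float
    n: int
    degenerate: bool

    @property
    def k(self) -> int:
        """Parameter count: intercept + slopes + residual variance."""
        return len(self.spec) + 2

    @property
    def r_squared(self) -> float:
        if self.tss == 0:
            return 1.0 if self.degenerate else 0.0
        return 1.0 - self.rss / self.tss

    @property
    def sigma2(self) -> float:
        """ML residual-variance estimate RSS/n."""
        return self.rss / self.n

    @property
    def loglik(self) -> float:
        if self.degenerate:
            return np.inf
        return -(self.n / 2.0) * (np.log(2.0 * np.pi) + np.log(self.rss / self.n) + 1.0)

    @property
    def intercept(self) -> float:
        return float(self.params[0])

    @property
    def slopes(self) -> dict[str, float]:
        return dict(zip(self.spec, map(float, self.params[1:])))


def fit_gaussian_glm(design: pd.DataFrame, response) -> FitResult:
    """Ordinary least squares fit of the response on the design columns.

    ``design`` holds exactly the candidate indices of the model spec (the
    intercept is added here).  Raises :class:`SingularityError` for rank-
    deficient designs.  An exact fit (RSS = 0) is returned with
    ``degenerate=True``; its AIC is undefined (see :func:`aic`).
    """
    y = np.asarray(response, dtype=float)
    spec = tuple(design.columns)
    X = np.column_stack([np.ones(len(y))] + [np.asarray(design[c], float) for c in spec])
    n, p = X.shape
    if n <= len(spec) + 2:
        raise ValueError(f"need n > k = {len(spec) + 2} samples, got n = {n}")
    if np.linalg.matrix_rank(X) < p:
        raise SingularityError(f"rank-deficient design for spec {spec}")
    res = sm.OLS(y, X).fit()
    rss = float(res.ssr)
    tss = float(np.sum((y - y.mean()) ** 2))
    degenerate = rss <= _DEGENERATE_RTOL * max(tss, 1.0)
    return FitResult(
        spec=spec,
        params=np.asarray(res.params, dtype=float),
        rss=rss,
        tss=tss,
        n=n,
        degenerate=degenerate,
    )


def aic(fit: FitResult) -> float:
    """AIC = -2 logLik + 2k (k counts intercept, slopes, residual variance)."""
    if fit.degenerate:
        raise DegenerateFitError(
            "RSS = 0: Gaussian log-likelihood is unbounded, AIC undefined"
        )
    return -2.0 * fit.loglik + 2.0 * fit.k


def enumerate_models(
    candidates: list[str], max_candidates: int = 20, force: bool = False
) -> list[ModelSpec]:
    """All 2^m index subsets (including intercept-only), deterministic order.

    Subsets are listed by increasing size, preserving candidate order within
    each size.  Refuses m > ``max_candidates`` unless ``force`` (2^m fits).
    """
    if len(set(candidates)) != len(candidates):
        raise ValueError("candidate names must be unique")
    if len(candidates) > max_candidates and not force:
        raise ValueError(
            f"{len(candidates)} candidates imply 2^{len(candidates)} fits; "
            "pass force=True to run an exhaustive search this large"
        )
    specs: list[ModelSpec] = []
    for size in range(len(candidates) + 1):
        specs.extend(itertools.combinations(candidates, size))
    return specs


class SelectionTable:
    """Ranked all-subsets fits with dAIC and Akaike weights.

    ``table`` is a frame with one row per model: rank, spec, r_squared, df
    (the AIC parameter count k), aic, delta_aic, weight.  Degenerate fits
    appear first with aic/delta_aic of -inf/0 and uniform weight share.
    """

    def __init__(self, fits: list[FitResult]):
        if not fits:
            raise ValueError("need at least one fit to rank")

        def sort_key(f: FitResult):
            a = -np.inf if f.degenerate else aic(f)
            return (a, f.k, f.spec)

        self.fits = sorted(fits, key=sort_key)
        n_deg = sum(f.degenerate for f in self.fits)
        aics = np.array(
            [-np.inf if f.degenerate else aic(f) for f in self.fits]
        )
        if n_deg:
            delta = np.where(np.isneginf(aics), 0.0, np.inf)
            weights = np.where(np.isneginf(aics), 1.0 / n_deg, 0.0)
        else:
            delta = aics - aics[0]
            rel = np.exp(-delta / 2.0)
            weights = rel / rel.sum()
        self.table = pd.DataFrame(
            {
                "rank": np.arange(1, len(self.fits) + 1),
                "spec": [" + ".join(f.spec) if f.spec else "(intercept)" for f in self.fits],
                "r_squared": [f.r_squared for f in self.fits],
                "df": [f.k for f in self.fits],
                "aic": aics,
                "delta_aic": delta,
                "weight": weights,
            }
        )

    def __len__(self) -> int:
        return len(self.fits)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def rank_models(fits: list[FitResult]) -> SelectionTable:
    """Sort fits by AIC ascending; ties broken by smaller k, then spec."""
    return SelectionTable(fits)


def best_model(table: SelectionTable) -> FitResult:
    """The rank-1 fit: lowest AIC (or the minimal exact fit if RSS = 0)."""
    return table.fits[0]


def fit_all_subsets(
    data: pd.DataFrame,
    candidates: list[str],
    response: str,
    max_candidates: int = 20,
    force: bool = False,
) -> SelectionTable:
    """Convenience wrapper: enumerate, fit and rank every candidate subset."""
    y = data[response]
    fits = [
        fit_gaussian_glm(data[list(spec)], y)
        for spec in enumerate_models(candidates, max_candidates, force)
    ]
    return rank_models(fits)


# ---------------------------------------------------------------------------
# plain-text model persistence
# ---------------------------------------------------------------------------

def save_best_model(fit: FitResult, path) -> None:
    """Serialize a fitted model as plain key=value text."""
    lines = [
        f"spec={','.join(fit.spec)}",
        f"intercept={fit.intercept!r}",
        f"n={fit.n}",
        f"rss={fit.rss!r}",
        f"sigma2={fit.sigma2!r}",
    ]
    for name, b in fit.slopes.items():
        lines.append(f"coef.{name}={b!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_best_model(path) -> FitResult:
    kv: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if "=" in line:
                key, val = line.strip().split("=", 1)
                kv[key] = val
    spec = tuple(s for s in kv["spec"].split(",") if s)
    params = np.array(
        [float(kv["intercept"])] + [float(kv[f"coef.{name}"]) for name in spec]
    )
    n = int(kv["n"])
    rss = float(kv["rss"])
    return FitResult(spec=spec, params=params, rss=rss, tss=np.nan, n=n,
                     degenerate=rss <= 0.0)
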