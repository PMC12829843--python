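"""Yearly aggregation and temporal-trend testing.

Each tracked variable is collapsed to one value per publication year (means
for per-species variables, counts for species and papers, percentages for
genetics use).  The trend over years is then fitted both by ordinary least
squares on year and by a penalized cubic-spline GAM (smoothness chosen by
generalized cross-validation); the method with the larger unadjusted R^2 is
selected, with ties going to the simpler linear model.  A degree-2 tricube
LOESS smoother is provided for presentation only and never used for
p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.gam.api import BSplines, GLMGam

from .records import TypeSeriesRecord, covariate_frame

TREND_VARIABLES = (
    "overall_y", "collection_y", "description_y", "n_authors",
    "n_species_per_year", "n_papers_per_year", "n_species_per_paper",
    "n_types", "pct_genetics", "n_trips",
)

_PER_SPECIES_MEANS = {"overall_y", "collection_y", "description_y",
                      "n_authors", "n_types", "n_trips"}


@dataclass
class TrendSeries:
    variable: str
    scope: str
    data: pd.DataFrame  # columns: year, value, n

    @property
    def years(self) -> np.ndarray:
        return self.data["year"].to_numpy(dtype=float)

    @property
    def values(self) -> np.ndarray:
        return self.data["value"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class TrendFit:
    method: str  # "LM" or "GAM"
    r2_lm: float
    r2_gam: float
    p_value: float  # chosen method's trend-term p
    p_lm: float
    p_gam: float | None
    slope: float  # LM slope, always reported
    fitted: np.ndarray
    gam_edf: float | None = None
    gam_deviance_explained: float | None = None
    note: str | None = None

    def to_dict(self) -> dict:
        return {
            "method": self.method, "r2_lm": self.r2_lm,
            "r2_gam": self.r2_gam, "p_value": self.p_value,
            "p_lm": self.p_lm, "p_gam": self.p_gam, "slope": self.slope,
            "gam_edf": self.gam_edf,
            "gam_deviance_explained": self.gam_deviance_explained,
            "note": self.note,
        }


def yearly_series(records: list[TypeSeriesRecord], lag_df: pd.DataFrame,
                  variable: str, scope: str = "global") -> TrendSeries:
    """One value per publication year for ``variable`` within ``scope``.

    Years with no described species are absent (no zero-filling): yearly
    values are averages over that year's descriptions.
    """
    if variable not in TREND_VARIABLES:
        raise ValueError(f"unknown trend variable {variable!r}")
    cov = covariate_frame(records)
    df = cov.merge(lag_df[["species", "overall_y", "collection_y",
                           "description_y", "n_trips"]],
                   on="species", how="inner")
    if scope != "global":
        df = df[df["region"] == scope]
    if df.empty:
        raise ValueError(f"no records in scope {scope!r}")
    grp = df.groupby("publication_year", sort=True)
    if variable in _PER_SPECIES_MEANS:
        out = grp[variable].mean().rename("value").reset_index()
        out["n"] = grp.size().to_numpy()
    elif variable == "n_species_per_year":
        out = grp.size().rename("value").reset_index()
        out["n"] = out["value"]
    elif variable == "n_papers_per_year":
        out = grp["publication_id"].nunique().rename("value").reset_index()
        out["n"] = out["value"]
    elif variable == "n_species_per_paper":
        papers = df.drop_duplicates("publication_id")
        pg = papers.groupby("publication_year", sort=True)
        out = pg["n_species_in_paper"].mean().rename("value").reset_index()
        out["n"] = pg.size().to_numpy()
    elif variable == "pct_genetics":
        out = (100.0 * grp["genetics"].mean()).rename("value").reset_index()
        out["n"] = grp.size().to_numpy()
    out = out.rename(columns={"publication_year": "year"})
    return TrendSeries(variable=variable, scope=scope,
                       data=out[["year", "value", "n"]])


def _lm_fit(x: np.ndarray, y: np.ndarray):
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    fitted = np.asarray(res.fittedvalues)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((y - fitted) ** 2)) / tss if tss > 0 else 1.0
    slope = float(res.params[1])
    p = float(res.pvalues[1])
    return r2, p, slope, fitted


_GCV_ALPHAS = np.logspace(-4, 6, 21)

#: inflation factor on effective degrees of freedom in the GCV score;
#: plain GCV (gamma = 1) is known to overfit short series, and ~1.4 is the
#: standard corrective for smoothness selection
_GCV_GAMMA = 1.4


def _gam_fit(x: np.ndarray, y: np.ndarray, basis_dim: int):
    bs = BSplines(x, df=[basis_dim], degree=[3])
    exog = np.ones((x.size, 1))
    best = None
    for alpha in _GCV_ALPHAS:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = GLMGam(y, exog=exog, smoother=bs, alpha=[alpha]).fit()
            except Exception:
                # a residual-free fit (deterministic series) aborts PIRLS;
                # skip that penalty weight
                continue
        edf = float(res.hat_matrix_trace)
        rss = float(np.sum((y - res.fittedvalues) ** 2))
        denom = max(x.size - _GCV_GAMMA * edf, 1e-8)
        gcv = x.size * rss / denom ** 2
        if best is None or gcv < best[0]:
            best = (gcv, res, edf, rss)
    if best is None:
        return float("nan"), float("nan"), None, None, None
    _, res, edf, rss = best
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            sig = res.test_significance(0)
            p = float(np.squeeze(sig.pvalue))
        except Exception:
            p = float("nan")
    dev_expl = 1.0 - rss / tss if tss > 0 else 1.0
    return r2, p, np.asarray(res.fittedvalues), edf, dev_expl


def fit_trend(series: TrendSeries, min_gam_points: int = 5) -> TrendFit:
    """LM-vs-GAM trend fit, selected by unadjusted R^2 (ties -> LM).

    Deterministic given the series.  With fewer than ``min_gam_points``
    yearly points the GAM is not attempted and the LM is used with a note.
    """
    x, y = series.years, series.values
    if x.size < 3:
        raise ValueError("need at least 3 yearly points")
    r2_lm, p_lm, slope, fitted_lm = _lm_fit(x, y)
    if x.size < min_gam_points:
        return TrendFit(method="LM", r2_lm=r2_lm, r2_gam=float("nan"),
                        p_value=p_lm, p_lm=p_lm, p_gam=None, slope=slope,
                        fitted=fitted_lm,
                        note="too few points for GAM; LM used")
    basis_dim = min(8, x.size - 1)
    r2_gam, p_gam, fitted_gam, edf, dev = _gam_fit(x, y, basis_dim)
    if fitted_gam is None:
        return TrendFit(method="LM", r2_lm=r2_lm, r2_gam=r2_gam,
                        p_value=p_lm, p_lm=p_lm, p_gam=None, slope=slope,
                        fitted=fitted_lm,
                        note="GAM fit unavailable (residual-free series)")
    if r2_gam > r2_lm + 1e-9:
        return TrendFit(method="GAM", r2_lm=r2_lm, r2_gam=r2_gam,
                        p_value=p_gam, p_lm=p_lm, p_gam=p_gam, slope=slope,
                        fitted=fitted_gam, gam_edf=edf,
                        gam_deviance_explained=dev)
    return TrendFit(method="LM", r2_lm=r2_lm, r2_gam=r2_gam, p_value=p_lm,
                    p_lm=p_lm, p_gam=p_gam, slope=slope, fitted=fitted_lm,
                    gam_edf=edf, gam_deviance_explained=dev)


def loess_smooth(series: TrendSeries, span: float = 0.75,
                 degree: int = 2) -> np.ndarray:
    """Locally weighted polynomial regression with tricube weights.

    At each year the ``ceil(span * n)`` nearest points (by |x - x0|) get
    tricube weights on distance scaled by the furthest neighbour, and a
    weighted degree-``degree`` polynomial is evaluated at the year.
    Presentation-only; no inference is derived from it.
    """
    x, y = series.years, series.values
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 points for LOESS")
    q = max(int(np.ceil(span * n)), degree + 1)
    q = min(q, n)
    out = np.empty(n)
    for i, x0 in enumerate(x):
        dist = np.abs(x - x0)
        idx = np.argsort(dist, kind="stable")[:q]
        dmax = dist[idx].max()
        if dmax == 0:
            out[i] = y[idx].mean()
            continue
        w = (1 - (dist[idx] / dmax) ** 3) ** 3
        w = np.clip(w, 0.0, None)
        # guard: keep at least the point itself weighted
        if w.sum() <= 0:
            out[i] = y[i]
            continue
        V = np.vander(x[idx] - x0, degree + 1, increasing=True)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(sw[:, None] * V, sw * y[idx], rcond=None)
        out[i] = coef[0]
    return out
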