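"""Gaussian linear mixed models for log description time.

The response is log(description lag in years); fixed effects are the
per-species covariates (genetics indicator, author count, type-series size,
species per paper, field-trip count, genus richness); random intercepts are
crossed grouping factors (genus and region in the global model, genus only
in regional models).

Estimation is maximum likelihood (not REML) so that likelihoods and AICs of
nested fixed-effect structures are comparable.  The deviance is profiled:
for variance ratios gamma_f = sigma_f^2 / sigma^2 the marginal covariance is
sigma^2 (I + Z Gamma Z'), beta and sigma^2 have closed forms, and the
remaining 1-2 parameters are optimised by bounded quasi-Newton on the log
scale.  The n x n covariance never materialises: all solves go through the
q x q capacitance matrix I_q + Gamma^(1/2) Z'Z Gamma^(1/2) with q the total
number of random-effect levels.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

DEFAULT_FIXED = ("genetics", "n_authors", "n_types", "n_species_in_paper",
                 "n_trips", "genus_richness")

#: variance ratios below this are pinned to an exact zero component
_GAMMA_FLOOR = 1e-8


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: response, fixed effects, random intercepts, scope."""
    response: str = "log_description_y"
    fixed: tuple[str, ...] = DEFAULT_FIXED
    random_intercepts: tuple[str, ...] = ("genus", "region")
    scope: str = "global"
    zscale: bool = False

    def for_region(self, region: str) -> "ModelSpec":
        """Regional variant: drops the region random effect."""
        return ModelSpec(
            response=self.response, fixed=self.fixed,
            random_intercepts=tuple(r for r in self.random_intercepts
                                    if r != "region"),
            scope=region, zscale=self.zscale)


@dataclass
class RandomFactor:
    name: str
    levels: list[str]
    codes: np.ndarray  # observation -> level index
    variance: float = 0.0


@dataclass
class ModelFit:
    spec: ModelSpec
    exog_names: list[str]
    params: np.ndarray
    bse: np.ndarray
    vcov: np.ndarray
    sigma2_resid: float
    random_factors: list[RandomFactor]
    loglik: float
    aic: float
    n: int
    k_params: int
    converged: bool
    X: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)

    @property
    def variance_components(self) -> dict[str, float]:
        return {f.name: f.variance for f in self.random_factors}

    def fitted_fixed(self) -> np.ndarray:
        return self.X @ self.params

    def coef_table(self) -> pd.DataFrame:
        z = self.params / self.bse
        return pd.DataFrame({
            "term": self.exog_names, "estimate": self.params,
            "se": self.bse, "z": z,
            "p": 2 * stats.norm.sf(np.abs(z)),
        })

    def to_dict(self) -> dict:
        return {
            "scope": self.spec.scope,
            "response": self.spec.response,
            "fixed": list(self.spec.fixed),
            "random": [f.name for f in self.random_factors],
            "coefficients": self.coef_table().to_dict(orient="records"),
            "variance_components": self.variance_components,
            "sigma2_resid": self.sigma2_resid,
            "loglik": self.loglik, "aic": self.aic,
            "n": self.n, "k": self.k_params,
            "converged": bool(self.converged),
        }


def collinearity_screen(df: pd.DataFrame, threshold: float = 0.70,
                        columns: list[str] | None = None
                        ) -> list[tuple[str, str, float]]:
    """Pairs of numeric covariates with |Pearson r| above ``threshold``.

    An empty list means the screen passes.  Constant columns make the
    correlation undefined and raise.
    """
    cols = columns or [c for c in df.columns
                       if pd.api.types.is_numeric_dtype(df[c])]
    if len(cols) < 2:
        raise ValueError("need at least two numeric columns")
    for c in cols:
        if df[c].nunique() < 2:
            raise ValueError(f"constant column {c!r}: correlation undefined")
    offending = []
    for a, b in itertools.combinations(cols, 2):
        r = float(np.corrcoef(df[a].astype(float), df[b].astype(float))[0, 1])
        if abs(r) > threshold:
            offending.append((a, b, r))
    return offending


def build_model_frame(covariates: pd.DataFrame,
                      lag_df: pd.DataFrame) -> pd.DataFrame:
    """Merge per-species covariates with the lag table and add the
    log-transformed response (description lag must be positive)."""
    df = covariates.merge(
        lag_df[["species", "overall_y", "collection_y", "description_y",
                "n_trips"]],
        on="species", how="inner")
    if (df["description_y"] <= 0).any():
        raise ValueError("non-positive description lag in model frame")
    df["log_description_y"] = np.log(df["description_y"].astype(float))
    df["genetics"] = df["genetics"].astype(int)
    return df


def _design(df: pd.DataFrame, spec: ModelSpec):
    n = len(df)
    cols = [np.ones(n)]
    names = ["Intercept"]
    for c in spec.fixed:
        x = df[c].astype(float).to_numpy()
        if spec.zscale:
            sd = x.std(ddof=1)
            x = (x - x.mean()) / (sd if sd > 0 else 1.0)
        cols.append(x)
        names.append(c)
    X = np.column_stack(cols)
    y = df[spec.response].astype(float).to_numpy()
    factors: list[RandomFactor] = []
    for name in spec.random_intercepts:
        levels, codes = np.unique(df[name].astype(str).to_numpy(),
                                  return_inverse=True)
        if len(levels) < 2:
            raise ValueError(
                f"random factor {name!r} has fewer than 2 levels")
        factors.append(RandomFactor(name=name, levels=list(levels),
                                    codes=codes))
    return X, y, names, factors


def _factor_Z(n: int, factors: list[RandomFactor]) -> tuple[np.ndarray, list]:
    blocks = []
    slices = []
    start = 0
    for f in factors:
        q = len(f.levels)
        Z = np.zeros((n, q))
        Z[np.arange(n), f.codes] = 1.0
        blocks.append(Z)
        slices.append(slice(start, start + q))
        start += q
    Z = np.concatenate(blocks, axis=1) if blocks else np.zeros((n, 0))
    return Z, slices


def fit_lmm(df: pd.DataFrame, spec: ModelSpec,
            deviance_tol: float = 1e-8) -> ModelFit:
    """ML fit of the Gaussian mixed model defined by ``spec`` on ``df``.

    Deterministic given the data and optimiser settings.  Non-convergence
    returns a fit flagged ``converged=False`` with a warning, never a
    silent success.
    """
    X, y, names, factors = _design(df, spec)
    n, p = X.shape
    if n <= p:
        raise ValueError("more parameters than observations")

    Z, slices = _factor_Z(n, factors)
    q = Z.shape[1]
    XtX, Xty, yty = X.T @ X, X.T @ y, float(y @ y)
    ZtZ, ZtX, Zty = Z.T @ Z, Z.T @ X, Z.T @ y

    def profile(log_gamma: np.ndarray):
        """Profiled -2 loglik and the profiled estimates at gamma."""
        gam = np.exp(np.clip(log_gamma, -40.0, 40.0))
        s = np.empty(q)
        for g, sl in zip(gam, slices):
            s[sl] = math.sqrt(g)
        A = np.eye(q) + (s[:, None] * ZtZ) * s[None, :]
        cf = linalg.cho_factor(A, lower=True)
        logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        SZtX = s[:, None] * ZtX
        SZty = s * Zty
        AiSZtX = linalg.cho_solve(cf, SZtX)
        AiSZty = linalg.cho_solve(cf, SZty)
        XtVX = XtX - SZtX.T @ AiSZtX
        XtVy = Xty - SZtX.T @ AiSZty
        ytVy = yty - float(SZty @ AiSZty)
        beta = linalg.solve(XtVX, XtVy, assume_a="pos")
        rss = max(ytVy - float(beta @ XtVy), 1e-300)
        sigma2 = rss / n
        m2ll = n * math.log(2 * math.pi * sigma2) + logdet + n
        return m2ll, beta, sigma2, XtVX

    if q == 0:
        m2ll, beta, sigma2, XtVX = profile(np.zeros(0))
        best_lg = np.zeros(0)
        success = True
    else:
        nfac = len(factors)
        starts = [np.full(nfac, v) for v in (-1.0, -4.0)]
        if nfac > 1:
            starts += [np.array(c) for c in
                       itertools.product((-4.0, 1.0), repeat=nfac)]
        best = None
        success = False
        for x0 in starts:
            res = optimize.minimize(
                lambda lg: profile(lg)[0], x0, method="L-BFGS-B",
                bounds=[(-30.0, 15.0)] * nfac,
                options={"ftol": deviance_tol * 1e-4, "gtol": 1e-10,
                         "maxiter": 500})
            if best is None or res.fun < best.fun - 0.0:
                best = res
            success = success or res.success
        best_lg = best.x
        m2ll, beta, sigma2, XtVX = profile(best_lg)
        if not success:
            warnings.warn("mixed-model optimiser did not report convergence",
                          RuntimeWarning)

    vcov = sigma2 * linalg.inv(XtVX)
    bse = np.sqrt(np.diag(vcov))
    gam = np.exp(best_lg)
    for f, g in zip(factors, gam):
        f.variance = 0.0 if g < _GAMMA_FLOOR else float(g * sigma2)
    loglik = -0.5 * m2ll
    k = p + len(factors) + 1
    return ModelFit(
        spec=spec, exog_names=names, params=beta, bse=bse, vcov=vcov,
        sigma2_resid=float(sigma2), random_factors=factors,
        loglik=float(loglik), aic=float(2 * k - 2 * loglik), n=n,
        k_params=k, converged=bool(success), X=X, y=y)


def wald_anova(fit: ModelFit) -> pd.DataFrame:
    """Type-II Wald chi-square test per fixed term (intercept excluded).

    Every fixed term here is a single column (continuous covariates and the
    0/1 genetics indicator), so each test has one degree of freedom and the
    statistic reduces to (coef/se)^2; the implementation is the general
    joint form so multi-column terms would be tested jointly.
    """
    if not fit.converged:
        raise ValueError("Wald tests require a converged fit")
    rows = []
    for term in fit.spec.fixed:
        idx = [i for i, nm in enumerate(fit.exog_names) if nm == term]
        b = fit.params[idx]
        C = fit.vcov[np.ix_(idx, idx)]
        try:
            stat = float(b @ linalg.solve(C, b, assume_a="pos"))
            df = len(idx)
            p = float(stats.chi2.sf(stat, df))
        except linalg.LinAlgError:
            stat, df, p = float("nan"), len(idx), float("nan")
        rows.append({"term": term, "chisq": stat, "df": df, "p": p})
    return pd.DataFrame(rows)


def compare_null(full: ModelFit, null: ModelFit) -> dict:
    """Likelihood-ratio and AIC comparison of a full model against the
    null model (random effects only), both ML fits on the same data."""
    if full.n != null.n:
        raise ValueError("models were fitted to different data sizes")
    full_terms = set(full.exog_names)
    if not set(null.exog_names) <= full_terms:
        raise ValueError("null fixed part is not nested in the full model")
    if [f.name for f in full.random_factors] != \
            [f.name for f in null.random_factors]:
        raise ValueError("random structures differ")
    lr = 2.0 * (full.loglik - null.loglik)
    df = len(full.exog_names) - len(null.exog_names)
    p = float(stats.chi2.sf(max(lr, 0.0), df)) if df > 0 else float("nan")
    return {
        "lr_statistic": float(lr), "df": int(df), "p": p,
        "aic_full": full.aic, "aic_null": null.aic,
        "aic_delta": float(full.aic - null.aic),
        "lower_aic": "full" if full.aic < null.aic else "null",
    }


def null_spec(spec: ModelSpec) -> ModelSpec:
    return ModelSpec(response=spec.response, fixed=(),
                     random_intercepts=spec.random_intercepts,
                     scope=spec.scope, zscale=spec.zscale)
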