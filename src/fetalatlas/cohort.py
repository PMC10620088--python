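"""Cohort-level and multi-site variability statistics.

Standardised site differences (SSD), one-way random-effects variance
components, two-sample Kolmogorov–Smirnov comparisons, White's Lagrange
multiplier heteroscedasticity test, Cohen's d effect sizes, and growth-curve
fits of the volumetric measures against gestational age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.interpolate import make_lsq_spline
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_white

__all__ = [
    "SSDTable", "VarianceComponents", "GrowthFit",
    "compute_ssd", "flag_ssd_outside_interval",
    "between_site_variance_fraction", "ks_two_sample", "white_lm_test",
    "cohens_d", "fit_growth_model",
]

#: the prespecified acceptability interval for SSD values, in pooled-s.d. units
SSD_INTERVAL = (-0.5, 0.5)


@dataclass
class SSDTable:
    """Per-site standardised site differences for one measure."""

    measure: str
    table: pd.DataFrame  # columns: site_id, n, ssd, within_interval

    @property
    def values(self) -> np.ndarray:
        return self.table["ssd"].to_numpy()

    @property
    def n_outside_interval(self) -> int:
        return int((~self.table["within_interval"]).sum())


def _ga_residualize(values: np.ndarray, ga: np.ndarray) -> np.ndarray:
    """Residuals of a measure on a quadratic gestational-age trend."""
    X = np.column_stack([np.ones_like(ga), ga, ga ** 2])
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    return values - X @ beta


def compute_ssd(table: pd.DataFrame, measure: str,
                ga_adjust: bool = False) -> SSDTable:
    """Standardised site difference per site.

    SSD = (site mean − pooled mean) / pooled sample s.d., where pooling runs
    over all sites and all gestational ages.  With ``ga_adjust`` the measure
    is first residualised against a quadratic gestational-age trend, covering
    the "adjusted for gestational age" reading of the definition.
    """
    if measure not in table.columns:
        raise KeyError(f"measure {measure!r} not in table")
    df = table.dropna(subset=[measure])
    values = df[measure].to_numpy(dtype=np.float64)
    if ga_adjust:
        values = _ga_residualize(values, df["ga_weeks"].to_numpy(np.float64))
    sites = df["site_id"].to_numpy()
    if len(np.unique(sites)) < 2:
        raise ValueError("need at least 2 sites")
    pooled_mean = values.mean()
    pooled_sd = values.std(ddof=1)
    if pooled_sd < 1e-300:
        raise ValueError("zero pooled standard deviation")
    rows = []
    for site in sorted(np.unique(sites)):
        v = values[sites == site]
        ssd = (v.mean() - pooled_mean) / pooled_sd
        rows.append({"site_id": site, "n": len(v), "ssd": ssd,
                     "within_interval":
                         SSD_INTERVAL[0] <= ssd <= SSD_INTERVAL[1]})
    return SSDTable(measure, pd.DataFrame(rows))


def flag_ssd_outside_interval(ssd_values,
                              bounds: tuple[float, float] = SSD_INTERVAL
                              ) -> tuple[np.ndarray, int]:
    """Flag SSD values outside the prespecified interval (bounds inclusive)."""
    v = np.asarray(ssd_values, dtype=np.float64)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite SSD values")
    outside = (v < bounds[0]) | (v > bounds[1])
    return outside, int(outside.sum())


@dataclass
class VarianceComponents:
    """One-way random-effects decomposition of a measure across sites."""

    between_site: float
    within_site: float
    clamped: bool  # True when the moment estimate of σ²_between was negative

    @property
    def between_fraction(self) -> float:
        total = self.between_site + self.within_site
        return self.between_site / total if total > 0 else 0.0


def between_site_variance_fraction(table: pd.DataFrame, measure: str,
                                   ga_adjust: bool = True
                                   ) -> VarianceComponents:
    """Between-site share of total variance by the ANOVA moment estimator.

    One-way random-effects model on (optionally GA-residualised) values:
    σ̂²_w = MSW, σ̂²_b = (MSB − MSW)/n₀ with the unbalanced-design
    n₀ = (N − Σnᵢ²/N)/(k − 1); a negative between-site estimate is clamped to
    zero and flagged.
    """
    df = table.dropna(subset=[measure])
    values = df[measure].to_numpy(dtype=np.float64)
    if ga_adjust:
        values = _ga_residualize(values, df["ga_weeks"].to_numpy(np.float64))
    sites = df["site_id"].to_numpy()
    uniq = np.unique(sites)
    if len(uniq) < 2:
        raise ValueError("need at least 2 sites")
    groups = [values[sites == s] for s in uniq]
    if any(len(g) < 2 for g in groups):
        raise ValueError("need at least 2 values per site")
    N, k = len(values), len(groups)
    grand = values.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    msb = ssb / (k - 1)
    msw = ssw / (N - k)
    n0 = (N - sum(len(g) ** 2 for g in groups) / N) / (k - 1)
    sigma_b = (msb - msw) / n0
    clamped = sigma_b < 0
    return VarianceComponents(max(sigma_b, 0.0), msw, clamped)


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test (asymptotic two-sided p)."""
    x, y = np.asarray(x, np.float64), np.asarray(y, np.float64)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty input sample")
    res = sps.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def white_lm_test(y, x) -> tuple[float, float]:
    """White's Lagrange multiplier test for heteroscedasticity of y on x.

    Regresses y on {1, x}; the auxiliary regression of squared residuals on
    {x, x²} gives the statistic n·R², χ² with 2 degrees of freedom.
    """
    y = np.asarray(y, np.float64)
    x = np.asarray(x, np.float64)
    if len(y) != len(x) or len(y) <= 5:
        raise ValueError("need matched samples with n > 5")
    if np.ptp(x) < 1e-300:
        raise ValueError("degenerate regressor")
    exog = sm.add_constant(x)
    resid = sm.OLS(y, exog).fit().resid
    if np.abs(resid).max() < 1e-12 * max(np.abs(y).max(), 1.0):
        return 0.0, 1.0  # perfect fit: nothing left to be heteroscedastic
    lm, lm_p, _, _ = het_white(resid, exog)
    return float(lm), float(lm_p)


def cohens_d(x, y) -> float:
    """Cohen's d: (mean x − mean y) / pooled standard deviation."""
    x, y = np.asarray(x, np.float64), np.asarray(y, np.float64)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 values per group")
    nx, ny = len(x), len(y)
    pooled = np.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1))
                     / (nx + ny - 2))
    if pooled < 1e-300:
        raise ValueError("zero pooled standard deviation")
    return float((x.mean() - y.mean()) / pooled)


@dataclass
class GrowthFit:
    """A fitted growth trajectory of one measure against gestational age."""

    family: str
    coefficients: np.ndarray | None
    predict: object                  # callable ga -> fitted mean
    quad_coef: float | None
    quad_coef_ci: tuple[float, float] | None
    f_quad_vs_linear: float | None
    p_quad_vs_linear: float | None
    prefers_quadratic: bool | None

    def monotonic_increasing(self, lo: float = 14.0, hi: float = 31.0,
                             n: int = 400) -> bool:
        ga = np.linspace(lo, hi, n)
        fit = self.predict(ga)
        return bool(np.all(np.diff(fit) > -1e-9 * max(np.ptp(fit), 1.0)))


def fit_growth_model(ga, y, family: str = "quadratic") -> GrowthFit:
    """Least-squares growth fit with a nested quadratic-vs-linear comparison.

    ``family`` ∈ {linear, quadratic, spline}; the spline is a least-squares
    cubic B-spline with interior knots at GA quantiles (falls back to the
    quadratic when there are too few distinct ages).  The F-comparison and
    the quadratic coefficient's 95% CI are reported for every family.
    """
    ga = np.asarray(ga, np.float64)
    y = np.asarray(y, np.float64)
    n_unique = len(np.unique(ga))
    if n_unique < 3:
        raise ValueError("need at least 3 distinct gestational ages")
    X1 = np.column_stack([np.ones_like(ga), ga])
    X2 = np.column_stack([np.ones_like(ga), ga, ga ** 2])
    fit2 = sm.OLS(y, X2).fit()
    fit1 = sm.OLS(y, X1).fit()
    n = len(y)
    sse1, sse2 = float(fit1.ssr), float(fit2.ssr)
    dof2 = n - 3
    if dof2 > 0 and sse2 > 1e-300 * max(float((y ** 2).sum()), 1.0):
        F = (sse1 - sse2) / (sse2 / dof2)
        p = float(sps.f.sf(F, 1, dof2))
    elif sse1 > sse2:            # exact quadratic data: infinite evidence
        F, p = np.inf, 0.0
    else:
        F, p = 0.0, 1.0
    ci = tuple(fit2.conf_int()[2]) if dof2 > 0 else (fit2.params[2],) * 2

    if family == "linear":
        coef = fit1.params
        predict = lambda g: coef[0] + coef[1] * np.asarray(g, np.float64)
    elif family == "quadratic":
        coef = fit2.params
        predict = lambda g: (coef[0] + coef[1] * np.asarray(g, np.float64)
                             + coef[2] * np.asarray(g, np.float64) ** 2)
    elif family == "spline":
        order = np.argsort(ga, kind="stable")
        gs, ys = ga[order], y[order]
        if n_unique >= 8:
            interior = np.quantile(np.unique(gs), [0.25, 0.5, 0.75])
            t = np.concatenate([[gs[0]] * 4, interior, [gs[-1]] * 4])
            # collapse duplicate abscissae to their means for stability
            gu, inv = np.unique(gs, return_inverse=True)
            yu = np.bincount(inv, ys) / np.bincount(inv)
            spl = make_lsq_spline(gu, yu, t, k=3)
            coef = np.asarray(spl.c)
            predict = lambda g: spl(np.clip(np.asarray(g, np.float64),
                                            gs[0], gs[-1]))
        else:
            coef = fit2.params
            predict = lambda g: (coef[0] + coef[1] * np.asarray(g, np.float64)
                                 + coef[2] * np.asarray(g, np.float64) ** 2)
            family = "quadratic"
    else:
        raise ValueError(f"unknown family {family!r}")
    return GrowthFit(family=family, coefficients=np.asarray(coef),
                     predict=predict, quad_coef=float(fit2.params[2]),
                     quad_coef_ci=(float(ci[0]), float(ci[1])),
                     f_quad_vs_linear=float(F), p_quad_vs_linear=float(p),
                     prefers_quadratic=bool(p < 0.05))
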