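"""Segmented-regression interrupted time series, single and controlled.

Model for an annual rate series y_t with a known intervention year T0
(time is coded t = year - T0, so the intercept is the level at T0):

    y_t = b0 + b1*t + b2*1[year >= corrector]            (pre-period trend,
        + b3*1[year >= T0]                                corrector level
        + b4*max(0, year - (T0 - 1))                      bump, level change,
        + b5*max(0, year - (shock - 1)) + e_t             trend change, optional
                                                          common-shock trend)

so b4 is the accumulating per-year change in trend from the intervention
onward.  The controlled (two-unit) variant stacks a treated and a control
series in one regression with treated-unit interactions on the level and
trend-change terms; those interaction coefficients are the effect estimates
with common shocks to both units differenced out.

Errors may be serially correlated at lag 1.  The default correction is
Prais-Winsten GLS with the AR(1) parameter estimated by REML profile
likelihood and Satterthwaite degrees of freedom for the confidence
intervals: residual-based rho estimates collapse toward zero in saturated
segmented designs (the trend terms absorb most of the serial correlation),
which REML avoids by accounting for the fitted regression.  The classic
iterative Cochrane-Orcutt scheme and plain OLS with Newey-West standard
errors are available as alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm
from statsmodels.stats.stattools import durbin_watson as _sm_dw

__all__ = [
    "ITSSpec", "ITSFit", "ControlledITSResult", "DesignInfo",
    "build_design", "fit_segmented", "controlled_comparison",
    "durbin_watson", "InsufficientDataError", "SingularDesignError",
    "ConvergenceError",
]


class InsufficientDataError(ValueError):
    pass


class SingularDesignError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class ITSSpec:
    """Configuration of the segmented model.

    corrector_year: level dummy from this year on, applied to every unit
        (default 1996, the UK oral-contraceptive "pill scare" bump).
    common_shock_year: optional extra trend-change term shared by all units
        (2008 in sensitivity mode).
    parallel_pre_trends: controlled models share one pre-intervention slope.
    phase_in_exclusion: years dropped as rows (phase-in of the policy).
    ar1_correction: correct for lag-1 serial correlation; the method is
        chosen by ``ar1_method``:
        "reml" (default) — rho by REML profile likelihood with
            Satterthwaite degrees of freedom for the CIs.  Residual-based
            rho estimates are severely attenuated in saturated segmented
            designs (the trend terms absorb most serial correlation), which
            REML avoids by accounting for the fitted regression.
        "co" — iterative Cochrane-Orcutt with Prais-Winsten first-row
            retention, rho from the lag-1 residual regression.
        When off, OLS with optional Newey-West (HAC, lag 1) standard errors.
    """

    intervention_year: int = 1999
    corrector_year: int | None = 1996
    common_shock_year: int | None = None
    parallel_pre_trends: bool = True
    phase_in_exclusion: frozenset[int] = frozenset()
    ar1_correction: bool = True
    ar1_method: str = "reml"
    hac: bool = False
    share_corrector: bool = True  # one pill-dummy coefficient across units

    def __post_init__(self) -> None:
        if (self.corrector_year is not None
                and self.corrector_year >= self.intervention_year):
            raise ValueError("corrector_year must precede intervention_year")
        if (self.common_shock_year is not None
                and self.common_shock_year <= self.intervention_year):
            raise ValueError("common_shock_year must follow intervention_year")
        if self.ar1_method not in ("reml", "co"):
            raise ValueError(f"unknown ar1_method: {self.ar1_method}")
        object.__setattr__(self, "phase_in_exclusion",
                           frozenset(self.phase_in_exclusion))


@dataclass
class DesignInfo:
    """Design matrix plus bookkeeping for AR blocks and naming."""

    X: np.ndarray
    names: list[str]
    years: np.ndarray          # calendar year per row
    unit_index: np.ndarray     # 0-based unit id per row (AR(1) runs within)
    outcome: np.ndarray | None = None


@dataclass
class ITSFit:
    coefficients: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    se: dict[str, float]
    rho: float
    dw: float
    acf1: float
    pacf1: float
    residuals: np.ndarray
    names: list[str] = field(default_factory=list)
    df_resid: int = 0
    n_iter: int = 0

    def coef(self, name: str) -> float:
        return self.coefficients[name]


@dataclass
class ControlledITSResult:
    level_diff: float
    level_ci95: tuple[float, float]
    trend_diff: float
    trend_ci95: tuple[float, float]
    counterfactual: pd.Series
    fit: ITSFit


# ---------------------------------------------------------------------------
# design construction

def _unit_columns(years: np.ndarray, spec: ITSSpec) -> tuple[np.ndarray, list[str]]:
    T0 = spec.intervention_year
    cols = [np.ones_like(years, dtype=float),
            (years - T0).astype(float)]
    names = ["intercept", "pre_trend"]
    if spec.corrector_year is not None:
        cols.append((years >= spec.corrector_year).astype(float))
        names.append("pill_level")
    cols.append((years >= T0).astype(float))
    names.append("level_change")
    cols.append(np.maximum(0.0, years - (T0 - 1)).astype(float))
    names.append("trend_change")
    if spec.common_shock_year is not None:
        cols.append(np.maximum(0.0, years - (spec.common_shock_year - 1))
                    .astype(float))
        names.append("shock_trend_change")
    return np.column_stack(cols), names


def build_design(years: Sequence[int], spec: ITSSpec,
                 treated_flag: Sequence[int] | None = None) -> DesignInfo:
    """Design matrix for a single series or a stacked treated/control pair.

    For the stacked case, pass one row per (unit, year) with ``treated_flag``
    1 for treated rows; interactions treated x level_change and
    treated x trend_change (and treated x pre_trend iff parallel pre-trends
    is off) are appended, plus a treated intercept.
    """
    years = np.asarray(list(years), dtype=int)
    if treated_flag is None:
        uidx = np.zeros(len(years), dtype=int)
    else:
        uidx = np.asarray(list(treated_flag), dtype=int)
        if uidx.shape != years.shape:
            raise ValueError("treated_flag length mismatch")

    keep = ~np.isin(years, list(spec.phase_in_exclusion))
    years, uidx = years[keep], uidx[keep]

    for u in np.unique(uidx):
        ys = np.sort(years[uidx == u])
        if (ys < spec.intervention_year).sum() < 3:
            raise InsufficientDataError(
                f"unit {u}: fewer than 3 pre-intervention points")
        span = np.arange(ys[0], ys[-1] + 1)
        expected = span[~np.isin(span, list(spec.phase_in_exclusion))]
        if not np.array_equal(ys, expected):
            raise InsufficientDataError(f"unit {u}: year gaps in series")
    if treated_flag is not None:
        y0 = np.sort(years[uidx == 0])
        y1 = np.sort(years[uidx == 1])
        if not np.array_equal(y0, y1):
            raise InsufficientDataError(
                "treated and control must cover identical years")

    X, names = _unit_columns(years, spec)
    if treated_flag is not None:
        tr = uidx.astype(float)
        add_cols, add_names = [tr], ["treated_intercept"]
        if not spec.parallel_pre_trends:
            add_cols.append(tr * X[:, names.index("pre_trend")])
            add_names.append("treated_x_pre_trend")
        if spec.corrector_year is not None and not spec.share_corrector:
            add_cols.append(tr * X[:, names.index("pill_level")])
            add_names.append("treated_x_pill_level")
        add_cols.append(tr * X[:, names.index("level_change")])
        add_names.append("treated_x_level_change")
        add_cols.append(tr * X[:, names.index("trend_change")])
        add_names.append("treated_x_trend_change")
        X = np.column_stack([X] + add_cols)
        names = names + add_names
    return DesignInfo(X=X, names=names, years=years, unit_index=uidx)


# ---------------------------------------------------------------------------
# diagnostics

def durbin_watson(residuals: Sequence[float]) -> float:
    """Durbin-Watson statistic sum((e_t - e_{t-1})^2) / sum(e_t^2) in [0, 4]."""
    e = np.asarray(residuals, dtype=float)
    if e.size < 3:
        raise ValueError("need at least 3 residuals")
    denom = float(np.sum(e * e))
    if denom == 0.0:
        raise ValueError("Durbin-Watson undefined for all-zero residuals")
    return float(_sm_dw(e))


def _lag1_stats(e: np.ndarray, unit_index: np.ndarray) -> tuple[float, float, float]:
    """(rho, acf1, pacf1) pooled over within-unit lag-1 pairs."""
    num = den = 0.0
    for u in np.unique(unit_index):
        eu = e[unit_index == u]
        num += float(eu[1:] @ eu[:-1])
        den += float(eu[:-1] @ eu[:-1])
    rho = num / den if den > 0 else 0.0
    tot = float(e @ e)
    acf1 = num / tot if tot > 0 else 0.0
    return rho, acf1, acf1  # pacf at lag 1 equals acf at lag 1


# ---------------------------------------------------------------------------
# fitting

def _pw_transform(Z: np.ndarray, unit_index: np.ndarray, rho: float) -> np.ndarray:
    """Prais-Winsten transform applied within each unit block.

    First row of each block scaled by sqrt(1 - rho^2) (retained, not
    dropped); subsequent rows are quasi-differenced z_t - rho z_{t-1}.
    """
    out = np.empty_like(Z, dtype=float)
    for u in np.unique(unit_index):
        m = unit_index == u
        B = Z[m]
        TB = np.empty_like(B, dtype=float)
        TB[0] = np.sqrt(1.0 - rho ** 2) * B[0]
        TB[1:] = B[1:] - rho * B[:-1]
        out[m] = TB
    return out


def _ols(X: np.ndarray, y: np.ndarray, hac: bool = False):
    model = sm.OLS(y, X)
    if hac:
        return model.fit(cov_type="HAC", cov_kwds={"maxlags": 1})
    return model.fit()


def _gls_at(X: np.ndarray, y: np.ndarray, uidx: np.ndarray, rho: float,
            ) -> tuple[np.ndarray, np.ndarray, float]:
    """(beta, (X*'X*)^-1, rss) of the Prais-Winsten-transformed fit."""
    Xs = _pw_transform(X, uidx, rho)
    ys = _pw_transform(y[:, None], uidx, rho)[:, 0]
    XtX = Xs.T @ Xs
    XtXinv = np.linalg.inv(XtX)
    beta = XtXinv @ (Xs.T @ ys)
    r = ys - Xs @ beta
    return beta, XtXinv, float(r @ r)


def _fit_reml(X: np.ndarray, y: np.ndarray, uidx: np.ndarray,
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """REML AR(1) fit: (beta, se, satterthwaite_df, rho).

    rho maximises the restricted likelihood (profiled over beta and sigma^2);
    per-coefficient degrees of freedom come from a Satterthwaite match using
    the observed REML information for (sigma^2, rho), so CIs reflect the
    uncertainty in the variance parameters, which dominates in series this
    short.
    """
    n, k = X.shape
    nb = len(np.unique(uidx))

    def negreml(rho: float) -> float:
        rho = float(np.clip(rho, -0.98, 0.98))
        _, XtXinv, rss = _gls_at(X, y, uidx, rho)
        sign, logdet_inv = np.linalg.slogdet(XtXinv)
        return (0.5 * (n - k) * np.log(max(rss, 1e-300))
                - 0.5 * nb * np.log(1.0 - rho ** 2) - 0.5 * logdet_inv)

    res = optimize.minimize_scalar(negreml, bounds=(-0.95, 0.95),
                                   method="bounded",
                                   options={"xatol": 1e-6})
    rho = float(res.x)
    beta, XtXinv, rss = _gls_at(X, y, uidx, rho)
    sig2 = rss / (n - k)
    cdiag = np.diag(XtXinv).copy()
    se = np.sqrt(sig2 * cdiag)
    df = np.full(k, float(n - k))
    if sig2 > 1e-12 * max(1.0, float(y @ y) / n):
        df = _satterthwaite_df(X, y, uidx, rho, sig2, cdiag, n, k, nb)
    return beta, se, df, rho


def _satterthwaite_df(X, y, uidx, rho, sig2, cdiag, n, k, nb) -> np.ndarray:
    """Per-coefficient df matching the variance of sig2*c_ii(rho) under the
    REML covariance of (sig2, rho); clipped to [3, n-k]."""
    h = 0.02
    _, XtXinv_p, _ = _gls_at(X, y, uidx, min(rho + h, 0.98))
    _, XtXinv_m, _ = _gls_at(X, y, uidx, max(rho - h, -0.98))
    dcd = (np.diag(XtXinv_p) - np.diag(XtXinv_m)) / (2 * h)

    def nll(th):
        s2, r = th
        if s2 <= 0 or abs(r) >= 0.99:
            return 1e12
        _, XtXinv_, rss_ = _gls_at(X, y, uidx, r)
        sign, logdet_inv = np.linalg.slogdet(XtXinv_)
        return 0.5 * ((n - k) * np.log(s2) + rss_ / s2
                      - nb * np.log(1 - r ** 2) - logdet_inv)

    th = np.array([sig2, rho])
    steps = np.array([max(1e-6, 0.05 * sig2), 0.02])
    H = np.empty((2, 2))
    for a in range(2):
        for b in range(2):
            e1 = np.zeros(2); e1[a] = steps[a]
            e2 = np.zeros(2); e2[b] = steps[b]
            H[a, b] = (nll(th + e1 + e2) - nll(th + e1 - e2)
                       - nll(th - e1 + e2) + nll(th - e1 - e2)
                       ) / (4 * steps[a] * steps[b])
    df = np.full(k, float(n - k))
    try:
        V = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return df
    g = sig2 * cdiag
    for i in range(k):
        grad = np.array([cdiag[i], sig2 * dcd[i]])
        var_g = float(grad @ V @ grad)
        if var_g > 0 and g[i] > 0:
            df[i] = float(np.clip(2.0 * g[i] ** 2 / var_g, 3.0, n - k))
    return df


def fit_segmented(design: DesignInfo, outcome: Sequence[float],
                  spec: ITSSpec, *, tol: float = 1e-6,
                  max_iter: int = 50) -> ITSFit:
    """Fit the segmented model, correcting for AR(1) errors per the spec.

    Residuals, rho and the Durbin-Watson/ACF/PACF diagnostics are always
    reported on the original (untransformed) scale so the user can judge
    whether a correction was warranted, mirroring the practice of applying
    it only when all three diagnostics agree.
    """
    X = design.X
    y = np.asarray(list(outcome), dtype=float)
    n, k = X.shape
    if y.shape[0] != n:
        raise ValueError("outcome length does not match design")
    if n <= k + 1:
        raise InsufficientDataError(f"n={n} too small for {k} coefficients")
    if np.linalg.matrix_rank(X) < k:
        raise SingularDesignError("design matrix is rank deficient")

    n_iter = 0
    dof_arr: np.ndarray
    if not spec.ar1_correction:
        res = _ols(X, y, hac=spec.hac)
        beta = np.asarray(res.params, dtype=float)
        se = np.asarray(res.bse, dtype=float)
        dof_arr = np.full(k, float(res.df_resid))
        rho_used = 0.0
    elif spec.ar1_method == "reml":
        beta, se, dof_arr, rho_used = _fit_reml(X, y, design.unit_index)
    else:  # iterative Cochrane-Orcutt / Prais-Winsten
        res = _ols(X, y)
        beta = np.asarray(res.params, dtype=float)
        rho = 0.0
        for n_iter in range(1, max_iter + 1):
            e = y - X @ beta
            rho_new, _, _ = _lag1_stats(e, design.unit_index)
            rho_new = float(np.clip(rho_new, -0.99, 0.99))
            if not np.isfinite(rho_new):
                raise ConvergenceError(
                    f"rho became non-finite at iteration {n_iter}")
            Xs = _pw_transform(X, design.unit_index, rho_new)
            ys = _pw_transform(y[:, None], design.unit_index, rho_new)[:, 0]
            res = _ols(Xs, ys)
            beta = np.asarray(res.params, dtype=float)
            if abs(rho_new - rho) < tol:
                rho = rho_new
                break
            rho = rho_new
        else:
            raise ConvergenceError(
                f"AR(1) iteration did not converge in {max_iter} steps "
                f"(last rho={rho:.6f})")
        rho_used = rho
        se = np.asarray(res.bse, dtype=float)
        dof_arr = np.full(k, float(res.df_resid))

    resid = y - X @ beta
    rho_hat, acf1, pacf1 = _lag1_stats(resid, design.unit_index)
    try:
        dw = durbin_watson(resid)
    except ValueError:
        dw = 2.0  # perfect fit: no autocorrelation evidence by construction

    tcrit = stats.t.ppf(0.975, dof_arr)
    names = design.names
    coeffs = dict(zip(names, beta.tolist()))
    ses = dict(zip(names, se.tolist()))
    ci = {nm: (b - tc * s, b + tc * s)
          for nm, b, s, tc in zip(names, beta, se, tcrit)}
    return ITSFit(coefficients=coeffs, ci95=ci, se=ses,
                  rho=rho_used if spec.ar1_correction else rho_hat,
                  dw=dw, acf1=acf1, pacf1=pacf1, residuals=resid,
                  names=list(names), df_resid=int(n - k), n_iter=n_iter)


def fit_single(series: pd.Series, spec: ITSSpec) -> ITSFit:
    """Single-unit before/after ITS on a year-indexed rate series."""
    years = np.asarray(series.index, dtype=int)
    design = build_design(years, spec)
    keep = ~np.isin(years, list(spec.phase_in_exclusion))
    return fit_segmented(design, np.asarray(series)[keep], spec)


def counterfactual_single(series: pd.Series, spec: ITSSpec,
                          fit: ITSFit) -> pd.Series:
    """No-intervention projection: fitted values with the intervention
    terms (level_change, trend_change, shock) zeroed."""
    years = np.asarray(series.index, dtype=int)
    design = build_design(years, spec)
    beta = np.array([fit.coefficients[nm] for nm in design.names])
    drop = {"level_change", "trend_change", "shock_trend_change"}
    beta = np.array([0.0 if nm in drop else b
                     for nm, b in zip(design.names, beta)])
    return pd.Series(design.X @ beta, index=design.years, name="counterfactual")


def controlled_comparison(treated: pd.Series, control: pd.Series,
                          spec: ITSSpec) -> ControlledITSResult:
    """Two-unit controlled ITS: the treated-over-control level and trend
    changes at the intervention, from one stacked regression.

    The counterfactual series is the model's prediction for the treated
    unit with the treated-specific intervention interactions removed —
    i.e. the treated pre-trend carrying only the changes the control unit
    experienced.
    """
    ty = np.asarray(treated.index, dtype=int)
    cy = np.asarray(control.index, dtype=int)
    if not np.array_equal(ty, cy):
        raise InsufficientDataError(
            "treated and control series must share the same years")
    years = np.concatenate([cy, ty])
    flags = np.concatenate([np.zeros(len(cy), int), np.ones(len(ty), int)])
    design = build_design(years, spec, treated_flag=flags)
    y_all = np.concatenate([np.asarray(control, float),
                            np.asarray(treated, float)])
    keep = ~np.isin(years, list(spec.phase_in_exclusion))
    fit = fit_segmented(design, y_all[keep], spec)

    level = fit.coefficients["treated_x_level_change"]
    trend = fit.coefficients["treated_x_trend_change"]

    # counterfactual on the treated unit's rows: base columns plus the
    # treated-specific pre-period terms, intervention interactions zeroed
    keep_t = ty[~np.isin(ty, list(spec.phase_in_exclusion))]
    Xb, base_names = _unit_columns(keep_t, spec)
    pred = Xb @ np.array([fit.coefficients[nm] for nm in base_names])
    pred = pred + fit.coefficients["treated_intercept"]
    if "treated_x_pre_trend" in fit.coefficients:
        pred = pred + (fit.coefficients["treated_x_pre_trend"]
                       * (keep_t - spec.intervention_year))
    if "treated_x_pill_level" in fit.coefficients:
        pred = pred + (fit.coefficients["treated_x_pill_level"]
                       * (keep_t >= spec.corrector_year))
    cf = pd.Series(pred, index=keep_t, name="counterfactual")
    return ControlledITSResult(
        level_diff=level, level_ci95=fit.ci95["treated_x_level_change"],
        trend_diff=trend, trend_ci95=fit.ci95["treated_x_trend_change"],
        counterfactual=cf, fit=fit)
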