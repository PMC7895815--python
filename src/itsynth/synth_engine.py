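"""Synthetic control construction for one treated unit and a donor pool.

The synthetic control is the convex combination of donor outcome series
that best matches the treated unit's pre-intervention predictors: donor
weights w live on the probability simplex and minimise the V-weighted
predictor discrepancy

    min_w  sum_k v_k (x1_k - X0_k . w)^2    s.t.  w >= 0,  sum w = 1,

where predictors are means of the outcome over contiguous groups of
pre-intervention years (optionally plus auxiliary covariates, z-scaled).
The predictor-importance weights v can be fixed equal or themselves
optimised so that the induced w*(v) minimises the pre-period outcome MSPE
(the standard nested formulation).  Because the pre-period is short
(<= 15 years), the grouping of years into predictor blocks is chosen by
exhaustive enumeration of all contiguous partitions, preferring the fewest
blocks among those within a tolerance band of the minimal MSPE.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .panel_io import AnalysisWindow, RatePanel, PanelIntegrityError

__all__ = [
    "PredictorSpec", "SynthWeights", "SynthFit", "GroupingSearchResult",
    "build_predictors", "solve_w", "optimize_v", "search_groupings",
    "fit_synth", "enumerate_partitions", "OptimizationError",
]


class OptimizationError(RuntimeError):
    pass


def enumerate_partitions(years: Sequence[int]) -> list[tuple[tuple[int, ...], ...]]:
    """All 2^(n-1) ordered partitions of consecutive years into contiguous
    blocks, from a single block to all singletons."""
    years = list(years)
    n = len(years)
    out = []
    for cuts in itertools.product([0, 1], repeat=n - 1):
        blocks, start = [], 0
        for i, c in enumerate(cuts, start=1):
            if c:
                blocks.append(tuple(years[start:i]))
                start = i
        blocks.append(tuple(years[start:]))
        out.append(tuple(blocks))
    return out


@dataclass(frozen=True)
class PredictorSpec:
    """Which predictors enter the weight fit.

    year_groups: ordered partition of the pre-period into contiguous blocks;
        each block contributes the block-mean outcome as one predictor row.
    covariates: names of auxiliary panel columns (z-scaled before entering).
    v_mode: "equal" or "optimized" predictor-importance weights.
    """

    year_groups: tuple[tuple[int, ...], ...]
    covariates: tuple[str, ...] = ()
    v_mode: str = "optimized"

    def __post_init__(self) -> None:
        flat = [y for g in self.year_groups for y in g]
        if not flat:
            raise ValueError("year_groups must be non-empty")
        if len(set(flat)) != len(flat):
            raise ValueError("year_groups blocks must be disjoint")
        if sorted(flat) != list(range(min(flat), max(flat) + 1)):
            raise ValueError("year_groups must cover the pre-period exactly")
        for g in self.year_groups:
            if not g:
                raise ValueError("empty year group")
            if list(g) != list(range(g[0], g[-1] + 1)):
                raise ValueError(f"non-contiguous year group: {g}")
        if self.v_mode not in ("equal", "optimized"):
            raise ValueError(f"unknown v_mode: {self.v_mode}")

    @classmethod
    def single_group(cls, window: AnalysisWindow, **kw) -> "PredictorSpec":
        return cls(year_groups=(tuple(window.pre_years),), **kw)

    @classmethod
    def yearly(cls, window: AnalysisWindow, **kw) -> "PredictorSpec":
        return cls(year_groups=tuple((y,) for y in window.pre_years), **kw)


@dataclass
class SynthWeights:
    w: dict[str, float]     # donor -> weight, on the simplex
    v: np.ndarray           # predictor importance, normalised

    def top_donor(self, tol: float = 1e-9) -> str:
        """Heaviest donor; weights within ``tol`` of the maximum count as
        tied and the alphabetically first tied donor wins."""
        best = max(self.w.values())
        return min(d for d, wt in self.w.items() if wt >= best - tol)


@dataclass
class SynthFit:
    weights: SynthWeights
    synthetic_series: pd.Series
    observed_series: pd.Series
    gaps: pd.Series
    mspe_pre: float
    mspe_post: float
    window: AnalysisWindow
    spec: PredictorSpec

    @property
    def prediction_error(self) -> float:
        """RMSE-style pre-period prediction error: sqrt(mspe_pre)."""
        return float(np.sqrt(self.mspe_pre))

    @property
    def mspe_ratio(self) -> float:
        return self.mspe_post / self.mspe_pre


def prediction_error(mspe: float) -> float:
    """Root-mean-squared prediction error from an MSPE."""
    if mspe < 0:
        raise ValueError("MSPE must be non-negative")
    return float(np.sqrt(mspe))


# ---------------------------------------------------------------------------
# predictors

def build_predictors(panel: RatePanel, spec: PredictorSpec, treated: str,
                     donors: Sequence[str], window: AnalysisWindow,
                     age_group: str = "U18",
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Predictor matrices: treated vector x1 (k,) and donor matrix X0 (k, J).

    Rows are year-group means of the outcome followed by any covariates;
    covariate rows are z-scaled across all units so the V-weighted objective
    is not dominated by scale.
    """
    donors = list(donors)
    units = [treated] + donors
    flat = sorted(y for g in spec.year_groups for y in g)
    wide = panel.wide(age_group, units, flat)  # raises on missing years
    rows = []
    for g in spec.year_groups:
        rows.append(wide.loc[list(g)].mean(axis=0).to_numpy())
    for cov in spec.covariates:
        vals = _covariate_means(panel, cov, units, flat)
        mu, sd = vals.mean(), vals.std(ddof=0)
        rows.append((vals - mu) / sd if sd > 0 else vals * 0.0)
    M = np.asarray(rows, dtype=float)
    return M[:, 0], M[:, 1:]


def _covariate_means(panel: RatePanel, col: str, units: Sequence[str],
                     years: Sequence[int]) -> np.ndarray:
    df = panel.data
    if col not in df.columns:
        raise PanelIntegrityError(f"covariate column not in panel: {col}")
    out = []
    for u in units:
        sub = df[(df["country"] == u) & (df["year"].isin(years))]
        vals = sub.groupby("year")[col].mean()
        missing = [y for y in years if y not in vals.index or pd.isna(vals[y])]
        if missing:
            raise PanelIntegrityError(
                f"covariate '{col}' missing for {u}, year(s) {missing}")
        out.append(float(vals.mean()))
    return np.asarray(out)


# ---------------------------------------------------------------------------
# weight solvers

def solve_w(treated_vec: np.ndarray, donor_mat: np.ndarray,
            v: np.ndarray | None = None) -> np.ndarray:
    """Donor weights minimising the V-weighted predictor discrepancy on the
    simplex, by a primal active-set method for the convex QP.

    Starting from the best single donor, the support is grown by adding the
    most KKT-violating excluded donor and shrunk whenever the
    equality-constrained solve turns a weight negative; at termination the
    KKT conditions hold to machine tolerance, so the solution is the exact
    global optimum.  Deterministic given inputs.
    """
    x1 = np.asarray(treated_vec, dtype=float).ravel()
    X0 = np.asarray(donor_mat, dtype=float)
    if X0.ndim != 2 or X0.shape[0] != x1.size:
        raise ValueError("donor matrix shape mismatch")
    k, J = X0.shape
    if J < 2:
        raise ValueError("need at least 2 donors")
    if v is None:
        v = np.full(k, 1.0 / k)
    v = np.asarray(v, dtype=float)
    if v.size != k or (v < 0).any():
        raise ValueError("invalid importance weights")
    sv = np.sqrt(v)
    A = X0 * sv[:, None]
    b = x1 * sv
    return _active_set_qp(A, b)


def _active_set_qp(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """min ||Aw - b||^2 s.t. w >= 0, sum w = 1, primal active set.

    The Hessian 2A'A is only positive semidefinite when there are fewer
    predictors than donors, so a tiny ridge is added for the direction
    solves (guaranteeing strict descent, hence finite termination) and the
    final support is re-solved without it.
    """
    J = A.shape[1]
    H = 2.0 * A.T @ A
    g0 = -2.0 * A.T @ b
    eps = 1e-10 * (np.trace(H) / J + 1.0)
    Hr = H + eps * np.eye(J)
    scale = float(np.abs(g0).max()) + 1.0

    w = np.zeros(J)
    w[int(np.argmin(np.sum((A - b[:, None]) ** 2, axis=0)))] = 1.0
    active = w == 0.0                      # working set: bound constraints

    for _ in range(200 * J):
        free = np.flatnonzero(~active)
        grad = Hr @ w + g0
        m = free.size
        KKT = np.zeros((m + 1, m + 1))
        KKT[:m, :m] = Hr[np.ix_(free, free)]
        KKT[:m, m] = 1.0
        KKT[m, :m] = 1.0
        rhs = np.concatenate([-grad[free], [0.0]])
        sol = np.linalg.solve(KKT, rhs)
        p = np.zeros(J)
        p[free] = sol[:m]
        # stationary if the step's predicted objective decrease is at noise
        # level (guards the near-perfect-fit regime where grad ~ eps)
        pred_dec = -(grad @ p + 0.5 * p @ (Hr @ p))
        if (np.abs(p).max() <= 1e-12 * (1.0 + np.abs(w).max())
                or pred_dec <= 1e-13 * (1.0 + float(b @ b))):
            # bound multipliers: lambda_j = grad_j - (common free gradient)
            lam = grad - float(np.mean(grad[free]))
            cand = np.flatnonzero(active)
            if cand.size == 0 or lam[cand].min() >= -1e-9 * scale:
                break
            active[cand[int(np.argmin(lam[cand]))]] = False
            continue
        shrink = np.flatnonzero((p < 0) & ~active)
        alpha = 1.0
        block = -1
        if shrink.size:
            ratios = -w[shrink] / p[shrink]
            i = int(np.argmin(ratios))
            if ratios[i] < alpha:
                alpha = float(max(ratios[i], 0.0))
                block = int(shrink[i])
        w = w + alpha * p
        w = np.clip(w, 0.0, None)
        if block >= 0:
            w[block] = 0.0
            active[block] = True
    else:
        raise OptimizationError("active-set QP failed to converge")

    w = np.clip(w, 0.0, None)
    w /= w.sum()
    # polish: exact solve (no ridge) on the final support
    support = np.flatnonzero(w > 1e-9)
    ws = _eq_qp_on_support(A, b, support, J)
    if ws is not None:
        f_old = float(np.sum((A @ w - b) ** 2))
        f_new = float(np.sum((A @ ws - b) ** 2))
        if f_new <= f_old + 1e-15:
            w = ws
    return w


def _eq_qp_solve(A: np.ndarray, b: np.ndarray,
                 support: Sequence[int]) -> np.ndarray:
    """Minimise ||A_S w_S - b|| s.t. sum w_S = 1 (weights may go negative)."""
    As = A[:, list(support)]
    m = As.shape[1]
    if m == 1:
        return np.ones(1)
    KKT = np.zeros((m + 1, m + 1))
    KKT[:m, :m] = 2.0 * As.T @ As
    KKT[:m, m] = 1.0
    KKT[m, :m] = 1.0
    rhs = np.concatenate([2.0 * As.T @ b, [1.0]])
    try:
        sol = np.linalg.solve(KKT, rhs)
    except np.linalg.LinAlgError:
        sol, *_ = np.linalg.lstsq(KKT, rhs, rcond=None)
    return sol[:m]


def _eq_qp_on_support(A: np.ndarray, b: np.ndarray,
                      support: np.ndarray, J: int) -> np.ndarray | None:
    """Minimise ||A_S w_S - b|| s.t. sum w_S = 1 via KKT; None if infeasible
    (any negative weight) or singular."""
    As = A[:, support]
    m = support.size
    H = 2.0 * As.T @ As
    g = -2.0 * As.T @ b
    KKT = np.zeros((m + 1, m + 1))
    KKT[:m, :m] = H
    KKT[:m, m] = 1.0
    KKT[m, :m] = 1.0
    rhs = np.concatenate([-g, [1.0]])
    try:
        sol = np.linalg.solve(KKT, rhs)
    except np.linalg.LinAlgError:
        sol, *_ = np.linalg.lstsq(KKT, rhs, rcond=None)
    ws = sol[:m]
    if (ws < -1e-10).any():
        return None
    full = np.zeros(J)
    full[support] = np.clip(ws, 0.0, None)
    s = full.sum()
    if not np.isfinite(s) or s <= 0:
        return None
    return full / s


def solve_w_exact(treated_vec: np.ndarray, donor_mat: np.ndarray,
                  v: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Global optimum by enumerating every support subset (exponential in
    the donor count; intended as an independent check on small pools)."""
    x1 = np.asarray(treated_vec, float).ravel()
    X0 = np.asarray(donor_mat, float)
    k, J = X0.shape
    if v is None:
        v = np.full(k, 1.0 / k)
    sv = np.sqrt(np.asarray(v, float))
    A = X0 * sv[:, None]
    b = x1 * sv
    best_w, best_f = None, np.inf
    for r in range(1, J + 1):
        for support in itertools.combinations(range(J), r):
            w = _eq_qp_on_support(A, b, np.asarray(support), J)
            if w is None:
                continue
            f = float(np.sum((A @ w - b) ** 2))
            if f < best_f - 1e-15:
                best_f, best_w = f, w
    if best_w is None:
        raise OptimizationError("no feasible support found")
    return best_w, best_f


# ---------------------------------------------------------------------------
# nested V optimisation

def _pre_mspe_of_w(w: np.ndarray, Y1_pre: np.ndarray,
                   Y0_pre: np.ndarray) -> float:
    g = Y1_pre - Y0_pre @ w
    return float(np.mean(g * g))


def optimize_v(treated_vec: np.ndarray, donor_mat: np.ndarray,
               Y1_pre: np.ndarray, Y0_pre: np.ndarray, *,
               n_starts: int = 5, seed: int = 0,
               ) -> tuple[np.ndarray, np.ndarray]:
    """Importance weights v minimising pre-period outcome MSPE of the
    induced w*(v); multi-start Nelder-Mead on a log-parametrisation of the
    simplex (equal-v start plus seeded random starts).  Returns (v, w)."""
    k = np.asarray(treated_vec).ravel().size
    if k == 1:
        v = np.ones(1)
        return v, solve_w(treated_vec, donor_mat, v)

    def v_of(theta: np.ndarray) -> np.ndarray:
        e = np.exp(theta - theta.max())
        return e / e.sum()

    def loss(theta: np.ndarray) -> float:
        v = v_of(theta)
        try:
            w = solve_w(treated_vec, donor_mat, v)
        except OptimizationError:
            return np.inf
        return _pre_mspe_of_w(w, Y1_pre, Y0_pre)

    rng = np.random.default_rng(seed)
    starts = [np.zeros(k)] + [rng.normal(scale=1.5, size=k)
                              for _ in range(n_starts - 1)]
    best_v, best_loss = None, np.inf
    for th0 in starts:
        res = optimize.minimize(loss, th0, method="Nelder-Mead",
                                options={"maxiter": 200 * k, "xatol": 1e-6,
                                         "fatol": 1e-12})
        if res.fun < best_loss:
            best_loss, best_v = res.fun, v_of(res.x)
    if best_v is None:
        raise OptimizationError("all V-optimisation starts failed")
    return best_v, solve_w(treated_vec, donor_mat, best_v)


# ---------------------------------------------------------------------------
# grouping search and full fit

@dataclass
class GroupingSearchResult:
    spec: PredictorSpec
    audit: pd.DataFrame = field(repr=False)  # partition, n_groups, mspe_pre


def search_groupings(panel: RatePanel, treated: str, donors: Sequence[str],
                     window: AnalysisWindow, *, age_group: str = "U18",
                     max_groups: int | None = None, tolerance: float = 0.05,
                     v_mode: str = "equal", seed: int = 0,
                     allow_large: bool = False) -> GroupingSearchResult:
    """Exhaustively enumerate contiguous pre-year partitions and pick one.

    Every partition is fitted (equal predictor weights by default; the
    selection concerns the grouping, and the final fit can still optimise V)
    and scored by pre-period outcome MSPE.  Among partitions within
    ``(1+tolerance)`` of the global minimum MSPE, the fewest-group partition
    wins; ties break to lower MSPE then to lexicographically earliest cut
    positions.  The full enumeration table is returned for audit.
    """
    pre = list(window.pre_years)
    n = len(pre)
    if n > 15 and not allow_large:
        raise ValueError(
            f"{n} pre-years means 2^{n-1} partitions; pass allow_large=True "
            f"to force the enumeration")
    wide = panel.wide(age_group, [treated] + list(donors), window.years)
    Y1_pre = wide.loc[pre, treated].to_numpy()
    Y0_pre = wide.loc[pre, list(donors)].to_numpy()
    rows = []
    for part in enumerate_partitions(pre):
        if max_groups is not None and len(part) > max_groups:
            continue
        x1, X0 = _group_means(wide, part, treated, donors)
        if v_mode == "optimized":
            _, w = optimize_v(x1, X0, Y1_pre, Y0_pre, seed=seed)
        else:
            w = solve_w(x1, X0)
        rows.append({"partition": part, "n_groups": len(part),
                     "mspe_pre": _pre_mspe_of_w(w, Y1_pre, Y0_pre)})
    audit = pd.DataFrame(rows)
    m_star = audit["mspe_pre"].min()
    # absolute epsilon keeps the degenerate perfect-fit case (every
    # partition at MSPE ~ 0) inside one tie band
    band = audit[audit["mspe_pre"] <= (1.0 + tolerance) * m_star + 1e-12]
    band = band.sort_values(
        by=["n_groups", "mspe_pre", "partition"],
        key=lambda s: s.map(_partition_key) if s.name == "partition" else s)
    chosen = band.iloc[0]["partition"]
    spec = PredictorSpec(year_groups=chosen, v_mode=v_mode)
    return GroupingSearchResult(spec=spec,
                                audit=audit.sort_values("mspe_pre")
                                .reset_index(drop=True))


def _partition_key(part: tuple[tuple[int, ...], ...]) -> tuple[int, ...]:
    return tuple(g[0] for g in part)


def _group_means(wide: pd.DataFrame, part, treated: str,
                 donors: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    arr = wide.to_numpy()
    yidx = {y: i for i, y in enumerate(wide.index)}
    cidx = {c: j for j, c in enumerate(wide.columns)}
    M = np.stack([arr[[yidx[y] for y in g]].mean(axis=0) for g in part])
    return (M[:, cidx[treated]],
            M[:, [cidx[d] for d in donors]])


def fit_synth(panel: RatePanel, treated: str, donors: Sequence[str],
              window: AnalysisWindow, spec: PredictorSpec, *,
              age_group: str = "U18", seed: int = 0,
              _wide: pd.DataFrame | None = None) -> SynthFit:
    """Fit the synthetic control and assemble series, gaps and MSPEs.

    The synthetic series applies the fitted donor weights to donor outcomes
    over the whole window — pre (fit quality) and post (counterfactual).
    ``_wide`` lets batch callers (placebo loops) reuse one extracted
    year x country rate matrix.
    """
    donors = list(donors)
    if treated in donors:
        raise ValueError("treated unit cannot be its own donor")
    if _wide is None:
        wide = panel.wide(age_group, [treated] + donors, window.years)
    else:
        wide = _wide[[treated] + donors]
    if spec.covariates:
        x1, X0 = build_predictors(panel, spec, treated, donors, window,
                                  age_group=age_group)
    else:
        x1, X0 = _group_means(wide, spec.year_groups, treated, donors)
    pre = list(window.pre_years)
    Y1_pre = wide.loc[pre, treated].to_numpy()
    Y0_pre = wide.loc[pre, donors].to_numpy()
    if spec.v_mode == "optimized" and x1.size > 1:
        v, w = optimize_v(x1, X0, Y1_pre, Y0_pre, seed=seed)
    else:
        v = np.full(x1.size, 1.0 / x1.size)
        w = solve_w(x1, X0, v)
    weights = SynthWeights(w=dict(zip(donors, w.tolist())), v=v)
    synth = pd.Series(wide[donors].to_numpy() @ w, index=wide.index,
                      name="synthetic")
    obs = wide[treated].rename("observed")
    gaps = (obs - synth).rename("gap")
    pre_mask = gaps.index < window.intervention_year
    mspe_pre = float(np.mean(gaps[pre_mask] ** 2))
    mspe_post = float(np.mean(gaps[~pre_mask] ** 2))
    return SynthFit(weights=weights, synthetic_series=synth,
                    observed_series=obs, gaps=gaps, mspe_pre=mspe_pre,
                    mspe_post=mspe_post, window=window, spec=spec)
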