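"""Simulated country-year rate panels with the structure the analyses assume.

Each unit's latent mean is a shared piecewise-linear secular trend (slope
changes at configurable knot years, emulating the gentle rise to the late
1990s, the post-1999 decline, and the extra steepening from 2008) plus a
unit-specific level offset; "UK-like" units get an additional level bump
from the contraceptive-scare year (1996).  The treated unit may carry an
intervention effect (level shift and/or accumulating trend change) from the
intervention year, and in mixture mode its latent mean is instead a stated
convex combination of donor latent means — which makes planted-weight
recovery by the synthetic control engine a well-posed exercise.  Noise is a
stationary AR(1) process per unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .panel_io import RatePanel

__all__ = ["SimConfig", "generate_panel", "inject_intervention",
           "default_units"]

#: treated + 15-donor roster mirroring a realistic high-income pool
DEFAULT_TREATED = "England and Wales"
DEFAULT_DONORS = (
    "Denmark", "Finland", "France", "Germany", "Iceland", "Italy",
    "Netherlands", "Norway", "Portugal", "Scotland", "Spain", "Sweden",
    "Switzerland", "USA", "New Zealand",
)


def default_units() -> tuple[str, tuple[str, ...]]:
    return DEFAULT_TREATED, DEFAULT_DONORS


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the panel generator.

    trend_knots: (year, slope_change) pairs; the latent slope starts at
        ``base_slope`` and each knot adds its slope change from that year
        on.  Defaults: +0.5/yr until 1998, then -2.0 at 1999 (net -1.5/yr),
        then an extra -1.0/yr from 2008.
    baseline_mean: latent rate at the first year for the average unit.
    offset_sd: spread of per-unit level offsets.
    slope_sd: spread of per-unit deviations from the common secular slope
        (rate/yr).  Default 0: all units share the trend exactly, the world
        the parallel-trends ITS design assumes.  Set positive to give donors
        heterogeneous declines, which makes planted mixture weights
        identifiable from the deterministic structure.
    pill_shock: level bump for uk_like units from pill_year on.
    intervention_effect: (level, trend/yr) applied to the treated unit from
        the intervention year; (0, 0) is the null world.
    mixture_weights: donor -> weight; when given, the treated series is this
        convex combination of the donors' realised series (their latent
        means plus their noise paths) plus the treated unit's own noise —
        the construction under which weight recovery by the synthetic
        control fit is well posed.  Intervention effects still apply on top.
    rho / noise_sd: AR(1) coefficient and innovation standard deviation,
        initialised at stationarity.
    """

    treated: str = DEFAULT_TREATED
    donors: tuple[str, ...] = DEFAULT_DONORS
    uk_like: tuple[str, ...] = (DEFAULT_TREATED, "Scotland")
    start_year: int = 1990
    end_year: int = 2016
    base_slope: float = 0.5
    trend_knots: tuple[tuple[int, float], ...] = ((1999, -2.0), (2008, -1.0))
    baseline_mean: float = 45.0
    offset_sd: float = 3.0
    slope_sd: float = 0.0
    pill_year: int = 1996
    pill_shock: float = 2.0
    intervention_year: int = 1999
    intervention_effect: tuple[float, float] = (0.0, 0.0)
    mixture_weights: Mapping[str, float] | None = None
    rho: float = 0.3
    noise_sd: float = 0.8
    age_group: str = "U18"
    population: int = 100_000
    emit_counts: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        years = [y for y, _ in self.trend_knots]
        if years != sorted(years) or len(set(years)) != len(years):
            raise ValueError("trend_knots must have strictly increasing years")
        if not abs(self.rho) < 1.0:
            raise ValueError("AR(1) coefficient must satisfy |rho| < 1")
        if self.start_year >= self.end_year:
            raise ValueError("start_year must precede end_year")
        if self.mixture_weights is not None:
            w = dict(self.mixture_weights)
            if not set(w) <= set(self.donors):
                raise ValueError("mixture weights name unknown donors")
            if any(v < 0 for v in w.values()) or abs(sum(w.values()) - 1) > 1e-9:
                raise ValueError("mixture weights must be convex")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)


def _secular_trend(cfg: SimConfig) -> np.ndarray:
    """Shared piecewise-linear component, zero at the first year."""
    years = cfg.years
    t = (years - cfg.start_year).astype(float)
    out = cfg.base_slope * t
    for knot_year, dslope in cfg.trend_knots:
        out = out + dslope * np.maximum(0.0, years - (knot_year - 1))
    return out


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    if sd == 0.0:
        return np.zeros(n)
    e = np.empty(n)
    e[0] = rng.normal(scale=sd / np.sqrt(1.0 - rho ** 2))
    innov = rng.normal(scale=sd, size=n - 1)
    for i in range(1, n):
        e[i] = rho * e[i - 1] + innov[i - 1]
    return e


def generate_panel(cfg: SimConfig) -> RatePanel:
    """Deterministic-in-seed panel of rates (and optionally counts).

    Rates that would go negative are truncated at zero with a warning; the
    default parameters keep that probability negligible.
    """
    rng = np.random.default_rng(cfg.seed)
    years = cfg.years
    trend = _secular_trend(cfg)
    units = [cfg.treated] + list(cfg.donors)
    offsets = {u: rng.normal(scale=cfg.offset_sd) for u in units}
    slopes = {u: rng.normal(scale=cfg.slope_sd) if cfg.slope_sd else 0.0
              for u in units}
    t_idx = (years - cfg.start_year).astype(float)

    def unit_latent(u: str) -> np.ndarray:
        mu = cfg.baseline_mean + offsets[u] + trend + slopes[u] * t_idx
        if u in cfg.uk_like:
            mu = mu + cfg.pill_shock * (years >= cfg.pill_year)
        return mu

    latent: dict[str, np.ndarray] = {u: unit_latent(u) for u in cfg.donors}
    if cfg.mixture_weights is None:
        latent[cfg.treated] = unit_latent(cfg.treated)

    # one noise path per unit, in a fixed (unit-ordered) draw sequence so
    # the panel is reproducible from the seed alone
    noise = {u: _ar1(rng, len(years), cfg.rho, cfg.noise_sd) for u in units}
    realised = {u: latent[u] + noise[u] for u in cfg.donors}
    if cfg.mixture_weights is not None:
        w = dict(cfg.mixture_weights)
        treated_series = (np.sum([wt * realised[d] for d, wt in w.items()],
                                 axis=0) + noise[cfg.treated])
    else:
        treated_series = latent[cfg.treated] + noise[cfg.treated]
    lvl, trd = cfg.intervention_effect
    post = years >= cfg.intervention_year
    treated_series = treated_series + post * (
        lvl + trd * (years - cfg.intervention_year + 1))
    realised[cfg.treated] = treated_series

    rows = []
    truncated = 0
    for u in units:
        rate = realised[u]
        truncated += int((rate < 0).sum())
        rate = np.maximum(rate, 0.0)
        for y, r in zip(years, rate):
            row = {"country": u, "year": int(y), "age_group": cfg.age_group,
                   "rate": float(r)}
            if cfg.emit_counts:
                # invert the rate against a fixed population for I/O tests
                row["population"] = float(cfg.population)
                row["births"] = r * cfg.population / 1000.0
                row["abortions"] = 0.0
            rows.append(row)
    if truncated:
        warnings.warn(f"{truncated} simulated rates truncated at 0",
                      stacklevel=2)
    return RatePanel(pd.DataFrame(rows))


def inject_intervention(panel: RatePanel, treated: str, level: float,
                        trend: float, from_year: int) -> RatePanel:
    """Shift the treated unit's rates by ``level + trend*(year-from_year+1)``
    for every year >= from_year; all other rows untouched."""
    df = panel.data.copy()
    if treated not in df["country"].unique():
        raise KeyError(f"unknown unit: {treated}")
    m = (df["country"] == treated) & (df["year"] >= from_year)
    shift = level + trend * (df.loc[m, "year"] - from_year + 1)
    df.loc[m, "rate"] = df.loc[m, "rate"] + shift
    return RatePanel(df)
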