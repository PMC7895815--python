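"""Placebo-based robustness checks and permutation inference for the
synthetic control fit.

The logic of the tests: if the policy had an effect, the treated unit's
post-intervention divergence from its synthetic control should be unusual
relative to (a) the same procedure applied to each unexposed donor as if it
had been treated (placebo-in-space), and (b) fictitious earlier intervention
dates (placebo-in-time).  The summary statistic is the post/pre-MSPE ratio;
its permutation p-value is the treated unit's descending rank among all
units divided by the number of units (treated included), with ties counted
as outranking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel_io import AnalysisWindow, RatePanel
from .synth_engine import (PredictorSpec, SynthFit, fit_synth,
                           search_groupings)

__all__ = [
    "PlaceboSet", "RatioTest", "placebo_in_space", "filter_placebos",
    "mspe_ratio_test", "rank_p_value", "time_placebo", "leave_one_out",
]


@dataclass
class PlaceboSet:
    """The treated unit's fit plus one fit per donor treated-in-turn.

    For each placebo the donor pool is all remaining units with the real
    treated unit excluded, so no placebo can borrow the exposed series.
    """

    treated: str
    fits: dict[str, SynthFit]          # unit -> fit (treated included)
    protocol: str = "full"

    @property
    def units(self) -> list[str]:
        return list(self.fits)


@dataclass
class RatioTest:
    ratios: dict[str, float]           # unit -> mspe_post / mspe_pre
    treated: str
    treated_rank: int                  # descending rank counting itself
    p: float                           # treated_rank / n_units

    @property
    def p_display(self) -> float:
        return round(self.p, 2)


def _protocol_spec(panel: RatePanel, unit: str, pool: Sequence[str],
                   window: AnalysisWindow, protocol: str,
                   base_spec: PredictorSpec | None, age_group: str,
                   seed: int) -> PredictorSpec:
    if protocol == "fixed":
        if base_spec is None:
            raise ValueError("fixed protocol needs a base PredictorSpec")
        return base_spec
    if protocol == "full":
        res = search_groupings(panel, unit, pool, window,
                               age_group=age_group, seed=seed,
                               v_mode=base_spec.v_mode if base_spec else "equal")
        return res.spec
    raise ValueError(f"unknown protocol: {protocol}")


def placebo_in_space(panel: RatePanel, treated: str, donors: Sequence[str],
                     window: AnalysisWindow, *,
                     spec: PredictorSpec | None = None,
                     protocol: str = "full", age_group: str = "U18",
                     seed: int = 0) -> PlaceboSet:
    """Refit the full SC procedure treating every unit as exposed in turn.

    protocol="full" re-runs the grouping search for each unit (the
    methodologically symmetric choice); protocol="fixed" reuses ``spec``
    for everyone, which is much cheaper.
    """
    donors = list(donors)
    units = [treated] + donors
    if len(units) < 3:
        raise ValueError("need at least 3 units for placebo analysis")
    wide = panel.wide(age_group, units, window.years)
    fits: dict[str, SynthFit] = {}
    for unit in units:
        pool = [u for u in donors if u != unit]  # treated never a donor
        sp = _protocol_spec(panel, unit, pool, window, protocol, spec,
                            age_group, seed)
        fits[unit] = fit_synth(panel, unit, pool, window, sp,
                               age_group=age_group, seed=seed, _wide=wide)
    return PlaceboSet(treated=treated, fits=fits, protocol=protocol)


def filter_placebos(pset: PlaceboSet, multiple: float = 5.0) -> PlaceboSet:
    """Drop placebos whose pre-period fit is worse than ``multiple`` times
    the treated unit's pre-MSPE; the treated unit is always retained.
    Idempotent by construction."""
    base = pset.fits[pset.treated].mspe_pre
    kept = {u: f for u, f in pset.fits.items()
            if u == pset.treated or f.mspe_pre <= multiple * base}
    return PlaceboSet(treated=pset.treated, fits=kept,
                      protocol=pset.protocol)


def rank_p_value(ratios: Mapping[str, float], treated: str,
                 ) -> tuple[int, float]:
    """Descending rank of the treated unit (counting itself, ties count as
    outranking) and the permutation p-value rank / n_units."""
    if treated not in ratios:
        raise KeyError(f"treated unit {treated!r} not among ratios")
    r_t = ratios[treated]
    rank = sum(1 for r in ratios.values() if r >= r_t)
    return rank, rank / len(ratios)


def mspe_ratio_test(pset: PlaceboSet) -> RatioTest:
    """Post/pre-MSPE ratio for every unit and the treated unit's
    permutation p-value."""
    ratios: dict[str, float] = {}
    for unit, f in pset.fits.items():
        if f.mspe_pre == 0.0:
            raise ZeroDivisionError(
                f"pre-period MSPE is zero for unit {unit!r}; ratio undefined")
        ratios[unit] = f.mspe_post / f.mspe_pre
    rank, p = rank_p_value(ratios, pset.treated)
    return RatioTest(ratios=ratios, treated=pset.treated,
                     treated_rank=rank, p=p)


def time_placebo(panel: RatePanel, treated: str, donors: Sequence[str],
                 window: AnalysisWindow, *,
                 dummy_years: Sequence[int] = (1995, 1996, 1997, 1998),
                 spec: PredictorSpec | None = None, protocol: str = "full",
                 age_group: str = "U18", seed: int = 0,
                 ) -> dict[int, SynthFit]:
    """Re-run the SC protocol with fictitious intervention dates.

    For dummy year d the pre-period ends at d-1 and the fit follows exactly
    the same code path as the main analysis, so a dummy at the true
    intervention year reproduces the main fit bit-for-bit.
    """
    out: dict[int, SynthFit] = {}
    for d in dummy_years:
        win = AnalysisWindow(pre_start=window.pre_start, intervention_year=d,
                             post_end=window.post_end)
        if len(win.pre_years) < 3:
            raise ValueError(
                f"dummy year {d}: fewer than 3 pre-dummy observations")
        if protocol == "full":
            sp = search_groupings(
                panel, treated, donors, win, age_group=age_group, seed=seed,
                v_mode=spec.v_mode if spec else "equal").spec
        else:
            if spec is None:
                raise ValueError("fixed protocol needs a base PredictorSpec")
            groups = tuple(tuple(y for y in g if y < d)
                           for g in spec.year_groups)
            groups = tuple(g for g in groups if g)
            sp = PredictorSpec(year_groups=groups,
                               covariates=spec.covariates, v_mode=spec.v_mode)
        out[d] = fit_synth(panel, treated, donors, win, sp,
                           age_group=age_group, seed=seed)
    return out


def leave_one_out(panel: RatePanel, treated: str, donors: Sequence[str],
                  window: AnalysisWindow, spec: PredictorSpec, *,
                  max_iter: int | None = None, age_group: str = "U18",
                  seed: int = 0) -> pd.DataFrame:
    """Iteratively drop the top-weighted donor and refit.

    The PredictorSpec stays fixed across iterations so that changes are
    attributable to donor removal alone.  Weight ties break alphabetically.
    Stops when 2 donors remain or after ``max_iter`` removals.  Returns the
    iteration table (dropped unit, remaining pool size, new weights,
    mspe_pre, mspe_post).
    """
    pool = list(donors)
    if len(pool) < 3:
        raise ValueError("need at least 3 donors for leave-one-out")
    rows = []
    fit = fit_synth(panel, treated, pool, window, spec,
                    age_group=age_group, seed=seed)
    rows.append({"iteration": 0, "dropped": None, "n_donors": len(pool),
                 "weights": dict(fit.weights.w), "mspe_pre": fit.mspe_pre,
                 "mspe_post": fit.mspe_post})
    it = 0
    while len(pool) > 2 and (max_iter is None or it < max_iter):
        drop = fit.weights.top_donor()
        pool = [d for d in pool if d != drop]
        fit = fit_synth(panel, treated, pool, window, spec,
                        age_group=age_group, seed=seed)
        it += 1
        rows.append({"iteration": it, "dropped": drop, "n_donors": len(pool),
                     "weights": dict(fit.weights.w),
                     "mspe_pre": fit.mspe_pre, "mspe_post": fit.mspe_post})
    return pd.DataFrame(rows)
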