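import itertools

import numpy as np
import pytest

from itsynth import (AnalysisWindow, PredictorSpec, SimConfig,
                     build_predictors, fit_synth, generate_panel, optimize_v,
                     search_groupings, solve_w)
from itsynth.panel_io import PanelIntegrityError
from itsynth.synth_engine import (enumerate_partitions, prediction_error,
                                  solve_w_exact, _group_means)


def simplex_grid(J, step):
    """All weight vectors on the J-simplex with coordinates multiple of
    step (independent oracle enumeration)."""
    n = round(1 / step)
    for comp in itertools.combinations(range(n + J - 1), J - 1):
        parts = np.diff([-1, *comp, n + J - 1]) - 1
        yield parts * step


class TestEnumeratePartitions:
    def test_counts_are_powers_of_two(self):
        assert len(enumerate_partitions(range(1990, 1999))) == 256
        assert len(enumerate_partitions([1, 2, 3])) == 4

    def test_blocks_cover_and_stay_contiguous(self):
        for part in enumerate_partitions(range(1990, 1995)):
            flat = [y for g in part for y in g]
            assert flat == list(range(1990, 1995))
            for g in part:
                assert list(g) == list(range(g[0], g[-1] + 1))


class TestPredictorSpec:
    def test_rejects_non_contiguous_block(self):
        with pytest.raises(ValueError):
            PredictorSpec(year_groups=((1990, 1992),))

    def test_rejects_gap_between_blocks(self):
        with pytest.raises(ValueError):
            PredictorSpec(year_groups=((1990,), (1992,)))


class TestBuildPredictors:
    def test_single_group_is_pre_period_mean(self, null_panel, window):
        spec = PredictorSpec.single_group(window)
        treated = "England and Wales"
        donors = [c for c in null_panel.countries if c != treated]
        x1, X0 = build_predictors(null_panel, spec, treated, donors, window)
        assert x1.shape == (1,)
        assert X0.shape == (1, 15)
        wide = null_panel.wide("U18", [treated] + donors, window.pre_years)
        assert x1[0] == pytest.approx(wide[treated].mean())
        assert X0[0, 0] == pytest.approx(wide[donors[0]].mean())

    def test_four_groups_make_four_rows(self, null_panel, window):
        spec = PredictorSpec(year_groups=(
            tuple(range(1990, 1994)), (1994,), (1995,),
            tuple(range(1996, 1999))))
        treated = "England and Wales"
        donors = [c for c in null_panel.countries if c != treated]
        x1, X0 = build_predictors(null_panel, spec, treated, donors, window)
        assert x1.shape == (4,) and X0.shape == (4, 15)

    def test_constant_series_gives_constant_means(self, tiny_panel):
        win = AnalysisWindow(1990, 1999, 2013)
        spec = PredictorSpec(year_groups=((1990, 1991), (1992,),
                                          tuple(range(1993, 1999))))
        x1, X0 = build_predictors(tiny_panel, spec, "C", ["A", "B"], win,
                                  age_group="U18")
        # C is nearly linear; its block means follow the trend, sanity only
        assert x1.shape == (3,)

    def test_missing_year_names_unit(self, null_panel, window):
        df = null_panel.data
        df = df[~((df.country == "France") & (df.year == 1994))]
        from itsynth import RatePanel
        broken = RatePanel(df)
        with pytest.raises(PanelIntegrityError):
            build_predictors(broken, PredictorSpec.single_group(window),
                             "England and Wales",
                             [c for c in broken.countries
                              if c != "England and Wales"], window)


class TestSolveW:
    def test_exact_match_puts_full_weight_on_clone(self):
        rng = np.random.default_rng(0)
        X0 = rng.normal(size=(4, 6))
        w = solve_w(X0[:, 2], X0)
        assert w[2] == pytest.approx(1.0, abs=1e-8)

    def test_midpoint_of_two_donors_split_evenly(self):
        X0 = np.array([[0.0, 2.0], [1.0, 3.0], [5.0, 1.0]])
        x1 = X0.mean(axis=1)
        w = solve_w(x1, X0)
        assert np.allclose(w, [0.5, 0.5], atol=1e-8)

    def test_objective_matches_exact_kkt_oracle(self):
        # active-set solution vs exhaustive support enumeration
        rng = np.random.default_rng(1)
        for _ in range(20):
            X0 = rng.normal(size=(4, 5))
            x1 = X0 @ rng.dirichlet(np.ones(5)) + rng.normal(scale=0.3,
                                                             size=4)
            w = solve_w(x1, X0)
            _, f_star = solve_w_exact(x1, X0)
            A, b = X0 / 2.0, x1 / 2.0   # v = 1/4 per predictor
            f = float(np.sum((A @ w - b) ** 2))
            assert f <= f_star + 1e-6

    def test_objective_never_above_any_grid_point(self):
        rng = np.random.default_rng(2)
        X0 = rng.normal(size=(4, 5))
        x1 = X0 @ rng.dirichlet(np.ones(5)) + rng.normal(scale=0.3, size=4)
        w = solve_w(x1, X0)
        f = float(np.mean((X0 @ w - x1) ** 2))
        for g in simplex_grid(5, 0.05):
            assert f <= float(np.mean((X0 @ g - x1) ** 2)) + 1e-9

    def test_weights_on_simplex(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            X0 = rng.normal(size=(3, 8))
            x1 = rng.normal(size=3)
            w = solve_w(x1, X0)
            assert w.sum() == pytest.approx(1.0, abs=1e-8)
            assert (w >= -1e-10).all()

    def test_donor_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        X0 = rng.normal(size=(4, 6))
        x1 = X0 @ rng.dirichlet(np.ones(6))
        w = solve_w(x1, X0)
        perm = rng.permutation(6)
        w_perm = solve_w(x1, X0[:, perm])
        assert np.allclose(w[perm], w_perm, atol=1e-7)

    def test_superset_donor_pool_never_worse(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            X0 = rng.normal(size=(4, 6))
            x1 = rng.normal(size=4)
            f_small = np.sum((X0[:, :4] @ solve_w(x1, X0[:, :4]) - x1) ** 2)
            f_big = np.sum((X0 @ solve_w(x1, X0) - x1) ** 2)
            assert f_big <= f_small + 1e-9


class TestOptimizeV:
    def test_single_predictor_forces_unit_v(self):
        rng = np.random.default_rng(6)
        X0 = rng.normal(size=(1, 4))
        x1 = np.array([X0[0].mean()])
        v, w = optimize_v(x1, X0, np.ones(5), rng.normal(size=(5, 4)))
        assert v == pytest.approx([1.0])

    def test_optimized_v_no_worse_than_equal_v(self, null_panel, window):
        treated = "England and Wales"
        donors = [c for c in null_panel.countries if c != treated]
        wide = null_panel.wide("U18", [treated] + donors, window.pre_years)
        spec = PredictorSpec(year_groups=((1990, 1991, 1992, 1993),
                                          tuple(range(1994, 1999))))
        x1, X0 = _group_means(wide, spec.year_groups, treated, donors)
        Y1 = wide[treated].to_numpy()
        Y0 = wide[donors].to_numpy()
        v, w_opt = optimize_v(x1, X0, Y1, Y0, seed=0)
        w_eq = solve_w(x1, X0)
        mspe = lambda w: float(np.mean((Y1 - Y0 @ w) ** 2))
        assert mspe(w_opt) <= mspe(w_eq) + 1e-12
        assert v.sum() == pytest.approx(1.0)


class TestSearchGroupings:
    def test_enumerates_256_partitions_of_nine_years(self, null_panel,
                                                     window):
        treated = "England and Wales"
        donors = [c for c in null_panel.countries if c != treated]
        res = search_groupings(null_panel, treated, donors, window)
        assert len(res.audit) == 256

    def test_reproducible_treated_selects_single_group(self, tiny_panel):
        # T is an exact donor mixture: every partition fits perfectly, so
        # the fewest-group partition (one block) must win the tie
        win = AnalysisWindow(1990, 1999, 2013)
        res = search_groupings(tiny_panel, "T", ["A", "B", "C"], win)
        assert res.spec.year_groups == (tuple(range(1990, 1999)),)

    def test_matches_brute_force_re_enumeration(self, null_panel, window):
        treated = "England and Wales"
        donors = [c for c in null_panel.countries if c != treated]
        res = search_groupings(null_panel, treated, donors, window,
                               tolerance=0.05)
        # independent re-enumeration
        wide = null_panel.wide("U18", [treated] + donors, window.years)
        pre = list(window.pre_years)
        Y1 = wide.loc[pre, treated].to_numpy()
        Y0 = wide.loc[pre, donors].to_numpy()
        rows = []
        for part in enumerate_partitions(pre):
            x1, X0 = _group_means(wide, part, treated, donors)
            w = solve_w(x1, X0)
            rows.append((part, len(part), float(np.mean((Y1 - Y0 @ w) ** 2))))
        m_star = min(r[2] for r in rows)
        band = [r for r in rows if r[2] <= 1.05 * m_star]
        band.sort(key=lambda r: (r[1], r[2], tuple(g[0] for g in r[0])))
        assert res.spec.year_groups == band[0][0]

    def test_refuses_oversized_pre_period(self, null_panel):
        treated = "England and Wales"
        donors = [c for c in null_panel.countries if c != treated]
        win = AnalysisWindow(1980, 2000, 2013)
        with pytest.raises(ValueError, match="partitions"):
            search_groupings(null_panel, treated, donors, win)


class TestFitSynth:
    def test_cloned_treated_gives_zero_gaps(self, tiny_panel):
        win = AnalysisWindow(1990, 1999, 2013)
        spec = PredictorSpec.yearly(win, v_mode="equal")
        fit = fit_synth(tiny_panel, "T", ["A", "B", "C"], win, spec)
        assert np.abs(fit.gaps).max() < 1e-8
        assert fit.mspe_pre == pytest.approx(0.0, abs=1e-16)
        assert fit.mspe_post == pytest.approx(0.0, abs=1e-16)
        assert fit.weights.w["A"] == pytest.approx(0.6, abs=1e-6)
        assert fit.weights.w["B"] == pytest.approx(0.4, abs=1e-6)

    def test_mspe_consistent_with_gap_series(self, null_panel, window):
        treated = "England and Wales"
        donors = [c for c in null_panel.countries if c != treated]
        spec = PredictorSpec.yearly(window, v_mode="equal")
        fit = fit_synth(null_panel, treated, donors, window, spec)
        pre = fit.gaps[fit.gaps.index < window.intervention_year]
        post = fit.gaps[fit.gaps.index >= window.intervention_year]
        assert fit.mspe_pre == pytest.approx(float(np.mean(pre ** 2)),
                                             abs=1e-10)
        assert fit.mspe_post == pytest.approx(float(np.mean(post ** 2)),
                                              abs=1e-10)

    def test_synthetic_series_invariant_to_donor_order(self, null_panel,
                                                       window):
        treated = "England and Wales"
        donors = [c for c in null_panel.countries if c != treated]
        spec = PredictorSpec.yearly(window, v_mode="equal")
        a = fit_synth(null_panel, treated, donors, window, spec)
        b = fit_synth(null_panel, treated, donors[::-1], window, spec)
        assert np.allclose(a.synthetic_series, b.synthetic_series, atol=1e-7)

    def test_level_effect_recovered_in_post_gap(self):
        win = AnalysisWindow(1990, 1999, 2013)
        donors = ("Scotland", "Portugal", "France", "Sweden")
        gaps = []
        for s in range(30):
            cfg = SimConfig(seed=s, donors=donors,
                            mixture_weights={"Scotland": 0.6,
                                             "Portugal": 0.4},
                            noise_sd=0.05, rho=0.3, slope_sd=0.5,
                            end_year=2013, intervention_effect=(-3.0, 0.0))
            p = generate_panel(cfg)
            fit = fit_synth(p, cfg.treated, donors, win,
                            PredictorSpec.yearly(win, v_mode="equal"))
            gaps.append(fit.gaps[fit.gaps.index >= 1999].mean())
        assert np.mean(gaps) == pytest.approx(-3.0, abs=0.3)


def test_prediction_error_is_rmse_of_mspe():
    assert prediction_error(0.09) == pytest.approx(0.3)
    with pytest.raises(ValueError):
        prediction_error(-1.0)
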