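import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stiffkmc import (
    CostModel,
    CostPoint,
    DownscaleConfig,
    ErrorModel,
    ErrorPoint,
    choose_window,
    compute_tss,
    detect_df_max,
    evaluate_acceptance,
    fit_cost_model,
    fit_error_model,
    initialize_engine,
    iat_error_norm,
    make_cost_error_points,
    make_toy_network,
    minimize_objective,
    ordering_check,
    qe_check,
    run_with_downscaling,
)

CFG = DownscaleConfig()


class TestQECheck:
    @pytest.mark.parametrize("nf,nr,expected", [
        (100, 100, True),    # perfectly balanced
        (105, 100, True),    # imbalance 0.0244 <= 0.05
        (120, 100, False),   # imbalance 0.0909 > 0.05
        (0, 0, False),       # unsampled pair fails
        (10, 0, False),
    ])
    def test_balance_predicate(self, nf, nr, expected):
        assert qe_check(nf, nr, 0.05) is expected

    @given(nf=st.integers(0, 10**6), nr=st.integers(0, 10**6))
    @settings(max_examples=200, deadline=None)
    def test_symmetric_in_forward_reverse(self, nf, nr):
        assert qe_check(nf, nr, 0.05) == qe_check(nr, nf, 0.05)


class TestOrderingAndTSS:
    def test_separated_frequencies_pass(self):
        freq = {1: 1e5, 2: 1e4, 3: 1e2, 4: 10.0}
        assert ordering_check(freq, {1, 2}, {3, 4})

    def test_slow_faster_than_fast_fails(self):
        freq = {1: 1e5, 2: 50.0, 3: 1e2}
        assert not ordering_check(freq, {1, 2}, {3})

    def test_all_equal_fails(self):
        freq = {1: 7.0, 2: 7.0, 3: 7.0}
        assert not ordering_check(freq, {1, 2}, {3})

    def test_tss_log_ratio(self):
        freq = {1: 1e5, 2: 1e2}
        assert compute_tss(freq, {1}, {2}) == pytest.approx(3.0)

    def test_tss_equal_frequencies_zero(self):
        freq = {1: 10.0, 2: 10.0}
        assert compute_tss(freq, {1}, {2}) == pytest.approx(0.0)

    def test_tss_unsampled_slow_is_infinite(self):
        freq = {1: 1e5, 2: 0.0}
        assert compute_tss(freq, {1}, {2}) == math.inf


class TestDetectDfMax:
    @staticmethod
    def _points(df_grid, costs):
        return [CostPoint(df=float(d), c=float(c))
                for d, c in zip(df_grid, costs)]

    def test_pure_power_law_keeps_all_points(self):
        dfs = 5.0 ** np.arange(9)
        pts = self._points(dfs, dfs ** -1.0)
        assert detect_df_max(pts, CFG) == pytest.approx(5.0 ** 8)

    def test_kink_flags_before_the_plateau(self):
        # exact 1/df law up to 5^4 = 625, constant afterwards: the slope
        # detector flags 625 (window 25..3125 has slope -0.70) and the
        # curvature detector flags 125 (second difference 0.27 at 625)
        dfs = 5.0 ** np.arange(9)
        costs = np.minimum(dfs, 625.0) ** -1.0
        pts = self._points(dfs, costs)
        assert detect_df_max(pts, CFG) == pytest.approx(125.0)

    def test_input_order_is_irrelevant(self):
        rng = np.random.default_rng(0)
        dfs = 5.0 ** np.arange(9)
        costs = np.minimum(dfs, 625.0) ** -1.0
        pts = self._points(dfs, costs)
        shuffled = list(pts)
        rng.shuffle(shuffled)
        assert detect_df_max(shuffled, CFG) == detect_df_max(pts, CFG)

    def test_too_few_points_rejected(self):
        pts = self._points([1, 5, 25], [1, 0.2, 0.04])
        with pytest.raises(ValueError, match="cost points"):
            detect_df_max(pts, CFG)


class TestCostFit:
    def test_exact_inverse_law(self):
        dfs = 5.0 ** np.arange(6)
        model = fit_cost_model([CostPoint(d, 1.0 / d) for d in dfs])
        assert model.slope == pytest.approx(-1.0)
        assert model.intercept == pytest.approx(0.0, abs=1e-12)

    def test_prefactor_recovered(self):
        dfs = 5.0 ** np.arange(6)
        model = fit_cost_model([CostPoint(d, 2.0 / d) for d in dfs])
        assert model.slope == pytest.approx(-1.0)
        assert model(1.0) == pytest.approx(2.0)

    def test_noisy_slope_in_confidence_band(self):
        cost, _ = make_cost_error_points(-1.0, 1e-3, 0.5,
                                         5.0 ** np.arange(9), 0.02, seed=4)
        model = fit_cost_model(cost)
        assert model.slope == pytest.approx(-1.0, abs=0.05)


class TestIATErrorNorm:
    def test_identical_lists_give_zero(self):
        t = np.array([1.0, 2.5, 4.0])
        assert iat_error_norm(t, t, 0.0) == 0.0

    def test_three_four_five(self):
        # reference IATs (1, 2); replicate IATs (4, 6) -> differences (3, 4)
        ref = np.array([1.0, 3.0])
        rep = np.array([4.0, 10.0])
        assert iat_error_norm(ref, rep, 0.0) == pytest.approx(5.0)

    def test_truncation_to_common_length(self):
        rng = np.random.default_rng(1)
        ref = np.cumsum(rng.exponential(1.0, 10))
        rep = np.cumsum(rng.exponential(1.0, 8))
        full = iat_error_norm(ref, rep, 0.0)
        trunc = iat_error_norm(ref[:8], rep, 0.0)
        assert full == pytest.approx(trunc)

    def test_empty_list_undefined(self):
        assert iat_error_norm(np.array([]), np.array([1.0]), 0.0) is None

    def test_first_iat_measured_from_window_start(self):
        ref = np.array([2.0])
        rep = np.array([3.0])
        assert iat_error_norm(ref, rep, t_start=1.0) == pytest.approx(1.0)


class TestErrorFit:
    def test_exact_power_law(self):
        dfs = 5.0 ** np.arange(9)
        pts = [ErrorPoint(d, 1, 1e-3 * d ** 0.5) for d in dfs]
        model, ok = fit_error_model(pts, df_max=5.0 ** 8, config=CFG)
        assert model.p == pytest.approx(1e-3)
        assert model.q == pytest.approx(0.5)
        assert ok

    def test_saturated_channel_fails_check(self):
        dfs = 5.0 ** np.arange(9)
        pts = [ErrorPoint(d, 1, 1e-3 * d ** 0.5) for d in dfs]
        pts += [ErrorPoint(d, 2, 2e-3) for d in dfs]  # flat channel
        model, ok = fit_error_model(pts, df_max=5.0 ** 8, config=CFG)
        assert not ok
        assert model.per_channel[2][1] == pytest.approx(0.0, abs=1e-9)

    def test_points_beyond_df_max_ignored(self):
        dfs = 5.0 ** np.arange(9)
        pts = [ErrorPoint(d, 1, 1e-3 * d ** 0.5) for d in dfs]
        # corrupt the large-df points; they must not affect the fit
        pts += [ErrorPoint(5.0 ** 8, 1, 37.0)]
        model, _ = fit_error_model(pts, df_max=5.0 ** 4, config=CFG)
        assert model.q == pytest.approx(0.5)

    def test_scale_equivariance(self):
        dfs = 5.0 ** np.arange(6)
        pts = [ErrorPoint(d, 1, 1e-3 * d ** 0.4) for d in dfs]
        doubled = [ErrorPoint(p.df, p.channel, 2 * p.norm) for p in pts]
        m1, _ = fit_error_model(pts, 5.0 ** 5, CFG)
        m2, _ = fit_error_model(doubled, 5.0 ** 5, CFG)
        assert m2.p == pytest.approx(2 * m1.p)
        assert m2.q == pytest.approx(m1.q)

    def test_all_zero_norms_degenerate(self):
        pts = [ErrorPoint(d, 1, 0.0) for d in (1, 5, 25)]
        with pytest.raises(ValueError):
            fit_error_model(pts, 25.0, CFG)


class TestMinimizeObjective:
    def test_closed_form_stationary_point(self):
        # alpha/df + 2e-3*df^0.5 has F'=0 at df^1.5 = 1000, i.e. df = 100
        cost = CostModel(slope=-1.0, intercept=0.0)
        err = ErrorModel(p=1e-3, q=0.5)
        df_opt = minimize_objective(cost, err, 1.0, 2.0, 1.0, 5.0 ** 8)
        assert df_opt == pytest.approx(100.0, rel=1e-3)

    def test_zero_error_weight_hits_upper_bound(self):
        cost = CostModel(slope=-1.0, intercept=0.0)
        err = ErrorModel(p=1e-3, q=0.5)
        assert minimize_objective(cost, err, 1.0, 0.0, 1.0, 625.0) \
            == pytest.approx(625.0)

    def test_zero_cost_weight_hits_lower_bound(self):
        cost = CostModel(slope=-1.0, intercept=0.0)
        err = ErrorModel(p=1e-3, q=0.5)
        assert minimize_objective(cost, err, 0.0, 1.0, 3.0, 625.0) \
            == pytest.approx(3.0)

    def test_agrees_with_brute_force_grid(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            slope = rng.uniform(-1.1, -0.9)
            p = 10.0 ** rng.uniform(-4, -2)
            q = rng.uniform(0.2, 1.0)
            alpha = rng.uniform(0.5, 2.0)
            beta = rng.uniform(0.5, 10.0)
            cost = CostModel(slope=slope, intercept=0.0)
            err = ErrorModel(p=p, q=q)
            df_opt = minimize_objective(cost, err, alpha, beta, 1.0, 5.0 ** 8)
            grid = np.logspace(0, 8 * np.log10(5), 10_000)
            f = alpha * cost(grid) + beta * err(grid)
            brute = grid[np.argmin(f)]
            assert abs(df_opt - brute) / brute < 0.01


class TestAcceptance:
    def test_paper_style_accept(self):
        err = ErrorModel(p=0.0013, q=0.523)  # E(81.3) ~ 0.013
        d = evaluate_acceptance(81.3, err, baseline_norm=0.0013, config=CFG)
        assert d.accepted and d.absolute_ok and d.relative_ok
        assert d.error_at_opt == pytest.approx(0.013, rel=0.05)

    def test_absolute_cap_rejects(self):
        err = ErrorModel(p=0.06, q=0.0)
        d = evaluate_acceptance(10.0, err, baseline_norm=0.05, config=CFG)
        assert not d.accepted and not d.absolute_ok

    def test_relative_cap_rejects_three_orders(self):
        err = ErrorModel(p=1e-1, q=0.0)
        d = evaluate_acceptance(10.0, err, baseline_norm=1e-4, config=CFG)
        assert not d.accepted and not d.relative_ok

    def test_zero_baseline_skips_relative_criterion(self):
        err = ErrorModel(p=1e-3, q=0.5)
        d = evaluate_acceptance(10.0, err, baseline_norm=0.0, config=CFG)
        assert d.accepted and not d.relative_checked


class TestChooseWindow:
    def test_degenerate_bounds(self, birth_death):
        eng = initialize_engine(birth_death.network, master_seed=1)
        cfg = DownscaleConfig(w_min=10.0, w_max=10.0)
        t_s, t_f = choose_window(eng, cfg)
        assert t_f - t_s == pytest.approx(10.0)

    def test_width_never_exceeds_w_max(self):
        # a network whose slow channel cannot fire forces full extension
        toy = make_toy_network("fast-pair-slow-sink", kf=10.0, kr=10.0,
                               ks=1e-9, n0=4)
        eng = initialize_engine(toy.network, master_seed=1)
        cfg = DownscaleConfig(w_min=2.0, w_max=7.0)
        t_s, t_f = choose_window(eng, cfg)
        assert t_f - t_s <= 7.0 + 1e-12


class TestFullLoop:
    def test_disabled_controller_accepts_nothing(self, fast_pair):
        cfg = DownscaleConfig(N=2000, w_min=1.0, w_max=2.0,
                              TSS_min=math.inf)
        res = run_with_downscaling(fast_pair.network, None, cfg,
                                   master_seed=5, t_end=3.0)
        assert res.attempts, "controller should have been invoked"
        assert not any(a.accepted for a in res.attempts)
        assert res.final_downscale_factor == 1.0

    def test_empty_fast_set_aborts_on_gates(self):
        toy = make_toy_network("two-slow-channels", lam=50.0, mu=1.0)
        cfg = DownscaleConfig(N=500, w_min=1.0, w_max=1.0)
        res = run_with_downscaling(toy.network, None, cfg, master_seed=1,
                                   t_end=20.0)
        assert res.attempts
        assert not any(a.accepted for a in res.attempts)

    def test_accepted_attempt_bookkeeping(self):
        toy = make_toy_network("fast-pair-slow-sink", kf=2e4, kr=2e4,
                               ks=1.0, n0=40)
        cfg = DownscaleConfig(N=20_000, w_min=6.0, w_max=6.0, df_b=5.0,
                              n=9, TSS_min=2.0, alpha=1.0, beta=2.0)
        res = run_with_downscaling(toy.network, {"A": 20, "B": 20, "C": 0},
                                   cfg, master_seed=3, t_end=10.0)
        accepted = [a for a in res.attempts if a.accepted]
        prod = 1.0
        for a in res.attempts:
            if a.accepted:
                assert a.df_cumulative == pytest.approx(a.df_opt)
                assert a.df_opt <= a.df_max
                prod = a.df_cumulative
        assert res.final_downscale_factor == pytest.approx(prod)
        if accepted:
            assert all(a.gates.get("qe") and a.gates.get("tss")
                       for a in accepted)

    def test_attempt_ledger_is_reproducible(self):
        toy = make_toy_network("fast-pair-slow-sink", kf=2e4, kr=2e4,
                               ks=1.0, n0=40)
        cfg = DownscaleConfig(N=20_000, w_min=4.0, w_max=4.0)
        runs = [run_with_downscaling(toy.network,
                                     {"A": 20, "B": 20, "C": 0}, cfg,
                                     master_seed=11, t_end=6.0)
                for _ in range(2)]
        a, b = (r.attempts for r in runs)
        assert len(a) == len(b)
        for ra, rb in zip(a, b):
            assert ra.to_dict() == rb.to_dict()
        ta, va = runs[0].series("C")
        tb, vb = runs[1].series("C")
        assert np.array_equal(va, vb)


class TestSyntheticPointsIntegration:
    def test_noiseless_points_recover_truth(self):
        dfs = 5.0 ** np.arange(9)
        cost, err = make_cost_error_points(-1.0, 2e-3, 0.45, dfs, 0.0, seed=0)
        assert detect_df_max(cost, CFG) == pytest.approx(dfs[-1])
        cm = fit_cost_model(cost)
        em, ok = fit_error_model(err, dfs[-1], CFG)
        assert cm.slope == pytest.approx(-1.0)
        assert em.p == pytest.approx(2e-3)
        assert em.q == pytest.approx(0.45)
        assert ok

    def test_same_seed_reproduces_points(self):
        dfs = 5.0 ** np.arange(5)
        a = make_cost_error_points(-1.0, 1e-3, 0.5, dfs, 0.1, seed=3)
        b = make_cost_error_points(-1.0, 1e-3, 0.5, dfs, 0.1, seed=3)
        assert a == b
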