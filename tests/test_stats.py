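"""State-resolved pooling, paired comparisons, correlations, regression."""

import numpy as np
import pytest

from gradstate.behavior import RTSeries
from gradstate.exgauss import ExGaussParams, exgauss_rvs
from gradstate.mem import StateSeries
from gradstate.stats import (
    StateRTPools,
    compare_states,
    correlate_params,
    hedges_g,
    mind_wandering_correlation,
    paired_stats,
    pool_rts,
    regress_errors,
)

REF = (0.80, 0.08, 0.05)


def make_rt_series(onsets, rts, classification=None, isi=0.8):
    n = len(onsets)
    if classification is None:
        classification = np.where(np.isnan(rts), "omission_error",
                                  "correct_commission")
    return RTSeries(
        rts=np.asarray(rts, dtype=float),
        classification=np.asarray(classification),
        assigned_press=np.arange(n),
        press_times=np.asarray(onsets, dtype=float),
        isi=isi,
        onsets=np.asarray(onsets, dtype=float),
    )


def make_pools(rng, params_a, params_b, n=200, participant=0):
    return StateRTPools(
        pools={
            0: exgauss_rvs(params_a, n, rng),
            1: exgauss_rvs(params_b, n, rng),
        },
        participant=participant,
    )


class TestPooling:
    def test_single_state_single_pool(self):
        onsets = np.arange(20) * 0.8
        series = make_rt_series(onsets, np.full(20, 0.7))
        states = StateSeries(labels=np.zeros(8, dtype=int), tr=2.0,
                             shift_volumes=0)
        pools = pool_rts(series, states)
        assert pools.n(0) == 20
        assert pools.n_dropped == 0

    def test_alternating_states_split_evenly(self):
        # one trial per 2-s volume, states alternating per volume
        onsets = np.arange(40) * 2.0
        series = make_rt_series(onsets, np.full(40, 0.7))
        labels = np.tile([7, 248], 20)
        states = StateSeries(labels=labels, tr=2.0, shift_volumes=0)
        pools = pool_rts(series, states)
        assert abs(pools.n(7) - pools.n(248)) <= 1

    def test_trials_beyond_labels_dropped(self):
        onsets = np.arange(20) * 0.8
        series = make_rt_series(onsets, np.full(20, 0.7))
        states = StateSeries(labels=np.zeros(4, dtype=int), tr=2.0,
                             shift_volumes=2)
        pools = pool_rts(series, states)
        assert pools.n(0) + pools.n_dropped == 20
        assert pools.n_dropped == 10   # onsets >= 8 s fall past volume 3

    def test_only_correct_commissions_pooled(self):
        onsets = np.arange(4) * 0.8
        rts = np.array([0.7, 0.7, np.nan, 0.7])
        cls = np.array(["correct_commission", "commission_error",
                        "omission_error", "correct_commission"])
        series = make_rt_series(onsets, rts, cls)
        states = StateSeries(labels=np.zeros(3, dtype=int), tr=2.0,
                             shift_volumes=0)
        pools = pool_rts(series, states)
        assert pools.n(0) == 2

    def test_generator_round_trip_pools(self):
        # pools keyed by the pipeline's shifted states match the generator's
        # per-trial generating states exactly in a clean world
        from gradstate.mem import build_landscape, state_series
        from gradstate.simulate import (
            SimConfig, StateBehavior, gen_behavior, gen_network_series,
            gen_trial_stream, planted_two_state_model,
        )
        from gradstate.behavior import assign_presses
        from gradstate.mem import pattern_index

        model = planted_two_state_model()
        scape = build_landscape(model)
        rng = np.random.default_rng(21)
        stream = gen_trial_stream(200, 0.8, 0.10, rng)
        cfg = SimConfig(
            n_trials_per_run=200,
            mem_truth=model,
            state_params={
                7: StateBehavior(params=ExGaussParams(0.80, 0.05, 0.03)),
                248: StateBehavior(params=ExGaussParams(0.80, 0.05, 0.03)),
            },
        )
        binary, _ = gen_network_series(model, cfg.volumes_per_run, 8, rng)
        true_states = scape.basin[pattern_index(binary)]
        presses, truth = gen_behavior(stream, true_states, cfg, rng)
        series = assign_presses(stream, presses)
        sseries = state_series(binary, scape, tr=cfg.tr, lag=cfg.hemodynamic_lag)
        pools = pool_rts(series, sseries)
        city = stream.is_city()
        for state in (7, 248):
            want = np.sort(truth.trial_rts[city & (truth.trial_states == state)])
            got = np.sort(pools.pools.get(state, np.empty(0)))
            np.testing.assert_allclose(got, want, atol=1e-12)


class TestPairedStats:
    def test_hand_computed_t(self):
        # differences (1, 1, 2): mean 4/3, sd 1/sqrt(3) -> t = 4.0
        t, df, p = paired_stats([2.0, 3.0, 5.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(4.0)
        assert df == 2
        assert p == pytest.approx(0.0572, abs=1e-3)

    def test_identical_vectors(self):
        t, df, p = paired_stats([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_hedges_g_small_sample_correction(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 3.0, 4.0, 5.0])
        sp = np.sqrt((3 * np.var(x, ddof=1) + 3 * np.var(y, ddof=1)) / 6)
        expected = (1 - 3 / (4 * 6 - 1)) * (x.mean() - y.mean()) / sp
        assert hedges_g(x, y) == pytest.approx(expected, abs=1e-12)


class TestCompareStates:
    def test_identical_pools_null_result(self, rng):
        pools = []
        for p in range(6):
            x = exgauss_rvs(REF, 300, rng)
            pools.append(StateRTPools(pools={0: x, 1: x.copy()}, participant=p))
        res = compare_states(pools, 0, 1)
        for _, row in res.table.iterrows():
            assert row["t"] == 0.0
            assert row["hedges_g"] == 0.0

    def test_planted_sigma_difference_detected(self):
        rng = np.random.default_rng(33)
        pools = [
            make_pools(rng, REF, (0.80, 0.12, 0.05), n=400, participant=p)
            for p in range(20)
        ]
        res = compare_states(pools, 0, 1)
        tab = res.table.set_index("parameter")
        assert tab.loc["sigma", "p"] < 0.05
        assert tab.loc["sigma", "mean_a"] < tab.loc["sigma", "mean_b"]
        assert tab.loc["mu", "p"] > 0.05
        assert tab.loc["tau", "p"] > 0.05

    def test_exclusion_bookkeeping(self, rng):
        pools = [make_pools(rng, REF, REF, participant=p) for p in range(5)]
        # participant 5: too few trials in state 1
        pools.append(StateRTPools(
            pools={0: exgauss_rvs(REF, 200, rng), 1: exgauss_rvs(REF, 4, rng)},
            participant=5,
        ))
        # participant 6: negatively skewed overall
        pools.append(StateRTPools(
            pools={0: -exgauss_rvs(REF, 200, rng), 1: -exgauss_rvs(REF, 200, rng)},
            participant=6,
        ))
        res = compare_states(pools, 0, 1)
        assert res.n_included + res.n_excluded == 7
        assert res.exclusions[5].startswith("insufficient_trials")
        assert res.exclusions[6] == "negative_skewness"

    def test_all_excluded_raises(self, rng):
        pools = [
            StateRTPools(pools={0: -exgauss_rvs(REF, 100, rng),
                                1: -exgauss_rvs(REF, 100, rng)},
                         participant=p)
            for p in range(4)
        ]
        with pytest.raises(ValueError, match="at least 3"):
            compare_states(pools, 0, 1)

    def test_type_one_error_rate_under_null(self):
        # identical state parameters: the sigma comparison should reject at
        # the nominal 5% level (within +/- 3 points over 400 experiments)
        rejections = 0
        n_exp = 400
        for e in range(n_exp):
            rng = np.random.default_rng(50_000 + e)
            pools = [make_pools(rng, REF, REF, n=80, participant=p)
                     for p in range(15)]
            res = compare_states(pools, 0, 1)
            tab = res.table.set_index("parameter")
            rejections += tab.loc["sigma", "p"] < 0.05
        assert 0.02 <= rejections / n_exp <= 0.08

    def test_power_monotone_in_sigma_ratio(self):
        # common random numbers across the ratio grid
        ratios = [1.0, 1.25, 1.5, 2.0]
        power = []
        for ratio in ratios:
            rej = 0
            for e in range(60):
                rng = np.random.default_rng(90_000 + e)
                pools = [
                    make_pools(rng, REF, (0.80, 0.08 * ratio, 0.05),
                               n=150, participant=p)
                    for p in range(12)
                ]
                tab = compare_states(pools, 0, 1).table.set_index("parameter")
                rej += tab.loc["sigma", "p"] < 0.05
            power.append(rej / 60)
        assert all(b >= a - 1e-9 for a, b in zip(power, power[1:]))
        assert power[-1] > 0.9


class TestCorrelations:
    def test_monotone_extremes(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        rho, _ = correlate_params(x, x**2)
        assert rho == pytest.approx(1.0)
        rho, _ = correlate_params(x, -np.sqrt(x))
        assert rho == pytest.approx(-1.0)

    def test_planted_rank_correlation(self):
        from gradstate.simulate import gen_population

        df = gen_population(5_000, error_link=0.5, seed=4)
        rho, p = correlate_params(df["sigma"].to_numpy(),
                                  df["omission_rate"].to_numpy())
        assert rho == pytest.approx(0.5, abs=0.05)
        assert p < 1e-10

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            correlate_params([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestRegression:
    def test_exact_linear_outcome(self, rng):
        X = rng.normal(size=(50, 3))
        y = 2.0 * X[:, 0]
        res = regress_errors(X, y)
        assert res["coef"]["mu"] == pytest.approx(2.0, abs=1e-10)
        assert res["coef"]["sigma"] == pytest.approx(0.0, abs=1e-10)
        assert res["coef"]["tau"] == pytest.approx(0.0, abs=1e-10)
        assert res["r2"] == pytest.approx(1.0, abs=1e-10)

    def test_independent_outcome(self, rng):
        X = rng.normal(size=(5_000, 3))
        y = rng.normal(size=5_000)
        res = regress_errors(X, y)
        assert res["r2"] < 0.01

    def test_five_point_fixture_matches_normal_equations(self):
        X = np.array([
            [0.7, 0.05, 0.03],
            [0.8, 0.08, 0.05],
            [0.9, 0.06, 0.09],
            [0.75, 0.10, 0.04],
            [0.85, 0.07, 0.06],
        ])
        y = np.array([3.0, 5.0, 9.0, 6.0, 4.0])
        res = regress_errors(X, y)
        A = np.column_stack([np.ones(5), X])
        beta = np.linalg.solve(A.T @ A, A.T @ y)   # independent route
        for i, name in enumerate(["intercept", "mu", "sigma", "tau"]):
            assert res["coef"][name] == pytest.approx(beta[i], abs=1e-8)

    def test_standardized_betas_emitted(self, rng):
        X = rng.normal(size=(100, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + rng.normal(size=100)
        res = regress_errors(X, y)
        assert set(res["coef_std"]) == {"intercept", "mu", "sigma", "tau"}
        assert abs(res["coef_std"]["intercept"]) < 1e-10


class TestMindWandering:
    def test_constant_probes_rejected(self):
        with pytest.raises(ValueError):
            mind_wandering_correlation([0.1, 0.2, 0.3], [0.0, 0.0, 0.0])

    def test_out_of_range_probe_rejected(self):
        with pytest.raises(ValueError, match="0, 100"):
            mind_wandering_correlation([0.1, 0.2, 0.3], [10.0, 50.0, 101.0])

    def test_planted_monotone_link(self, rng):
        sigma = rng.uniform(0.05, 0.15, 40)
        probes = 100 * (sigma - 0.05) / 0.10 + rng.normal(0, 5, 40)
        probes = np.clip(probes, 0, 100)
        rho, p = mind_wandering_correlation(sigma, probes)
        assert rho > 0.5 and p < 0.01
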