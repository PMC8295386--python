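"""Pairwise maximum-entropy model, energy landscape, and state series."""

import numpy as np
import pytest
from scipy import special

from conftest import random_model
from gradstate.mem import (
    EnergyLandscape,
    MEMModel,
    NetworkActivity,
    all_energies,
    all_patterns,
    basin_assign,
    binarize,
    build_landscape,
    clean_and_average,
    empirical_moments,
    energy,
    find_minima,
    fit_mem,
    fit_quality,
    label_named_states,
    lag_to_shift,
    pattern_index,
    pattern_probabilities,
    spin_to_binary,
    state_series,
)


def brute_minima(e: np.ndarray, n: int) -> set[int]:
    """Literal-definition oracle: strictly below every Hamming-1 neighbour."""
    out = set()
    for k in range(2**n):
        if all(e[k] < e[k ^ (1 << i)] for i in range(n)):
            out.add(k)
    return out


def brute_basin(e: np.ndarray, n: int, k: int) -> int:
    """Literal steepest descent with lowest-index tie-break."""
    while True:
        nbrs = sorted(k ^ (1 << i) for i in range(n))
        best = min(nbrs, key=lambda j: (e[j], j))
        if e[best] < e[k]:
            k = best
        else:
            return k


class TestPreprocessing:
    def test_intercept_only_residualization_is_centering(self, rng):
        x = rng.normal(2.0, 1.0, (50, 4))
        act = clean_and_average(x, ["DMN", "DMN", "Limbic", "Limbic"],
                                networks=("DMN", "Limbic"))
        assert np.allclose(act.values.mean(axis=0), 0, atol=1e-12)
        # standardization before averaging: per-ROI unit variance
        assert act.values.shape == (50, 2)

    def test_column_equal_to_confound_flags_zero_variance(self, rng):
        conf = rng.normal(size=(40, 1))
        x = np.column_stack([conf[:, 0], rng.normal(size=40)])
        with pytest.raises(ValueError, match="zero-variance"):
            clean_and_average(x, ["DMN", "Limbic"], confounds=conf,
                              networks=("DMN", "Limbic"))

    def test_opposite_rois_average_to_zero(self, rng):
        v = rng.normal(size=40)
        x = np.column_stack([v, -v, rng.normal(size=40), rng.normal(size=40)])
        act = clean_and_average(x, ["DMN", "DMN", "Limbic", "Limbic"],
                                networks=("DMN", "Limbic"))
        assert np.allclose(act.values[:, 0], 0.0, atol=1e-12)

    def test_empty_network_rejected(self, rng):
        with pytest.raises(ValueError, match="no member"):
            clean_and_average(rng.normal(size=(10, 2)), ["DMN", "DMN"],
                              networks=("DMN", "Limbic"))

    def test_binarize_threshold_and_ties(self):
        col = np.array([[1.0], [2.0], [6.0]])
        np.testing.assert_array_equal(binarize(col).ravel(), [0, 0, 1])
        const = np.ones((5, 1))
        assert not binarize(const).any()   # ties at the mean map to 0

    def test_empirical_moments(self):
        b = np.ones((7, 3))
        m1, m2 = empirical_moments(b)
        assert np.all(m1 == 1) and np.all(m2 == 1)
        anti = np.array([[1, 0], [0, 1], [1, 0], [0, 1]])
        _, m2 = empirical_moments(anti)
        assert m2[0, 1] == 0
        # hand-enumerated 4 x 2 case
        b = np.array([[1, 1], [1, 0], [0, 0], [1, 1]])
        m1, m2 = empirical_moments(b)
        np.testing.assert_allclose(m1, [0.75, 0.5])
        assert m2[0, 1] == pytest.approx(0.5)


class TestEnergyAndProbability:
    def test_energy_examples(self):
        zero = MEMModel(h=np.zeros(2), J=np.zeros((2, 2)), networks=("a", "b"))
        assert energy(np.array([1, 1]), zero) == 0.0
        biased = MEMModel(h=np.array([1.0, 0.0]), J=np.zeros((2, 2)),
                          networks=("a", "b"))
        assert energy(np.array([1, 0]), biased) == -1.0
        J = np.array([[0.0, 2.0], [2.0, 0.0]])
        coupled = MEMModel(h=np.zeros(2), J=J, networks=("a", "b"))
        assert energy(np.array([1, 1]), coupled) == -2.0

    def test_uniform_when_no_parameters(self):
        model = MEMModel(h=np.zeros(8), J=np.zeros((8, 8)))
        p = pattern_probabilities(model)
        np.testing.assert_allclose(p, 1 / 256, atol=1e-15)

    def test_normalization_random_models(self, rng):
        for _ in range(10):
            p = pattern_probabilities(random_model(6, rng))
            assert abs(p.sum() - 1.0) < 1e-12

    def test_independence_closed_form(self, rng):
        # J = 0: marginal P(s_i = 1) = e^h / (1 + e^h), from enumeration
        h = rng.uniform(-2, 2, 5)
        model = MEMModel(h=h, J=np.zeros((5, 5)),
                         networks=tuple("abcde"))
        p = pattern_probabilities(model)
        pats = all_patterns(5)
        marginals = p @ pats
        np.testing.assert_allclose(marginals, special.expit(h), atol=1e-10)

    def test_spin_binary_conversion_preserves_energy_differences(self, rng):
        n = 5
        hs = rng.normal(size=n)
        Js = rng.normal(size=(n, n))
        Js = 0.5 * (Js + Js.T)
        np.fill_diagonal(Js, 0.0)
        h01, J01 = spin_to_binary(hs, Js)
        model = MEMModel(h=h01, J=J01, networks=tuple("abcde"))
        e01 = all_energies(model)
        pats = all_patterns(n)
        x = 2.0 * pats - 1.0
        e_spin = -(x @ hs) - 0.5 * np.einsum("ki,ij,kj->k", x, Js, x)
        diff = e01 - e_spin
        assert np.ptp(diff) < 1e-10   # equal up to an additive constant


class TestFit:
    def test_uniform_data_gives_null_model(self):
        # perfectly balanced data: every pattern exactly once
        b = all_patterns(4).astype(int)
        model = fit_mem(b, tol=1e-6)
        assert np.max(np.abs(model.h)) < 0.05
        assert np.max(np.abs(model.J)) < 0.05

    def test_independent_columns_recover_logits(self, rng):
        p = np.array([0.2, 0.5, 0.8])
        b = (rng.random((200_000, 3)) < p).astype(int)
        model = fit_mem(b)
        np.testing.assert_allclose(model.h, special.logit(p), atol=0.06)
        assert np.max(np.abs(model.J)) < 0.1

    def test_moment_matching_at_convergence(self, rng):
        b = (rng.random((2_000, 5)) < 0.4).astype(int)
        model = fit_mem(b, tol=1e-5)
        assert model.converged
        assert model.max_moment_mismatch <= 1e-5

    def test_loglik_nondecreasing(self, rng):
        b = (rng.random((1_000, 4)) < rng.uniform(0.2, 0.8, 4)).astype(int)
        model = fit_mem(b, track_loglik=True)
        trace = model.loglik_trace
        assert np.all(np.diff(trace) >= -1e-12)

    def test_boundary_moment_clamped(self):
        b = np.zeros((50, 3), dtype=int)
        b[:, 1] = np.arange(50) % 2
        b[:, 2] = np.arange(50) % 3 == 0
        with pytest.warns(UserWarning, match="clamping"):
            model = fit_mem(b, max_iter=20_000)
        assert np.isfinite(model.h).all()

    def test_planted_recovery(self, rng):
        from gradstate.simulate import sample_boltzmann

        truth = random_model(6, rng, scale=0.8)
        idx = sample_boltzmann(truth, 50_000, rng)
        b = ((idx[:, None] >> np.arange(6)) & 1).astype(int)
        fit = fit_mem(b)
        assert np.max(np.abs(fit.h - truth.h)) < 0.15
        assert np.max(np.abs(fit.J - truth.J)) < 0.15


class TestFitQuality:
    def test_self_consistency(self, rng):
        from gradstate.simulate import sample_boltzmann

        truth = random_model(5, rng, scale=0.7)
        idx = sample_boltzmann(truth, 40_000, rng)
        b = ((idx[:, None] >> np.arange(5)) & 1).astype(int)
        model = fit_mem(b)
        assert fit_quality(b, model) > 0.99

    def test_zero_variance_flagged(self):
        model = MEMModel(h=np.zeros(2), J=np.zeros((2, 2)), networks=("a", "b"))
        b = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
        with pytest.warns(UserWarning, match="zero-variance"):
            r = fit_quality(b, model)
        assert np.isnan(r)

    def test_hand_counted_case(self):
        # patterns (0,0), (0,0), (1,0), (1,1) -> empirical (0.5, 0.25, 0, 0.25)
        b = np.array([[0, 0], [0, 0], [1, 0], [1, 1]])
        idx = pattern_index(b)
        emp = np.bincount(idx, minlength=4) / 4
        np.testing.assert_allclose(emp, [0.5, 0.25, 0.0, 0.25])


class TestLandscape:
    def test_two_state_toy(self):
        # energies: 00 -> 0, 10 -> 1, 01 -> 1, 11 -> 0.5
        e = np.array([0.0, 1.0, 1.0, 0.5])
        minima = find_minima(e)
        np.testing.assert_array_equal(minima, [0, 3])
        basin = basin_assign(e)
        assert basin[1] == 0 and basin[2] == 0
        assert basin[0] == 0 and basin[3] == 3

    def test_monotone_energies_single_minimum(self):
        pats = all_patterns(6)
        e = pats.sum(axis=1) * 1.0
        minima = find_minima(e)
        np.testing.assert_array_equal(minima, [0])
        assert np.all(basin_assign(e) == 0)

    def test_ties_are_not_minima(self):
        e = np.array([0.0, 0.0, 1.0, 1.0])
        assert 0 not in find_minima(e) and 1 not in find_minima(e)

    @pytest.mark.parametrize("n", [2, 4, 8])
    def test_matches_bruteforce_oracle(self, n):
        rng = np.random.default_rng(100 + n)
        for _ in range(100):
            model = random_model(n, rng)
            e = all_energies(model)
            minima = find_minima(e)
            assert set(minima.tolist()) == brute_minima(e, n)
            basin = basin_assign(e)
            assert set(basin.tolist()) <= set(minima.tolist())
            for m in minima:
                assert basin[m] == m
            for k in range(2**n):
                assert basin[k] == brute_basin(e, n, k)


class TestStateSeries:
    @pytest.mark.parametrize(
        "tr,lag,expected",
        [(2.0, 0.0, 0), (1.08, 5.0, 5), (2.0, 5.0, 2)],
    )
    def test_lag_rounding(self, tr, lag, expected):
        # round(lag/tr) with exact halves rounded down: 5/1.08 = 4.63 -> 5,
        # 5/2 = 2.5 -> 2
        assert lag_to_shift(lag, tr) == expected

    def test_shift_applied(self, planted_model):
        scape = build_landscape(planted_model)
        rng = np.random.default_rng(5)
        b = (rng.random((20, 8)) < 0.5).astype(int)
        s0 = state_series(b, scape, tr=2.0, lag=0.0)
        assert len(s0) == 20 and s0.shift_volumes == 0
        s = state_series(b, scape, tr=2.0, lag=5.0)
        assert s.shift_volumes == 2 and len(s) == 18
        np.testing.assert_array_equal(s.labels, s0.labels[2:])

    def test_run_too_short(self, planted_model):
        scape = build_landscape(planted_model)
        b = np.zeros((2, 8), dtype=int)
        with pytest.raises(ValueError, match="shorter"):
            state_series(b, scape, tr=2.0, lag=5.0)


class TestNamedStates:
    def test_canonical_patterns(self, planted_model):
        scape = build_landscape(planted_model)
        labels = label_named_states(scape.minima)
        # DMN, Limbic, FPN_A are bits 0-2 -> pattern 7; complement 248
        assert labels[7] == "State1"
        assert labels[248] == "State2"

    def test_all_zero_is_other(self):
        labels = label_named_states(np.array([0]))
        assert labels[0] == "other"

    def test_all_on_is_other(self):
        labels = label_named_states(np.array([255]))
        assert labels[255] == "other"
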