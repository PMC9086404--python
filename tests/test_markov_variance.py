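import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import simulate_chain
from localtrend import (
    DegenerateChainError,
    PairCounts,
    ThreeStateParams,
    TwoStateParams,
    autocov_exact,
    estimate_three_state,
    estimate_two_state,
    iid_params,
    pair_counts,
    sigma2_mixed,
    sigma2_three,
    sigma2_two,
)


class TestPairCounts:
    def test_direct_enumeration(self):
        c = pair_counts(np.array([1, 1, -1, 1]))
        assert c.count(1, 1) == 1 and c.count(1, -1) == 1 and c.count(-1, 1) == 1
        assert c.total == 3

    def test_alternating(self):
        c = pair_counts(np.array([1, -1, 1, -1]))
        assert c.count(1, -1) == 2 and c.count(-1, 1) == 1

    def test_all_flat(self):
        c = pair_counts(np.array([0, 0, 0]))
        assert c.count(0, 0) == 2 and c.total == 2

    def test_too_short(self):
        with pytest.raises(ValueError):
            pair_counts(np.array([1]))


class TestEstimators:
    def test_two_state_direct_substitution(self):
        a = estimate_two_state(pair_counts(np.array([1, 1, -1, 1]))).a
        assert a == pytest.approx(0.5 * (0 / 1 + 1 / 2))

    def test_never_switching_chain(self):
        assert estimate_two_state(pair_counts(np.array([1, 1, 1]))).a == 1.0

    def test_three_state_direct_substitution(self):
        tab = np.array([[2, 1, 1], [1, 2, 1], [1, 1, 2]])
        p = estimate_three_state(PairCounts(tab))
        assert p.b == pytest.approx(0.5) and p.c == pytest.approx(0.25)
        assert p.d == pytest.approx(0.25)

    def test_all_zero_sequence_is_degenerate(self):
        with pytest.raises(DegenerateChainError):
            estimate_three_state(pair_counts(np.array([0, 0, 0, 0])))

    def test_zero_row_needs_two_state_fallback(self):
        # zero state seen only at the final position
        with pytest.raises(DegenerateChainError):
            estimate_three_state(pair_counts(np.array([1, -1, 1, 0])))

    @pytest.mark.parametrize("m", [1000, 10_000, 100_000])
    def test_two_state_recovery(self, m, rng):
        chain = simulate_chain(TwoStateParams(0.7), m, rng)
        tol = 6.0 / np.sqrt(m)
        assert estimate_two_state(pair_counts(chain)).a == pytest.approx(0.7, abs=tol)

    @pytest.mark.parametrize("m", [1000, 10_000, 100_000])
    def test_three_state_recovery(self, m, rng, three_state):
        chain = simulate_chain(three_state, m, rng)
        est = estimate_three_state(pair_counts(chain))
        tol = 8.0 / np.sqrt(m)
        assert est.b == pytest.approx(0.5, abs=tol)
        assert est.c == pytest.approx(0.1, abs=tol)
        assert est.d == pytest.approx(0.2, abs=tol)


class TestSigma2:
    def test_two_state_values(self):
        assert sigma2_two(TwoStateParams(0.5), TwoStateParams(0.5)) == pytest.approx(1.0)
        assert sigma2_two(TwoStateParams(0.75), TwoStateParams(0.75)) == pytest.approx(5 / 3)
        p = TwoStateParams(1 / 3)
        assert sigma2_two(p, p) == pytest.approx(1.25)  # the i.i.d. value at t = 0

    def test_three_state_values(self, three_state):
        assert sigma2_three(three_state, three_state) == pytest.approx(
            0.25 * 1.16 / 0.84
        )
        sym = ThreeStateParams(0.25, 0.25, 0.25)
        assert sigma2_three(sym, sym) == pytest.approx(0.25)  # rho = 0 closed form

    def test_three_state_rho_zero_reduces_to_marginal(self):
        pX = ThreeStateParams(0.3, 0.3, 0.15)
        pY = ThreeStateParams(0.2, 0.2, 0.4)
        assert sigma2_three(pX, pY) == pytest.approx(4 * pX.phi1 * pY.phi1)

    def test_mixed_value_and_symmetry(self, three_state):
        p2 = TwoStateParams(0.8)
        expect = 0.5 * 1.24 / 0.76
        assert sigma2_mixed(p2, three_state) == pytest.approx(expect)
        assert sigma2_mixed(three_state, p2) == pytest.approx(expect)

    def test_mixed_with_uncorrelated_two_state(self, three_state):
        assert sigma2_mixed(TwoStateParams(0.5), three_state) == pytest.approx(
            2 * three_state.phi1
        )

    def test_degenerate_chain_rejected(self):
        with pytest.raises(DegenerateChainError):
            sigma2_two(TwoStateParams(1.0), TwoStateParams(1.0))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        aX=st.floats(0.06, 0.94),
        aY=st.floats(0.06, 0.94),
    )
    def test_two_state_closed_form_equals_truncated_series(self, aX, aY):
        """sigma^2 == E(Z^2) + 2 sum_k autocov products, summed via matrix powers."""
        pX, pY = TwoStateParams(aX), TwoStateParams(aY)
        series = 1.0 + 2.0 * sum(
            autocov_exact(pX, k) * autocov_exact(pY, k) for k in range(1, 201)
        )
        assert sigma2_two(pX, pY) == pytest.approx(series, abs=1e-10)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_three_and_mixed_closed_forms_equal_truncated_series(self, data):
        b = data.draw(st.floats(0.05, 0.9))
        c = data.draw(st.floats(0.0, min(0.9, 0.95 - b)))
        d = data.draw(st.floats(0.05, 0.45))
        a = data.draw(st.floats(0.06, 0.94))
        p3 = ThreeStateParams(b, c, d)
        p2 = TwoStateParams(a)
        e0_3 = 2 * p3.phi1
        series3 = e0_3 * e0_3 + 2.0 * sum(
            autocov_exact(p3, k) ** 2 for k in range(1, 201)
        )
        assert sigma2_three(p3, p3) == pytest.approx(series3, abs=1e-10)
        series_m = e0_3 + 2.0 * sum(
            autocov_exact(p2, k) * autocov_exact(p3, k) for k in range(1, 201)
        )
        assert sigma2_mixed(p2, p3) == pytest.approx(series_m, abs=1e-10)


class TestAutocov:
    def test_uncorrelated_two_state(self):
        assert autocov_exact(TwoStateParams(0.5), 3) == pytest.approx(0.0)

    def test_matrix_power_examples(self, three_state):
        assert autocov_exact(TwoStateParams(0.75), 2) == pytest.approx(0.25)
        assert autocov_exact(three_state, 1) == pytest.approx(2 * 0.25 * 0.4)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(data=st.data(), k=st.integers(1, 20))
    def test_matrix_power_equals_closed_forms(self, data, k):
        a = data.draw(st.floats(0.01, 0.99))
        p2 = TwoStateParams(a)
        assert autocov_exact(p2, k) == pytest.approx((2 * a - 1) ** k, abs=1e-12)
        b = data.draw(st.floats(0.0, 0.95))
        c = data.draw(st.floats(0.0, 0.99 - b))
        d = data.draw(st.floats(0.01, 0.5))
        p3 = ThreeStateParams(b, c, d)
        assert autocov_exact(p3, k) == pytest.approx(
            2 * p3.phi1 * (b - c) ** k, abs=1e-12
        )


class TestStationaryLaw:
    def test_balance_equation(self, three_state, two_state):
        for p in (three_state, two_state):
            pi = p.stationary
            assert pi @ p.transition_matrix == pytest.approx(pi)
            assert pi.sum() == pytest.approx(1.0)

    def test_stationary_mass(self, three_state):
        assert three_state.phi1 == pytest.approx(0.2 / (1 - 0.6 + 0.4))


class TestIIDParams:
    def test_zero_threshold_is_exact_third(self):
        p = iid_params(0.0)
        assert isinstance(p, TwoStateParams)
        assert p.a == pytest.approx(1 / 3)

    def test_distribution_free_at_zero_threshold(self, rng):
        # empirical check of the rank-invariance: any continuous marginal
        for sample in (rng.standard_normal(200_000), rng.exponential(size=200_000)):
            from localtrend import discretize

            est = estimate_two_state(pair_counts(discretize(sample, 0.0)))
            assert est.a == pytest.approx(1 / 3, abs=0.01)

    def test_monte_carlo_self_consistency(self):
        p1 = iid_params(0.5, "normal", 10**6, seed=1)
        p2 = iid_params(0.5, "normal", 10**6, seed=2)
        assert p1.b == pytest.approx(p2.b, abs=0.005)
        assert p1.c == pytest.approx(p2.c, abs=0.005)
        assert p1.d == pytest.approx(p2.d, abs=0.005)

    def test_small_sample_warns(self):
        with pytest.warns(UserWarning):
            iid_params(0.7, "normal", 10**4, seed=3)
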