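"""Expected-gain model: classification, probabilities, optima, surfaces."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.stats import norm

import riskaim as ra
from riskaim.payoff import GaussianResponder, PayoffScheme

from conftest import grid_search_optimal_aim


def eg_quadrature(aim, sigma, scheme):
    """Numerical-integration oracle for expected gain."""

    def gain(x):
        if x < scheme.lower:
            return scheme.gain_early
        if x > scheme.upper:
            return scheme.gain_late
        return scheme.gain_hit

    val, _ = quad(
        lambda x: gain(x) * norm.pdf(x, aim, sigma),
        aim - 10 * sigma,
        aim + 10 * sigma,
        points=[scheme.lower, scheme.upper],
        limit=200,
    )
    return val


class TestClassification:
    @pytest.mark.parametrize(
        "x,block,expected",
        [
            (750.0, "2", ("hit", 5.0)),
            (500.0, "4", ("early", -30.0)),
            (1000.0, "1", ("late", 0.0)),
            (1000.0, "4", ("late", 0.0)),
            (500.0, "3", ("early", 0.0)),
            (525.0, "4", ("hit", 5.0)),  # closed lower boundary
            (975.0, "4", ("hit", 5.0)),  # closed upper boundary
            (750.0, "P", ("hit", 0.0)),  # practice earns nothing
        ],
    )
    def test_outcomes_and_points(self, timing_schemes, x, block, expected):
        assert ra.classify_response(x, timing_schemes[block]) == expected

    def test_negative_response_rejected(self, timing_schemes):
        with pytest.raises(ValueError):
            ra.classify_response(-1.0, timing_schemes["1"])

    def test_scheme_invariants_enforced(self):
        with pytest.raises(ValueError):
            PayoffScheme(target=-750.0)
        with pytest.raises(ValueError):
            PayoffScheme(target=750.0, margin_fraction=1.5)
        with pytest.raises(ValueError):
            PayoffScheme(target=750.0, gain_early=3.0)


class TestProbabilities:
    def test_symmetric_aim_at_target(self, timing_schemes):
        r = GaussianResponder(aim=750.0, sigma=123.0)
        p_early, p_hit, p_late = ra.response_probabilities(r, timing_schemes["1"])
        assert p_early == pytest.approx(p_late)

    def test_degenerate_low_noise_limit(self, timing_schemes):
        r = GaussianResponder(aim=750.0, sigma=1e-6)
        p = ra.response_probabilities(r, timing_schemes["1"])
        assert p == pytest.approx((0.0, 1.0, 0.0), abs=1e-12)

    def test_hit_probability_against_quadrature(self, timing_schemes):
        # p_hit for S=750, sigma=100 equals the mass of N(750, 100^2) in
        # [525, 975]; frozen from the quadrature oracle.
        r = GaussianResponder(aim=750.0, sigma=100.0)
        _, p_hit, _ = ra.response_probabilities(r, timing_schemes["1"])
        mass, _ = quad(lambda x: norm.pdf(x, 750, 100), 525, 975)
        assert p_hit == pytest.approx(mass, abs=1e-9)
        assert p_hit == pytest.approx(0.9755510546899107, abs=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(
        aim=st.floats(1.0, 3000.0),
        sigma=st.floats(0.1, 500.0),
        block=st.sampled_from(["1", "2", "3", "4", "5"]),
    )
    def test_probabilities_sum_to_one(self, timing_schemes, aim, sigma, block):
        p = ra.response_probabilities(
            GaussianResponder(aim=aim, sigma=sigma), timing_schemes[block]
        )
        assert sum(p) == pytest.approx(1.0, abs=1e-12)
        assert all(0.0 <= q <= 1.0 for q in p)


class TestExpectedGain:
    def test_precise_responder_earns_full_reward(self, timing_schemes):
        for block in ("1", "2", "3", "4", "5"):
            r = GaussianResponder(aim=750.0, sigma=0.01)
            assert ra.expected_gain(r, timing_schemes[block]) == pytest.approx(5.0)

    def test_all_zero_gains_give_zero(self):
        scheme = PayoffScheme(target=750.0, gain_hit=0.0)
        for aim, sigma in [(500, 50), (750, 100), (1100, 300)]:
            assert ra.expected_gain(GaussianResponder(aim, sigma), scheme) == 0.0

    def test_matches_quadrature_oracle(self, timing_schemes):
        # zero-penalty scheme at S=750, sigma=100: EG = 5 * (2 Phi(2.25) - 1)
        r = GaussianResponder(aim=750.0, sigma=100.0)
        eg = ra.expected_gain(r, timing_schemes["1"])
        assert eg == pytest.approx(eg_quadrature(750, 100, timing_schemes["1"]), abs=1e-7)
        assert eg == pytest.approx(4.877755273449554, abs=1e-9)

    @pytest.mark.parametrize("block", ["2", "4"])
    @pytest.mark.parametrize("aim,sigma", [(700.0, 80.0), (800.0, 150.0), (900.0, 60.0)])
    def test_penalty_schemes_match_quadrature(self, timing_schemes, block, aim, sigma):
        eg = ra.expected_gain(GaussianResponder(aim, sigma), timing_schemes[block])
        assert eg == pytest.approx(eg_quadrature(aim, sigma, timing_schemes[block]), abs=1e-7)

    @settings(derandomize=True, max_examples=100)
    @given(aim=st.floats(100.0, 2000.0), sigma=st.floats(1.0, 400.0))
    def test_bounded_by_extreme_gains(self, timing_schemes, aim, sigma):
        scheme = timing_schemes["4"]
        eg = ra.expected_gain(GaussianResponder(aim, sigma), scheme)
        assert scheme.gain_early - 1e-9 <= eg <= scheme.gain_hit + 1e-9

    def test_dimensional_neutrality(self):
        # rescaling target, aim and sigma by a common factor leaves
        # probabilities and EG unchanged (ms task vs mm task symmetry)
        for factor in (55.0 / 750.0, 10.0):
            a = PayoffScheme(target=750.0, gain_early=-30.0)
            b = PayoffScheme(target=750.0 * factor, gain_early=-30.0)
            for aim, sigma in [(700, 80), (820, 150)]:
                pa = ra.response_probabilities(GaussianResponder(aim, sigma), a)
                pb = ra.response_probabilities(
                    GaussianResponder(aim * factor, sigma * factor), b
                )
                assert pa == pytest.approx(pb, abs=1e-12)


class TestOptimalAim:
    def test_zero_penalty_optimum_is_target(self, timing_schemes, distance_schemes):
        for sigma in (10.0, 50.0, 100.0, 250.0):
            assert ra.optimal_aim(sigma, timing_schemes["1"]) == 750.0
        assert ra.optimal_aim(5.0, distance_schemes["1"]) == 55.0

    def test_nonpositive_sigma_rejected(self, timing_schemes):
        with pytest.raises(ValueError):
            ra.optimal_aim(0.0, timing_schemes["1"])
        with pytest.raises(ValueError):
            ra.optimal_aim(-5.0, timing_schemes["4"])

    @pytest.mark.parametrize("block", ["2", "4"])
    @pytest.mark.parametrize("sigma", [25.0, 50.0, 100.0, 200.0, 300.0])
    def test_matches_grid_search_oracle(self, timing_schemes, block, sigma):
        scheme = timing_schemes[block]
        s_star = ra.optimal_aim(sigma, scheme)
        s_grid, eg_grid = grid_search_optimal_aim(sigma, scheme)
        # the optimum value always matches; the location is only well posed
        # when the peak is sharp (at small sigma the EG surface has a wide
        # plateau of near-maximal aims and the tie-break picks the target)
        assert ra.max_expected_gain(sigma, scheme) == pytest.approx(eg_grid, abs=1e-4)
        if sigma >= 50.0:
            assert s_star == pytest.approx(s_grid, abs=0.5)

    def test_penalty_shifts_aim_late(self, timing_schemes):
        s5 = ra.optimal_aim(100.0, timing_schemes["2"])
        s30 = ra.optimal_aim(100.0, timing_schemes["4"])
        assert 750.0 < s5 < s30

    def test_aim_nondecreasing_in_penalty_and_sigma(self):
        sigmas = [25.0, 50.0, 100.0, 150.0, 200.0, 250.0, 300.0]
        for sigma in (50.0, 150.0):
            aims = [
                ra.optimal_aim(sigma, PayoffScheme(target=750.0, gain_early=-g))
                for g in (0.0, 5.0, 15.0, 30.0, 60.0)
            ]
            assert all(b - a >= -0.1 for a, b in zip(aims, aims[1:]))
        for block in ("2", "4"):
            scheme = ra.timing_scheme(block)
            aims = [ra.optimal_aim(s, scheme) for s in sigmas]
            assert all(b - a >= -0.1 for a, b in zip(aims, aims[1:]))

    def test_max_gain_nonincreasing_in_sigma(self):
        for block in ("1", "2", "3", "4", "5"):
            scheme = ra.timing_scheme(block)
            assert ra.max_expected_gain(50.0, scheme) >= ra.max_expected_gain(200.0, scheme) - 1e-9

    def test_low_noise_limit_approaches_full_reward(self, timing_schemes):
        assert ra.max_expected_gain(0.01, timing_schemes["4"]) == pytest.approx(5.0)
        for sigma in (1.0, 10.0, 100.0):
            assert ra.max_expected_gain(sigma, timing_schemes["4"]) <= 5.0
        assert ra.max_expected_gain(100.0, timing_schemes["4"]) < 5.0


class TestRewardSurface:
    def test_zero_penalty_ridge_constant_at_target(self, timing_schemes):
        surf = ra.reward_surface(np.linspace(25, 300, 12), np.linspace(400, 1200, 33),
                                 timing_schemes["1"])
        assert np.allclose(surf.optimal_ridge, 750.0)

    def test_penalty_ridge_nondecreasing_and_matches_oracle(self, timing_schemes):
        sigma_grid = np.linspace(25, 300, 12)
        surf = ra.reward_surface(sigma_grid, np.linspace(400, 1500, 45), timing_schemes["4"])
        assert np.all(np.diff(surf.optimal_ridge) >= -0.1)
        for sig, ridge in zip(sigma_grid[::4], surf.optimal_ridge[::4]):
            _, eg_grid = grid_search_optimal_aim(sig, timing_schemes["4"])
            eg_ridge = ra.expected_gain(
                ra.GaussianResponder(float(ridge), float(sig)), timing_schemes["4"])
            assert eg_ridge == pytest.approx(eg_grid, abs=1e-4)

    def test_cells_bounded_by_gains(self, timing_schemes):
        scheme = timing_schemes["4"]
        surf = ra.reward_surface(np.linspace(25, 300, 8), np.linspace(300, 1500, 25), scheme)
        assert surf.expected_points.min() >= scheme.gain_early - 1e-9
        assert surf.expected_points.max() <= scheme.gain_hit + 1e-9

    def test_bad_grids_rejected(self, timing_schemes):
        with pytest.raises(ValueError):
            ra.reward_surface(np.array([]), np.array([700.0, 800.0]), timing_schemes["1"])
        with pytest.raises(ValueError):
            ra.reward_surface(np.array([100.0, 50.0]), np.array([700.0, 800.0]),
                              timing_schemes["1"])
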