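"""Closed-form forces, slip/tilt criteria, interval finding, classification."""

import math

import numpy as np
import pytest

from railfall import (
    Anthropometry,
    ForceDemand,
    Posture,
    RailingScenario,
    StabilityCategory,
    anti_slip_holds,
    anti_tilt_holds,
    arcsin_branch_pair,
    classify_posture,
    derive_segments,
    force_demand,
    friction_demand,
    ground_reaction,
    slip_beta_interval,
    slip_threshold_sine,
    split_weights,
    tilt_beta_interval,
    tilt_threshold_sine,
)

BETA_DOMAIN = (0.0, math.radians(130.0))


def brute_force_slip_set(anthro, scenario, alpha, n=130001):
    """Independent oracle: dense evaluation of the primitive slip inequality.

    Writes the force expressions out explicitly instead of calling the
    library's margin functions.
    """
    geom = derive_segments(anthro, scenario, alpha)
    w = split_weights(anthro, geom)
    a, b = anthro.cog_fraction_lower, anthro.cog_fraction_upper
    g1, g2 = w.lower_weight, w.upper_weight
    r = geom.upper_length / geom.lower_length
    beta = np.linspace(BETA_DOMAIN[0], BETA_DOMAIN[1], n)
    sab = np.sin(alpha + beta)
    f = (a * g1 * np.sin(alpha) + g2 * np.sin(alpha) + b * g2 * r * sab) * np.cos(alpha)
    grf = g1 * (1 - a * np.sin(alpha) ** 2) + g2 * (
        np.cos(alpha) ** 2 - b * r * np.sin(alpha) * sab
    )
    mu = scenario.friction_coefficient
    return beta, f > mu * grf


class TestClosedForms:
    def test_upright_grf_is_total_weight(self, case_anthro, scenario_low_friction):
        geom = derive_segments(case_anthro, scenario_low_friction, 0.0)
        w = split_weights(case_anthro, geom)
        for beta_deg in (0.0, 45.0, 120.0):
            p = Posture.from_degrees(0.0, beta_deg)
            assert ground_reaction(case_anthro, w, geom, p) == pytest.approx(
                w.total, rel=1e-12
            )

    def test_friction_demand_vanishes_for_straight_vertical_rod(
        self, case_anthro, scenario_low_friction
    ):
        geom = derive_segments(case_anthro, scenario_low_friction, 0.0)
        w = split_weights(case_anthro, geom)
        assert friction_demand(case_anthro, w, geom, Posture(0.0, 0.0)) == 0.0

    def test_friction_demand_horizontal_upper_segment(
        self, case_anthro, scenario_low_friction
    ):
        # alpha=0, beta=90 deg: only the upper COG offset loads the feet
        geom = derive_segments(case_anthro, scenario_low_friction, 0.0)
        w = split_weights(case_anthro, geom)
        expected = (
            case_anthro.cog_fraction_upper
            * w.upper_weight
            * geom.upper_length
            / geom.lower_length
        )
        assert friction_demand(
            case_anthro, w, geom, Posture.from_degrees(0.0, 90.0)
        ) == pytest.approx(expected, rel=1e-12)

    def test_invalid_geometry_rejected(self, case_anthro, scenario_low_friction):
        geom = derive_segments(case_anthro, scenario_low_friction, math.radians(60.0))
        w_ok = derive_segments(case_anthro, scenario_low_friction, 0.0)
        weights = split_weights(case_anthro, w_ok)
        with pytest.raises(ValueError):
            ground_reaction(case_anthro, weights, geom, Posture(0.0, 0.0))


class TestCriteria:
    @pytest.mark.parametrize(
        "f, grf, mu, expected",
        [
            (0.0, 100.0, 0.2, True),
            (60.0, 100.0, 0.7, True),
            (80.0, 100.0, 0.7, False),
            (70.0, 100.0, 0.7, True),  # boundary F = mu*GRF is anti-slip
        ],
    )
    def test_anti_slip_inequality(self, f, grf, mu, expected):
        assert anti_slip_holds(ForceDemand(grf, f), mu) is expected

    def test_anti_tilt_at_zero_lean(self, case_anthro, scenario_low_friction):
        # alpha = 0: the threshold is beta = 0, so any flexion tips,
        # while the straight posture balances exactly
        geom = derive_segments(case_anthro, scenario_low_friction, 0.0)
        w = split_weights(case_anthro, geom)
        assert anti_tilt_holds(case_anthro, w, geom, Posture(0.0, 0.0))
        assert not anti_tilt_holds(
            case_anthro, w, geom, Posture(0.0, math.radians(1.0))
        )

    def test_case_posture_is_inside_tilt_interval(
        self, case_anthro, scenario_low_friction, alpha_10
    ):
        geom = derive_segments(case_anthro, scenario_low_friction, alpha_10)
        w = split_weights(case_anthro, geom)
        assert not anti_tilt_holds(
            case_anthro, w, geom, Posture.from_degrees(10.0, 80.0)
        )


class TestBranchPair:
    @pytest.mark.parametrize(
        "beta1_deg, alpha_deg, beta2_deg",
        [(30.0, 10.0, 130.0), (50.0, 10.0, 110.0), (37.0, 0.0, 143.0)],
    )
    def test_second_branch(self, beta1_deg, alpha_deg, beta2_deg):
        pair = arcsin_branch_pair(math.radians(beta1_deg), math.radians(alpha_deg))
        assert math.degrees(pair.beta_2) == pytest.approx(beta2_deg, abs=1e-10)
        alpha = math.radians(alpha_deg)
        assert math.sin(pair.beta_1 + alpha) == pytest.approx(
            math.sin(pair.beta_2 + alpha), abs=1e-12
        )


class TestIntervals:
    def test_slip_interval_high_friction_empty(
        self, case_anthro, scenario_high_friction, alpha_10
    ):
        iv = slip_beta_interval(case_anthro, scenario_high_friction, alpha_10)
        assert iv.is_empty
        # and the closed-form arcsin argument confirms: > 1
        assert slip_threshold_sine(case_anthro, scenario_high_friction, alpha_10) > 1.0

    def test_slip_interval_low_friction_matches_brute_force(
        self, case_anthro, scenario_low_friction, alpha_10
    ):
        iv = slip_beta_interval(case_anthro, scenario_low_friction, alpha_10)
        beta, unstable = brute_force_slip_set(
            case_anthro, scenario_low_friction, alpha_10
        )
        lo_oracle = beta[unstable][0]
        assert not iv.is_empty
        assert math.degrees(iv.lower) == pytest.approx(
            math.degrees(lo_oracle), abs=2e-3
        )
        # frozen from the brute-force oracle; upper end clipped by the domain
        assert math.degrees(iv.lower) == pytest.approx(21.517, abs=2e-3)
        assert iv.upper == pytest.approx(BETA_DOMAIN[1], abs=1e-12)
        assert unstable[-1]  # condition still holds at the domain edge

    def test_tilt_interval_matches_printed_endpoints(
        self, case_anthro, scenario_low_friction, alpha_10
    ):
        iv = tilt_beta_interval(case_anthro, scenario_low_friction, alpha_10)
        assert round(math.degrees(iv.lower)) == 50
        assert round(math.degrees(iv.upper)) == 110

    def test_tilt_interval_zero_lean_tips_for_any_flexion(
        self, case_anthro, scenario_low_friction
    ):
        iv = tilt_beta_interval(case_anthro, scenario_low_friction, 0.0)
        assert iv.lower == pytest.approx(0.0, abs=1e-8)
        assert iv.upper == pytest.approx(BETA_DOMAIN[1], abs=1e-8)

    def test_tilt_interval_invariant_under_friction(
        self, case_anthro, scenario_low_friction, scenario_high_friction, alpha_10
    ):
        low = tilt_beta_interval(case_anthro, scenario_low_friction, alpha_10)
        high = tilt_beta_interval(case_anthro, scenario_high_friction, alpha_10)
        assert low == high  # bit-identical dataclasses

    def test_slip_intervals_nested_decreasing_in_friction(
        self, case_anthro, alpha_10
    ):
        widths = []
        for mu in (0.05, 0.1, 0.15, 0.2, 0.3):
            iv = slip_beta_interval(
                case_anthro, RailingScenario(0.92, mu), alpha_10
            )
            widths.append(iv.width())
        assert all(w1 >= w2 for w1, w2 in zip(widths, widths[1:]))
        assert widths[-1] == 0.0  # interval already empty at mu = 0.3
        # containment, not just width: lower endpoints increase with mu
        iv1 = slip_beta_interval(case_anthro, RailingScenario(0.92, 0.05), alpha_10)
        iv2 = slip_beta_interval(case_anthro, RailingScenario(0.92, 0.15), alpha_10)
        assert iv1.lower <= iv2.lower and iv1.upper >= iv2.upper

    def test_branch_identity_for_interior_endpoints(self, case_anthro):
        """Where both endpoints are interior, beta2 = pi - beta1 - 2*alpha."""
        scenario = RailingScenario(0.92, 0.2)
        # interior endpoints exist only in a narrow alpha band (~8-11 deg):
        # below it the upper branch leaves the beta domain, above it the
        # tilt arcsin argument exceeds 1 and the interval is empty
        for alpha_deg in (8.0, 9.0, 10.0, 11.0):
            alpha = math.radians(alpha_deg)
            iv = tilt_beta_interval(case_anthro, scenario, alpha)
            if iv.is_empty or iv.upper >= BETA_DOMAIN[1] - 1e-9:
                continue
            assert iv.upper == pytest.approx(
                math.pi - iv.lower - 2 * alpha, abs=1e-8
            )

    def test_closed_form_endpoints_match_scan(self, case_anthro):
        """arcsin thresholds agree with scan+bisection where they apply."""
        for mu, alpha_deg in [(0.2, 5.0), (0.2, 10.0), (0.2, 25.0), (0.7, 40.0)]:
            scenario = RailingScenario(0.92, mu)
            alpha = math.radians(alpha_deg)
            arg_t = tilt_threshold_sine(case_anthro, scenario, alpha)
            iv = tilt_beta_interval(case_anthro, scenario, alpha)
            if -1.0 < arg_t < 1.0 and not iv.is_empty:
                beta1 = math.asin(arg_t) - alpha
                if iv.lower > 1e-9:
                    assert iv.lower == pytest.approx(beta1, abs=1e-8)
            arg_s = slip_threshold_sine(case_anthro, scenario, alpha)
            ivs = slip_beta_interval(case_anthro, scenario, alpha)
            if -1.0 < arg_s < 1.0 and not ivs.is_empty and ivs.lower > 1e-9:
                assert ivs.lower == pytest.approx(math.asin(arg_s) - alpha, abs=1e-8)


class TestClassification:
    @pytest.mark.parametrize(
        "mu, expected",
        [(0.2, StabilityCategory.FALL_POSSIBLE), (0.7, StabilityCategory.TILT_ONLY)],
    )
    def test_case_posture_classification(self, case_anthro, mu, expected):
        scenario = RailingScenario(0.92, mu)
        result = classify_posture(
            case_anthro, scenario, Posture.from_degrees(10.0, 80.0)
        )
        assert result.category is expected
        assert result.fall_possible is (expected is StabilityCategory.FALL_POSSIBLE)

    def test_straight_vertical_posture_is_stable(self, case_anthro):
        for mu in (0.0, 0.2, 0.7):
            result = classify_posture(
                case_anthro, RailingScenario(0.92, mu), Posture(0.0, 0.0)
            )
            assert result.category is StabilityCategory.STABLE

    def test_invalid_geometry_class(self, case_anthro, scenario_low_friction):
        result = classify_posture(
            case_anthro, scenario_low_friction, Posture.from_degrees(56.0, 10.0)
        )
        assert result.category is StabilityCategory.INVALID_GEOMETRY
        assert result.demand is None

    def test_classification_matches_intervals_on_beta_sweep(
        self, case_anthro, scenario_low_friction, alpha_10
    ):
        """FALL_POSSIBLE cells = slip interval intersected with tilt interval."""
        slip = slip_beta_interval(case_anthro, scenario_low_friction, alpha_10)
        tilt = tilt_beta_interval(case_anthro, scenario_low_friction, alpha_10)
        for beta_deg in np.arange(0.0, 130.5, 0.5):
            beta = math.radians(beta_deg)
            cat = classify_posture(
                case_anthro, scenario_low_friction, Posture(alpha_10, beta)
            ).category
            expected_fall = slip.contains(beta) and tilt.contains(beta)
            assert (cat is StabilityCategory.FALL_POSSIBLE) == expected_fall

    def test_force_demand_pair_consistent(self, case_anthro, scenario_low_friction):
        geom = derive_segments(case_anthro, scenario_low_friction, math.radians(10.0))
        w = split_weights(case_anthro, geom)
        p = Posture.from_degrees(10.0, 80.0)
        d = force_demand(case_anthro, w, geom, p)
        assert d.ground_reaction == ground_reaction(case_anthro, w, geom, p)
        assert d.friction_demand == friction_demand(case_anthro, w, geom, p)
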