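"""Likelihood core: background odds, probability thresholds, integrated
binomial areas, the LR, and its conversion to exponent points and bands."""

import math

import mpmath
import numpy as np
import pytest
from hypothesis import given, strategies as st

from ps4lr import (
    CaseControlCounts,
    DegenerateTableError,
    NoCarriersError,
    Ps4lrError,
    Strength,
    TargetORPair,
    background_case_odds,
    combine_eps,
    compute_lr,
    ep_to_strength,
    likelihood_area,
    log_likelihood_area,
    lr_to_ep,
    probability_under_or,
)


def quadrature_oracle_log(k: int, n: int, p_lo: float, p_hi: float) -> float:
    """Independent oracle: adaptive (tanh-sinh) quadrature of the raw
    binomial integrand; returns the natural log.

    Precision is escalated until the quadrature's own error estimate is
    negligible relative to the value: narrow extreme-tail intervals need the
    extra node density that comes with higher working precision.
    """
    for dps in (40, 120, 300, 600):
        with mpmath.mp.workdps(dps):
            coef = mpmath.binomial(n, k)
            f = lambda p: coef * p**k * (1 - p) ** (n - k)
            points = [p_lo, p_hi]
            mode = k / n
            if p_lo < mode < p_hi:
                points = [p_lo, mode, p_hi]
            val, err = mpmath.quad(f, points, error=True)
            if val > 0 and err < 1e-15 * val:
                return float(mpmath.log(val))
    return float(mpmath.log(val)) if val > 0 else -math.inf


class TestBackgroundCaseOdds:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            (CaseControlCounts(10, 10_000, 2, 10_000), 9990 / 9998),
            (CaseControlCounts(10, 10_000, 10, 10_000), 1.0),
            (CaseControlCounts(2, 30, 2, 300_000), 28 / 299_998),
        ],
    )
    def test_observed_noncarrier_odds(self, counts, expected):
        assert background_case_odds(counts) == pytest.approx(expected, rel=1e-12)

    def test_every_individual_a_carrier_is_degenerate(self):
        with pytest.raises(DegenerateTableError):
            background_case_odds(CaseControlCounts(5, 5, 2, 100))
        with pytest.raises(DegenerateTableError):
            background_case_odds(CaseControlCounts(2, 100, 7, 7))


class TestProbabilityUnderOr:
    @pytest.mark.parametrize(
        "odds, target, expected",
        [
            (1.0, 1.0, 0.5),
            (1.0, 5.0, 5 / 6),
            # closed form: (9990/9998)*5 / (1 + (9990/9998)*5) = 0.8332224…
            (9990 / 9998, 5.0, 0.833222),
        ],
    )
    def test_scaled_odds_to_probability(self, odds, target, expected):
        assert probability_under_or(odds, target) == pytest.approx(expected, abs=5e-7)

    @pytest.mark.parametrize("odds, target", [(0.0, 1.0), (1.0, 0.0), (-1.0, 2.0), (1.0, math.inf)])
    def test_nonpositive_or_nonfinite_inputs_rejected(self, odds, target):
        with pytest.raises(Ps4lrError):
            probability_under_or(odds, target)

    @given(
        # ranges kept away from logistic saturation (|log odds·OR| < ~30),
        # where strictness is genuinely lost to double rounding
        odds=st.floats(1e-4, 1e2),
        target=st.floats(1e-4, 1e2),
        factor=st.floats(1.01, 10.0),
    )
    def test_strictly_increasing_in_both_arguments(self, odds, target, factor):
        base = probability_under_or(odds, target)
        assert probability_under_or(odds * factor, target) > base
        assert probability_under_or(odds, target * factor) > base

    def test_extreme_products_stay_in_open_interval(self):
        # products far outside double comfort must not saturate to exactly 0/1
        assert 0 < probability_under_or(1e-6, 1e-6) < 1e-10
        assert 1 - 1e-10 < probability_under_or(1e6, 1e6) < 1


class TestLikelihoodArea:
    @pytest.mark.parametrize("k", [0, 5, 12])
    def test_full_interval_area_is_reciprocal_n_plus_one(self, k):
        assert likelihood_area(k, 12, 0, 1) == pytest.approx(1 / 13, rel=1e-12)

    def test_half_interval_linear_integrand(self):
        # 2 * integral of p dp over [0, 0.5] = 0.25; with C(1,1)=1 coefficient
        # the integrand is p itself
        assert likelihood_area(1, 1, 0, 0.5, include_coefficient=False) == pytest.approx(
            0.125, rel=1e-12
        )

    def test_agrees_with_adaptive_quadrature(self):
        impl = log_likelihood_area(10, 12, 0.833278, 1.0)
        oracle = quadrature_oracle_log(10, 12, 0.833278, 1.0)
        assert math.exp(impl - oracle) == pytest.approx(1.0, rel=1e-8)

    @pytest.mark.parametrize(
        "k, n, lo, hi",
        [(5, 4, 0, 1), (0, 0, 0, 1), (1, 2, 0.7, 0.3), (1, 2, -0.1, 0.5), (1, 2, 0.5, 1.1)],
    )
    def test_invalid_inputs_rejected(self, k, n, lo, hi):
        with pytest.raises(Ps4lrError):
            likelihood_area(k, n, lo, hi)

    @given(n=st.integers(1, 500), frac=st.floats(0, 1))
    def test_area_conservation(self, n, frac):
        k = min(int(frac * (n + 1)), n)
        assert likelihood_area(k, n, 0, 1) * (n + 1) == pytest.approx(1.0, rel=1e-12)

    def test_log_space_path_survives_underflowing_tails(self):
        # closed form: area over [0.999, 1] for k=0 is 0.001^501 / 501,
        # ~1e-1506 — far below double range, finite only in log space
        got = log_likelihood_area(0, 500, 0.999, 1.0)
        expected = 501 * math.log(1e-3) - math.log(501)
        assert got == pytest.approx(expected, rel=1e-9)
        assert likelihood_area(0, 500, 0.999, 1.0) == 0.0  # linear scale underflows

    def test_oracle_sweep_random_instances(self):
        rng = np.random.default_rng(20240901)
        checked = 0
        while checked < 200:
            n = int(rng.integers(1, 201))
            k = int(rng.integers(0, n + 1))
            lo, hi = sorted(rng.uniform(0, 1, size=2))
            if hi - lo < 1e-6:
                continue
            impl = log_likelihood_area(k, n, lo, hi)
            oracle = quadrature_oracle_log(k, n, lo, hi)
            assert math.exp(impl - oracle) == pytest.approx(1.0, rel=1e-8), (k, n, lo, hi)
            checked += 1


class TestComputeLr:
    @pytest.mark.parametrize(
        "counts, targets, lr, ep",
        [
            (CaseControlCounts(10, 10_000, 2, 10_000), TargetORPair(5, 1), 33.28, 4.8),
            (CaseControlCounts(10, 10_000, 10, 10_000), TargetORPair(5, 1), 3.75e-4, -10.8),
            (CaseControlCounts(2, 300, 20, 300_000), TargetORPair(1000, 1), 20.63, 4.1),
            (CaseControlCounts(12, 10_000, 6, 10_000), TargetORPair(2, 1), 5.5, 2.3),
        ],
    )
    def test_reference_scenarios(self, counts, targets, lr, ep):
        result = compute_lr(counts, targets)
        assert result.lr == pytest.approx(lr, rel=5e-3)
        assert result.ep == pytest.approx(ep, abs=0.05)

    def test_no_carriers_is_an_error(self):
        with pytest.raises(NoCarriersError, match="no variant observations"):
            compute_lr(CaseControlCounts(0, 100, 0, 100), TargetORPair(5, 1))

    def test_degenerate_noncarriers_propagates(self):
        with pytest.raises(DegenerateTableError):
            compute_lr(CaseControlCounts(30, 30, 2, 100), TargetORPair(5, 1))

    def test_binomial_coefficient_cancels_in_ratio(self, scenario1_counts, default_targets):
        with_coef = compute_lr(scenario1_counts, default_targets, include_coefficient=True)
        without = compute_lr(scenario1_counts, default_targets, include_coefficient=False)
        assert with_coef.log_lr == pytest.approx(without.log_lr, rel=1e-12, abs=1e-12)

    def test_strictly_increasing_in_case_carriers(self):
        # grid over k with the control column fixed
        log_lrs = [
            compute_lr(CaseControlCounts(k, 10_000, 2, 10_000), TargetORPair(5, 1)).log_lr
            for k in range(0, 31)
        ]
        assert all(b > a for a, b in zip(log_lrs, log_lrs[1:]))

    @pytest.mark.parametrize(
        "counts",
        [
            CaseControlCounts(2, 10_000, 4, 10_000),
            CaseControlCounts(2, 10_000, 10, 10_000),
            CaseControlCounts(1, 1_000, 30, 10_000),
        ],
    )
    def test_protective_direction_gives_benign_evidence(self, counts):
        result = compute_lr(counts, TargetORPair(5, 1))
        assert result.lr < 1 and result.ep < 0

    def test_zero_control_carriers_handled_without_correction(self):
        # k = n: the non-association area is the tiny lower tail; no
        # continuity correction is needed or applied
        result = compute_lr(CaseControlCounts(5, 300, 0, 300_000), TargetORPair(10, 1))
        assert math.isfinite(result.log_lr) and result.log_lr > 0

    def test_default_targets_are_five_versus_one(self, scenario1_counts):
        assert compute_lr(scenario1_counts).lr == pytest.approx(33.28, rel=5e-3)

    def test_regions_identities(self, scenario1_counts, default_targets):
        regions = compute_lr(scenario1_counts, default_targets).regions
        n = scenario1_counts.carrier_total
        assert regions.area_total == pytest.approx(1 / (n + 1), rel=1e-12)
        assert regions.area_assoc + regions.area_nonassoc <= regions.area_total * (1 + 1e-12)
        assert regions.p_nonassoc < regions.p_assoc


class TestEpConversion:
    @pytest.mark.parametrize(
        "lr, ep, tol",
        [(33.28, 4.79, 0.005), (1.0, 0.0, 1e-12), (350.4, 8.0, 0.01)],
    )
    def test_log_base_2_08(self, lr, ep, tol):
        assert lr_to_ep(lr) == pytest.approx(ep, abs=tol)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_lr_rejected(self, bad):
        with pytest.raises(Ps4lrError):
            lr_to_ep(bad)

    def test_exactly_one_input_form(self):
        with pytest.raises(Ps4lrError):
            lr_to_ep(2.0, log_lr=0.5)
        with pytest.raises(Ps4lrError):
            lr_to_ep()

    @pytest.mark.parametrize("exponent", range(-20, 21, 4))
    def test_round_trip_over_forty_orders_of_magnitude(self, exponent):
        x = 10.0**exponent
        assert 2.08 ** lr_to_ep(log_lr=math.log(x)) == pytest.approx(x, rel=1e-10)


class TestStrengthBands:
    @pytest.mark.parametrize(
        "ep, band",
        [
            (9.0, Strength.VERY_STRONG_PATHOGENIC),
            (8.0, Strength.VERY_STRONG_PATHOGENIC),
            (4.8, Strength.STRONG_PATHOGENIC),
            (4.0, Strength.STRONG_PATHOGENIC),
            (2.3, Strength.MODERATE_PATHOGENIC),
            (1.0, Strength.SUPPORTING_PATHOGENIC),
            (0.5, Strength.NEUTRAL),
            (-0.99, Strength.NEUTRAL),
            (-1.0, Strength.SUPPORTING_BENIGN),
            (-2.6, Strength.MODERATE_BENIGN),
            (-4.0, Strength.STRONG_BENIGN),
            (-8.0, Strength.VERY_STRONG_BENIGN),
            (-21.4, Strength.VERY_STRONG_BENIGN),
        ],
    )
    def test_band_boundaries(self, ep, band):
        assert ep_to_strength(ep) is band

    def test_band_boundaries_match_lr_table(self):
        # LR boundaries 2.08, 4.33, 18.72, 350.4 map to EP 1, 2, 4, 8
        for lr, ep in [(2.08, 1), (4.33, 2), (18.72, 4), (350.4, 8)]:
            assert lr_to_ep(lr) == pytest.approx(ep, abs=0.01)

    def test_nonfinite_rejected(self):
        with pytest.raises(Ps4lrError):
            ep_to_strength(math.inf)


class TestCombineEps:
    def test_sum_and_empty(self):
        assert combine_eps([4.8, -2.6]) == pytest.approx(2.2)
        assert combine_eps([]) == 0.0

    def test_sum_equals_log_of_lr_product(self):
        ep = lr_to_ep(33.28)
        combined = combine_eps([ep, ep])
        assert combined == pytest.approx(2 * ep)
        assert 2.08**combined == pytest.approx(33.28**2, rel=1e-10)
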