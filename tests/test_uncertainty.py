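"""Duplicate statistics, propagation components and the budget."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pocpipe.synthetic import simulate_duplicate_pairs
from pocpipe.uncertainty import (assemble_budget, calibration_uncertainty,
                                 contamination_uncertainty,
                                 estimate_mass_correlation, estimate_sigma_r,
                                 robust_sd, scaled_difference,
                                 sigma_c_experimental, sigma_c_volume,
                                 volume_uncertainty)

SQRT2 = math.sqrt(2.0)


class TestScaledDifference:
    def test_equal_pair_is_zero(self):
        delta, delta_r = scaled_difference(10.0, 10.0)
        assert delta == 0.0 and delta_r == 0.0

    def test_hand_example(self):
        delta, delta_r = scaled_difference(12.0, 10.0)
        assert delta == pytest.approx(SQRT2)
        assert delta_r == pytest.approx(SQRT2 / 11.0)

    def test_zero_mean_flagged_nan(self):
        _, delta_r = scaled_difference(5.0, -5.0)
        assert np.isnan(delta_r)

    @given(st.floats(1e-3, 1e3), st.floats(0.1, 100), st.floats(0.1, 100))
    @settings(max_examples=50, deadline=None)
    def test_relative_difference_is_scale_free(self, c, d1, d2):
        _, base = scaled_difference(d1, d2)
        _, scaled = scaled_difference(c * d1, c * d2)
        assert scaled == pytest.approx(base, rel=1e-9)


class TestRobustSd:
    def test_constant_vector_is_zero(self):
        assert robust_sd([3.0] * 10) == 0.0

    def test_standard_normal_approaches_z84(self, rng):
        draws = rng.standard_normal(1_000_000)
        # z(0.84) = 0.99446; 3 Monte-Carlo SEs of the estimator ~ 0.004
        assert robust_sd(draws) == pytest.approx(0.994457883, abs=0.004)

    def test_hand_computed_decade(self):
        # percentiles of 1..10 by linear interpolation: P84=8.56, P16=2.44
        assert robust_sd(range(1, 11)) == pytest.approx(3.06)

    def test_brute_force_percentile_oracle(self, rng):
        def oracle(v):
            v = np.sort(np.asarray(v, dtype=float))
            out = []
            for q in (0.16, 0.84):
                pos = q * (v.size - 1)
                lo = int(math.floor(pos))
                hi = min(lo + 1, v.size - 1)
                out.append(v[lo] + (pos - lo) * (v[hi] - v[lo]))
            return (out[1] - out[0]) / 2.0

        for _ in range(100):
            v = rng.normal(0, rng.uniform(0.1, 10), rng.integers(2, 40))
            assert robust_sd(v) == pytest.approx(oracle(v), abs=1e-12)

    def test_requires_two_finite_values(self):
        with pytest.raises(ValueError):
            robust_sd([1.0])
        with pytest.raises(ValueError):
            robust_sd([1.0, np.nan])


class TestSigmaR:
    def test_recovery_of_known_noise(self, rng):
        pairs = simulate_duplicate_pairs(500, 0.12, rng)
        sigma_r, _ = estimate_sigma_r(pairs, by_zone=True)
        assert sigma_r["productive"] == pytest.approx(0.12, abs=0.015)

    def test_identical_duplicates_give_zero(self):
        pairs = pd.DataFrame(dict(d1=[5.0, 7.0, 9.0], d2=[5.0, 7.0, 9.0],
                                  zone="productive"))
        sigma_r, _ = estimate_sigma_r(pairs)
        assert sigma_r["productive"] == 0.0

    def test_excluded_pairs_ignored(self, rng):
        good = simulate_duplicate_pairs(200, 0.10, rng)
        bad = simulate_duplicate_pairs(200, 0.80, rng)
        bad["excluded"] = True
        sigma_r, _ = estimate_sigma_r(pd.concat([good, bad]))
        assert sigma_r["productive"] == pytest.approx(0.10, abs=0.02)

    def test_empty_zone_raises(self):
        pairs = pd.DataFrame(dict(d1=[5.0], d2=[5.1], zone="productive"))
        with pytest.raises(ValueError, match="productive"):
            estimate_sigma_r(pairs)

    def test_diagnostics_show_delta_scaling(self, rng):
        # absolute differences grow with concentration, relative ones do not
        pairs = simulate_duplicate_pairs(400, 0.2, rng, spread=1.0)
        _, diag = estimate_sigma_r(pairs)
        row = diag.iloc[0]
        assert row["r_delta"] > 0.3
        assert abs(row["r_delta_r"]) < row["r_delta"]


class TestComponents:
    def test_sigma_c_experimental(self):
        assert sigma_c_experimental(10.0, 0.12) == pytest.approx(1.2)
        assert sigma_c_experimental(0.0, 0.12) == 0.0
        assert sigma_c_experimental(7.0, 0.35) == pytest.approx(2.45)

    def test_volume_uncertainty_quadrature(self):
        assert volume_uncertainty(1) == pytest.approx(0.010)
        assert volume_uncertainty(4) == pytest.approx(0.020)
        with pytest.raises(ValueError):
            volume_uncertainty(0)

    def test_sigma_c_volume(self):
        assert sigma_c_volume(47.0, 4.0, 0.020) == pytest.approx(0.05875)
        assert sigma_c_volume(47.0, 4.0, 0.0) == 0.0
        with pytest.raises(ValueError):
            sigma_c_volume(47.0, 0.0, 0.01)

    def test_calibration_uncertainty_limits(self):
        assert calibration_uncertainty(2.0, 2.0, 1.0, 4.0) == 0.0
        assert calibration_uncertainty(3.0, 4.0, 0.0, 2.0) == \
            pytest.approx(5.0 / 2.0)
        assert calibration_uncertainty(2.0, 2.0, 0.5, 4.0) == \
            pytest.approx(0.5)
        with pytest.raises(ValueError):
            calibration_uncertainty(1.0, 1.0, 1.5, 4.0)

    @given(st.floats(0, 5), st.floats(0, 5), st.floats(-1, 1),
           st.floats(0.5, 8))
    @settings(max_examples=100, deadline=None)
    def test_calibration_uncertainty_symmetric_nonnegative(self, s1, s2, r, v):
        a = calibration_uncertainty(s1, s2, r, v)
        b = calibration_uncertainty(s2, s1, r, v)
        assert a == pytest.approx(b, rel=1e-9, abs=1e-12)
        assert a >= 0.0

    def test_contamination_uncertainty_hand_example(self):
        # blanks {3,4,5} ug, V=4 L: sigma_eta = 1/sqrt(3), sqrt(2)*sigma_eta/V
        val = contamination_uncertainty([3.0, 4.0, 5.0], 4.0)
        assert val == pytest.approx(SQRT2 / math.sqrt(3.0) / 4.0)
        assert val == pytest.approx(0.2041, abs=2e-4)

    def test_contamination_identical_blanks_zero_and_volume_scaling(self):
        assert contamination_uncertainty([4.0, 4.0, 4.0], 4.0) == 0.0
        v1 = contamination_uncertainty([3.0, 4.0, 5.0], 2.0)
        v2 = contamination_uncertainty([3.0, 4.0, 5.0], 4.0)
        assert v1 == pytest.approx(2 * v2)
        with pytest.raises(ValueError):
            contamination_uncertainty([3.0], 4.0)


class TestMassCorrelation:
    def test_proportional_masses_give_unity(self):
        u = np.array([10.0, 20.0, 30.0, 40.0])
        assert estimate_mass_correlation(u, 0.2 * u) == pytest.approx(1.0)

    def test_anticorrelated_toy_set(self):
        assert estimate_mass_correlation([1, 2, 3], [3, 2, 1]) == \
            pytest.approx(-1.0)

    def test_independent_masses_near_zero(self, rng):
        n = 1000
        r = estimate_mass_correlation(rng.normal(50, 10, n),
                                      rng.normal(8, 2, n))
        assert abs(r) < 3 / math.sqrt(n)

    def test_pooled_fallback(self, rng):
        pooled = (rng.normal(50, 10, 100), rng.normal(8, 2, 100))
        r = estimate_mass_correlation([1.0, 2.0], [3.0, 4.0], pooled=pooled)
        assert r == pytest.approx(estimate_mass_correlation(*pooled))


class TestBudget:
    def test_single_component_share(self):
        b = assemble_budget(2.0, 0.5, 0.0, 0.0)
        assert b["u_v"].iloc[0] == pytest.approx(0.25)

    def test_linear_remainder_hand_example(self):
        b = assemble_budget(1.0, 0.03, 0.2, 0.03)
        assert b["unquantified_linear"].iloc[0] == pytest.approx(0.74)

    def test_all_zero_components_full_remainder(self):
        b = assemble_budget(1.5, 0.0, 0.0, 0.0)
        assert b["unquantified_linear"].iloc[0] == pytest.approx(1.0)
        assert b["unquantified_variance"].iloc[0] == pytest.approx(1.0)

    def test_nonpositive_sigma_c_flagged(self):
        b = assemble_budget([0.0, 1.0], [0.1, 0.1], [0.1, 0.1], [0.1, 0.1])
        assert bool(b["undefined"].iloc[0]) is True
        assert np.isnan(b["u_v"].iloc[0])
        assert bool(b["undefined"].iloc[1]) is False

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            assemble_budget(1.0, 0.1, 0.1, 0.1, residual_mode="geometric")
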