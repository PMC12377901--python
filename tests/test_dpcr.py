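"""Poisson occupancy estimation and the broken-fraction arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.proportion import proportion_confint

from dsbquant import (
    ClampWarning,
    ConsistencyWarning,
    DropletCounts,
    GatingInconsistencyError,
    SaturationError,
    ValidationError,
    calibrate_droplet_volume,
    estimate_lambda,
    lambda_to_concentration,
    quantify_dsb,
)
from dsbquant._util import round_half_up
from oracles import grid_mle_lambda

counts_strategy = st.integers(min_value=1, max_value=50_000).flatmap(
    lambda n: st.tuples(st.just(n), st.integers(min_value=0, max_value=n - 1))
)


class TestEstimateLambda:
    @pytest.mark.parametrize(
        "k, n, expected",
        [
            (0, 23_527, 0.0),  # empty chip
            (4_516, 23_527, 0.2131309),  # blue double population
            (2_844, 23_527, 0.1288366),  # green JEM1
            (2_863, 23_527, 0.1297556),  # blue JEM1
        ],
    )
    def test_point_estimate(self, k, n, expected):
        est = estimate_lambda(DropletCounts(n, k))
        assert est.lambda_hat == pytest.approx(expected, rel=1e-6)

    def test_matches_brute_force_likelihood_maximizer(self):
        rng = np.random.default_rng(42)
        for n in (2, 3, 10, 137, 1_000, 23_527):
            for k in sorted(set(rng.integers(0, n, size=8).tolist())):
                lam = estimate_lambda(DropletCounts(n, int(k))).lambda_hat
                assert lam == pytest.approx(grid_mle_lambda(int(k), n), rel=1e-4)

    def test_saturated_chip_raises(self):
        with pytest.raises(SaturationError):
            estimate_lambda(DropletCounts(23_527, 23_527))

    def test_invalid_counts_raise(self):
        with pytest.raises(ValidationError):
            DropletCounts(0, 0)
        with pytest.raises(ValidationError):
            DropletCounts(100, 101)
        with pytest.raises(ValidationError):
            DropletCounts(100, -1)

    def test_invalid_confidence_level(self):
        with pytest.raises(ValidationError):
            estimate_lambda(DropletCounts(100, 10), confidence_level=1.0)

    @given(counts_strategy, st.integers(min_value=1, max_value=1000))
    @settings(max_examples=200, deadline=None)
    def test_strictly_monotone_in_k(self, nk, delta):
        n, k = nk
        k2 = min(k + delta, n - 1)
        lam1 = estimate_lambda(DropletCounts(n, k)).lambda_hat
        lam2 = estimate_lambda(DropletCounts(n, k2)).lambda_hat
        assert (lam2 > lam1) == (k2 > k)

    @given(counts_strategy)
    @settings(max_examples=200, deadline=None)
    def test_ci_brackets_point_estimate(self, nk):
        n, k = nk
        for method in ("wilson", "clopper-pearson"):
            est = estimate_lambda(DropletCounts(n, k), ci_method=method)
            lo, hi = est.lambda_ci
            assert lo <= est.lambda_hat <= hi
            assert lo >= 0.0
        assert estimate_lambda(DropletCounts(n, 0)).lambda_ci[0] == 0.0

    def test_nominal_coverage_of_wilson_interval(self):
        """95% intervals on λ cover the truth 93–97% of the time."""
        rng = np.random.default_rng(2_024)
        n = 23_527
        reps = 2_000
        for lam in (0.05, 0.2, 1.0):
            k = rng.binomial(n, 1.0 - math.exp(-lam), size=reps)
            lo_p, hi_p = proportion_confint(k, n, alpha=0.05, method="wilson")
            lo = -np.log1p(-np.asarray(lo_p))
            hi = -np.log1p(-np.asarray(hi_p))
            coverage = np.mean((lo <= lam) & (lam <= hi))
            assert 0.93 <= coverage <= 0.97, (lam, coverage)


class TestConcentration:
    def test_zero_lambda_gives_zero_concentration(self):
        est = estimate_lambda(DropletCounts(23_527, 0))
        assert lambda_to_concentration(est, 6.236e-4).concentration == 0.0

    @pytest.mark.parametrize(
        "k, reported",
        [(4_516, 341.8), (2_863, 208.1)],
    )
    def test_reproduces_vendor_ledger(self, k, reported, calibrated_volume):
        est = lambda_to_concentration(
            estimate_lambda(DropletCounts(23_527, k)), calibrated_volume
        )
        assert round_half_up(est.concentration, 1) == reported

    def test_nonpositive_volume_rejected(self):
        est = estimate_lambda(DropletCounts(100, 10))
        with pytest.raises(ValidationError):
            lambda_to_concentration(est, 0.0)

    def test_ci_maps_through_volume(self):
        est = lambda_to_concentration(estimate_lambda(DropletCounts(1000, 100)), 2.0)
        assert est.concentration_ci == pytest.approx(
            tuple(b / 2.0 for b in est.lambda_ci)
        )


class TestCalibrateDropletVolume:
    def test_green_row_calibration(self):
        v = calibrate_droplet_volume(DropletCounts(23_527, 2_844), 206.6)
        assert v == pytest.approx(6.2360e-4, rel=1e-4)

    def test_rows_agree_within_two_permille(self):
        v_green = calibrate_droplet_volume(DropletCounts(23_527, 2_844), 206.6)
        v_blue = calibrate_droplet_volume(DropletCounts(23_527, 2_863), 208.1)
        assert v_blue == pytest.approx(6.2352e-4, rel=1e-4)
        assert abs(v_blue - v_green) / v_green < 0.002

    @pytest.mark.parametrize("k, c", [(0, 206.6), (23_527, 206.6), (2_844, 0.0)])
    def test_degenerate_inputs_rejected(self, k, c):
        with pytest.raises(ValidationError):
            calibrate_droplet_volume(DropletCounts(23_527, k), c)


class TestQuantifyDsb:
    def test_reproduces_published_ledger(self, chip_counts, calibrated_volume):
        res = quantify_dsb(
            chip_counts["blue_total"],
            chip_counts["blue_jem1"],
            chip_counts["green_jem1"],
            droplet_volume=calibrated_volume,
        )
        rep = res.as_report()
        assert rep["c_blue_total_cp_per_ul"] == 341.8
        assert rep["c_jem1_cp_per_ul"] == 206.6
        assert rep["c_ctg_unbroken_cp_per_ul"] == 135.2
        assert rep["pct_unbroken"] == 65.4
        assert rep["pct_broken"] == 34.6
        # cross-channel JEM1 agreement: ~0.7% relative, below the 5% tolerance
        assert res.consistency_delta < 0.05
        lo, hi = res.pct_broken_ci
        assert lo < 34.6 < hi

    def test_blue_reference_switch(self, chip_counts, calibrated_volume):
        res = quantify_dsb(
            chip_counts["blue_total"],
            chip_counts["blue_jem1"],
            chip_counts["green_jem1"],
            droplet_volume=calibrated_volume,
            jem1_reference="blue",
        )
        assert res.c_jem1 == pytest.approx(208.07, abs=0.01)

    def test_all_broken_when_blue_equals_reference(self):
        n = 10_000
        res = quantify_dsb(
            DropletCounts(n, 1_500),
            DropletCounts(n, 1_500),
            DropletCounts(n, 1_500),
        )
        assert res.pct_broken == 100.0
        assert res.c_ctg_unbroken == 0.0

    def test_zero_reference_rejected(self):
        n = 10_000
        with pytest.raises(ValidationError, match="reference"):
            quantify_dsb(
                DropletCounts(n, 1_500),
                DropletCounts(n, 0),
                DropletCounts(n, 0),
            )

    def test_mismatched_totals_rejected(self):
        with pytest.raises(ValidationError, match="n_total"):
            quantify_dsb(
                DropletCounts(10_000, 1_500),
                DropletCounts(10_000, 1_000),
                DropletCounts(9_999, 1_000),
            )

    def test_small_negative_difference_clamped(self):
        n = 23_527
        with pytest.warns(ClampWarning):
            res = quantify_dsb(
                DropletCounts(n, 2_840),
                DropletCounts(n, 2_840),
                DropletCounts(n, 2_844),
            )
        assert res.c_ctg_unbroken == 0.0
        assert res.pct_broken == 100.0

    def test_large_negative_difference_is_error(self):
        n = 23_527
        with pytest.raises(GatingInconsistencyError):
            quantify_dsb(
                DropletCounts(n, 2_500),
                DropletCounts(n, 2_500),
                DropletCounts(n, 2_844),
            )

    def test_channel_disagreement_warns(self):
        n = 23_527
        with pytest.warns(ConsistencyWarning):
            quantify_dsb(
                DropletCounts(n, 4_516),
                DropletCounts(n, 3_400),  # blue JEM1 gate far off the green count
                DropletCounts(n, 2_844),
            )

    @given(
        st.integers(min_value=1_000, max_value=50_000),
        st.floats(min_value=0.01, max_value=0.6),
        st.floats(min_value=0.0, max_value=0.9),
    )
    @settings(max_examples=100, deadline=None)
    def test_percentages_always_sum_to_100(self, n, p_ref, extra):
        k_ref = int(n * p_ref)
        k_total = min(int(k_ref + n * (1 - p_ref) * extra * 0.5), n - 1)
        if k_ref == 0:
            return
        res = quantify_dsb(
            DropletCounts(n, max(k_total, k_ref)),
            DropletCounts(n, k_ref),
            DropletCounts(n, k_ref),
        )
        assert res.pct_unbroken + res.pct_broken == 100.0

    def test_additivity_of_independent_targets(self):
        """λ̂ of the union gate matches λ̂1 + λ̂2 for independent targets."""
        rng = np.random.default_rng(7)
        n, lam1, lam2, reps = 100_000, 0.13, 0.084, 40
        diffs = []
        for _ in range(reps):
            a = rng.poisson(lam1, n)
            b = rng.poisson(lam2, n)
            l_union = estimate_lambda(
                DropletCounts(n, int(((a + b) > 0).sum()))
            ).lambda_hat
            l1 = estimate_lambda(DropletCounts(n, int((a > 0).sum()))).lambda_hat
            l2 = estimate_lambda(DropletCounts(n, int((b > 0).sum()))).lambda_hat
            diffs.append(l_union - (l1 + l2))
        diffs = np.asarray(diffs)
        se = diffs.std(ddof=1) / math.sqrt(reps)
        assert abs(diffs.mean()) < 3 * se
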