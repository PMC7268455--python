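"""The four MR estimators and effect-scale conversion."""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from mrpipe.estimators import (
    DOUBLING_EXPONENT,
    Z95,
    egger,
    ivw,
    mode_based,
    ratios_and_weights,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
    _weighted_median,
)
from mrpipe.gwas_io import TraitMeta
from conftest import make_hs, random_hs


class TestWaldRatio:
    def test_arithmetic(self):
        r = wald_ratio({"gamma": 0.1, "se_gamma": 0.01, "Gamma": 0.05, "se_Gamma": 0.02})
        assert (r.beta, r.se) == (pytest.approx(0.5), pytest.approx(0.2))

    def test_zero_outcome_effect(self):
        r = wald_ratio({"gamma": 0.1, "se_gamma": 0.01, "Gamma": 0.0, "se_Gamma": 0.02})
        assert r.beta == 0.0

    def test_antisymmetry_in_gamma_sign(self):
        a = wald_ratio({"gamma": 0.1, "se_gamma": 0.01, "Gamma": 0.05, "se_Gamma": 0.02})
        b = wald_ratio({"gamma": -0.1, "se_gamma": 0.01, "Gamma": 0.05, "se_Gamma": 0.02})
        assert b.beta == pytest.approx(-a.beta)
        assert b.se == pytest.approx(a.se)


class TestIVW:
    def test_single_snp_degenerates_to_wald(self):
        hs = make_hs([0.1], [0.01], [0.05], [0.02])
        for model in ("fixed", "multiplicative_random"):
            r = ivw(hs, model=model)
            assert r.beta == pytest.approx(0.5)
            assert r.se == pytest.approx(0.2)
            assert r.extra["dispersion"] == 1.0

    def test_equal_ratios_no_overdispersion(self, rng):
        gamma = rng.uniform(0.05, 0.2, 6)
        hs = make_hs(gamma, 0.01, 0.7 * gamma, rng.uniform(0.02, 0.05, 6))
        r = ivw(hs)
        assert r.beta == pytest.approx(0.7, abs=1e-12)
        assert r.extra["dispersion"] == 1.0

    def test_fixed_equals_precision_weighted_ratio_average(self, rng):
        """Algebraic identity between the regression and ratio forms."""
        for _ in range(20):
            hs = random_hs(rng)
            b, w = ratios_and_weights(hs)
            assert ivw(hs, model="fixed").beta == pytest.approx(
                float(np.sum(w * b) / np.sum(w)), abs=1e-10
            )

    def test_matches_wls_through_origin_oracle(self, rng):
        for _ in range(20):
            hs = random_hs(rng)
            gamma, _, big, se_big = hs.arrays()
            fit = sm.WLS(big, gamma, weights=1 / se_big**2).fit()
            r = ivw(hs, model="fixed")
            assert r.beta == pytest.approx(float(fit.params[0]), abs=1e-10)

    def test_mre_never_deflates_se(self, rng):
        for _ in range(10):
            hs = random_hs(rng)
            assert ivw(hs).se >= ivw(hs, model="fixed").se - 1e-15


class TestEgger:
    def test_exact_linear_input(self, rng):
        gamma = rng.uniform(0.05, 0.3, 8)
        hs = make_hs(gamma, 0.01, 0.01 + 0.4 * gamma, rng.uniform(0.02, 0.05, 8))
        r = egger(hs)
        assert r.extra["intercept"] == pytest.approx(0.01, abs=1e-12)
        assert r.beta == pytest.approx(0.4, abs=1e-12)
        assert r.extra["q_prime"] == pytest.approx(0.0, abs=1e-10)

    def test_orients_gamma_nonnegative(self, rng):
        gamma = rng.uniform(0.05, 0.3, 8)
        big = 0.01 + 0.4 * gamma
        hs_pos = make_hs(gamma, 0.01, big, 0.03)
        flip = np.array([1, -1] * 4)
        hs_mix = make_hs(gamma * flip, 0.01, big * flip, 0.03)
        a, b = egger(hs_pos), egger(hs_mix)
        assert b.beta == pytest.approx(a.beta, abs=1e-12)
        assert b.extra["intercept"] == pytest.approx(a.extra["intercept"], abs=1e-12)

    def test_collinear_design_rejected(self):
        hs = make_hs([0.1] * 5, 0.01, [0.05] * 5, 0.02)
        with pytest.raises(ValueError, match="collinear"):
            egger(hs)

    def test_too_few_snps_rejected(self):
        hs = make_hs([0.1, 0.2], 0.01, [0.05, 0.1], 0.02)
        with pytest.raises(ValueError, match="insufficient SNPs"):
            egger(hs)

    def test_matches_wls_oracle(self, rng):
        for _ in range(20):
            hs = random_hs(rng)
            gamma, _, big, se_big = hs.arrays()
            s = np.sign(gamma)
            x = sm.add_constant(gamma * s)
            fit = sm.WLS(big * s, x, weights=1 / se_big**2).fit()
            r = egger(hs)
            assert r.extra["intercept"] == pytest.approx(float(fit.params[0]), abs=1e-10)
            assert r.beta == pytest.approx(float(fit.params[1]), abs=1e-10)


class TestWeightedMedian:
    def test_equal_weights_plain_median(self):
        assert _weighted_median(np.array([1.0, 2.0, 3.0]), np.ones(3) / 3) == pytest.approx(2.0)

    def test_interpolation_matches_exhaustive_oracle(self):
        b = np.array([1.0, 2.0, 3.0])
        w = np.array([1.0, 1.0, 2.0]) / 4.0
        # cumulative midpoints: 0.125, 0.375, 0.75; 0.5 lies between the
        # 2nd and 3rd ratios at fraction (0.5-0.375)/(0.75-0.375) = 1/3
        expect = 2.0 + (3.0 - 2.0) / 3.0
        assert _weighted_median(b, w) == pytest.approx(expect)

    def test_estimator_on_harmonized_set(self, rng):
        gamma = rng.uniform(0.1, 0.3, 9)
        hs = make_hs(gamma, 0.005, 0.3 * gamma, 0.05)
        r = weighted_median(hs, n_boot=200, seed=1)
        assert r.beta == pytest.approx(0.3, abs=1e-9)
        assert r.se > 0

    def test_bootstrap_seeded(self, rng):
        hs = random_hs(rng)
        a = weighted_median(hs, n_boot=100, seed=5)
        b = weighted_median(hs, n_boot=100, seed=5)
        assert a.se == b.se


class TestModeBased:
    def test_degenerate_all_equal(self):
        gamma = np.array([0.1, 0.2, 0.3])
        hs = make_hs(gamma, 0.01, 0.7 * gamma, 0.02)
        assert mode_based(hs, n_boot=10, seed=1).beta == pytest.approx(0.7)

    def test_mode_near_dominant_cluster(self):
        gamma = np.ones(4)
        hs = make_hs(gamma, 0.01, np.array([0.0, 0.0, 0.01, 5.0]), 1.0)  # equal weights
        r = mode_based(hs, n_boot=10, seed=1)
        assert abs(r.beta) <= r.extra["bandwidth"] + 1e-12

    def test_estimate_stays_in_ratio_hull_when_phi_doubles(self, rng):
        for _ in range(5):
            hs = random_hs(rng, j=8)
            b, _ = ratios_and_weights(hs)
            for phi in (1.0, 2.0, 4.0):
                est = mode_based(hs, phi=phi, n_boot=10, seed=2).beta
                assert b.min() - 1e-9 <= est <= b.max() + 1e-9


class TestSignEquivariance:
    @given(st.integers(0, 1000))
    @settings(deadline=None, max_examples=20)
    def test_negating_both_leaves_estimates_negating_outcome_flips(self, seed):
        rng = np.random.default_rng(seed)
        hs = random_hs(rng, j=8)
        p = hs.pairs
        hs_both = make_hs(-p["gamma"], p["se_gamma"], -p["Gamma"], p["se_Gamma"])
        hs_out = make_hs(p["gamma"], p["se_gamma"], -p["Gamma"], p["se_Gamma"])
        for est in (lambda h: ivw(h).beta,
                    lambda h: egger(h).beta,
                    lambda h: weighted_median(h, n_boot=10, seed=3).beta,
                    lambda h: mode_based(h, n_boot=10, seed=3).beta):
            assert est(hs_both) == pytest.approx(est(hs), abs=1e-9)
            assert est(hs_out) == pytest.approx(-est(hs), abs=1e-9)


class TestOddsRatioConversion:
    CONT = TraitMeta("bmi", "continuous", n_total=1000)
    BIN = TraitMeta("allergy", "binary", n_total=1000, case_fraction=0.3)

    def _res(self, beta, se):
        from mrpipe.estimators import MRResult

        return MRResult(method="ivw_mre", beta=beta, se=se, pval=0.5, n_snp=3)

    def test_null_effect_or_one(self):
        for meta in (self.CONT, self.BIN):
            or_, lo, hi = to_odds_ratio(self._res(0.0, 0.1), meta)
            assert or_ == pytest.approx(1.0)
            assert lo < 1.0 < hi

    def test_binary_doubling_is_ln2_identity(self):
        or_, _, _ = to_odds_ratio(self._res(1.0, 0.1), self.BIN)
        assert or_ == pytest.approx(math.e**DOUBLING_EXPONENT)
        assert or_ == pytest.approx(2.0, abs=1e-12)

    def test_continuous_ci_arithmetic(self):
        or_, lo, hi = to_odds_ratio(self._res(0.5, 0.1), self.CONT)
        assert or_ == pytest.approx(math.exp(0.5))
        assert lo == pytest.approx(math.exp(0.5 - Z95 * 0.1))
        assert hi == pytest.approx(math.exp(0.5 + Z95 * 0.1))
        # at the conventional 1.96 quantile these are e^0.304 and e^0.696
        assert lo == pytest.approx(math.exp(0.304), abs=2e-4)
        assert hi == pytest.approx(math.exp(0.696), abs=2e-4)
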