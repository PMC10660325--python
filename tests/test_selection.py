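import numpy as np
import pytest

from repskew.annual import estimate_annual_partition
from repskew.demography import DeathStructure
from repskew.scaling import GroupRawStats
from repskew.selection import (
    attribute_reductions,
    effective_breeders,
    effective_size_generation,
    opportunity_annual,
    opportunity_lifetime,
    overall_variance,
    sum_k_squared,
    wright_sex_ratio,
)


class TestSumKSquared:
    def test_bear_age2(self):
        assert sum_k_squared(166, 0.1399, 0.541) == pytest.approx(72, rel=1e-2)

    def test_zero_variance(self):
        assert sum_k_squared(5, 0.0, 1.0) == 5.0

    def test_inverse_of_overall_variance(self, rng):
        for _ in range(50):
            N = int(rng.integers(2, 500))
            sigma2 = float(rng.uniform(0, 20))
            kbar = float(rng.uniform(0.1, 5))
            total = sum_k_squared(N, sigma2, kbar)
            assert overall_variance(total, N, kbar) == pytest.approx(
                sigma2, abs=1e-10)


class TestOverallVariance:
    def test_bear_totals(self):
        assert overall_variance(5359, 448, 1.17) == pytest.approx(10.6, rel=1e-2)

    def test_poisson_inputs_return_mean(self):
        kbar = 1.7
        total = 100 * (kbar + kbar**2)
        assert overall_variance(total, 100, kbar) == pytest.approx(kbar)

    def test_direct_oracle_on_raw_counts(self, rng):
        k = rng.integers(0, 8, size=60).astype(float)
        sigma2 = overall_variance(float((k**2).sum()), len(k), float(k.mean()))
        assert sigma2 == pytest.approx(k.var(), abs=1e-10)  # population variance

    def test_inconsistent_inputs_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            overall_variance(10.0, 100, 5.0)


class TestEffectiveBreeders:
    def test_bear_values(self):
        nb, ratio = effective_breeders(1.17, 10.6, 448)
        assert nb == pytest.approx(56.7, rel=1e-2)
        assert ratio == pytest.approx(0.126, rel=1e-2)

    def test_poisson_limit(self):
        nb, ratio = effective_breeders(2.0, 2.0, 10000)
        assert nb == pytest.approx((2 * 10000 - 1) / 2)
        assert ratio == pytest.approx(1.0, abs=1e-3)

    def test_zero_variance_substitution(self):
        nb, _ = effective_breeders(2.0, 0.0, 100)
        assert nb == pytest.approx(199.0)

    def test_degenerate_denominator(self):
        with pytest.raises(ValueError):
            effective_breeders(0.5, 0.1, 100)


class TestEffectiveSizeGeneration:
    def test_poisson_lifetime_variance_simplifies(self):
        assert effective_size_generation(81, 1.7, 2.0) == pytest.approx(81 * 1.7)

    def test_direct_substitution(self):
        assert effective_size_generation(81, 1.7, 6.0) == pytest.approx(68.85)

    def test_linear_in_generation_length(self):
        assert effective_size_generation(100, 4.0, 3.0) == pytest.approx(
            2 * effective_size_generation(100, 2.0, 3.0))


class TestWrightSexRatio:
    def test_equal_sexes(self):
        assert wright_sex_ratio(25, 25) == pytest.approx(50)

    def test_uneven_sexes(self):
        assert wright_sex_ratio(50, 150) == pytest.approx(150)

    def test_vanishing_sex_collapses(self):
        assert wright_sex_ratio(1e-9, 100) < 1e-6


class TestOpportunityAnnual:
    def test_bear_values(self):
        ofs = opportunity_annual(1.17, 10.6)
        assert ofs.I == pytest.approx(7.74, rel=1e-2)
        assert ofs.dI == pytest.approx(6.89, rel=1e-2)

    def test_poisson_null_is_zero(self):
        assert opportunity_annual(1.7, 1.7).dI == pytest.approx(0.0, abs=1e-12)

    def test_double_poisson(self):
        assert opportunity_annual(1.0, 2.0).dI == pytest.approx(1.0)


class TestOpportunityLifetime:
    def test_great_tit_values(self):
        deaths = DeathStructure(q=[1, 2, 3, 4], D_q=[48, 14, 14, 5])
        ofs = opportunity_lifetime(0.753, 1.34, deaths)
        assert ofs.I == pytest.approx(2.36, rel=1e-2)
        assert ofs.C == pytest.approx(0.32, rel=1.5e-2)
        assert ofs.dI == pytest.approx(0.713, rel=1.5e-2)

    def test_uniform_death_age_no_longevity_term(self):
        deaths = DeathStructure(q=[3], D_q=[20])
        assert opportunity_lifetime(2.0, 1.0, deaths).C == 0.0

    def test_two_individual_hand_oracle(self):
        deaths = DeathStructure(q=[1, 3], D_q=[1, 1])
        # qbar = 2; sum D (q - qbar)^2 = 2; C = 2 / (4 * 2) = 0.25
        assert opportunity_lifetime(1.0, 1.0, deaths).C == pytest.approx(0.25)


class TestAttribution:
    def _partition(self, sse_gt, ssb_gt):
        stats = [GroupRawStats(label=1, n=10, kbar=1.0, s2=1.0),
                 GroupRawStats(label=2, n=10, kbar=1.0, s2=1.0)]
        p = estimate_annual_partition(stats, N_x=[10, 10], Q=1.0)
        p.SSE_hat = p.SSE_null + sse_gt
        p.SSB_hat = ssb_gt
        return p

    def test_bear_shares(self):
        p = self._partition(3524.0, 451.0)
        att = attribute_reductions(p, ratio=0.126, dI=6.89)
        assert att.within_share == pytest.approx(0.887, rel=1e-2)
        assert att.between_share == pytest.approx(0.113, rel=1e-2)
        assert att.within_reduction == pytest.approx(0.774, rel=1e-2)
        assert att.between_reduction == pytest.approx(0.099, rel=2e-2)
        assert att.dI_within == pytest.approx(6.11, rel=1e-2)

    def test_pure_within(self):
        att = attribute_reductions(self._partition(10.0, 0.0), 0.5, 1.0)
        assert att.within_share == 1.0

    def test_equal_components(self):
        att = attribute_reductions(self._partition(5.0, 5.0), 0.5, 1.0)
        assert att.within_share == pytest.approx(0.5)

    def test_no_signal_rejected(self):
        with pytest.raises(ValueError, match="shares undefined"):
            attribute_reductions(self._partition(0.0, 0.0), 1.0, 0.0)
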