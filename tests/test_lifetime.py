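import numpy as np
import pandas as pd
import pytest

from repskew.demography import VitalRates, stabilize_fecundity
from repskew.lifetime import (
    estimate_lifetime_from_records,
    estimate_lifetime_partition,
    lrs_from_matrix,
    parametric_ss_lifetime,
    records_to_stats,
    rho_alpha_plus,
)
from repskew.partition_core import grouped_ss
from repskew.scaling import GroupRawStats

L5 = np.array([1, 0.5, 0.25, 0.125, 0.0625])
AGES5 = np.arange(1, 6)


def make_vr(N1=160, relative_b=None, phi=1.0):
    rel = np.ones(5) if relative_b is None else np.asarray(relative_b, float)
    return VitalRates(ages=AGES5, l=L5, N1=N1,
                      b=stabilize_fecundity(L5, rel), phi=np.full(5, float(phi)))


class TestLrsFromMatrix:
    def test_worked_matrix_semantics(self, tit_matrix):
        derived = lrs_from_matrix(tit_matrix)
        # observed zeros count as breeding attempts; NA never extends lifespan
        assert derived["q"].tolist() == [2, 3, 1, 1, 4]
        assert derived["lrs"].tolist() == [0, 2, 0, 1, 5]

    def test_all_missing_row_rejected(self):
        mat = pd.DataFrame({"age_1": [1, np.nan], "age_2": [np.nan, np.nan]},
                           index=pd.Index(["a", "b"], name="id"))
        with pytest.raises(ValueError, match="b"):
            lrs_from_matrix(mat)

    def test_records_to_stats_groups(self, tit_matrix):
        stats, deaths = records_to_stats(lrs_from_matrix(tit_matrix))
        assert deaths.q.tolist() == [1, 2, 3, 4]
        assert deaths.D_q.tolist() == [2, 1, 1, 1]


class TestParametric:
    def test_constant_fecundity_reduces_to_longevity(self):
        sse, ssb, ssb_long = parametric_ss_lifetime(make_vr())
        assert ssb == pytest.approx(ssb_long, rel=1e-9)

    def test_decreasing_fecundity_lowers_between_below_longevity(self):
        _, ssb, ssb_long = parametric_ss_lifetime(
            make_vr(relative_b=np.arange(5, 0, -1)))
        assert ssb < ssb_long

    def test_increasing_fecundity_raises_between_above_longevity(self):
        _, ssb, ssb_long = parametric_ss_lifetime(
            make_vr(relative_b=np.arange(1, 6)))
        assert ssb > ssb_long

    def test_direct_sum_oracle(self):
        vr = make_vr(relative_b=np.arange(1, 6), phi=2.0)
        sse, ssb, ssb_long = parametric_ss_lifetime(vr)
        D = [80, 40, 20, 10, 10]      # N1=160: N_x = 160,80,40,20,10
        bbar = 2 * 160 / 310
        sse_o = sum(d * sum(2.0 * b for b in vr.b[:q]) for q, d in enumerate(D, 1))
        ssb_o = sum(d * (sum(vr.b[:q]) - 2) ** 2 for q, d in enumerate(D, 1))
        long_o = sum(d * (q * bbar - 2) ** 2 for q, d in enumerate(D, 1))
        assert sse == pytest.approx(sse_o)
        assert ssb == pytest.approx(ssb_o)
        assert ssb_long == pytest.approx(long_o)


class TestEstimator:
    def test_great_tit_longevity_component(self, tit_summary):
        stats, _ = tit_summary
        part = estimate_lifetime_partition(stats)
        assert part.bbar_hat == pytest.approx(2 * 81 / 138, rel=1e-9)
        assert part.SSB_dot_longevity == pytest.approx(103.2, rel=1e-2)

    def test_additive_identity_on_raw_records(self, rng):
        # SST. = SSE. + SSB. exactly when computed from raw LRS data
        for _ in range(20):
            n = rng.integers(5, 40)
            records = pd.DataFrame({
                "q": rng.integers(1, 4, size=n),
                "lrs": rng.integers(0, 6, size=n),
            })
            groups = [records.loc[records["q"] == q, "lrs"].tolist()
                      for q in np.unique(records["q"])]
            ss = grouped_ss(groups)
            assert ss.SST == pytest.approx(ss.SSE + ss.SSB, abs=1e-9)
            # and the estimator's raw cohort variance matches the total SS
            part = estimate_lifetime_from_records(records)
            assert part.s2_lrs_raw == pytest.approx(ss.SST / (n - 1), abs=1e-9)

    def test_degenerate_cohort_all_components_zero(self):
        # everyone dies at q=2 having produced exactly 2 offspring
        stats = [GroupRawStats(label=2, n=30, kbar=2.0, s2=0.0)]
        part = estimate_lifetime_partition(stats)
        assert part.Q == pytest.approx(1.0)
        assert part.SSE_dot_hat == 0.0
        assert part.SSB_dot_hat == 0.0
        assert part.SST_dot_hat == 0.0

    def test_weighted_correction_option(self, tit_summary):
        stats, _ = tit_summary
        unweighted = estimate_lifetime_partition(stats)
        weighted = estimate_lifetime_partition(stats, weighted_correction=True)
        n, D = 4, np.array([48, 14, 14, 5])
        sig = unweighted.per_group["sigma2_hat"].to_numpy()
        assert unweighted.SSB_dot_random == pytest.approx(
            (n - 1) / n * sig.sum())
        assert weighted.SSB_dot_random == pytest.approx(
            (n - 1) / n * (D * sig).sum())

    def test_underdispersed_group_clamped_and_kept(self, tit_summary):
        stats, _ = tit_summary
        with pytest.warns(UserWarning, match="clamped"):
            part = estimate_lifetime_partition(stats)
        tab = part.per_group.set_index("q")
        assert tab.loc[4, "sigma2_hat"] == 0.0
        assert tab.loc[4, "SSB_q"] > 0  # the group still contributes between-SS
        assert part.n_groups == 4

    def test_noninteger_labels_rejected(self):
        with pytest.raises(ValueError, match="integers"):
            estimate_lifetime_partition(
                [GroupRawStats(label="x", n=2, kbar=1.0, s2=0.0)])


class TestRhoAlphaPlus:
    def test_perfect_persistence(self):
        mat = pd.DataFrame({"age_1": [1, 2, 3], "age_2": [1.0, 2, 3]})
        rho, p, n = rho_alpha_plus(mat)
        assert rho == pytest.approx(1.0)
        assert n == 3

    def test_orthogonal_by_construction(self):
        mat = pd.DataFrame({"age_1": [1, 2, 3], "age_2": [2.0, 1, 2]})
        rho, _, _ = rho_alpha_plus(mat)
        assert rho == pytest.approx(0.0, abs=1e-12)

    def test_missing_maturity_entries_flagged(self):
        mat = pd.DataFrame({"age_1": [1, np.nan, 3, 0],
                            "age_2": [2.0, 1, 2, 4]})
        with pytest.warns(UserWarning, match="treated as 0"):
            rho, p, n = rho_alpha_plus(mat)
        assert n == 4

    def test_zero_variance_margin_rejected(self):
        mat = pd.DataFrame({"age_1": [1, 1, 1], "age_2": [0.0, 1, 2]})
        with pytest.raises(ValueError, match="zero variance"):
            rho_alpha_plus(mat)
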