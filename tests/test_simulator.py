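import numpy as np
import pytest

from repskew.annual import estimate_annual_partition
from repskew.lifetime import lrs_from_matrix
from repskew.simulate import (
    SimScenario,
    annual_counts_to_stats,
    simulate_annual,
    simulate_lifetime,
    subsample_offspring,
)


class TestScenario:
    def test_fecundity_is_stabilized(self, reference_scenario):
        sc = reference_scenario(relative_b="increasing")
        assert (sc.l * sc.b).sum() == pytest.approx(2.0)

    def test_underdispersion_target_rejected(self, reference_scenario):
        with pytest.raises(ValueError, match="phi"):
            reference_scenario(phi=0.5)

    def test_config_round_trip(self, tmp_path, reference_scenario):
        cfg = tmp_path / "scenario.yaml"
        cfg.write_text(
            "N1: 160\nv: [0.5, 0.5, 0.5, 0.5, 0.0]\n"
            "relative_b: increasing\nphi: 3.0\nQ: 0.5\nseed: 7\n"
        )
        sc = SimScenario.from_config(cfg)
        ref = reference_scenario(relative_b="increasing", phi=3.0, Q=0.5, seed=7)
        assert np.allclose(sc.b, ref.b)
        assert sc.Q == 0.5 and sc.seed == 7


class TestDeterminism:
    def test_annual_bitwise(self, reference_scenario):
        sc = reference_scenario(replicates=3, seed=42)
        a = simulate_annual(sc)
        b = simulate_annual(sc)
        for rep_a, rep_b in zip(a, b):
            for ga, gb in zip(rep_a, rep_b):
                assert np.array_equal(ga, gb)

    def test_lifetime_bitwise(self, reference_scenario):
        sc = reference_scenario(replicates=2, seed=42, persistence=True, phi=3.0)
        a = simulate_lifetime(sc)
        b = simulate_lifetime(sc)
        for fa, fb in zip(a, b):
            assert fa.equals(fb)


class TestAnnualMoments:
    def test_offspring_total_is_fixed(self, reference_scenario):
        sc = reference_scenario(Q=0.4, replicates=5)
        for rep in simulate_annual(sc):
            assert sum(g.sum() for g in rep) == round(0.4 * 2 * sc.N1)

    def test_means_track_Q_times_fecundity(self, reference_scenario):
        sc = reference_scenario(N1=500, relative_b="increasing", Q=0.5,
                                replicates=400, seed=5)
        sums = np.zeros(sc.n_ages)
        for rep in simulate_annual(sc):
            sums += [g.mean() for g in rep]
        assert np.allclose(sums / 400, 0.5 * sc.b, rtol=0.03)

    def test_equal_weights_give_poisson_dispersion(self, reference_scenario):
        # rescaled phi-hat per age should hover near 1 under equal weights
        sc = reference_scenario(N1=500, relative_b="increasing", replicates=400,
                                seed=6)
        vr = sc.vital_rates()
        phi = np.zeros(sc.n_ages)
        for rep in simulate_annual(sc):
            p = estimate_annual_partition(annual_counts_to_stats(rep), vr=vr,
                                          drop_negative_variance=False)
            phi += p.per_age["phi_hat"].to_numpy()
        assert np.all(np.abs(phi / 400 - 1.0) < 0.1)

    def test_gamma_weights_hit_overdispersion_target(self, reference_scenario):
        # analytic weight calibration: realized rescaled phi-hat ~ target
        sc = reference_scenario(N1=500, phi=3.0, Q=0.5, replicates=400, seed=8)
        vr = sc.vital_rates()
        phi = np.zeros(sc.n_ages)
        for rep in simulate_annual(sc):
            p = estimate_annual_partition(annual_counts_to_stats(rep), vr=vr,
                                          drop_negative_variance=False)
            phi += p.per_age["phi_hat"].to_numpy()
        assert np.allclose(phi / 400, 3.0, rtol=0.1)


class TestLifetimeCohorts:
    def test_stable_cohort_mean_lrs_near_two(self, reference_scenario):
        sc = reference_scenario(N1=200, replicates=200, seed=9)
        means = [lrs_from_matrix(m)["lrs"].mean() for m in simulate_lifetime(sc)]
        assert np.mean(means) == pytest.approx(2.0, rel=0.03)

    def test_certain_death_after_first_age(self):
        sc = SimScenario(N1=50, v=[0.0, 0.0], relative_b="constant",
                         phi=1.0, seed=3)
        records = lrs_from_matrix(simulate_lifetime(sc)[0])
        assert (records["q"] == 1).all()

    def test_lifespan_never_exceeds_omega(self, reference_scenario):
        sc = reference_scenario(N1=100, replicates=5, seed=10)
        for m in simulate_lifetime(sc):
            q = lrs_from_matrix(m)["q"]
            assert q.between(1, sc.n_ages).all()


class TestSubsampling:
    def test_full_intensity_identity(self, rng):
        counts = rng.poisson(2, size=50)
        assert np.array_equal(subsample_offspring(counts, 1.0, seed=1), counts)

    def test_halving_in_expectation(self, rng):
        # per-parent expectation of the thinned counts is Q * counts
        counts = rng.poisson(3, size=200)
        m = round(0.5 * counts.sum())
        draws = np.array([subsample_offspring(counts, 0.5, seed=s)
                          for s in range(300)])
        expected = counts * m / counts.sum()
        assert np.allclose(draws.mean(axis=0), expected, atol=0.35)
        assert np.all(draws.sum(axis=1) == m)

    def test_thinned_poisson_stays_poisson(self, rng):
        # dispersion index of thinned Poisson counts stays near 1
        phis = []
        for s in range(200):
            counts = np.random.default_rng(s).poisson(4, size=300)
            thinned = subsample_offspring(counts, 0.25, seed=s + 1)
            phis.append(thinned.var(ddof=1) / thinned.mean())
        assert np.mean(phis) == pytest.approx(1.0, abs=0.05)

    def test_total_preserved_exactly(self, rng):
        counts = rng.poisson(2, size=30)
        out = subsample_offspring(counts, 0.3, seed=2)
        assert out.sum() == round(0.3 * counts.sum())
        assert np.all(out <= counts)
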