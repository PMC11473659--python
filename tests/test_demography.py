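"""Tests for expected spectra, composite-likelihood fits and trajectories."""

import math

import numpy as np
import pytest

from glacialsfs.core import Demography, FoldedSFS
from glacialsfs.demography import (
    bootstrap_ci,
    compare_models_aic,
    composite_loglik,
    count_reversals,
    expected_sfs,
    fit_epoch_model,
    mixed_population_check,
    power_study,
    stairway_like_fit,
    EpochFit,
)
from glacialsfs.simdata import simulate_coalescent_sfs, simulate_genotype_matrix


BENCHMARKS = [
    Demography(((1e4, 0.0),)),
    Demography(((1e5, 0.0), (1e4, 5e3))),
    Demography(((2e4, 0.0), (2e3, 4e3), (1e4, 2e4))),
]


class TestExpectedSfs:
    def test_constant_size_is_watterson_exactly(self):
        theta_l = 4 * 1e4 * 1e-8 * 1e6
        exp = expected_sfs(Demography(((1e4, 0.0),)), 10, 1e-8, 1e6)
        want = [theta_l / i + theta_l / (10 - i) for i in range(1, 5)] + [theta_l / 5]
        assert np.allclose(exp.eta, want, rtol=1e-10)

    def test_monomorphic_expectation_closes_the_total(self):
        exp = expected_sfs(BENCHMARKS[2], 8, 1e-8, 1e6)
        assert exp.n_mono + exp.eta.sum() == pytest.approx(1e6)

    @pytest.mark.parametrize("dem", BENCHMARKS)
    def test_scaling_identity_exact(self, dem):
        a = expected_sfs(dem, 10, 1e-8, 1e6)
        b = expected_sfs(dem.rescaled(2.0), 10, 0.5e-8, 1e6)
        assert np.allclose(a.eta, b.eta, rtol=1e-10)

    @pytest.mark.parametrize("dem", BENCHMARKS)
    def test_agrees_with_msprime_oracle(self, dem):
        # independent coalescent oracle: msprime branch-mode spectra
        msprime = pytest.importorskip("msprime")
        n = 6
        d = msprime.Demography()
        d.add_population(initial_size=dem.epochs[0][0])
        for ne, t in dem.epochs[1:]:
            d.add_population_parameters_change(time=t, initial_size=ne)
        reps = 3000
        afs = np.zeros(n + 1)
        afs_sq = np.zeros(n + 1)
        for ts in msprime.sim_ancestry(
            samples=n // 2, demography=d, num_replicates=reps, random_seed=7
        ):
            a = ts.allele_frequency_spectrum(
                mode="branch", polarised=True, span_normalise=False
            )
            afs += a
            afs_sq += a**2
        mu, L = 1e-8, 1e6
        mean = afs / reps
        se = np.sqrt(np.maximum(afs_sq / reps - mean**2, 0) / reps)
        xi_mc = mu * L * mean
        xi_se = mu * L * se
        eta_mc = np.array([xi_mc[i] + xi_mc[n - i] if i != n - i else xi_mc[i]
                           for i in range(1, n // 2 + 1)])
        eta_se = np.array([math.hypot(xi_se[i], xi_se[n - i]) if i != n - i else xi_se[i]
                           for i in range(1, n // 2 + 1)])
        exp = expected_sfs(dem, n, mu, L)
        z = (eta_mc - exp.eta) / eta_se
        assert np.all(np.abs(z) < 3.5), z

    def test_rejects_tiny_n(self):
        with pytest.raises(ValueError):
            expected_sfs(BENCHMARKS[0], 1, 1e-8, 1e6)


class TestCompositeLoglik:
    def test_maximised_at_observed_counts(self):
        obs = FoldedSFS([40.0, 20.0, 12.0], 6, 1e4)
        base = composite_loglik(obs, obs)
        for i in range(3):
            for bump in (-5.0, 5.0):
                pert = obs.copy()
                pert.eta = pert.eta.copy()
                pert.eta[i] += bump
                assert composite_loglik(obs, pert) < base

    def test_additive_over_entry_subsets(self):
        # independent Poisson cells: total equals the sum of cell terms
        from scipy.special import gammaln

        obs = FoldedSFS([7.0, 3.0], 4, 100.0)
        exp = FoldedSFS([6.0, 4.0], 4, 100.0)
        cells_o = [obs.n_mono, 7.0, 3.0]
        cells_e = [exp.n_mono, 6.0, 4.0]
        manual = sum(o * math.log(e) - e - gammaln(o + 1) for o, e in zip(cells_o, cells_e))
        assert composite_loglik(obs, exp) == pytest.approx(manual, abs=1e-9)

    def test_zero_expectation_with_observed_mass(self):
        obs = FoldedSFS([5.0, 1.0], 4, 100.0)
        exp = FoldedSFS([5.0, 0.0], 4, 100.0)
        assert composite_loglik(obs, exp) == -math.inf

    def test_mismatched_n_rejected(self):
        with pytest.raises(ValueError):
            composite_loglik(FoldedSFS([1.0], 2, 10.0), FoldedSFS([1.0, 1.0], 4, 10.0))


@pytest.fixture(scope="module")
def epoch2_obs():
    # 10,000 probe-sized loci over 3 Mbp: the targeted-sequencing scale
    truth = Demography(((1e5, 0.0), (1e4, 5000.0)))
    return simulate_coalescent_sfs(truth, 20, 3e6, 7.77e-9, reps=10_000, seed=55)


class TestEpochFits:

    def test_snm_recovery_within_ten_percent(self):
        obs = simulate_coalescent_sfs(
            Demography(((5e4, 0.0),)), 20, 3e6, 7.77e-9, reps=1500, seed=54
        )
        fit = fit_epoch_model(obs, "SNM", 7.77e-9, n_starts=8, seed=1, maxiter=200)
        assert fit.params["NCUR"] == pytest.approx(5e4, rel=0.10)

    def test_epoch2_recovery_and_model_selection(self, epoch2_obs):
        mu = 7.77e-9
        fit2 = fit_epoch_model(epoch2_obs, "epoch2", mu, n_starts=10, seed=2)
        fit1 = fit_epoch_model(epoch2_obs, "SNM", mu, n_starts=10, seed=2)
        assert fit2.params["NCUR"] == pytest.approx(1e5, rel=0.25)
        assert fit2.params["NANC"] == pytest.approx(1e4, rel=0.25)
        assert fit2.params["TBOT"] == pytest.approx(5000.0, rel=0.30)
        assert fit2.aic < fit1.aic

    def test_nesting_of_likelihoods(self, epoch2_obs):
        mu = 7.77e-9
        lls = [
            fit_epoch_model(epoch2_obs, m, mu, n_starts=12, seed=3, maxiter=300).loglik
            for m in ("SNM", "epoch2", "epoch3")
        ]
        # nested families: richer models can only raise the maximum
        assert lls[1] >= lls[0] - 1e-3
        assert lls[2] >= lls[1] - 0.5  # epoch3 optimum is harder to locate exactly

    def test_params_within_bounds(self, epoch2_obs):
        fit = fit_epoch_model(epoch2_obs, "epoch3", 7.77e-9, n_starts=4, seed=4, maxiter=150)
        for name, v in fit.params.items():
            assert 10.0 <= v <= 2e7  # TENDBOT = TBOT + increment may reach 2e7

    def test_unknown_model_rejected(self, epoch2_obs):
        with pytest.raises(ValueError):
            fit_epoch_model(epoch2_obs, "epoch9", 1e-8)


class TestAicComparison:
    def test_parameter_penalty(self):
        f1 = EpochFit("SNM", {"NCUR": 1.0}, -100.0, 202.0, 1, True, (4, 1, 1))
        f3 = EpochFit("epoch2", {"NCUR": 1, "NANC": 1, "TBOT": 1}, -100.0, 206.0, 1, True, (4, 1, 1))
        table = compare_models_aic([f1, f3])
        assert table.iloc[0]["model"] == "SNM"
        assert table.iloc[1]["delta_aic"] == pytest.approx(4.0)

    def test_input_order_invariance(self):
        fits = [
            EpochFit("SNM", {"NCUR": 1.0}, -10.0, 22.0, 1, True, (4, 1, 1)),
            EpochFit("epoch2", {"a": 1, "b": 1, "c": 1}, -5.0, 16.0, 1, True, (4, 1, 1)),
        ]
        t1 = compare_models_aic(fits)
        t2 = compare_models_aic(fits[::-1])
        assert t1.equals(t2)

    def test_mixed_datasets_rejected(self):
        f1 = EpochFit("SNM", {"NCUR": 1.0}, -10.0, 22.0, 1, True, (4, 1.0, 1.0))
        f2 = EpochFit("SNM", {"NCUR": 1.0}, -10.0, 22.0, 1, True, (6, 2.0, 2.0))
        with pytest.raises(ValueError):
            compare_models_aic([f1, f2])


class TestBootstrapCi:
    def test_intervals_bracket_the_point_estimate(self):
        obs = simulate_coalescent_sfs(
            Demography(((5e4, 0.0),)), 10, 1e6, 1e-8, reps=1000, seed=66
        )
        fit = fit_epoch_model(obs, "SNM", 1e-8, n_starts=6, seed=5, maxiter=150)
        ci = bootstrap_ci(obs=obs, best=fit, mu=1e-8, n_boot=20, n_starts=4, seed=6, maxiter=150)
        lo, hi = ci["NCUR"]
        assert lo <= fit.params["NCUR"] <= hi
        assert ci["_n_failed"] == 0

    def test_reproducible_under_seed(self):
        obs = simulate_coalescent_sfs(
            Demography(((5e4, 0.0),)), 10, 1e6, 1e-8, reps=500, seed=67
        )
        fit = fit_epoch_model(obs, "SNM", 1e-8, n_starts=4, seed=5, maxiter=120)
        a = bootstrap_ci(obs=obs, best=fit, mu=1e-8, n_boot=6, n_starts=3, seed=9, maxiter=120)
        b = bootstrap_ci(obs=obs, best=fit, mu=1e-8, n_boot=6, n_starts=3, seed=9, maxiter=120)
        assert a == b


class TestStairway:
    def test_constant_ne_recovered_flat(self):
        obs = simulate_coalescent_sfs(
            Demography(((5e4, 0.0),)), 20, 3e6, 7.77e-9, reps=1500, seed=71
        )
        traj = stairway_like_fit(
            obs, 7.77e-9, gen_time_years=1.0, n_boot=10, n_starts=3, maxiter=200, seed=72
        )
        assert np.all(np.abs(traj.ne / 5e4 - 1) < 0.2)

    def test_expansion_recovered(self):
        grown = Demography(((1e5, 0.0), (1e4, 2e4)))
        obs = simulate_coalescent_sfs(grown, 20, 3e6, 7.77e-9, reps=1500, seed=73)
        traj = stairway_like_fit(
            obs, 7.77e-9, gen_time_years=1.0, n_boot=10, n_starts=3, maxiter=200, seed=74
        )
        assert traj.ne[0] / traj.ne[-1] > 3.0

    def test_mutation_rate_only_rescales(self):
        obs = simulate_coalescent_sfs(
            Demography(((5e4, 0.0),)), 20, 3e6, 7.77e-9, reps=1500, seed=75
        )
        a = stairway_like_fit(obs, 7.77e-9, n_boot=8, n_starts=3, maxiter=200, seed=76)
        b = stairway_like_fit(obs, 7.77e-9 / 2, n_boot=8, n_starts=3, maxiter=200, seed=76)
        # halving mu doubles sizes and times; the shape is unchanged
        assert np.allclose(b.t_lo, 2 * a.t_lo, rtol=1e-9)
        assert np.median(b.ne / a.ne) == pytest.approx(2.0, rel=0.15)

    def test_refuses_sparse_spectra(self):
        obs = FoldedSFS(np.ones(10) * 5, 20, 1e6)
        with pytest.raises(ValueError):
            stairway_like_fit(obs, 1e-8)


class TestReversals:
    def test_counts_significant_direction_changes(self):
        assert count_reversals(np.array([1e3, 1e2, 1e3, 1e2])) == 2
        assert count_reversals(np.array([1e3, 950.0, 1e3])) == 0  # 5% wiggle ignored
        assert count_reversals(np.array([1.0, 2.0, 3.0, 4.0])) == 0
        assert count_reversals(np.array([100.0, 101.0, 100.0, 101.0]), 0.1) == 0

    def test_time_restriction(self):
        ne = np.array([1e3, 1e2, 1e3, 1e4])
        t = np.array([1.0, 2.0, 3.0, 4.0])
        assert count_reversals(ne, t=t, t_max=2.5) == 0
        assert count_reversals(ne, t=t, t_max=4.5) == 1


class TestPowerStudyAndMixing:
    def test_power_study_deterministic_and_reports_pi(self):
        scen = [{"gen_time": 25.0, "ne_current": 1e5, "mu": 2.7e-8, "L": 1e6}]
        kw = dict(seed=81, sim_reps=400, n_boot=4, n_starts=2, maxiter=100)
        t1 = power_study(scen, **kw)
        t2 = power_study(scen, **kw)
        assert t1.drop(columns=[]).equals(t2)
        assert t1["pi"].iloc[0] > 0
        assert {"reversals_total", "reversals_last_cycle"} <= set(t1.columns)

    def test_mixed_population_check_panmictic_null(self):
        gm = simulate_genotype_matrix(
            Demography(((2e4, 0.0),)), n_ind=16, L=3e5, mu=1e-7, seed=82,
            pop_labels=["A"] * 8 + ["B"] * 8, reps=400,
        )
        out = mixed_population_check(
            gm, mu=1e-7, seed=83, n_boot=5, n_starts=2, maxiter=120
        )
        assert set(out["trajectories"]) == {"pooled", "A", "B"}
        assert np.isfinite(out["max_log_ratio"])
        assert out["max_log_ratio"] < 1.5  # same gene pool: no strong divergence
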