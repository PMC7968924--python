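"""Likelihood, deterministic recursion, and MCMC sampler behavior."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom, kstest

from genedrive.inference import (
    CageObservations,
    FitParameters,
    McmcResult,
    cross_transmission,
    expected_phenotype_trajectory,
    log_likelihood,
    run_mcmc,
    summarize_posterior,
)

MENDELIAN = FitParameters(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
PERFECT = FitParameters(1.0, 1.0, 1.0, 1.0, 0.0, 0.0)


def _obs(rows, **kw):
    return CageObservations(
        pd.DataFrame(rows, columns=["cage_id", "generation", "n_marker_pos", "n_marker_neg"]),
        **kw,
    )


class TestRecursion:
    def test_mendelian_reaches_hardy_weinberg_carrier_value(self):
        """At 25% allele frequency the HW carrier fraction is 1 - 0.75^2."""
        traj = expected_phenotype_trajectory(MENDELIAN, 8)
        assert traj[0] == pytest.approx(0.5)  # G0: half sired by H/H fathers
        assert traj[1:] == pytest.approx(np.full(7, 1 - 0.75**2))

    def test_perfect_drive_is_absorbing(self):
        traj = expected_phenotype_trajectory(PERFECT, 6)
        assert traj[-1] == pytest.approx(1.0)
        assert np.all(np.diff(traj) >= -1e-12)

    def test_fitted_parameters_approach_fixation(self, fitted_fit_params):
        traj = expected_phenotype_trajectory(fitted_fit_params, 10)
        assert np.all(np.diff(traj) > 0)
        assert traj[-1] > 0.99

    def test_agrees_with_generic_cube_recursion(self, fitted_fit_params,
                                                fitted_cube_1l, fitted_fitness_1l):
        """Dual route: the fast path equals the recursion built from the
        full inheritance cube."""
        from genedrive.cage import expected_generation

        cube, fitm = fitted_cube_1l, fitted_fitness_1l
        T = cube.as_tensor()
        idx = cube.index
        genos = cube.genotypes
        viable = np.array([fitm.viable(g) for g in genos], dtype=float)
        fec = np.array([fitm.fecundity(g) for g in genos])
        f = np.zeros(len(genos))
        m = np.zeros(len(genos))
        f[idx[(("W", "W"),)]] = 1.0
        m[idx[(("W", "W"),)]] = 0.5
        m[idx[(("H", "H"),)]] = 0.5
        generic = []
        for _ in range(10):
            f, m = expected_generation(f, m, T, viable, fec)
            generic.append(sum(f[idx[g]] for g in genos if "H" in g[0]))
        fast = expected_phenotype_trajectory(fitted_fit_params, 10)
        assert fast == pytest.approx(np.array(generic), abs=1e-12)


class TestLikelihood:
    def test_matches_independent_binomial_pmf(self):
        obs = _obs([(0, 0, 50, 50)])
        # G0 expectation is 0.5 for the default cage seeding
        assert log_likelihood(obs, MENDELIAN) == pytest.approx(
            binom.logpmf(50, 100, 0.5)
        )

    def test_additive_across_cages(self, fitted_fit_params):
        one = _obs([(0, 0, 160, 140), (0, 1, 200, 100)])
        two = _obs([(1, 0, 150, 150), (1, 1, 190, 110)])
        both = _obs(
            [(0, 0, 160, 140), (0, 1, 200, 100), (1, 0, 150, 150), (1, 1, 190, 110)]
        )
        for p in (fitted_fit_params, MENDELIAN):
            assert log_likelihood(both, p) == pytest.approx(
                log_likelihood(one, p) + log_likelihood(two, p)
            )

    def test_exchangeable_under_cage_relabeling(self, fitted_fit_params):
        a = _obs([(0, 0, 160, 140), (1, 0, 150, 150)])
        b = _obs([(1, 0, 160, 140), (0, 0, 150, 150)])
        assert log_likelihood(a, fitted_fit_params) == pytest.approx(
            log_likelihood(b, fitted_fit_params)
        )

    def test_observed_at_expectation_is_local_maximum(self):
        base = log_likelihood(_obs([(0, 0, 150, 150)]), MENDELIAN)
        assert base > log_likelihood(_obs([(0, 0, 151, 149)]), MENDELIAN)
        assert base > log_likelihood(_obs([(0, 0, 149, 151)]), MENDELIAN)

    def test_contradicted_certain_prediction_is_impossible(self):
        # a perfect-drive female cross transmits H with probability exactly 1,
        # so a marker-negative F1 has zero likelihood
        crosses = pd.DataFrame(
            [("F", 199, 1)], columns=["parent_sex", "n_marker_pos", "n_marker_neg"]
        )
        obs = _obs([(0, 0, 150, 150)], crosses=crosses)
        assert log_likelihood(obs, PERFECT) == -np.inf

    def test_cross_terms_enter_likelihood(self, fitted_fit_params):
        crosses = pd.DataFrame(
            [("F", 199, 1), ("M", 110, 90)],
            columns=["parent_sex", "n_marker_pos", "n_marker_neg"],
        )
        plain = _obs([(0, 0, 150, 150)])
        with_x = _obs([(0, 0, 150, 150)], crosses=crosses)
        p = fitted_fit_params
        expected = (
            binom.logpmf(199, 200, cross_transmission(p, "F"))
            + binom.logpmf(110, 200, cross_transmission(p, "M"))
        )
        assert log_likelihood(with_x, p) == pytest.approx(
            log_likelihood(plain, p) + expected
        )

    def test_cross_transmission_closed_form(self):
        p = FitParameters(0.992, 0.996, 0.995, 0.096, 0.029, 0.003)
        assert cross_transmission(p, "F") == pytest.approx(0.99352)
        assert cross_transmission(p, "M") == pytest.approx(0.5 + 0.5 * 0.996 * 0.096)

    def test_orphan_survey_rows_rejected(self):
        surveys = pd.DataFrame(
            [(0, 7, "neg", "W/W", 3)],
            columns=["cage_id", "generation", "marker_class", "genotype", "count"],
        )
        with pytest.raises(ValueError, match="matching cage"):
            _obs([(0, 0, 150, 150)], surveys=surveys)

    def test_nonconsecutive_generations_rejected(self):
        with pytest.raises(ValueError, match="consecutive"):
            _obs([(0, 0, 10, 10), (0, 2, 10, 10)])


class TestSummaries:
    def test_constant_chain(self):
        s = summarize_posterior(np.full((100, 6), 0.5))
        assert s.median("c_F") == 0.5
        assert s.cri("c_F") == (0.5, 0.5)

    def test_uniform_samples_percentiles(self, rng):
        s = summarize_posterior(rng.uniform(size=(200_000, 6)))
        lo, hi = s.cri("cr")
        assert lo == pytest.approx(0.025, abs=0.005)
        assert hi == pytest.approx(0.975, abs=0.005)
        assert s.median("cr") == pytest.approx(0.5, abs=0.005)

    def test_ordering_invariant(self, rng):
        s = summarize_posterior(rng.beta(2, 5, size=(5_000, 6)))
        t = s.table
        assert (t["cri_lower"] <= t["median"]).all()
        assert (t["median"] <= t["cri_upper"]).all()

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            summarize_posterior(pd.DataFrame(columns=["c_F"]))


class TestMcmc:
    def test_zero_iterations_returns_initial_point(self):
        obs = _obs([(0, 0, 150, 150)])
        init = FitParameters(0.5, 0.5, 0.5, 0.5, 0.5, 0.5)
        res = run_mcmc(obs, iterations=0, init=init, seed=1)
        assert isinstance(res, McmcResult)
        assert res.samples.iloc[0].to_numpy() == pytest.approx(np.full(6, 0.5))

    def test_flat_likelihood_recovers_prior(self):
        """With no data the posterior must reproduce the uniform prior."""
        obs = _obs([])
        res = run_mcmc(obs, iterations=20_000, burn_in=4_000, seed=2,
                       init=FitParameters(0.5, 0.5, 0.5, 0.5, 0.5, 0.5))
        for name in res.samples.columns:
            stat = kstest(res.samples[name].to_numpy()[::10], "uniform").statistic
            assert stat < 0.12, f"{name} deviates from the prior (KS={stat:.3f})"

    def test_burn_in_validation(self):
        with pytest.raises(ValueError):
            run_mcmc(_obs([(0, 0, 1, 1)]), iterations=10, burn_in=20)

    def test_reproducible_under_seed(self):
        obs = _obs([(0, 0, 160, 140), (0, 1, 220, 80)])
        a = run_mcmc(obs, iterations=800, burn_in=200, seed=3)
        b = run_mcmc(obs, iterations=800, burn_in=200, seed=3)
        pd.testing.assert_frame_equal(a.samples, b.samples)

    def test_recovery_smoke(self, fitted_fit_params):
        """A reduced-size recovery run lands near the generating values."""
        from genedrive.synth import generate_cage_observations

        obs = generate_cage_observations(
            fitted_fit_params, n_cages=3, generations=8,
            flies_scored_per_gen=300, seed=99,
        )
        res = run_mcmc(obs, iterations=8_000, burn_in=3_000, seed=100)
        s = res.summary
        assert abs(s.median("c_F") - 0.992) < 0.03
        assert abs(s.median("ch_F") - 0.995) < 0.03
        assert abs(s.median("ch_M") - 0.096) < 0.06
        lo, hi = s.cri("cr")
        assert lo <= 0.029 <= hi
        assert 0.15 < res.acceptance_rate < 0.6
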