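import numpy as np
import pytest
from scipy import stats

from satox import (
    MCMCConfig,
    ModelParams,
    PatientRecord,
    PriorSpec,
    TrialData,
    log_likelihood_na,
    log_likelihood_sa,
    log_prior,
    outcome_probs,
    pi_T,
    quadrature_posterior,
    sample_posterior,
    summarize,
)
from satox.bayes_inference import PosteriorDraws
from satox.core_model import CycleTiming, pi_T_surface

from conftest import draw_prior_params, random_dataset


def two_patients(grid, outcomes):
    data = TrialData(grid=grid)
    for y in outcomes:
        data.add(PatientRecord(1, 1, y != 1, y))
    return data


class TestLikelihoods:
    def test_sa_no_dlt_pair(self, grid):
        params = ModelParams(1.0, 1.0, 0.0, 4 / 7)
        data = two_patients(grid, [0, 0])
        expected = 2 * np.log(1 - pi_T(grid, params, 1, 1))
        assert log_likelihood_sa(data, params) == pytest.approx(expected)

    def test_sa_zero_probability_outcome(self, grid):
        data = two_patients(grid, [1])
        assert log_likelihood_sa(data, ModelParams(1.0, 1.0, 0.0, 0.0)) == -np.inf

    def test_empty_data_gives_zero(self, grid):
        empty = TrialData(grid=grid)
        params = ModelParams(0.5, 1.5, -1.0, 0.3)
        assert log_likelihood_sa(empty, params) == 0.0
        assert log_likelihood_na(empty, params) == 0.0

    def test_na_no_dlt_pair(self, grid):
        params = ModelParams(1.0, 1.0, 0.0)
        data = two_patients(grid, [0, 0])
        # pi_T(a_1, b_1) = 0.10 + 0.06 - 0.006 = 0.154 at the prior centre
        assert log_likelihood_na(data, params) == pytest.approx(2 * np.log(1 - 0.154))

    def test_na_ignores_attribution(self, grid):
        params = ModelParams(1.0, 1.0, 0.0, 0.5)
        d1 = two_patients(grid, [1])
        d2 = two_patients(grid, [2])
        assert log_likelihood_na(d1, params) == pytest.approx(log_likelihood_na(d2, params))

    def test_collapse_identity_over_random_datasets(self, grid):
        # merging the two DLT categories turns the trinary likelihood into the
        # binary one at the same theta, for any lambda
        rng = np.random.default_rng(7)
        for _ in range(100):
            data = random_dataset(rng, grid, n=int(rng.integers(1, 12)))
            params = draw_prior_params(rng)
            collapsed = 0.0
            for r in data.records:
                probs = outcome_probs(grid, params, r.a_idx, r.b_idx)
                collapsed += np.log(probs.p0 if r.outcome == 0 else probs.p1 + probs.p2)
            assert collapsed == pytest.approx(log_likelihood_na(data, params), rel=1e-12)


class TestPriors:
    def test_lambda_beta_shapes_follow_timing(self):
        assert PriorSpec().lambda_beta_shapes == pytest.approx((4 / 3, 1.0))
        early = PriorSpec(timing=CycleTiming(t_B=2.0, T=7.0))
        assert early.lambda_beta_shapes == pytest.approx((1.0, 2.5))

    def test_outside_uniform_support(self, prior):
        assert log_prior(ModelParams(2.5, 1.0, 0.0, 0.5), prior) == -np.inf

    def test_lambda_term_only_when_estimated(self, prior):
        fixed = PriorSpec(lambda_mode="fixed")
        params = ModelParams(1.0, 1.0, 0.0, 0.5)
        without = log_prior(params, fixed, model="SA")
        with_term = log_prior(params, prior, model="SA")
        la, lb = prior.lambda_beta_shapes
        assert with_term - without == pytest.approx(stats.beta.logpdf(0.5, la, lb))
        assert log_prior(params, prior, model="NA") == pytest.approx(without)

    def test_fixed_mode_defaults_to_tB_over_T(self):
        fixed = PriorSpec(lambda_mode="fixed")
        assert fixed.lambda_fixed_value == pytest.approx(4 / 7)


class TestPatientRecord:
    def test_outcome_one_requires_b_withheld(self):
        with pytest.raises(ValueError):
            PatientRecord(1, 1, True, 1)
        with pytest.raises(ValueError):
            PatientRecord(1, 1, False, 0)
        with pytest.raises(ValueError):
            PatientRecord(1, 1, True, 3)

    def test_counts_aggregate_by_outcome(self, grid):
        data = TrialData(grid=grid)
        data.add(PatientRecord(1, 2, True, 0))
        data.add(PatientRecord(1, 2, False, 1))
        data.add(PatientRecord(3, 4, True, 2))
        n0, n1, n2 = data.counts_sa()
        assert n0[0, 1] == 1 and n1[0] == 1 and n2[2, 3] == 1 and n2.sum() == 1
        n0b, nd = data.counts_na()
        assert nd[0, 1] == 1 and nd[2, 3] == 1 and n0b[0, 1] == 1
        assert data.per_combo_counts().sum() == 3

    def test_frame_round_trip(self, grid):
        data = TrialData(grid=grid)
        data.add(PatientRecord(2, 3, True, 2))
        data.add(PatientRecord(1, 1, False, 1))
        back = TrialData.from_frame(data.to_frame(), grid)
        assert back.records == data.records


class TestSampler:
    def test_reproducible_given_seed(self, grid, prior, reduced_mcmc):
        data = two_patients(grid, [0, 2])
        d1 = sample_posterior(data, prior, "SA", reduced_mcmc, seed=3)
        d2 = sample_posterior(data, prior, "SA", reduced_mcmc, seed=3)
        np.testing.assert_array_equal(d1.params, d2.params)

    def test_draws_respect_prior_support(self, grid, prior, reduced_mcmc):
        data = random_dataset(np.random.default_rng(1), grid, 8)
        d = sample_posterior(data, prior, "SA", reduced_mcmc, seed=5)
        assert np.all((d.alpha >= 0) & (d.alpha <= 2))
        assert np.all((d.beta >= 0) & (d.beta <= 2))
        assert np.all((d.lam > 0) & (d.lam < 1))

    def test_na_model_has_no_lambda(self, grid, prior, reduced_mcmc):
        data = two_patients(grid, [0, 0])
        d = sample_posterior(data, prior, "NA", reduced_mcmc, seed=2)
        assert np.all(d.lam == 0.0)
        assert "lam" not in summarize(d, grid).param_medians

    def test_draw_frame_exports_lowest_combo_probability(self, grid, prior, reduced_mcmc):
        data = two_patients(grid, [0, 0])
        d = sample_posterior(data, prior, "NA", reduced_mcmc, seed=2)
        df = d.to_frame()
        assert {"chain", "iter", "alpha", "beta", "gamma", "lam", "pi_T_a1_b1"} <= set(df.columns)
        row = df.iloc[10]
        expected = pi_T(grid, ModelParams(row.alpha, row.beta, row.gamma), 1, 1)
        assert row.pi_T_a1_b1 == pytest.approx(expected)


class TestSummaries:
    def test_single_draw_degenerate(self, grid):
        params = np.array([[1.0, 1.0, 0.0, 0.5]])
        draws = PosteriorDraws(
            params=params,
            chain=np.zeros(1),
            model="SA",
            acceptance=np.zeros(4),
            rhat={},
            grid=grid,
        )
        s = summarize(draws, grid)
        np.testing.assert_allclose(
            s.median_pi_T, pi_T_surface(grid, ModelParams(1.0, 1.0, 0.0))
        )

    def test_truth_draws_reproduce_reference_table(self, grid, scenarios):
        # a posterior concentrated on the generating parameters recovers the
        # scenario-1 table to two decimals
        params = np.tile([1.0, 1.0, 0.0, 8 / 14], (50, 1))
        draws = PosteriorDraws(
            params=params, chain=np.zeros(50), model="SA",
            acceptance=np.zeros(4), rhat={}, grid=grid,
        )
        from satox.core_model import round_half_even

        s = summarize(draws, grid)
        rounded = np.vectorize(round_half_even)(s.median_pi_T)
        np.testing.assert_allclose(rounded, scenarios["scenario1-lam8"].true_pi_T)

    def test_exceedance_is_empirical_tail_fraction(self, grid, prior, reduced_mcmc):
        data = two_patients(grid, [2, 0])
        d = sample_posterior(data, prior, "NA", reduced_mcmc, seed=8)
        s = summarize(d, grid, gamma_target=0.25)
        direct = np.mean(
            [pi_T(grid, ModelParams(a, b, g), 1, 1) > 0.25 for a, b, g in d.params[:, :3]]
        )
        assert s.exceedance_lowest == pytest.approx(direct)


class TestQuadrature:
    def test_rejects_coarse_grid(self, grid, prior):
        with pytest.raises(ValueError):
            quadrature_posterior(TrialData(grid=grid), prior, "NA", n_points=8)

    def test_empty_data_recovers_prior_medians(self, grid, prior):
        s = quadrature_posterior(TrialData(grid=grid), prior, "NA", n_points=40)
        assert s.param_medians["alpha"] == pytest.approx(1.0, abs=0.02)
        assert s.param_medians["beta"] == pytest.approx(1.0, abs=0.02)
        assert s.param_medians["gamma"] == pytest.approx(0.0, abs=0.05)

    def test_lambda_prior_median_recovered(self, grid, prior):
        s = quadrature_posterior(TrialData(grid=grid), prior, "SA", n_points=24)
        assert s.param_medians["lam"] == pytest.approx(0.595, abs=0.01)
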