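"""Panel likelihood, state tables, crude inits, MLE fitting, and the LRT."""

import numpy as np
import pytest

import panelmsm as pm
from panelmsm.likelihood import FitConfig

from _oracles import series_expm


def _dataset(records, covariates=None, covariate_names=(), n_states=4):
    """records: {subject: [(t, state, exact), ...]}"""
    ids, times, states, exact = [], [], [], []
    for sid, obs in records.items():
        ids.append(sid)
        times.append(np.array([o[0] for o in obs], dtype=float))
        states.append(np.array([o[1] for o in obs], dtype=int))
        exact.append(np.array([len(o) > 2 and o[2] for o in obs], dtype=bool))
    return pm.PanelDataset(
        ids, times, states, exact, covariates, covariate_names, n_states
    )


class TestPanelDataset:
    def test_rejects_single_observation(self):
        with pytest.raises(ValueError):
            _dataset({"a": [(0, 1)]})

    def test_rejects_nonincreasing_times(self):
        with pytest.raises(ValueError):
            _dataset({"a": [(0, 1), (0, 2)]})

    def test_rejects_entry_in_other_state(self):
        with pytest.raises(ValueError):
            _dataset({"a": [(0, 2), (1, 2)]})

    def test_csv_roundtrip(self, tmp_path):
        data = _dataset(
            {"a": [(0, 1), (1, 2), (2.5, 4, True)], "b": [(0, 1), (1.2, 1)]},
            covariates=np.array([[50.0], [61.0]]),
            covariate_names=("age",),
        )
        path = tmp_path / "panel.csv"
        pm.write_panel_csv(path, data)
        back = pm.read_panel_csv(path)
        assert back.n_subjects == 2
        assert back.covariate_names == ("age",)
        assert np.allclose(back.times[0], [0, 1, 2.5])
        assert back.exact[0].tolist() == [False, False, True]

    def test_missing_covariates_exclude_subject(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame(
            {
                "subject_id": ["a", "a", "b", "b"],
                "time_years": [0, 1, 0, 1],
                "state": [1, 2, 1, 1],
                "exact_time": [0, 0, 0, 0],
                "age": [50.0, 50.0, np.nan, np.nan],
            }
        )
        path = tmp_path / "m.csv"
        df.to_csv(path, index=False)
        data = pm.read_panel_csv(path)
        assert data.n_subjects == 1
        assert data.subject_ids == ["a"]


class TestStateTable:
    def test_hand_counted_pairs(self):
        data = _dataset({"a": [(0, 1), (1, 1), (2, 2), (3, 4, True)]})
        counts = pm.state_table(data).counts
        expected = np.zeros((4, 4), dtype=int)
        expected[0, 0] = 1
        expected[0, 1] = 1
        expected[1, 3] = 1
        assert np.array_equal(counts, expected)

    def test_absorbing_row_is_zero(self, validation_model, annual_schedule):
        data = pm.generate_cohort(validation_model, 100, annual_schedule, seed=9)
        counts = pm.state_table(data).counts
        assert np.all(counts[3] == 0)

    def test_slow_rates_give_diagonal_dominance(self, structure, annual_schedule):
        lb = np.log(np.full(7, 0.02))
        model = pm.TrueModel(
            structure=structure, params=pm.ModelParameters(log_baseline=lb)
        )
        data = pm.generate_cohort(model, 200, annual_schedule, seed=10)
        counts = pm.state_table(data).counts
        assert np.trace(counts) > 0.8 * counts.sum()


class TestCrudeInitialValues:
    def test_single_interval(self, structure):
        data = _dataset({"a": [(0, 1), (2, 2)]})
        params = pm.crude_initial_values(data, structure, floor=1e-3)
        rates = np.exp(params.log_baseline)
        idx = structure.transition_index(1, 2)
        assert rates[idx] == pytest.approx(0.5)
        others = np.delete(rates, idx)
        assert np.allclose(others, 1e-3)

    def test_time_scale_equivariance(self, structure, small_cohort):
        doubled = pm.PanelDataset(
            small_cohort.subject_ids,
            [t * 2 for t in small_cohort.times],
            small_cohort.states,
            small_cohort.exact,
            None,
            (),
            4,
        )
        r1 = np.exp(pm.crude_initial_values(small_cohort, structure).log_baseline)
        r2 = np.exp(pm.crude_initial_values(doubled, structure).log_baseline)
        seen = r1 > 2e-3  # floored entries do not scale
        assert np.allclose(r2[seen], r1[seen] / 2)

    def test_near_truth_under_frequent_observation(self, structure, validation_model):
        # frequent visits make the crude estimator nearly unbiased; the cohort
        # is sized so Monte-Carlo noise on the rarest transition (~4%) is well
        # inside the 15% band
        sched = pm.VisitSchedule(
            scheme="fixed-interval", interval_years=0.05, max_followup_years=6.0
        )
        data = pm.generate_cohort(validation_model, 4000, sched, seed=77)
        crude = np.exp(pm.crude_initial_values(data, structure).log_baseline)
        truth = np.exp(validation_model.params.log_baseline)
        assert np.all(np.abs(crude / truth - 1) < 0.15)


class TestLogLikelihood:
    def test_alive_alive_closed_form(self, two_state):
        data = _dataset({"a": [(0, 1), (1.7, 1)]}, n_states=2)
        for q in [0.3, 1.0, 2.5]:
            params = pm.ModelParameters(log_baseline=np.array([np.log(q)]))
            ll = pm.log_likelihood(params, data, two_state)
            assert ll == pytest.approx(-q * 1.7, abs=1e-10)

    def test_exact_death_closed_form(self, two_state):
        t = 2.3
        data = _dataset({"a": [(0, 1), (t, 2, True)]}, n_states=2)
        for q in [0.4, 1.1]:
            params = pm.ModelParameters(log_baseline=np.array([np.log(q)]))
            ll = pm.log_likelihood(params, data, two_state)
            assert ll == pytest.approx(np.log(q * np.exp(-q * t)), abs=1e-10)

    def test_exact_death_reduces_to_panel_when_disabled(self, two_state):
        t = 2.3
        data = _dataset({"a": [(0, 1), (t, 2, True)]}, n_states=2)
        params = pm.ModelParameters(log_baseline=np.array([np.log(0.7)]))
        ll = pm.log_likelihood(params, data, two_state, exact_death=False)
        # plain panel contribution: log P(t)[alive, dead] = log(1 - e^{-qt})
        assert ll == pytest.approx(np.log(1 - np.exp(-0.7 * t)), abs=1e-10)

    def test_matches_series_oracle_products(self, structure):
        rng = np.random.default_rng(3)
        lb = rng.uniform(np.log(0.05), np.log(1.0), 7)
        params = pm.ModelParameters(log_baseline=lb)
        model = pm.TrueModel(structure=structure, params=params)
        sched = pm.VisitSchedule(
            scheme="fixed-interval", interval_years=1.0, max_followup_years=5.0
        )
        data = pm.generate_cohort(model, 5, sched, seed=8)
        ll = pm.log_likelihood(params, data, structure, exact_death=False)
        Q = pm.build_generator(params, structure).Q
        expected = 0.0
        for i in range(data.n_subjects):
            t, s = data.times[i], data.states[i]
            for j in range(len(t) - 1):
                P = series_expm(Q, t[j + 1] - t[j])
                expected += np.log(P[s[j] - 1, s[j + 1] - 1])
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_additive_and_order_invariant(self, structure, validation_model, small_cohort):
        params = validation_model.params
        full = pm.log_likelihood(params, small_cohort, structure)
        # reversed subject order
        rev = pm.PanelDataset(
            small_cohort.subject_ids[::-1],
            small_cohort.times[::-1],
            small_cohort.states[::-1],
            small_cohort.exact[::-1],
            None,
            (),
            4,
        )
        assert pm.log_likelihood(params, rev, structure) == pytest.approx(full, abs=1e-8)
        # split into two batches and sum
        half = small_cohort.n_subjects // 2

        def batch(sl):
            return pm.PanelDataset(
                small_cohort.subject_ids[sl],
                small_cohort.times[sl],
                small_cohort.states[sl],
                small_cohort.exact[sl],
                None,
                (),
                4,
            )

        parts = pm.log_likelihood(params, batch(slice(None, half)), structure) + \
            pm.log_likelihood(params, batch(slice(half, None)), structure)
        assert parts == pytest.approx(full, abs=1e-8)

    def test_extra_subject_decreases_loglik(self, structure, validation_model):
        params = validation_model.params
        base = _dataset({"a": [(0, 1), (1, 2)]})
        more = _dataset({"a": [(0, 1), (1, 2)], "b": [(0, 1), (1, 1)]})
        assert pm.log_likelihood(params, more, structure) < pm.log_likelihood(
            params, base, structure
        )

    def test_impossible_path_gives_minus_inf_with_diagnostic(self):
        st = pm.TransitionStructure(3, ((1, 2), (2, 3)))
        params = pm.ModelParameters(log_baseline=np.zeros(2))
        # 1 -> 3 is reachable via 2, but leaving the absorbing state 3 is not
        data2 = _dataset({"bad": [(0, 1), (1, 3), (2, 2)]}, n_states=3)
        with pytest.warns(UserWarning, match="bad"):
            ll = pm.log_likelihood(params, data2, st)
        assert ll == -np.inf


class TestFitMLE:
    def test_exponential_mle_closed_form(self, two_state):
        rng = np.random.default_rng(21)
        t_death = rng.exponential(1 / 0.6, size=40)
        data = _dataset(
            {f"s{i}": [(0, 1), (t, 2, True)] for i, t in enumerate(t_death)},
            n_states=2,
        )
        fit = pm.fit_mle(data, two_state)
        assert fit.converged
        expected = len(t_death) / t_death.sum()
        assert np.exp(fit.params.log_baseline[0]) == pytest.approx(
            expected, rel=1e-6
        )
        # Wald SE of log-rate for exponential data is 1/sqrt(n)
        se = np.sqrt(fit.covariance[0, 0])
        assert se == pytest.approx(1 / np.sqrt(len(t_death)), rel=0.01)

    def test_recovers_generating_parameters(self, structure, validation_model, annual_schedule):
        data = pm.generate_cohort(validation_model, 2000, annual_schedule, seed=100)
        fit = pm.fit_mle(data, structure)
        assert fit.converged
        se = np.sqrt(np.diag(fit.covariance))
        err = fit.params.log_baseline - validation_model.params.log_baseline
        assert np.all(np.abs(err) <= 3 * se)

    def test_stable_under_perturbed_start(self, structure, small_cohort):
        fit = pm.fit_mle(small_cohort, structure)
        rng = np.random.default_rng(4)
        init = pm.ModelParameters(
            log_baseline=fit.params.log_baseline + rng.uniform(-0.5, 0.5, 7)
        )
        refit = pm.fit_mle(small_cohort, structure, init=init)
        assert refit.log_likelihood == pytest.approx(fit.log_likelihood, abs=1e-4)

    def test_time_homogeneity_of_fitted_probabilities(self, structure, small_cohort):
        fit = pm.fit_mle(small_cohort, structure)
        Q = pm.build_generator(fit.params, structure)
        P1 = pm.transition_probability(Q, 1.0)
        P5 = pm.transition_probability(Q, 5.0)
        assert np.allclose(P5.P, np.linalg.matrix_power(P1.P, 5), atol=1e-8)

    def test_standardized_covariates_report_original_scale(self, two_state):
        rng = np.random.default_rng(33)
        n = 80
        age = rng.normal(50, 10, n)
        rate = 0.5 * np.exp(0.02 * (age - 50))
        t_death = rng.exponential(1 / rate)
        data = pm.PanelDataset(
            [f"s{i}" for i in range(n)],
            [np.array([0.0, t]) for t in t_death],
            [np.array([1, 2])] * n,
            [np.array([False, True])] * n,
            age[:, None],
            ("age",),
            n_states=2,
        )
        raw = pm.fit_mle(data, two_state, with_covariates=True)
        std = pm.fit_mle(
            data, two_state, with_covariates=True, config=FitConfig(standardize=True)
        )
        assert std.params.beta[0, 0] == pytest.approx(raw.params.beta[0, 0], abs=1e-4)
        assert std.params.log_baseline[0] == pytest.approx(
            raw.params.log_baseline[0], abs=1e-3
        )
        # covariance mapped back too: SEs agree between parameterizations
        assert np.sqrt(std.covariance[1, 1]) == pytest.approx(
            np.sqrt(raw.covariance[1, 1]), rel=0.02
        )

    def test_nonconvergence_is_flagged(self, structure, small_cohort):
        with pytest.warns(UserWarning, match="converge"):
            fit = pm.fit_mle(
                small_cohort, structure, config=FitConfig(maxiter=1)
            )
        assert not fit.converged


class TestLikelihoodRatioTest:
    def test_identical_fits_give_zero(self, structure, small_cohort):
        fit = pm.fit_mle(small_cohort, structure)
        res = pm.likelihood_ratio_test(fit, fit)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_df_counts_added_covariates(self, structure, validation_model, annual_schedule):
        model = pm.TrueModel(
            structure=structure,
            params=pm.ModelParameters(
                validation_model.params.log_baseline,
                np.zeros((7, 1)),
                ("grp",),
            ),
            covariate_model=(pm.Bernoulli("grp", 0.5),),
        )
        data = pm.generate_cohort(model, 150, annual_schedule, seed=55)
        cfg = FitConfig(compute_covariance=False)
        f0 = pm.fit_mle(data, structure, with_covariates=False, config=cfg)
        f1 = pm.fit_mle(data, structure, with_covariates=True, config=cfg)
        res = pm.likelihood_ratio_test(f0, f1)
        assert res.df == 7
        assert res.statistic >= 0

    def test_non_nested_fits_rejected(self, structure, two_state, small_cohort):
        fit4 = pm.fit_mle(small_cohort, structure)
        data2 = _dataset({"a": [(0, 1), (1, 2, True)]}, n_states=2)
        fit2 = pm.fit_mle(data2, two_state)
        with pytest.raises(ValueError):
            pm.likelihood_ratio_test(fit2, fit4)
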