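import numpy as np
import pandas as pd
import pytest

from lungtraj import trajectory as traj
from lungtraj.prep import DesignMatrix, build_design, filter_training
from lungtraj.synthetic import CohortConfig, generate_cohort, recovery_report

from conftest import make_truth, subject_truth_labels


def conjugate_posterior(X, y, m0, v0):
    """Closed-form conjugate normal-gamma regression posterior mean."""
    D0 = np.diag(1.0 / v0)
    P = D0 + X.T @ X
    return np.linalg.solve(P, D0 @ m0 + X.T @ y), P


class TestFitSingle:
    def test_k1_matches_conjugate_oracle(self, simple_design):
        priors = traj.Priors()
        model = traj.fit_single(simple_design, priors, K_max=1, seed=0,
                                compute_waic=False)
        for d in range(2):
            m_oracle, P = conjugate_posterior(
                simple_design.X, simple_design.Y[:, d],
                priors.m0[d], priors.v0[d],
            )
            np.testing.assert_allclose(model.coef_mean[0, d], m_oracle,
                                       atol=1e-6, rtol=0)
            # normal-gamma rate parameter also closed-form
            y = simple_design.Y[:, d]
            b_oracle = priors.b0[d] + 0.5 * (
                y @ y + priors.m0[d] @ np.diag(1.0 / priors.v0[d]) @ priors.m0[d]
                - m_oracle @ P @ m_oracle
            )
            assert model.gamma_b[0, d] == pytest.approx(b_oracle, rel=1e-9)
            assert model.gamma_a[0, d] == pytest.approx(
                priors.a0[d] + 0.5 * len(y)
            )

    def test_elbo_monotone_nondecreasing(self, three_comp_design):
        for seed in (0, 1, 2):
            model = traj.fit_single(three_comp_design, K_max=5, seed=seed,
                                    compute_waic=False)
            assert np.all(np.diff(model.elbo_trace) >= -1e-8)

    def test_well_separated_two_component_recovery(self):
        truth = make_truth([0.5, -3.5], [0.5, -3.5], sigma=0.5)
        cc = CohortConfig(n_subjects=500, censor_lo=12, censor_hi=14,
                          dropout_prob=0.05)
        visits, _, _, labels = generate_cohort(cc, truth, seed=8)
        design = build_design(filter_training(visits)[0])
        model = traj.prune(
            traj.fit_single(design, K_max=4, seed=2, compute_waic=False)
        )
        lab_true = subject_truth_labels(labels, 500, model.subject_ids)
        rep = recovery_report(lab_true, model.hard_labels, truth, model)
        assert rep["accuracy"] >= 0.99

    def test_responsibility_rows_sum_to_one(self, three_comp_design):
        model = traj.fit_single(three_comp_design, K_max=5, seed=3,
                                compute_waic=False)
        np.testing.assert_allclose(model.responsibilities.sum(axis=1), 1.0,
                                   atol=1e-9)

    def test_empty_design_rejected(self):
        d = DesignMatrix(X=np.empty((0, 4)), Y=np.empty((0, 2)),
                         subject_ids=np.array([]), subject_index=np.array([], int))
        with pytest.raises(ValueError):
            traj.fit_single(d, K_max=2, seed=0)

    def test_intercept_shrinks_toward_zero_as_prior_tightens(self, simple_design):
        loose = traj.Priors()
        v_tight = loose.v0.copy()
        v_tight[:, 0] = 1e-4
        tight = traj.Priors(v0=v_tight)
        m_loose = traj.fit_single(simple_design, loose, K_max=1, seed=0,
                                  compute_waic=False)
        m_tight = traj.fit_single(simple_design, tight, K_max=1, seed=0,
                                  compute_waic=False)
        for d in range(2):
            assert abs(m_tight.coef_mean[0, d, 0]) < abs(m_loose.coef_mean[0, d, 0])


class TestWaic2:
    def _point_mass_model(self, design, beta, sd, weights):
        K = len(weights)
        a = np.full((K, 2), 1e8)
        b = a * sd ** 2
        return traj.TrajectoryModel(
            K_max=K, alpha=np.asarray(weights) * 1e8, coef_mean=np.asarray(beta),
            coef_V=np.zeros((K, 2, 4, 4)), gamma_a=a, gamma_b=b,
            responsibilities=np.full((design.n_subjects, K), 1.0 / K),
            subject_ids=design.subject_ids, elbo_trace=np.array([0.0]),
            seed=0, converged=True, point_mass=True,
        )

    def test_point_mass_posterior_gives_zero_effective_parameters(
            self, simple_design):
        beta = np.zeros((1, 2, 4))
        beta[0, 0] = [0.4, -0.01, -0.003, -0.002]
        beta[0, 1] = [0.2, -0.006, -0.002, -0.001]
        model = self._point_mass_model(simple_design, beta,
                                       np.array([[0.6, 0.5]]), [1.0])
        with pytest.warns(UserWarning, match="degenerate"):
            got = traj.waic2(model, simple_design, S=50, seed=0)
        # oracle: -2 * sum_i log p(y_i | theta_hat)
        lam = 1.0 / np.array([0.6, 0.5]) ** 2
        ll = 0.0
        for d in range(2):
            resid = simple_design.Y[:, d] - simple_design.X @ beta[0, d]
            ll += np.sum(0.5 * np.log(lam[d] / (2 * np.pi))
                         - 0.5 * lam[d] * resid ** 2)
        assert got == pytest.approx(-2.0 * ll, rel=1e-9)

    def test_component_relabeling_leaves_waic_unchanged(self, simple_design):
        beta = np.zeros((2, 2, 4))
        beta[0, :, 0] = 0.5
        beta[1, :, 0] = -2.0
        sd = np.array([[0.6, 0.5], [0.7, 0.6]])
        m1 = self._point_mass_model(simple_design, beta, sd, [0.3, 0.7])
        m2 = self._point_mass_model(simple_design, beta[::-1], sd[::-1],
                                    [0.7, 0.3])
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w1 = traj.waic2(m1, simple_design, S=10, seed=0)
            w2 = traj.waic2(m2, simple_design, S=10, seed=0)
        assert w1 == pytest.approx(w2, rel=1e-12)

    def test_requires_at_least_two_draws(self, simple_design):
        model = traj.fit_single(simple_design, K_max=1, seed=0,
                                compute_waic=False)
        with pytest.raises(ValueError):
            traj.waic2(model, simple_design, S=1, seed=0)


class TestEnsemble:
    def test_singleton_matches_fit_single(self, simple_design):
        models = traj.fit_ensemble(simple_design, K_max=2, n_init=1,
                                   base_seed=5)
        seed = int(np.random.SeedSequence(5).generate_state(1)[0] % 2 ** 31)
        direct = traj.fit_single(simple_design, K_max=2, seed=seed)
        assert len(models) == 1
        np.testing.assert_allclose(models[0].coef_mean, direct.coef_mean)
        assert models[0].waic2 == pytest.approx(direct.waic2)

    def test_sorted_ascending_by_waic(self, three_comp_design):
        models = traj.fit_ensemble(three_comp_design, K_max=5, n_init=4,
                                   base_seed=1, max_iter=150)
        waics = [m.waic2 for m in models]
        assert waics == sorted(waics)
        assert models[0].waic2 <= min(waics)


class TestPrune:
    def _toy_model(self, fractions):
        n = 100
        fractions = np.asarray(fractions)
        K = len(fractions)
        counts = np.round(fractions * n).astype(int)
        counts[-1] = n - counts[:-1].sum()
        r = np.zeros((n, K))
        start = 0
        for k, c in enumerate(counts):
            r[start:start + c, k] = 1.0
            start += c
        return traj.TrajectoryModel(
            K_max=K, alpha=fractions * n, coef_mean=np.zeros((K, 2, 4)),
            coef_V=np.tile(np.eye(4), (K, 2, 1, 1)), gamma_a=np.ones((K, 2)),
            gamma_b=np.ones((K, 2)), responsibilities=r,
            subject_ids=np.array([f"S{i}" for i in range(n)]),
            elbo_trace=np.array([0.0]), seed=0, converged=True,
        )

    def test_small_component_removed_and_weights_renormalized(self):
        model = self._toy_model([0.50, 0.49, 0.01])
        pruned = traj.prune(model, threshold=0.02)
        assert pruned.K == 2
        np.testing.assert_allclose(pruned.weights, [0.5 / 0.99, 0.49 / 0.99],
                                   atol=1e-9)

    def test_identity_when_nothing_below_threshold(self):
        model = self._toy_model([0.6, 0.4])
        assert traj.prune(model, threshold=0.02) is model
        assert traj.prune(model, threshold=0.0) is model

    def test_all_below_threshold_is_an_error(self):
        model = self._toy_model([0.5, 0.5])
        with pytest.raises(ValueError):
            traj.prune(model, threshold=0.6)


class TestAssign:
    def _visits(self, rows):
        return pd.DataFrame(rows)

    def test_indistinguishable_components_return_prior_weights(self):
        # two identical components: posterior must equal mixture weights
        beta = np.zeros((2, 2, 4))
        beta[:, 0, 0] = -1.0
        beta[:, 1, 0] = -0.5
        model = traj.TrajectoryModel(
            K_max=2, alpha=np.array([3.0, 1.0]), coef_mean=beta,
            coef_V=np.zeros((2, 2, 4, 4)), gamma_a=np.full((2, 2), 2.0),
            gamma_b=np.full((2, 2), 0.72), responsibilities=np.full((1, 2), 0.5),
            subject_ids=np.array(["X"]), elbo_trace=np.array([0.0]),
            seed=0, converged=True,
        )
        visits = self._visits([{
            "subject_id": "Q", "sex": "male", "age": 60.0, "fev1_z": -1.2,
            "fvc_z": -0.6, "packyears": 0.0, "current_smoker": 0,
        }])
        assignment = traj.assign(model, visits, min_posterior=0.5)
        np.testing.assert_allclose(assignment.R[0], [0.75, 0.25], atol=1e-12)

    def test_single_visit_assignment_recovers_separated_components(
            self, three_comp_truth):
        cc = CohortConfig(n_subjects=400, visit_offsets_years=(0.0,))
        visits, _, _, labels = generate_cohort(cc, three_comp_truth, seed=13)
        # fit on an independent longitudinal cohort
        cc_fit = CohortConfig(n_subjects=600, censor_lo=12, censor_hi=14,
                              dropout_prob=0.05)
        fit_visits, _, _, _ = generate_cohort(cc_fit, three_comp_truth, seed=14)
        design = build_design(filter_training(fit_visits)[0])
        model = traj.prune(
            traj.fit_single(design, K_max=5, seed=1, compute_waic=False)
        )
        assignment = traj.assign(model, visits, min_posterior=0.5)
        lab_true = subject_truth_labels(labels, 400, assignment.subject_ids)
        rep = recovery_report(lab_true, assignment.hard_labels, three_comp_truth)
        assert rep["accuracy"] >= 0.9

    def test_subject_without_usable_visits_is_unassigned(self, simple_design):
        model = traj.fit_single(simple_design, K_max=2, seed=0,
                                compute_waic=False)
        visits = self._visits([
            {"subject_id": "OK", "sex": "male", "age": 60.0, "fev1_z": -1.0,
             "fvc_z": -0.5, "packyears": 10.0, "current_smoker": 0},
            {"subject_id": "BAD", "sex": "male", "age": 60.0, "fev1_z": np.nan,
             "fvc_z": -0.5, "packyears": 10.0, "current_smoker": 0},
        ])
        assignment = traj.assign(model, visits, min_posterior=0.0)
        assert assignment.assigned[0]
        assert not assignment.assigned[1]
        assert assignment.hard_labels[1] == -1

    def test_min_posterior_validation(self, simple_design):
        model = traj.fit_single(simple_design, K_max=1, seed=0,
                                compute_waic=False)
        visits = self._visits([
            {"subject_id": "A", "sex": "male", "age": 60.0, "fev1_z": -1.0,
             "fvc_z": -0.5, "packyears": 10.0, "current_smoker": 0},
        ])
        with pytest.raises(ValueError):
            traj.assign(model, visits, min_posterior=1.0 + 1e-9)


class TestSelectClinical:
    def _fit_models(self, design, n_init=3):
        return traj.fit_ensemble(design, K_max=5, n_init=n_init, base_seed=0,
                                 max_iter=150, waic_draws=50)

    def test_single_candidate_passthrough(self, three_comp_design):
        models = self._fit_models(three_comp_design, n_init=1)
        chosen, audit = traj.select_clinical(models, pd.DataFrame(), top_m=5)
        assert chosen is models[0]
        assert audit["flag"] == "single_candidate_passthrough"

    def test_graded_hazards_pass_adjacency_discrimination(self):
        truth = make_truth(
            [0.0, -2.0, -4.0], [0.0, -1.6, -3.0], sigma=0.5,
            log_hr=[0.0, np.log(3.0), np.log(9.0)],
            log_rate=np.log([0.3, 1.2, 4.0]),
        )
        cc = CohortConfig(n_subjects=1200, censor_lo=12, censor_hi=14,
                          dropout_prob=0.05, base_hazard=0.03)
        visits, _, outcomes, _ = generate_cohort(cc, truth, seed=17)
        design = build_design(filter_training(visits)[0])
        models = traj.fit_ensemble(design, K_max=5, n_init=2, base_seed=3,
                                   max_iter=200, waic_draws=50)
        chosen, audit = traj.select_clinical(models, outcomes, top_m=2)
        assert audit["flag"] is None
        assert traj.prune(chosen).K == 3
        passing = [c for c in audit["candidates"] if c["pass"]]
        assert passing and passing[-1]["seed"] == audit["chosen_seed"]

    def test_outcomes_independent_of_trajectory_raise_audit_flag(self):
        truth = make_truth([0.0, -2.0, -4.0], sigma=0.5,
                           log_hr=[0.0, 0.0, 0.0],
                           log_rate=np.log([0.4, 0.4, 0.4]))
        cc = CohortConfig(n_subjects=800, censor_lo=12, censor_hi=14,
                          dropout_prob=0.05, base_hazard=0.02)
        visits, _, outcomes, _ = generate_cohort(cc, truth, seed=19)
        design = build_design(filter_training(visits)[0])
        models = traj.fit_ensemble(design, K_max=5, n_init=2, base_seed=7,
                                   max_iter=200, waic_draws=50)
        chosen, audit = traj.select_clinical(models, outcomes, top_m=2)
        assert audit["flag"] == "no clinically discriminating model"
        assert chosen is models[0]
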