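"""EM steps, the fit driver, standard errors, criteria and classification."""
import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit

import qamrm as qm
from qamrm.estimation import EStepResult, _slot_stats, observed_information
from qamrm.likelihood import QuadratureRule

from conftest import brute_force_class_loglik


def _rasch_setup(J=4, G1=False):
    """K=1 setup: J items all measuring the single attribute."""
    q = qm.QMatrix.from_array(np.ones((J, 1), dtype=int))
    if G1:
        space = qm.enumerate_profiles(1, hierarchy=[(1,)])
    else:
        space = qm.enumerate_profiles(1)
    amap = qm.build_anchor_map(q, space, "non_compensatory")
    return q, space, qm.build_layout(amap)


class TestEStep:
    def test_identical_components_uniform_posterior(self, design_q, full_space):
        layout = qm.build_layout(
            qm.build_anchor_map(design_q, full_space, "non_compensatory")
        )
        rng = np.random.default_rng(0)
        b = np.repeat(rng.normal(size=14), 2)
        params = qm.QAMRMParams(difficulties=b, mixing=np.full(8, 1 / 8))
        y = qm.ResponseMatrix(
            values=rng.integers(0, 2, size=(20, 14)).astype(float)
        )
        est = qm.e_step(y, params, layout, QuadratureRule.gauss_hermite(21))
        np.testing.assert_allclose(est.posterior, 1 / 8, atol=1e-12)

    def test_near_degenerate_prior_pins_the_class(self, design_q, full_space):
        layout = qm.build_layout(
            qm.build_anchor_map(design_q, full_space, "non_compensatory")
        )
        rng = np.random.default_rng(1)
        eps = 1e-9
        mixing = np.full(8, eps)
        mixing[0] = 1.0 - 7 * eps
        params = qm.QAMRMParams(
            difficulties=rng.normal(size=layout.n_difficulty), mixing=mixing
        )
        y = qm.ResponseMatrix(
            values=rng.integers(0, 2, size=(10, 14)).astype(float)
        )
        est = qm.e_step(y, params, layout, QuadratureRule.gauss_hermite(21))
        np.testing.assert_allclose(est.posterior[:, 0], 1.0, atol=1e-4)

    def test_posterior_matches_bayes_rule_oracle(self):
        rng = np.random.default_rng(4)
        q = qm.QMatrix.from_array([[1, 0], [0, 1], [1, 1]])
        space = qm.enumerate_profiles(2)
        layout = qm.build_layout(qm.build_anchor_map(q, space, "compensatory"))
        params = qm.QAMRMParams(
            difficulties=rng.normal(size=layout.n_difficulty),
            mixing=rng.dirichlet(np.ones(4)),
            ability_sd=0.8,
        )
        y = qm.ResponseMatrix(values=rng.integers(0, 2, size=(6, 3)).astype(float))
        quad = QuadratureRule.gauss_hermite(41, sd=params.ability_sd)
        est = qm.e_step(y, params, layout, quad)
        cc = brute_force_class_loglik(y, params, layout)
        joint = np.exp(cc) * params.mixing[None, :]
        oracle = joint / joint.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(est.posterior, oracle, atol=1e-6)
        assert np.allclose(est.posterior.sum(axis=1), 1.0)


class TestMStep:
    def test_half_correct_at_theta_zero_gives_b_zero(self):
        q, space, layout = _rasch_setup(J=2, G1=True)
        y = qm.ResponseMatrix(
            values=np.array([[1.0, 1.0], [0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        )
        quad = QuadratureRule.degenerate(0.0)
        params = qm.QAMRMParams(
            difficulties=np.full(layout.n_difficulty, 0.5),
            mixing=np.array([1.0]),
        )
        est = qm.e_step(y, params, layout, quad)
        new = qm.m_step(y, est, params, layout, quad)
        np.testing.assert_allclose(new.difficulties, 0.0, atol=1e-9)

    def test_identical_level_columns_pool_like_a_merged_class(self):
        """Two classes with equal level rows must drive the shared slots
        exactly as one merged class of their combined mass."""
        q = qm.QMatrix.from_array([[1, 1], [1, 1]])
        space4 = qm.enumerate_profiles(2)  # (01) and (10) have equal rows
        space3 = qm.enumerate_profiles(2, hierarchy=[(0, 0), (0, 1), (1, 1)])
        lay4 = qm.build_layout(qm.build_anchor_map(q, space4, "non_compensatory"))
        lay3 = qm.build_layout(qm.build_anchor_map(q, space3, "non_compensatory"))
        rng = np.random.default_rng(2)
        y = qm.ResponseMatrix(values=rng.integers(0, 2, size=(40, 2)).astype(float))
        b = np.array([-0.5, 0.7, 0.1, 1.2])
        quad = QuadratureRule.gauss_hermite(21)
        p4 = qm.QAMRMParams(difficulties=b, mixing=np.array([0.3, 0.2, 0.25, 0.25]))
        p3 = qm.QAMRMParams(difficulties=b, mixing=np.array([0.3, 0.45, 0.25]))
        new4 = qm.m_step(y, qm.e_step(y, p4, lay4, quad), p4, lay4, quad)
        new3 = qm.m_step(y, qm.e_step(y, p3, lay3, quad), p3, lay3, quad)
        np.testing.assert_allclose(new4.difficulties, new3.difficulties, atol=1e-10)

    def test_newton_agrees_with_grid_search(self, design_q, full_space):
        layout = qm.build_layout(
            qm.build_anchor_map(design_q, full_space, "non_compensatory")
        )
        truth = qm.recovery_truth("non_compensatory")
        y, _, _ = qm.simulate_dataset(truth, 200, seed=3)
        params, _, _ = truth.true_params()
        quad = QuadratureRule.gauss_hermite(21)
        est = qm.e_step(y, params, layout, quad)
        new = qm.m_step(y, est, params, layout, quad)
        R, Nexp = _slot_stats(y, est.node_responsibilities, layout)
        grid = np.arange(-6.0, 6.0, 1e-4)
        for s in [0, 7, 13]:  # spot-check a few slots
            p = expit(quad.nodes[None, :] - grid[:, None])
            obj = (R[s] * np.log(p) + (Nexp[s] - R[s]) * np.log1p(-p)).sum(axis=1)
            assert abs(grid[np.argmax(obj)] - new.difficulties[s]) < 1e-3

    def test_constraint_preserved_by_construction(self, small_fit):
        """Cells sharing a slot hold literally equal values after fitting."""
        fit = small_fit["fit"]
        B = qm.class_difficulty_matrix(fit.params, fit.layout)
        for (j, lv), s in zip(
            fit.layout.difficulty_slots, range(fit.layout.n_difficulty)
        ):
            cells = B[j, fit.amap.levels[j] == lv]
            assert np.ptp(cells) == 0.0


class TestFitEM:
    def test_loglik_monotone_every_iteration(self, small_fit):
        path = small_fit["fit"].loglik_path
        assert (np.diff(path) >= -1e-8).all()

    def test_refit_same_seed_bit_identical(self, design_q, full_space):
        truth = qm.recovery_truth("non_compensatory")
        y, _, _ = qm.simulate_dataset(truth, 300, seed=8)
        cfg = qm.FitConfig(
            n_starts=3, burn_iters=4, n_survivors=1, n_quadrature=15,
            seed=42, compute_se=False,
        )
        f1 = qm.fit_em(y, design_q, full_space, "non_compensatory", cfg=cfg)
        f2 = qm.fit_em(y, design_q, full_space, "non_compensatory", cfg=cfg)
        assert f1.loglik == f2.loglik
        np.testing.assert_array_equal(f1.params.difficulties, f2.params.difficulties)

    def test_single_class_reduces_to_rasch_mml(self):
        """G=1 fit equals a direct quasi-Newton Rasch marginal ML fit."""
        q, space, layout = _rasch_setup(J=5, G1=True)
        rng = np.random.default_rng(12)
        theta = rng.normal(0, 1.2, size=300)
        b_true = np.linspace(-1.5, 1.5, 5)
        y = qm.ResponseMatrix(
            values=(rng.random((300, 5)) < expit(theta[:, None] - b_true)).astype(float)
        )
        cfg = qm.FitConfig(
            n_starts=2, burn_iters=5, n_survivors=1, tol=1e-12,
            max_iters=5000, n_quadrature=31, seed=1, compute_se=False,
        )
        fit = qm.fit_em(y, q, space, "non_compensatory", cfg=cfg)

        def negll(x):
            params = qm.QAMRMParams(
                difficulties=x[:5], mixing=np.array([1.0]),
                ability_sd=float(np.exp(x[5])),
            )
            quad = QuadratureRule.gauss_hermite(31, sd=params.ability_sd)
            return -qm.marginal_loglik(y, params, layout, quad)

        res = minimize(negll, np.zeros(6), method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000})
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-6)

    def test_recovers_truth_at_n4000(self, design_q, full_space):
        truth = qm.recovery_truth("non_compensatory")
        y, _, _ = qm.simulate_dataset(truth, 4000, seed=2024)
        tp, _, _ = truth.true_params()
        cfg = qm.FitConfig(
            n_starts=4, burn_iters=6, n_survivors=2, n_quadrature=21,
            seed=7, compute_se=False,
        )
        fit = qm.fit_em(y, design_q, full_space, "non_compensatory", cfg=cfg)
        assert fit.converged
        assert np.abs(fit.params.difficulties - tp.difficulties).max() < 0.15
        assert np.abs(fit.params.mixing - 0.125).max() < 0.03

    def test_anchored_loglik_below_unconstrained(self, design_q, full_space):
        """The anchored model is a restriction of the mixture Rasch model."""
        truth = qm.recovery_truth("non_compensatory")
        y, _, _ = qm.simulate_dataset(truth, 400, seed=5)
        cfg = qm.FitConfig(
            n_starts=3, burn_iters=5, n_survivors=1, n_quadrature=15,
            seed=3, compute_se=False,
        )
        anchored = qm.fit_em(y, design_q, full_space, "non_compensatory", cfg=cfg)
        # warm-start the unconstrained model at the anchored solution
        B = qm.class_difficulty_matrix(anchored.params, anchored.layout)
        init = qm.QAMRMParams(
            difficulties=B.reshape(-1).copy(),
            mixing=anchored.params.mixing,
            ability_sd=anchored.params.ability_sd,
        )
        mrm = qm.fit_em(
            y, design_q, full_space, "non_compensatory", cfg=cfg,
            anchored=False, init_params=init,
        )
        assert mrm.n_params == 120 and anchored.n_params == 36
        assert mrm.loglik >= anchored.loglik - 1e-6

    def test_dimension_mismatch_names_both_counts(self, design_q, full_space):
        y = qm.ResponseMatrix(values=np.ones((20, 13)))
        with pytest.raises(ValueError, match="13.*14"):
            qm.fit_em(y, design_q, full_space, "non_compensatory")


class TestStandardErrors:
    def test_difficulty_ses_in_unit_interval_at_n4000(self, design_q, full_space):
        truth = qm.recovery_truth("non_compensatory")
        y, _, _ = qm.simulate_dataset(truth, 4000, seed=77)
        tp, layout, _ = truth.true_params()
        cfg = qm.FitConfig(
            n_starts=2, burn_iters=5, n_survivors=1, n_quadrature=21,
            seed=9, compute_se=False,
        )
        fit = qm.fit_em(y, design_q, full_space, "non_compensatory", cfg=cfg)
        se = qm.standard_errors(y, fit.params, fit.layout, n_quadrature=21)
        assert se.ok
        assert (se.difficulties > 0).all() and (se.difficulties < 1).all()
        assert np.isfinite(se.mixing).all() and se.ability_sd > 0

    def test_se_shrinks_like_root_n(self, design_q, full_space):
        """Doubling n shrinks the median difficulty SE by roughly 1/sqrt(2)."""
        truth = qm.recovery_truth("non_compensatory")
        cfg = qm.FitConfig(
            n_starts=2, burn_iters=5, n_survivors=1, n_quadrature=21,
            compute_se=False,
        )
        ratios = []
        for seed in (101, 202, 303):
            medians = []
            for n in (1000, 2000):
                y, _, _ = qm.simulate_dataset(truth, n, seed=seed + n)
                from dataclasses import replace

                fit = qm.fit_em(
                    y, design_q, full_space, "non_compensatory",
                    cfg=replace(cfg, seed=seed),
                )
                se = qm.standard_errors(y, fit.params, fit.layout, 21)
                medians.append(np.median(se.difficulties))
            ratios.append(medians[1] / medians[0])
        assert 0.6 <= np.median(ratios) <= 0.8

    def test_hessian_robust_to_step_size(self):
        q, space, layout = _rasch_setup(J=4, G1=True)
        rng = np.random.default_rng(6)
        theta = rng.normal(size=400)
        y = qm.ResponseMatrix(
            values=(rng.random((400, 4)) < expit(theta[:, None])).astype(float)
        )
        cfg = qm.FitConfig(
            n_starts=2, burn_iters=5, n_survivors=1, tol=1e-10,
            n_quadrature=21, seed=4, compute_se=False,
        )
        fit = qm.fit_em(y, q, space, "non_compensatory", cfg=cfg)
        h1 = observed_information(y, fit.params, fit.layout, 21, step=1e-4)
        h2 = observed_information(y, fit.params, fit.layout, 21, step=5e-5)
        np.testing.assert_allclose(np.diag(h1), np.diag(h2), rtol=1e-3)


class TestCriteriaAndDerived:
    def test_information_criteria_closed_forms(self):
        zero = qm.information_criteria(0.0, 0, 10)
        assert zero == {"AIC": 0.0, "BIC": 0.0, "ABIC": 0.0}
        ic = qm.information_criteria(-100.0, 5, 100)
        assert ic["AIC"] == pytest.approx(210.0)
        assert ic["BIC"] == pytest.approx(200 + 5 * np.log(100))
        assert ic["ABIC"] == pytest.approx(200 + 5 * np.log(102 / 24))

    def test_classify_modal_and_tie_rule(self, small_fit):
        fit = small_fit["fit"]
        cls = qm.classify(fit)
        assert cls.class_index.shape == (fit.posterior.shape[0],)
        # tie handling: a synthetic uniform row resolves to the lowest-mastery profile
        from dataclasses import replace

        uniform = replace(fit, posterior=np.full((2, 8), 1 / 8))
        tied = qm.classify(uniform)
        assert (tied.class_index == 0).all()
        assert tied.labels[0] == "000"
        assert tied.n_ties == 2

    def test_classification_beats_chance(self, small_fit):
        cls = qm.classify(small_fit["fit"])
        accuracy = (cls.class_index == small_fit["classes"]).mean()
        assert accuracy > 0.5  # chance is 1/8

    def test_eap_ordering_and_oracle(self):
        q, space, layout = _rasch_setup(J=4, G1=True)
        values = np.array(
            [[1.0, 1, 1, 1], [0.0, 0, 0, 0], [1.0, 0, 1, 0]]
        )
        y = qm.ResponseMatrix(values=values)
        params = qm.QAMRMParams(
            difficulties=np.array([-1.0, -0.3, 0.3, 1.0]), mixing=np.array([1.0]),
        )
        cfg = qm.FitConfig(n_quadrature=61, compute_se=False)
        amap = qm.build_anchor_map(q, space, "non_compensatory")
        fake_fit = qm.FitResult(
            params=params, layout=layout, space=space, amap=amap,
            anchored=True, loglik=0.0, loglik_path=np.array([0.0]),
            converged=True, iterations=0, posterior=np.ones((3, 1)),
            n_params=layout.n_total, n_obs=3,
            ic=qm.information_criteria(0.0, layout.n_total, 3),
            class_mass=np.array([1.0]), config=cfg,
        )
        eap, psd = qm.ability_estimates(fake_fit, y)
        assert eap[0] > eap[2] > eap[1]
        assert (psd > 0).all()
        # dense-grid posterior-mean oracle
        theta = np.linspace(-8, 8, 20001)
        dens = np.exp(-0.5 * theta**2) / np.sqrt(2 * np.pi)
        B = params.difficulties[layout.slot_of][:, 0]
        for i in range(3):
            lik = np.prod(
                np.where(values[i][None, :] == 1.0,
                         expit(theta[:, None] - B[None, :]),
                         1 - expit(theta[:, None] - B[None, :])),
                axis=1,
            )
            oracle = np.trapezoid(theta * lik * dens, theta) / np.trapezoid(
                lik * dens, theta
            )
            assert eap[i] == pytest.approx(oracle, abs=1e-4)

    def test_eap_antisymmetric_for_mirrored_persons(self):
        """Symmetric classes and a shared b=0 item: complementary answers give
        equal and opposite EAP abilities."""
        q = qm.QMatrix.from_array([[1]])
        space = qm.enumerate_profiles(1)
        layout = qm.build_layout(qm.build_anchor_map(q, space, "compensatory"))
        params = qm.QAMRMParams(
            difficulties=np.array([0.0, 0.0]), mixing=np.array([0.5, 0.5])
        )
        y = qm.ResponseMatrix(values=np.array([[1.0], [0.0]]))
        amap = qm.build_anchor_map(q, space, "compensatory")
        fit = qm.FitResult(
            params=params, layout=layout, space=space, amap=amap,
            anchored=True, loglik=0.0, loglik_path=np.array([0.0]),
            converged=True, iterations=0, posterior=np.full((2, 2), 0.5),
            n_params=layout.n_total, n_obs=2,
            ic=qm.information_criteria(0.0, layout.n_total, 2),
            class_mass=np.array([0.5, 0.5]),
            config=qm.FitConfig(n_quadrature=41, compute_se=False),
        )
        eap, _ = qm.ability_estimates(fit, y)
        assert eap[0] == pytest.approx(-eap[1], abs=1e-10)
        assert eap[0] > 0
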