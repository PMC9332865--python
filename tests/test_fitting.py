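"""Likelihood oracles, gradient checks, and penalized-fit contracts."""

import math

import numpy as np
import pandas as pd
import pytest

import copulageo as cg
from copulageo import copulas as cop
from copulageo import fitting, links


class TestCellProbabilities:
    def test_independence_half_half(self):
        assert fitting.cell_probabilities(0.5, 0.5, "independence") == pytest.approx(
            (0.25, 0.25, 0.25, 0.25)
        )

    def test_comonotone_limit(self):
        p11, *_ = fitting.cell_probabilities(0.3, 0.7, "gumbel", 50.0)
        assert p11 == pytest.approx(0.3, abs=1e-3)

    def test_pooled_sample_margins_under_independence(self):
        """Product of the observed marginal prevalences (0.3209, 0.8301) gives
        p11 ~= 0.2664, above the observed 0.2523 both-conditions share —
        the data exhibit *negative* association at these margins."""
        p11, *_ = fitting.cell_probabilities(0.3209, 0.8301, "independence")
        assert p11 == pytest.approx(0.2664, abs=5e-4)
        assert p11 > 0.2523

    def test_sum_to_one_and_frechet(self, rng):
        for fam, th in [("clayton", 2.0), ("gumbel", 3.0), ("frank", -4.0)]:
            p1 = rng.uniform(0.01, 0.99, 200)
            p2 = rng.uniform(0.01, 0.99, 200)
            p11, p10, p01, p00 = fitting.cell_probabilities(p1, p2, fam, th)
            for q in (p11, p10, p01, p00):
                assert np.all(q >= -1e-12)
            np.testing.assert_allclose(p11 + p10 + p01 + p00, 1.0, atol=1e-12)
            assert np.all(p11 <= np.minimum(p1, p2) + 1e-12)
            assert np.all(p11 >= np.maximum(p1 + p2 - 1, 0) - 1e-12)

    def test_p11_monotone_in_theta(self):
        """Concordance ordering: p11 nondecreasing in theta at fixed margins."""
        for fam, grid in [("gumbel", np.linspace(1.0, 10, 20)),
                          ("clayton", np.linspace(0.05, 10, 20))]:
            p11s = [fitting.cell_probabilities(0.4, 0.6, fam, th)[0] for th in grid]
            assert np.all(np.diff(p11s) >= -1e-12)


def _brute_force_loglik(beta1, beta2, theta, m1, m2, family, link_pair, y1, y2):
    """Independent record-by-record enumeration oracle."""
    total = 0.0
    for k in range(len(y1)):
        p1 = links.inverse_link(link_pair[0], float(m1[k] @ beta1))
        p2 = links.inverse_link(link_pair[1], float(m2[k] @ beta2))
        if family == "independence":
            c = p1 * p2
        else:
            c = cop.copula_cdf(family, theta, p1, p2)
        table = {(1, 1): c, (1, 0): p1 - c, (0, 1): p2 - c, (0, 0): 1 - p1 - p2 + c}
        total += math.log(max(table[(int(y1[k]), int(y2[k]))], 1e-300))
    return total


class TestJointLoglik:
    def test_single_record_independence(self):
        m = np.array([[1.0]])
        ll = fitting.joint_loglik(
            [0.0], [0.0], None, m, m, "independence", ("logit", "logit"), [1], [1]
        )
        assert ll == pytest.approx(math.log(0.25), abs=1e-12)

    @pytest.mark.parametrize("family, theta", [("gumbel", 2.0), ("clayton", 1.5),
                                               ("frank", -3.0), ("independence", None)])
    def test_matches_brute_force_enumeration(self, family, theta, rng):
        n, p = 10, 3
        m1 = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        m2 = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        b1, b2 = rng.normal(size=p) * 0.5, rng.normal(size=p) * 0.5
        y1, y2 = rng.integers(0, 2, n), rng.integers(0, 2, n)
        lp = ("logit", "probit")
        ll = fitting.joint_loglik(b1, b2, theta, m1, m2, family, lp, y1, y2)
        oracle = _brute_force_loglik(b1, b2, theta, m1, m2, family, lp, y1, y2)
        assert ll == pytest.approx(oracle, abs=1e-10)

    def test_duplicating_records_doubles_loglik(self, rng):
        n = 8
        m = np.column_stack([np.ones(n), rng.normal(size=n)])
        b = np.array([0.2, -0.4])
        y1, y2 = rng.integers(0, 2, n), rng.integers(0, 2, n)
        args = ("gumbel", ("logit", "logit"))
        ll = fitting.joint_loglik(b, b, 2.0, m, m, *args[:1], args[1], y1, y2)
        ll2 = fitting.joint_loglik(
            b, b, 2.0, np.vstack([m, m]), np.vstack([m, m]), args[0], args[1],
            np.concatenate([y1, y1]), np.concatenate([y2, y2]),
        )
        assert ll2 == pytest.approx(2 * ll, abs=1e-10)


class TestPenalizedLoglik:
    def test_zero_penalized_coefficients(self, rng):
        n = 12
        m = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
        b = np.zeros(4)
        s = np.eye(2)
        y1, y2 = rng.integers(0, 2, n), rng.integers(0, 2, n)
        ll = fitting.joint_loglik(b, b, 2.0, m, m, "gumbel", ("logit", "logit"), y1, y2)
        pll = fitting.penalized_loglik(
            b, b, 2.0, m, m, "gumbel", ("logit", "logit"), y1, y2,
            penalties=[(1, slice(2, 4), s, 10.0)],
        )
        assert pll == pytest.approx(ll)

    def test_quadratic_form_against_matrix_oracle(self, rng):
        n = 12
        m = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
        b1 = rng.normal(size=4)
        b2 = rng.normal(size=4)
        d = rng.normal(size=(2, 2))
        s = d.T @ d
        lam = 3.7
        y1, y2 = rng.integers(0, 2, n), rng.integers(0, 2, n)
        ll = fitting.joint_loglik(b1, b2, 1.5, m, m, "clayton", ("probit", "logit"), y1, y2)
        pll = fitting.penalized_loglik(
            b1, b2, 1.5, m, m, "clayton", ("probit", "logit"), y1, y2,
            penalties=[(2, slice(1, 3), s, lam)],
        )
        assert pll == pytest.approx(ll - 0.5 * lam * b2[1:3] @ s @ b2[1:3], abs=1e-10)

    def test_negative_lambda_rejected(self, rng):
        m = np.ones((3, 1))
        with pytest.raises(ValueError):
            fitting.penalized_loglik(
                [0.0], [0.0], 2.0, m, m, "gumbel", ("logit", "logit"), [1, 0, 1], [0, 1, 1],
                penalties=[(1, slice(0, 1), np.eye(1), -1.0)],
            )


class TestGradient:
    def test_analytic_gradient_matches_central_differences(self, rng):
        """Spot-check at 10 random points of a small joint problem."""
        n = 60
        ds = cg.simulate_dataset(cg.SyntheticConfig(n=n, grid=(2, 2), seed=5))
        spec = cg.ModelSpec(
            factors1=("sex", "wealth"), factors2=("sex", "wealth"),
            smooth_age=True, spatial_structured=False, spatial_unstructured=False,
            family="gumbel", links=("logit", "probit"),
        )
        from copulageo.design import DesignBuilder
        builder = DesignBuilder(spec, ds.graph).fit(ds.records)
        margins = builder.matrices(ds.records)
        core = fitting._likelihood_core(
            margins[0], margins[1], spec.family, spec.links,
            ds.records["anaemia"], ds.records["malnourished"],
        )
        blocks = fitting._assemble_blocks(margins)
        lambdas = {b["label"]: 0.5 for b in blocks if b["S"] is not None}
        prob = fitting._JointProblem(core, blocks, lambdas)
        for _ in range(10):
            x = rng.normal(size=prob.n_par) * 0.3
            _, g, _ = prob.grad_and_scores(x)
            h = 1e-6
            for j in rng.choice(prob.n_par, size=4, replace=False):
                xp, xm = x.copy(), x.copy()
                xp[j] += h
                xm[j] -= h
                fd = (prob.penalized_loglik(xp) - prob.penalized_loglik(xm)) / (2 * h)
                assert g[j] == pytest.approx(fd, rel=1e-5, abs=1e-7)


class TestFitModel:
    def test_independence_fit_equals_separate_glms(self, small_dataset):
        """Factorized likelihood: with the independence family and no
        penalized terms, the joint fit must match two univariate GLM fits
        (statsmodels IRLS oracle) to 1e-5."""
        import statsmodels.api as sm

        spec = cg.ModelSpec.fixed_effects_only(family="independence",
                                               links=("logit", "probit"))
        fit = cg.fit_model(spec, small_dataset.records)
        from copulageo.design import DesignBuilder
        builder = DesignBuilder(spec).fit(small_dataset.records)
        margins = builder.matrices(small_dataset.records)
        for m_idx, (outcome, fam_link) in enumerate(
            [("anaemia", sm.families.links.Logit()), ("malnourished", sm.families.links.Probit())]
        ):
            glm = sm.GLM(
                small_dataset.records[outcome].to_numpy(),
                margins[m_idx].M,
                family=sm.families.Binomial(link=fam_link),
            ).fit()
            mine = fit.params[fit.block_slice(m_idx + 1, "fixed")]
            np.testing.assert_allclose(mine, glm.params, atol=1e-5)

    def test_converged_fit_contract(self, fe_fit):
        assert fe_fit.converged
        assert fe_fit.gradient_norm < 1e-6
        assert fe_fit.edf == pytest.approx(31.0, abs=1e-4)
        assert fe_fit.aic == pytest.approx(-2 * fe_fit.loglik + 2 * fe_fit.edf)
        # covariance symmetric positive semidefinite
        assert np.allclose(fe_fit.covariance, fe_fit.covariance.T)
        assert np.linalg.eigvalsh(fe_fit.covariance).min() > -1e-10

    def test_loglik_at_optimum_beats_truth(self, small_dataset, fe_fit):
        """The ML property: the fitted likelihood is at least the likelihood
        at the generating parameters (same model family/links)."""
        ds = small_dataset
        spec = fe_fit.spec
        from copulageo.design import DesignBuilder
        builder = DesignBuilder(spec).fit(ds.records)
        margins = builder.matrices(ds.records)
        names1 = margins[0].coef_names
        names2 = margins[1].coef_names
        b1 = np.array([ds.config.beta1.get(nm, 0.0) for nm in names1])
        b2 = np.array([ds.config.beta2.get(nm, 0.0) for nm in names2])
        ll_true = fitting.joint_loglik(
            b1, b2, ds.config.theta, margins[0], margins[1], spec.family, spec.links,
            ds.records["anaemia"], ds.records["malnourished"],
        )
        assert fe_fit.loglik >= ll_true - 1e-8

    def test_single_outcome_pattern_rejected(self):
        df = pd.DataFrame(
            {
                "anaemia": [1] * 20,
                "malnourished": [1] * 20,
                "residence": ["rural"] * 20,
                "sex": ["male"] * 20,
                "age_months": list(range(20)),
                "mother_education": ["primary"] * 20,
                "birth_interval": ["<24"] * 20,
                "wealth": ["poor"] * 20,
                "birth_order": ["2-3"] * 20,
                "region_id": ["R00"] * 20,
            }
        )
        with pytest.raises(ValueError, match="outcome patterns"):
            cg.fit_model(cg.ModelSpec.fixed_effects_only(), df)

    def test_fit_is_deterministic(self, small_dataset):
        spec = cg.ModelSpec.fixed_effects_only(family="clayton", links=("logit", "logit"))
        f1 = cg.fit_model(spec, small_dataset.records)
        f2 = cg.fit_model(spec, small_dataset.records)
        np.testing.assert_array_equal(f1.params, f2.params)


class TestEffectiveDof:
    def test_unpenalized_equals_parameter_count(self, fe_fit):
        assert cg.effective_dof(fe_fit) == pytest.approx(fe_fit.n_params, abs=1e-4)

    def test_edf_monotone_in_lambda_with_floor(self, small_dataset):
        """Smooth-block EDF decreases with lambda toward the penalty's
        null-space dimension (1 for a centered second-order P-spline)."""
        spec = cg.ModelSpec(
            factors1=("sex",), factors2=("sex",), smooth_age=True,
            spatial_structured=False, spatial_unstructured=False,
            family="gumbel", links=("logit", "probit"),
        )
        edfs = []
        for lam in (1e-3, 1.0, 1e3, 1e8):
            opt = cg.FitOptions(select_lambda=False, init_lambda=lam)
            fit = cg.fit_model(spec, small_dataset.records, options=opt)
            edfs.append(fit.edf_by_block["smooth_age_1"] + fit.edf_by_block["smooth_age_2"])
        assert np.all(np.diff(edfs) < 0)
        assert edfs[0] <= 18.0 + 1e-6  # raw count: 9 per margin
        assert edfs[-1] == pytest.approx(2.0, abs=0.05)  # floor: 1 per margin
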