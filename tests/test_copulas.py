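"""Copula-family identities, generator properties, and Kendall's tau oracles."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from copulageo import copulas as cop

FAMILIES_THETAS = [("clayton", 0.5), ("clayton", 2.0), ("gumbel", 1.5), ("gumbel", 3.0),
                   ("frank", 5.0), ("frank", -2.0), ("frank", 0.5)]


def _random_theta(fam, rng):
    if fam == "clayton":
        return float(rng.uniform(0.1, 8.0))
    if fam == "gumbel":
        return float(1.0 + rng.uniform(0.0, 7.0))
    th = float(rng.uniform(-10.0, 10.0))
    return th if abs(th) > 1e-3 else 1.0


class TestGenerator:
    @pytest.mark.parametrize(
        "family, theta, t, expected",
        [
            ("gumbel", 3.0, 1.0, 0.0),
            ("clayton", 1.0, 0.5, 1.0),
            ("frank", 1.0, 0.5, 0.4740769841801),
        ],
    )
    def test_known_values(self, family, theta, t, expected):
        assert cop.generator(family, theta, t) == pytest.approx(expected, abs=1e-10)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            cop.generator("gumbel", 0.5, 0.5)  # theta < 1
        with pytest.raises(ValueError):
            cop.generator("clayton", -1.0, 0.5)
        with pytest.raises(ValueError):
            cop.generator("frank", 0.0, 0.5)
        with pytest.raises(ValueError):
            cop.generator("clayton", 1.0, 0.0)  # t <= 0
        with pytest.raises(ValueError):
            cop.generator("clayton", 1.0, -0.2)

    def test_shape_properties_random_draws(self, rng):
        """lam(1)=0, non-increasing and convex on (0,1): finite differences
        on 1000 random (family, theta, t) draws."""
        fams = ["clayton", "gumbel", "frank"]
        for _ in range(1000):
            fam = fams[rng.integers(3)]
            theta = _random_theta(fam, rng)
            t = float(rng.uniform(0.05, 0.9))
            h = 1e-4
            lam = lambda s: cop.generator(fam, theta, s)
            assert lam(1.0) == pytest.approx(0.0, abs=1e-12)
            assert lam(t + h) <= lam(t) + 1e-10  # non-increasing
            # convexity: second difference nonnegative
            assert lam(t - h) - 2 * lam(t) + lam(t + h) >= -1e-8


class TestPseudoInverse:
    @pytest.mark.parametrize("family, theta", FAMILIES_THETAS)
    def test_s_zero_maps_to_one(self, family, theta):
        assert cop.generator_pseudo_inverse(family, theta, 0.0) == pytest.approx(1.0)

    def test_known_values(self):
        assert cop.generator_pseudo_inverse("clayton", 1.0, 1.0) == pytest.approx(0.5)
        assert cop.generator_pseudo_inverse("gumbel", 2.0, 4.0) == pytest.approx(
            math.exp(-2.0), abs=1e-12
        )

    def test_negative_s_rejected(self):
        with pytest.raises(ValueError):
            cop.generator_pseudo_inverse("gumbel", 2.0, -0.1)

    @pytest.mark.parametrize("family, theta", FAMILIES_THETAS)
    def test_round_trip(self, family, theta, rng):
        t = rng.uniform(0.01, 1.0, size=50)
        s = np.asarray(cop.generator(family, theta, t))
        back = np.asarray(cop.generator_pseudo_inverse(family, theta, s))
        np.testing.assert_allclose(back, t, atol=1e-10)


class TestCdf:
    @pytest.mark.parametrize(
        "family, theta, u, v, expected",
        [
            ("gumbel", 1.0, 0.3, 0.7, 0.21),  # theta=1 reduces to independence
            ("clayton", 2.0, 0.5, 0.5, 7.0 ** -0.5),
            ("frank", 5.0, 0.4, 1.0, 0.4),  # boundary C(u, 1) = u
            ("clayton", 1.0, 1.0, 1.0, 1.0),
            ("independence", None, 0.25, 0.5, 0.125),
        ],
    )
    def test_known_values(self, family, theta, u, v, expected):
        assert cop.copula_cdf(family, theta, u, v) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("family", ["clayton", "gumbel", "frank"])
    def test_generator_construction_agrees_with_closed_form(self, family, rng):
        """The generic pseudo-inverse construction must reproduce the closed
        forms to 1e-9 across the domain (core oracle)."""
        for _ in range(300):
            theta = _random_theta(family, rng)
            u, v = rng.uniform(0.001, 0.999, size=2)
            a = cop.copula_cdf(family, theta, u, v)
            b = cop.copula_cdf_via_generator(family, theta, u, v)
            assert a == pytest.approx(b, abs=1e-9)

    @pytest.mark.parametrize("family", ["clayton", "gumbel", "frank"])
    def test_symmetry_and_associativity(self, family, rng):
        for _ in range(200):
            theta = _random_theta(family, rng)
            u, v, w = rng.uniform(0.01, 0.99, size=3)
            c = lambda a, b: cop.copula_cdf(family, theta, a, b)
            assert c(u, v) == pytest.approx(c(v, u), abs=1e-9)
            assert c(c(u, v), w) == pytest.approx(c(u, c(v, w)), abs=1e-9)

    @pytest.mark.parametrize("family", ["clayton", "gumbel", "frank"])
    def test_frechet_bounds_and_2_increasing(self, family, rng):
        for _ in range(500):
            theta = _random_theta(family, rng)
            u1, u2 = np.sort(rng.uniform(0, 1, size=2))
            v1, v2 = np.sort(rng.uniform(0, 1, size=2))
            c = lambda a, b: cop.copula_cdf(family, theta, a, b)
            for (a, b) in [(u1, v1), (u2, v2), (u1, v2), (u2, v1)]:
                assert max(a + b - 1.0, 0.0) - 1e-12 <= c(a, b) <= min(a, b) + 1e-12
            vol = c(u2, v2) - c(u1, v2) - c(u2, v1) + c(u1, v1)
            assert vol >= -1e-9

    @pytest.mark.parametrize("family", ["clayton", "gumbel"])
    def test_comonotone_limit(self, family, rng):
        """C -> min(u, v) for large theta (checked at theta=50; arguments are
        kept separated since convergence is slowest along the diagonal)."""
        u = rng.uniform(0.1, 0.9, size=20)
        v = np.clip(u + np.where(rng.random(20) < 0.5, -1, 1) * rng.uniform(0.08, 0.4, 20), 0.05, 0.95)
        c = np.asarray(cop.copula_cdf(family, 50.0, u, v))
        np.testing.assert_allclose(c, np.minimum(u, v), atol=1e-3)

    def test_partial_u_matches_finite_differences(self, rng):
        for fam in ("clayton", "gumbel", "frank"):
            theta = _random_theta(fam, rng)
            u, v = rng.uniform(0.05, 0.95, size=2)
            h = 1e-6
            fd = (cop.copula_cdf(fam, theta, u + h, v) - cop.copula_cdf(fam, theta, u - h, v)) / (2 * h)
            assert cop.copula_cdf_partial_u(fam, theta, u, v) == pytest.approx(fd, rel=1e-5)

    def test_partial_theta_matches_finite_differences(self, rng):
        for fam in ("clayton", "gumbel"):
            theta = _random_theta(fam, rng)
            u, v = rng.uniform(0.05, 0.95, size=2)
            h = 1e-6 * max(1.0, theta)
            fd = (cop.copula_cdf(fam, theta + h, u, v) - cop.copula_cdf(fam, theta - h, u, v)) / (2 * h)
            assert cop.copula_cdf_partial_theta(fam, theta, u, v) == pytest.approx(
                fd, rel=1e-4, abs=1e-8
            )


def _tau_generator_integral(family, theta):
    """Independent oracle: tau = 1 + 4 * int_0^1 lam(t)/lam'(t) dt."""
    def ratio(t):
        h = 1e-7
        lam = cop.generator(family, theta, t)
        dlam = (cop.generator(family, theta, min(t + h, 1.0)) - cop.generator(family, theta, t - h)) / (
            min(t + h, 1.0) - (t - h)
        )
        return lam / dlam

    val, _ = integrate.quad(ratio, 1e-9, 1 - 1e-9, limit=200)
    return 1.0 + 4.0 * val


class TestKendallTau:
    @pytest.mark.parametrize(
        "family, theta, expected",
        [("gumbel", 1.0, 0.0), ("gumbel", 2.0, 0.5), ("clayton", 2.0, 0.5)],
    )
    def test_reference_values(self, family, theta, expected):
        assert cop.kendall_tau_from_theta(family, theta) == pytest.approx(expected, abs=1e-4)

    @pytest.mark.parametrize(
        "family, theta",
        [("clayton", 0.8), ("clayton", 3.0), ("gumbel", 1.7), ("gumbel", 4.0), ("frank", 4.0)],
    )
    def test_against_generator_integral_oracle(self, family, theta):
        oracle = _tau_generator_integral(family, theta)
        assert cop.kendall_tau_from_theta(family, theta) == pytest.approx(oracle, abs=1e-4)

    def test_monotone_in_theta(self):
        for fam, grid in [("gumbel", np.linspace(1.01, 8, 25)), ("clayton", np.linspace(0.1, 8, 25))]:
            taus = [cop.kendall_tau_from_theta(fam, th) for th in grid]
            assert np.all(np.diff(taus) > 0)

    @pytest.mark.parametrize("family", ["clayton", "gumbel", "frank"])
    def test_round_trip(self, family, rng):
        for _ in range(20):
            theta = _random_theta(family, rng)
            tau = cop.kendall_tau_from_theta(family, theta)
            assert cop.theta_from_kendall_tau(family, tau) == pytest.approx(theta, abs=1e-8, rel=1e-6)

    def test_inverse_boundaries_and_range_errors(self):
        assert cop.theta_from_kendall_tau("gumbel", 0.0) == pytest.approx(1.0)
        assert cop.theta_from_kendall_tau("gumbel", 0.5) == pytest.approx(2.0, abs=1e-8)
        with pytest.raises(ValueError):
            cop.theta_from_kendall_tau("gumbel", -0.3)
        with pytest.raises(ValueError):
            cop.theta_from_kendall_tau("clayton", -0.2)

    def test_unconstrained_transform_round_trip(self):
        for fam, theta in FAMILIES_THETAS:
            eta = cop.theta_to_unconstrained(fam, theta)
            assert cop.theta_from_unconstrained(fam, eta) == pytest.approx(theta, abs=1e-12)


class TestEmpiricalTau2x2:
    def test_perfect_concordance(self):
        assert cop.empirical_kendall_tau_2x2([[50, 0], [0, 50]]).tau_b == pytest.approx(1.0)

    def test_proportional_rows_give_zero(self):
        res = cop.empirical_kendall_tau_2x2([[20, 20], [30, 30]])
        assert res.tau_b == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            cop.empirical_kendall_tau_2x2([[0, 0], [3, 4]])

    def test_matches_scipy_on_expanded_table(self):
        """tau-b on the printed contingency table equals scipy's tau-b on the
        fully expanded paired data, and the association is significant."""
        counts = np.array([[2916, 793], [6677, 1171]])
        res = cop.empirical_kendall_tau_2x2(counts)
        x, y = [], []
        for i in range(2):
            for j in range(2):
                x += [1 - i] * counts[i, j]
                y += [1 - j] * counts[i, j]
        sp = stats.kendalltau(x, y, variant="b")
        assert res.tau_b == pytest.approx(sp.statistic, abs=1e-12)
        assert res.p_value < 0.05
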