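"""Unit and property tests of the NBII / copula / zero-inflated densities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import zicoex as zx
from zicoex.copula import CellParams, bvn_cdf


def params(mu1=2.0, mu2=2.0, s1=0.5, s2=0.5, rho=0.0, p1=0.0, p2=0.0):
    return CellParams(mu1=mu1, mu2=mu2, sigma1=s1, sigma2=s2, rho=rho,
                      p1=p1, p2=p2)


class TestNegativeBinomial:
    def test_zero_class_closed_form(self):
        # (1 + sigma*mu)^(-1/sigma) at mu=sigma=1 is 1/2
        assert zx.nb_pmf(0, 1.0, 1.0) == pytest.approx(0.5, abs=1e-12)

    def test_poisson_limit(self):
        assert zx.nb_pmf(2, 2.0, 1e-9) == pytest.approx(
            stats.poisson.pmf(2, 2.0), rel=1e-8)

    def test_mean_variance_and_normalization(self):
        mu, sigma = 3.0, 0.5
        ymax = int(stats.nbinom.ppf(1 - 1e-12, 1 / sigma,
                                    1 / (1 + sigma * mu)))
        y = np.arange(ymax + 1)
        pmf = zx.nb_pmf(y, mu, sigma)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-10)
        assert (pmf * y).sum() == pytest.approx(mu, rel=1e-9)
        assert (pmf * y * y).sum() - mu ** 2 == pytest.approx(
            mu + mu * mu * sigma, rel=1e-8)

    def test_matches_scipy_parameterization(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 40, 300)
        mu = np.exp(rng.uniform(-2, 3, 300))
        sigma = np.exp(rng.uniform(-5, 2, 300))
        r = 1.0 / sigma
        np.testing.assert_allclose(
            zx.nb_pmf(y, mu, sigma), stats.nbinom.pmf(y, r, r / (r + mu)),
            atol=1e-12)
        np.testing.assert_allclose(
            zx.nb_cdf(y, mu, sigma), stats.nbinom.cdf(y, r, r / (r + mu)),
            atol=1e-12)

    def test_cdf_edges(self):
        assert zx.nb_cdf(-1, 2.0, 0.5) == 0.0
        assert zx.nb_cdf(0, 1.0, 1.0) == pytest.approx(zx.nb_pmf(0, 1.0, 1.0))
        assert zx.nb_cdf(10 ** 6, 3.0, 0.5) == pytest.approx(1.0, abs=1e-12)
        y = np.arange(-1, 30)
        cdf = zx.nb_cdf(y, 2.0, 1.0)
        assert np.all(np.diff(cdf) >= 0)

    @pytest.mark.parametrize("bad", [
        dict(y=1.5, mu=1.0, sigma=1.0), dict(y=1, mu=0.0, sigma=1.0),
        dict(y=1, mu=1.0, sigma=-0.2), dict(y=-2, mu=1.0, sigma=1.0)])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            zx.nb_pmf(**bad)


class TestBivariateNormal:
    def test_against_scipy_mvn(self):
        pts = [-2.3, -0.7, 0.0, 0.4, 1.9]
        rhos = [-0.999, -0.95, -0.4, 0.0, 0.3, 0.9, 0.999]
        for x1 in pts:
            for x2 in pts:
                for r in rhos:
                    ref = stats.multivariate_normal.cdf(
                        [x1, x2], cov=[[1, r], [r, 1]])
                    assert bvn_cdf(x1, x2, r) == pytest.approx(
                        ref, abs=5e-10), (x1, x2, r)

    def test_rho_domain(self):
        with pytest.raises(ValueError):
            bvn_cdf(0.0, 0.0, 1.0)


class TestCopulaCdf:
    def test_independence_factorizes(self):
        p = params(rho=0.0)
        for y1 in range(5):
            for y2 in range(5):
                assert zx.copula_cdf(y1, y2, p) == pytest.approx(
                    zx.nb_cdf(y1, 2.0, 0.5) * zx.nb_cdf(y2, 2.0, 0.5),
                    abs=1e-12)

    def test_empty_event(self):
        p = params(rho=0.4)
        assert zx.copula_cdf(-1, 3, p) == 0.0
        assert zx.copula_cdf(3, -1, p) == 0.0

    def test_comonotone_limit(self):
        p = params(rho=1 - 1e-13)
        for y in range(6):
            assert zx.copula_cdf(y, y, p) == pytest.approx(
                zx.nb_cdf(y, 2.0, 0.5), abs=1e-6)

    def test_frechet_upper_bound_and_monotone(self):
        p = params(rho=0.6)
        vals = np.array([[zx.copula_cdf(a, b, p) for b in range(6)]
                         for a in range(6)])
        assert np.all(np.diff(vals, axis=0) >= -1e-14)
        assert np.all(np.diff(vals, axis=1) >= -1e-14)
        for a in range(6):
            for b in range(6):
                assert vals[a, b] <= min(zx.nb_cdf(a, 2.0, 0.5),
                                         zx.nb_cdf(b, 2.0, 0.5)) + 1e-12

    def test_monte_carlo_rectangle(self):
        # P(Y1<=2, Y2<=3) via the generative mechanism (Gaussian pair ->
        # NB quantile transform), 1e6 draws
        rng = np.random.default_rng(42)
        n = 10 ** 6
        rho = 0.4
        z1 = rng.standard_normal(n)
        z2 = rho * z1 + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)
        v1 = zx.nb_quantile(stats.norm.cdf(z1), 2.0, 0.5)
        v2 = zx.nb_quantile(stats.norm.cdf(z2), 2.0, 0.5)
        est = np.mean((v1 <= 2) & (v2 <= 3))
        se = np.sqrt(est * (1 - est) / n)
        ours = zx.copula_cdf(2, 3, params(rho=rho))
        assert abs(ours - est) < 3 * se


class TestJointPmf:
    def test_independence_factorizes(self):
        p = params(rho=0.0)
        for y1 in range(5):
            for y2 in range(5):
                assert zx.joint_pmf(y1, y2, p) == pytest.approx(
                    float(zx.nb_pmf(y1, 2.0, 0.5)) *
                    float(zx.nb_pmf(y2, 2.0, 0.5)), abs=1e-12)

    def test_lattice_normalization(self):
        p = params(rho=0.5)
        ymax = int(stats.nbinom.ppf(1 - 1e-10, 2.0, 1 / (1 + 0.5 * 2.0)))
        g1, g2 = np.meshgrid(np.arange(ymax + 1), np.arange(ymax + 1))
        total = zx.joint_pmf(g1, g2, p).sum()
        assert total >= 1 - 1e-6
        assert total <= 1 + 1e-9

    def test_zero_zero_mass_monotone_in_rho(self):
        vals = [float(zx.joint_pmf(0, 0, params(rho=r)))
                for r in np.linspace(-0.9, 0.9, 13)]
        assert np.all(np.diff(vals) >= -1e-13)

    def test_nonnegative(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            p = params(mu1=np.exp(rng.uniform(-1, 2)),
                       mu2=np.exp(rng.uniform(-1, 2)),
                       s1=np.exp(rng.uniform(-2, 1)),
                       s2=np.exp(rng.uniform(-2, 1)),
                       rho=rng.uniform(-0.99, 0.99))
            y1, y2 = rng.integers(0, 20, 2)
            assert zx.joint_pmf(int(y1), int(y2), p) >= 0.0


class TestZeroInflatedJoint:
    def test_no_dropout_reduces_to_joint(self):
        p = params(rho=0.3)
        for y1 in range(4):
            for y2 in range(4):
                assert zx.zi_joint_pmf(y1, y2, p) == pytest.approx(
                    float(zx.joint_pmf(y1, y2, p)), abs=1e-15)

    def test_full_dropout_point_mass(self):
        p = params(rho=0.3, p1=1.0, p2=1.0)
        assert zx.zi_joint_pmf(0, 0, p) == pytest.approx(1.0, abs=1e-14)
        assert zx.zi_joint_pmf(1, 0, p) == 0.0
        assert zx.zi_joint_pmf(2, 3, p) == 0.0

    def test_marginalization_matches_zinb(self):
        p = params(rho=0.45, p1=0.15, p2=0.25)
        y2 = np.arange(0, 120)
        for y1 in (0, 1, 2):
            total = zx.zi_joint_pmf(np.full_like(y2, y1), y2, p).sum()
            assert total == pytest.approx(
                float(zx.zinb_marginal_pmf(y1, 2.0, 0.5, 0.15)), abs=1e-8)

    def test_zinb_marginal_example(self):
        assert zx.zinb_marginal_pmf(0, 1.0, 1.0, 0.2) == pytest.approx(
            0.2 + 0.8 * 0.5, abs=1e-12)
        y = np.arange(0, 80)
        assert zx.zinb_marginal_pmf(y, 2.0, 0.5, 0.3).sum() == pytest.approx(
            1.0, abs=1e-10)
        np.testing.assert_allclose(zx.zinb_marginal_pmf(y, 2.0, 0.5, 0.0),
                                   zx.nb_pmf(y, 2.0, 0.5), atol=1e-15)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(mu1=st.floats(0.1, 10), mu2=st.floats(0.1, 10),
       s1=st.floats(0.05, 3), s2=st.floats(0.05, 3),
       rho=st.floats(-0.9, 0.9), p1=st.floats(0.0, 0.9),
       p2=st.floats(0.0, 0.9))
def test_zi_joint_pmf_is_normalized_probability(mu1, mu2, s1, s2, rho, p1, p2):
    """For any valid parameters the mixture is a probability distribution."""
    p = params(mu1, mu2, s1, s2, rho, p1, p2)
    q1 = int(stats.nbinom.ppf(1 - 1e-10, 1 / s1, 1 / (1 + s1 * mu1)))
    q2 = int(stats.nbinom.ppf(1 - 1e-10, 1 / s2, 1 / (1 + s2 * mu2)))
    g1, g2 = np.meshgrid(np.arange(q1 + 1), np.arange(q2 + 1))
    vals = zx.zi_joint_pmf(g1, g2, p)
    assert np.all(vals >= 0)
    assert np.all(vals <= 1)
    assert vals.sum() >= 1 - 1e-6
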