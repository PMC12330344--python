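"""Penalized likelihood, derivatives, trust region, and the nested fit."""

import numpy as np
import pandas as pd
import pytest

import zicoex as zx
from zicoex.copula import CellParams
from zicoex.design import build_design
from zicoex.fitting import FitControl, fit, fit_inner, starting_values
from zicoex.trustregion import trust_region_maximize


def _reorder(u, blocks_from, blocks_to):
    """Map stacked random coefficients between two column orderings."""
    src = {}
    for t, names in blocks_from.znames.items():
        s = blocks_from.u_slices[t]
        for k, nm in enumerate(names):
            src[f"{t}.{nm}"] = u[s.start + k]
    out = np.zeros(blocks_to.n_u)
    for t, names in blocks_to.znames.items():
        s = blocks_to.u_slices[t]
        for k, nm in enumerate(names):
            out[s.start + k] = src[f"{t}.{nm}"]
    return out


def fd_gradient(f, x, h0=1e-5):
    g = np.empty_like(x)
    for i in range(len(x)):
        h = h0 * (1 + abs(x[i]))
        xp = x.copy(); xp[i] += h
        xm = x.copy(); xm[i] -= h
        g[i] = (f(xp) - f(xm)) / (2 * h)
    return g


class TestPenalizedLoglik:
    def test_hand_composition_on_three_cells(self):
        data = zx.GenePairData(
            y1=[0, 2, 5], y2=[1, 0, 3], patient=["a", "a", "a"],
            covariates=pd.DataFrame({"group": [0, 1, 0]}),
            depth=[100.0, 100.0, 100.0])
        spec = zx.ModelSpec.two_group(random_params=())
        blocks = build_design(data, spec)
        rng = np.random.default_rng(1)
        delta = rng.normal(0, 0.3, blocks.n_delta)
        state = zx.CoefState(delta=delta, u=np.zeros(0), lam=np.zeros(0))
        ll = zx.penalized_loglik(data, blocks, state)
        from zicoex.design import predict_params
        p = predict_params(blocks, state)
        expected = sum(
            np.log(zx.zi_joint_pmf(int(data.y1[i]), int(data.y2[i]),
                                   CellParams(*[np.atleast_1d(getattr(p, f))[i]
                                                for f in ("mu1", "mu2",
                                                          "sigma1", "sigma2",
                                                          "rho", "p1", "p2")])))
            for i in range(3))
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_penalty_structure(self, toy_pair, toy_blocks):
        sv = starting_values(toy_pair, toy_blocks)
        rng = np.random.default_rng(2)
        sv.u = rng.normal(0, 0.3, toy_blocks.n_u)
        lam0 = zx.CoefState(sv.delta, sv.u, np.zeros(toy_blocks.n_comp))
        lam5 = zx.CoefState(sv.delta, sv.u, np.full(toy_blocks.n_comp, 5.0))
        ll0 = zx.penalized_loglik(toy_pair, toy_blocks, lam0)
        ll5 = zx.penalized_loglik(toy_pair, toy_blocks, lam5)
        assert ll0 - ll5 == pytest.approx(2.5 * np.sum(sv.u ** 2), rel=1e-10)
        # u = 0: penalty vanishes for any lambda
        z0 = zx.CoefState(sv.delta, np.zeros_like(sv.u),
                          np.full(toy_blocks.n_comp, 5.0))
        z1 = zx.CoefState(sv.delta, np.zeros_like(sv.u),
                          np.zeros(toy_blocks.n_comp))
        assert zx.penalized_loglik(toy_pair, toy_blocks, z0) == pytest.approx(
            zx.penalized_loglik(toy_pair, toy_blocks, z1), rel=1e-14)


class TestGradHess:
    def test_matches_central_differences(self, toy_pair, toy_blocks):
        sv = starting_values(toy_pair, toy_blocks)
        rng = np.random.default_rng(3)
        for _ in range(5):
            state = zx.CoefState(
                delta=sv.delta + rng.normal(0, 0.15, toy_blocks.n_delta),
                u=rng.normal(0, 0.15, toy_blocks.n_u),
                lam=np.full(toy_blocks.n_comp, 10.0))
            g, H = zx.grad_hess(toy_pair, toy_blocks, state)
            beta = state.beta

            def f(b):
                st = zx.CoefState.from_beta(b, toy_blocks, state.lam)
                return zx.penalized_loglik(toy_pair, toy_blocks, st)

            gfd = fd_gradient(f, beta)
            assert np.linalg.norm(g - gfd) / np.linalg.norm(gfd) < 1e-5
            f0 = f(beta)
            for i in range(0, len(beta), 5):
                h = 1e-3 * (1 + abs(beta[i]))
                bp = beta.copy(); bp[i] += h
                bm = beta.copy(); bm[i] -= h
                hfd = (f(bp) - 2 * f0 + f(bm)) / h ** 2
                assert abs(H[i, i] - hfd) / max(1.0, abs(hfd)) < 1e-3

    def test_penalty_gradient_is_exact(self, toy_pair, toy_blocks):
        sv = starting_values(toy_pair, toy_blocks)
        rng = np.random.default_rng(4)
        u = rng.normal(0, 0.2, toy_blocks.n_u)
        lam = np.full(toy_blocks.n_comp, 7.0)
        g1, _ = zx.grad_hess(toy_pair, toy_blocks,
                             zx.CoefState(sv.delta, u, lam))
        g0, _ = zx.grad_hess(toy_pair, toy_blocks,
                             zx.CoefState(sv.delta, u,
                                          np.zeros(toy_blocks.n_comp)))
        np.testing.assert_allclose(
            (g0 - g1)[toy_blocks.n_delta:],
            toy_blocks.penalty_diag(lam)[toy_blocks.n_delta:] * u,
            atol=1e-12)

    def test_symmetric_hessian(self, toy_pair, toy_blocks):
        sv = starting_values(toy_pair, toy_blocks)
        sv.lam = np.ones(toy_blocks.n_comp)
        _, H = zx.grad_hess(toy_pair, toy_blocks, sv)
        np.testing.assert_allclose(H, H.T, atol=1e-12)


class TestTrustRegion:
    def test_quadratic_converges_fast(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(4, 4))
        A = A @ A.T + np.eye(4)
        xstar = np.array([3.0, -2.0, 1.0, 0.5])

        def fun(x):
            d = x - xstar
            return -0.5 * d @ A @ d

        def fgh(x):
            d = x - xstar
            return fun(x), -A @ d, -A

        res = trust_region_maximize(fun, fgh, np.zeros(4))
        assert res.converged
        assert res.n_iter <= 10
        np.testing.assert_allclose(res.x, xstar, atol=1e-8)

    def test_overshoot_shrinks_radius_and_growth(self):
        # quartic with a deliberately flat curvature model: predicted gains
        # far exceed actual ones, so candidate steps get rejected and the
        # radius must shrink
        def fun(x):
            return -float(x[0] ** 4)

        def fgh(x):
            return fun(x), np.array([-4 * x[0] ** 3]), np.array([[-1e-3]])

        res = trust_region_maximize(fun, fgh, np.array([2.0]), radius=5.0,
                                    max_iter=80)
        assert res.radius < 5.0
        assert res.fun > fun(np.array([2.0]))
        # accurate model + boundary steps grow the radius: a distant
        # quadratic optimum is still reached quickly from a small radius
        A = np.eye(2)
        xstar = np.array([6.0, -6.0])

        def qfun(x):
            d = x - xstar
            return -0.5 * d @ A @ d

        def qfgh(x):
            d = x - xstar
            return qfun(x), -d, -A

        res2 = trust_region_maximize(qfun, qfgh, np.zeros(2), radius=0.5)
        assert res2.converged and res2.radius > 0.5
        np.testing.assert_allclose(res2.x, xstar, atol=1e-8)

    def test_iteration_cap_returns_flag_not_exception(self, toy_pair,
                                                      toy_blocks):
        sv = starting_values(toy_pair, toy_blocks)
        ctrl = FitControl(max_iter=1, polish_iter=1, bhhh_impr=0.0)
        res = fit_inner(toy_pair, toy_blocks, np.ones(toy_blocks.n_comp),
                        sv, ctrl)
        assert res.converged is False

    def test_ascent_from_start(self, toy_pair, toy_blocks):
        sv = starting_values(toy_pair, toy_blocks)
        lam = np.full(toy_blocks.n_comp, 10.0)
        res = fit_inner(toy_pair, toy_blocks, lam, sv)
        start_ll = zx.penalized_loglik(
            toy_pair, toy_blocks, zx.CoefState(sv.delta, sv.u, lam))
        assert res.loglik_pen >= start_ll
        assert np.max(np.abs(res.grad)) < 1e-5


class TestStartingValues:
    def test_no_zero_margin_clipped(self):
        rng = np.random.default_rng(6)
        n = 80
        data = zx.GenePairData(
            y1=rng.poisson(30, n) + 1, y2=rng.poisson(5, n),
            patient=np.repeat(["a", "b"], n // 2),
            covariates=pd.DataFrame({"group": np.tile([0, 1], n // 2)}),
            depth=np.full(n, 1e4))
        blocks = build_design(data, zx.ModelSpec.two_group())
        sv = starting_values(data, blocks)
        assert sv.delta[blocks.delta_slices["p1"]][0] == -15.0

    def test_degenerate_margin_raises(self):
        data = zx.GenePairData(
            y1=np.zeros(10, dtype=int), y2=np.ones(10, dtype=int),
            patient=["a"] * 10, covariates=pd.DataFrame({"group": [0] * 10}),
            depth=np.full(10, 1e4))
        blocks = build_design(data, zx.ModelSpec.two_group())
        with pytest.raises(ValueError, match="degenerate margin"):
            starting_values(data, blocks)

    def test_moment_start_no_zeros(self):
        rng = np.random.default_rng(7)
        n = 60
        y1 = rng.poisson(20, n) + 1
        data = zx.GenePairData(
            y1=y1, y2=rng.poisson(20, n) + 1, patient=["a"] * n,
            covariates=pd.DataFrame({"group": [0] * n}),
            depth=np.full(n, 5e3))
        spec = zx.ModelSpec.two_group(random_params=())
        blocks = build_design(data, spec)
        sv = starting_values(data, blocks)
        # single covariate pattern: rate = sum(y) / sum(S)
        assert sv.delta[blocks.delta_slices["mu1"]][0] == pytest.approx(
            np.log(y1.sum() / (n * 5e3)), abs=1e-10)

    def test_non_dropout_random_effects_start_at_zero(self, toy_pair,
                                                      toy_blocks):
        sv = starting_values(toy_pair, toy_blocks)
        for t in ("mu1", "mu2", "rho"):
            s = toy_blocks.u_slices[t]
            np.testing.assert_array_equal(sv.u[s], 0.0)


class TestFit:
    def test_large_patient_effects_select_smaller_lambda(self):
        big = zx.simulate(zx.droplet_preset(
            n_patients=6, cells_per_patient=80,
            re_sd={"mu1": 0.8, "mu2": 0.8, "rho": 0.2, "p1": 0.1,
                   "p2": 0.1}), seed=21)
        tiny = zx.simulate(zx.droplet_preset(
            n_patients=6, cells_per_patient=80,
            re_sd={"mu1": 0.02, "mu2": 0.02, "rho": 0.2, "p1": 0.1,
                   "p2": 0.1}), seed=21)
        rb = fit(big.to_pair_data())
        rt = fit(tiny.to_pair_data())
        i = rb.blocks.comp_names.index("mu1|patient")
        assert rb.state.lam[i] < rt.state.lam[i]
        assert np.isfinite(rb.state.lam[i])

    def test_single_fit_recovers_tau1(self):
        ds = zx.simulate(zx.droplet_preset(n_patients=15,
                                           cells_per_patient=500), seed=22)
        res = fit(ds.to_pair_data())
        assert res.converged
        from zicoex.inference import wald
        w = wald(res, "rho.group")
        assert abs(w.estimate - (-0.20)) < 3 * w.se
        assert res.blocks.n_delta <= res.edf <= res.blocks.n_coef

    def test_cell_permutation_invariance(self, droplet_small):
        # all seven parameters identified (zeros and over-dispersion
        # present), so the optimum is unique and order-independent
        data = droplet_small.to_pair_data()
        blocks = build_design(data, zx.ModelSpec.two_group())
        sv = starting_values(data, blocks)
        lam = np.full(blocks.n_comp, 10.0)
        res = fit_inner(data, blocks, lam, sv)
        perm = np.random.default_rng(8).permutation(data.n_cells)
        shuffled = data.subset(perm)
        blocks_p = build_design(shuffled, zx.ModelSpec.two_group())
        sv_p = starting_values(shuffled, blocks_p)
        sv_p = zx.CoefState(sv.delta.copy(),
                            _reorder(sv.u, blocks, blocks_p), sv.lam.copy())
        res_p = fit_inner(shuffled, blocks_p, lam, sv_p)
        # random-effect columns follow first-appearance order, so compare
        # coefficients by name
        ours = dict(zip(blocks.coef_names, res.state.beta))
        theirs = dict(zip(blocks_p.coef_names, res_p.state.beta))
        assert set(ours) == set(theirs)
        for name in ours:
            assert abs(ours[name] - theirs[name]) < 1e-8, name

    def test_lambda_upper_bound_shrinks_u(self, toy_pair, toy_blocks):
        sv = starting_values(toy_pair, toy_blocks)
        res = fit_inner(toy_pair, toy_blocks,
                        np.full(toy_blocks.n_comp, 1e8), sv)
        assert np.max(np.abs(res.state.u)) < 1e-4

    def test_aic_grid_agrees_with_em_on_tau1(self, droplet_small):
        data = droplet_small.to_pair_data()
        r_em = fit(data, control=FitControl(lambda_method="em"))
        r_grid = fit(data, control=FitControl(
            lambda_method="aic_grid",
            lambda_grid=tuple(np.logspace(-1, 4, 6)), refine=False))
        t_em = r_em.state.delta[r_em.blocks.delta_slices["rho"]][1]
        t_gr = r_grid.state.delta[r_grid.blocks.delta_slices["rho"]][1]
        assert abs(t_em - t_gr) < 0.02
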