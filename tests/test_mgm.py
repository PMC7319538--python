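"""Pseudo-likelihood objective, gradient, proximal operator, and fitting."""

import numpy as np
import pandas as pd
import pytest

from causalmix.dataset import from_dataframe
from causalmix.mgm import (
    MGM,
    LambdaTriple,
    MGMParameters,
    extract_graph,
    fit_mgm,
    negative_pseudo_loglik,
    prepare_mgm_data,
    proximal_operator,
    pseudo_loglik_gradient,
)
from causalmix.simulate import SimulationConfig, random_mixed_graph, sample_mixed_data

LOG_2PI = np.log(2 * np.pi)


def small_mixed_data(seed, n=60, p_cont=3, p_disc=2, levels=3):
    cfg = SimulationConfig(p_continuous=p_cont, p_discrete=p_disc, levels=levels,
                           expected_degree=2, n=n, seed=seed)
    ds = sample_mixed_data(random_mixed_graph(cfg), n=n, seed=seed + 100)
    return prepare_mgm_data(ds, standardize=True)


def random_params(data, seed, scale=0.2):
    rng = np.random.default_rng(seed)
    p = MGMParameters.zeros(data.cont_names, data.disc_names, data.levels)
    B = rng.normal(size=p.beta.shape) * scale
    p.beta = (B + B.T) / 2
    np.fill_diagonal(p.beta, 0.0)
    p.rho = rng.normal(size=p.rho.shape) * scale
    P = rng.normal(size=p.phi.shape) * scale
    p.phi = (P + P.T) / 2
    off = p.offsets
    for j in range(len(data.levels)):
        p.phi[off[j]:off[j + 1], off[j]:off[j + 1]] = 0.0
    p.alpha_c = rng.normal(size=p.alpha_c.shape) * scale
    p.alpha_d = rng.normal(size=p.alpha_d.shape) * scale
    return p


def free_indices(params):
    """Free coordinates: symmetric upper triangles for beta/phi (excluding
    phi's structural-zero diagonal blocks), everything else elementwise."""
    out = []
    off = params.offsets

    def phi_block_of(i):
        return int(np.searchsorted(off[1:], i, side="right"))

    for name in ("alpha_c", "beta", "rho", "phi", "alpha_d"):
        arr = getattr(params, name)
        for idx in np.ndindex(arr.shape):
            if name in ("beta", "phi") and idx[0] >= idx[1]:
                continue
            if name == "phi" and phi_block_of(idx[0]) == phi_block_of(idx[1]):
                continue
            out.append((name, idx))
    return out


class TestObjective:
    def test_zero_params_closed_form(self):
        data = small_mixed_data(seed=0)
        params = MGMParameters.zeros(data.cont_names, data.disc_names, data.levels)
        val = negative_pseudo_loglik(params, data)
        expected = sum(
            0.5 * np.mean(data.Xc[:, s] ** 2) + 0.5 * LOG_2PI
            for s in range(len(data.cont_names))
        ) + sum(np.log(L) for L in data.levels)
        assert val == pytest.approx(expected, rel=1e-12)

    def test_matches_nodewise_oracle(self):
        # independent re-computation: one conditional NLL per node
        data = small_mixed_data(seed=1)
        params = random_params(data, seed=2)
        n = data.n
        total = 0.0
        for s in range(len(data.cont_names)):
            eta = (params.alpha_c[s]
                   + data.Xc @ params.beta[s]
                   + data.D @ params.rho[s])
            total += np.mean(0.5 * (data.Xc[:, s] - eta) ** 2) + 0.5 * LOG_2PI
        for j in range(len(data.levels)):
            sl = params.cols(j)
            scores = (params.alpha_d[sl]
                      + data.Xc @ params.rho[:, sl]
                      + data.D @ params.phi[:, sl])
            num = scores[np.arange(n), data.codes[:, j]]
            lse = np.log(np.exp(scores).sum(axis=1))
            total += np.mean(lse - num)
        assert negative_pseudo_loglik(params, data) == pytest.approx(total, rel=1e-10)


class TestGradient:
    def test_zero_point_intercept_gradient_vanishes(self):
        data = small_mixed_data(seed=3)
        params = MGMParameters.zeros(data.cont_names, data.disc_names, data.levels)
        g = pseudo_loglik_gradient(params, data)
        # standardized data: mean(x_s) = 0 so the intercept gradient is 0
        np.testing.assert_allclose(g.alpha_c, 0.0, atol=1e-12)

    def test_beta_gradient_symmetric(self):
        data = small_mixed_data(seed=4)
        g = pseudo_loglik_gradient(random_params(data, seed=5), data)
        np.testing.assert_allclose(g.beta, g.beta.T)
        np.testing.assert_allclose(g.phi, g.phi.T)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_central_finite_differences(self, seed):
        data = small_mixed_data(seed=seed, p_cont=3, p_disc=2)
        params = random_params(data, seed=seed + 10)
        grad = pseudo_loglik_gradient(params, data)
        h = 1e-5
        worst = 0.0
        for name, idx in free_indices(params):
            p2 = params.copy()
            arr = getattr(p2, name)
            sym = name in ("beta", "phi")
            arr[idx] += h
            if sym:
                arr[idx[::-1]] += h
            f_plus = negative_pseudo_loglik(p2, data)
            arr[idx] -= 2 * h
            if sym:
                arr[idx[::-1]] -= 2 * h
            f_minus = negative_pseudo_loglik(p2, data)
            est = (f_plus - f_minus) / (2 * h)
            ana = getattr(grad, name)[idx]
            denom = max(1e-6, abs(est), abs(ana))
            worst = max(worst, abs(est - ana) / denom)
        assert worst < 1e-4

    def test_shape_mismatch_errors(self):
        data = small_mixed_data(seed=6)
        wrong = MGMParameters.zeros(["a", "b"], [], [])
        with pytest.raises(ValueError):
            negative_pseudo_loglik(wrong, data)


class TestProximalOperator:
    def _params(self):
        data = small_mixed_data(seed=7)
        return random_params(data, seed=8)

    def test_zero_lambda_is_identity(self):
        p = self._params()
        out = proximal_operator(p, LambdaTriple(0, 0, 0), step=0.5)
        np.testing.assert_allclose(out.beta, p.beta)
        np.testing.assert_allclose(out.rho, p.rho)
        np.testing.assert_allclose(out.phi, p.phi)

    def test_scalar_soft_threshold(self):
        p = MGMParameters.zeros(["a", "b"], [], [])
        p.beta[0, 1] = p.beta[1, 0] = 3.0
        out = proximal_operator(p, LambdaTriple(1.0, 0, 0), step=1.0)
        assert out.beta[0, 1] == pytest.approx(2.0)

    def test_group_threshold_zeroes_small_blocks(self):
        p = self._params()
        lam = LambdaTriple(0.0, 1e6, 1e6)
        out = proximal_operator(p, lam, step=1.0)
        assert not np.any(out.rho)
        assert not np.any(out.phi)

    def test_group_shrinkage_factor(self):
        data = small_mixed_data(seed=9)
        p = MGMParameters.zeros(data.cont_names, data.disc_names, data.levels)
        blk = np.array([3.0, -4.0, 0.0])  # norm 5
        p.rho[0, p.cols(0)] = blk
        out = proximal_operator(p, LambdaTriple(0, 1.0, 0), step=1.0)
        np.testing.assert_allclose(out.rho[0, p.cols(0)], blk * (1 - 1.0 / 5.0))

    def test_bad_step_errors(self):
        with pytest.raises(ValueError):
            proximal_operator(self._params(), LambdaTriple(0, 0, 0), step=0.0)


class TestFit:
    def test_huge_lambda_gives_empty_graph(self):
        cfg = SimulationConfig(p_continuous=4, p_discrete=3, expected_degree=2, seed=10)
        ds = sample_mixed_data(random_mixed_graph(cfg), n=200, seed=11)
        fit = fit_mgm(ds, lambdas=(1e6, 1e6, 1e6))
        assert extract_graph(fit.params).n_edges == 0

    def test_strong_correlation_edge_recovered(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=1000)
        y = 0.8 * x + 0.6 * rng.normal(size=1000)
        ds = from_dataframe(pd.DataFrame({"x": x, "y": y}))
        fit = fit_mgm(ds, lambdas=(0.1, 0.1, 0.1))
        assert extract_graph(fit.params).has_edge("x", "y")

    @pytest.mark.parametrize("seed,lambdas", [
        (0, (0.05, 0.05, 0.05)),
        (1, (0.25, 0.25, 0.25)),
        (2, (0.5, 0.5, 0.5)),
    ])
    def test_objective_trace_non_increasing(self, seed, lambdas):
        cfg = SimulationConfig(p_continuous=4, p_discrete=3, expected_degree=2,
                               seed=seed)
        ds = sample_mixed_data(random_mixed_graph(cfg), n=300, seed=seed + 50)
        fit = fit_mgm(ds, lambdas=lambdas)
        trace = np.asarray(fit.objective_trace)
        assert np.all(np.diff(trace) <= 1e-10)
        assert fit.converged

    def test_zero_lambda_dense_graph(self):
        # with n >> p and no penalty, essentially all blocks are nonzero
        cfg = SimulationConfig(p_continuous=4, p_discrete=2, expected_degree=2,
                               seed=13)
        ds = sample_mixed_data(random_mixed_graph(cfg), n=500, seed=14)
        fit = fit_mgm(ds, lambdas=(0, 0, 0))
        g = extract_graph(fit.params, eps=1e-8)
        assert g.n_edges == 6 * 5 // 2

    def test_continuous_only_matches_nodewise_lasso(self):
        # neighborhood selection: sklearn Lasso per node at penalty lam/2
        # (each beta entry appears in two node conditionals) should agree
        # with the joint pseudo-likelihood support on >= 95% of pairs
        from sklearn.linear_model import Lasso

        cfg = SimulationConfig(p_continuous=10, p_discrete=0,
                               expected_degree=2, seed=15)
        ds = sample_mixed_data(random_mixed_graph(cfg), n=500, seed=16)
        lam = 0.15
        fit = fit_mgm(ds, lambdas=(lam, lam, lam))
        est = extract_graph(fit.params)

        X = np.column_stack([ds.column(c) for c in ds.continuous_names])
        X = (X - X.mean(0)) / X.std(0)
        p = X.shape[1]
        support = np.zeros((p, p), dtype=bool)
        for s in range(p):
            others = [t for t in range(p) if t != s]
            model = Lasso(alpha=lam / 2, fit_intercept=True)
            model.fit(X[:, others], X[:, s])
            for t, coef in zip(others, model.coef_):
                if abs(coef) > 1e-8:
                    support[s, t] = True
        agree = 0
        total = 0
        names = ds.continuous_names
        for s in range(p):
            for t in range(s + 1, p):
                nodewise = support[s, t] or support[t, s]  # OR rule
                total += 1
                agree += nodewise == est.has_edge(names[s], names[t])
        assert agree / total >= 0.95

    def test_extract_graph_single_rho_block(self):
        p = MGMParameters.zeros(["c1", "c2"], ["d1", "d2"], [2, 2])
        p.rho[0, p.cols(1)] = [0.5, -0.5]
        g = extract_graph(p)
        assert g.n_edges == 1
        assert g.has_edge("c1", "d2")

    def test_estimator_api(self):
        cfg = SimulationConfig(p_continuous=4, p_discrete=2, expected_degree=2,
                               seed=17)
        ds = sample_mixed_data(random_mixed_graph(cfg), n=200, seed=18)
        est = MGM(lambda_cc=0.2, lambda_cd=0.2, lambda_dd=0.2)
        est.fit(ds.frame if hasattr(ds, "frame") else ds)
        assert hasattr(est, "graph_")
        assert est.get_params()["lambda_cc"] == 0.2
        cloned = est.set_params(lambda_cc=0.3)
        assert cloned.lambda_cc == 0.3
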