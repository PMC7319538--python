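"""Sparse pairwise mixed graphical models via penalized pseudo-likelihood.

The model is the standard pairwise Markov random field over continuous and
categorical variables (Lee–Hastie form).  Each continuous node x_s has a
Gaussian conditional with unit variance and linear predictor

    eta_s = alpha_s + sum_t beta_st x_t + sum_j rho_sj(y_j),

and each categorical node y_j has a multinomial-logistic conditional with
per-level scores

    score_j(l) = alpha_j(l) + sum_s rho_sj(l) x_s + sum_r phi_rj(y_r, l).

The fit minimizes the average negative log pseudo-likelihood (the sum of
the node-conditional negative log-likelihoods) plus edge-type-specific
sparsity penalties: an l1 penalty lambda_cc on each beta_st, a group-l2
penalty lambda_cd on each rho_sj vector and a group-Frobenius penalty
lambda_dd on each phi_rj matrix.  Optimization is proximal gradient with
backtracking line search and (by default) FISTA acceleration with a
monotone restart, so the recorded penalized objective never increases.

Identifiability: rho vectors are mean-centered over levels and phi blocks
are doubly centered after every proximal step; the shifts are absorbed into
the intercepts, which leaves every node conditional — and hence the smooth
loss — exactly unchanged while never increasing the group norms (centering
is an orthogonal projection).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .dataset import MixedDataset, as_mixed_dataset
from .graph import EndpointGraph

LOG_2PI = float(np.log(2.0 * np.pi))


class LambdaTriple(NamedTuple):
    """Penalty weights for the three edge types."""

    lambda_cc: float
    lambda_cd: float
    lambda_dd: float

    def validate(self) -> "LambdaTriple":
        for v in self:
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"penalty weights must be finite and >= 0, got {self}")
        return self


@dataclass
class MGMParameters:
    """Node and pairwise potentials of a pairwise mixed graphical model.

    Shapes: ``alpha_c`` (pc,); ``beta`` (pc, pc) symmetric with zero
    diagonal; ``rho`` (pc, Ltot) where Ltot is the total level count over
    discrete variables; ``phi`` (Ltot, Ltot) symmetric with zero diagonal
    blocks; ``alpha_d`` (Ltot,).
    """

    cont_names: tuple[str, ...]
    disc_names: tuple[str, ...]
    levels: tuple[int, ...]
    alpha_c: np.ndarray
    beta: np.ndarray
    rho: np.ndarray
    phi: np.ndarray
    alpha_d: np.ndarray

    @classmethod
    def zeros(
        cls,
        cont_names: Sequence[str],
        disc_names: Sequence[str],
        levels: Sequence[int],
    ) -> "MGMParameters":
        pc, ltot = len(cont_names), int(sum(levels))
        return cls(
            cont_names=tuple(cont_names),
            disc_names=tuple(disc_names),
            levels=tuple(int(l) for l in levels),
            alpha_c=np.zeros(pc),
            beta=np.zeros((pc, pc)),
            rho=np.zeros((pc, ltot)),
            phi=np.zeros((ltot, ltot)),
            alpha_d=np.zeros(ltot),
        )

    # -- block bookkeeping ----------------------------------------------
    @property
    def offsets(self) -> np.ndarray:
        return np.concatenate(([0], np.cumsum(self.levels))).astype(int)

    def cols(self, j: int) -> slice:
        off = self.offsets
        return slice(off[j], off[j + 1])

    def rho_block(self, s: int, j: int) -> np.ndarray:
        return self.rho[s, self.cols(j)]

    def phi_block(self, r: int, j: int) -> np.ndarray:
        return self.phi[self.cols(r), self.cols(j)]

    def copy(self) -> "MGMParameters":
        return MGMParameters(
            self.cont_names, self.disc_names, self.levels,
            self.alpha_c.copy(), self.beta.copy(), self.rho.copy(),
            self.phi.copy(), self.alpha_d.copy(),
        )

    def _arrays(self) -> tuple[np.ndarray, ...]:
        return (self.alpha_c, self.beta, self.rho, self.phi, self.alpha_d)


def _combine(a: MGMParameters, b: MGMParameters, ca: float, cb: float) -> MGMParameters:
    """ca*a + cb*b, elementwise over all parameter arrays."""
    out = a.copy()
    for xa, xb in zip(out._arrays(), b._arrays()):
        xa *= ca
        xa += cb * xb
    return out


# beta and phi store each free parameter twice (symmetric matrices), so
# inner products in the free parameter space weight those arrays by 1/2
_WEIGHTS = (1.0, 0.5, 1.0, 0.5, 1.0)  # alpha_c, beta, rho, phi, alpha_d


def _sqdist(a: MGMParameters, b: MGMParameters) -> float:
    return float(sum(
        w * np.sum((xa - xb) ** 2)
        for w, xa, xb in zip(_WEIGHTS, a._arrays(), b._arrays())
    ))


def _inner(a: MGMParameters, b: MGMParameters) -> float:
    return float(sum(
        w * np.sum(xa * xb)
        for w, xa, xb in zip(_WEIGHTS, a._arrays(), b._arrays())
    ))


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

@dataclass
class _MGMData:
    """Design matrices for the pseudo-likelihood: standardized-or-raw
    continuous block Xc (n, pc) and one-hot discrete block D (n, Ltot)."""

    cont_names: tuple[str, ...]
    disc_names: tuple[str, ...]
    levels: tuple[int, ...]
    Xc: np.ndarray
    D: np.ndarray
    codes: np.ndarray  # (n, pd) integer level codes

    @property
    def n(self) -> int:
        return self.Xc.shape[0] if self.Xc.size else self.D.shape[0]


def prepare_mgm_data(dataset: MixedDataset, standardize: bool = False) -> _MGMData:
    cont = dataset.continuous_names
    disc = dataset.categorical_names
    n = dataset.n
    Xc = np.column_stack([dataset.column(c) for c in cont]).astype(float) if cont \
        else np.zeros((n, 0))
    if standardize and Xc.size:
        sd = Xc.std(axis=0)
        if np.any(sd == 0):
            bad = [c for c, s in zip(cont, sd) if s == 0]
            raise ValueError(f"constant continuous columns {bad}; drop them first")
        Xc = (Xc - Xc.mean(axis=0)) / sd
    levels = tuple(dataset.spec(d).n_levels for d in disc)
    ltot = int(sum(levels))
    codes = np.column_stack([dataset.column(d) for d in disc]).astype(int) if disc \
        else np.zeros((n, 0), dtype=int)
    D = np.zeros((n, ltot))
    off = 0
    for j, L in enumerate(levels):
        D[np.arange(n), off + codes[:, j]] = 1.0
        off += L
    return _MGMData(tuple(cont), tuple(disc), levels, Xc, D, codes)


def _check_shapes(params: MGMParameters, data: _MGMData) -> None:
    if params.cont_names != data.cont_names or params.disc_names != data.disc_names \
            or params.levels != data.levels:
        raise ValueError("parameter block structure does not match the dataset")


# ---------------------------------------------------------------------------
# objective and gradient
# ---------------------------------------------------------------------------

def _nll_parts(params: MGMParameters, data: _MGMData):
    n = data.n
    pc = len(data.cont_names)
    # continuous conditionals
    if pc:
        eta = params.alpha_c + data.Xc @ params.beta.T + data.D @ params.rho.T
        resid = eta - data.Xc
        cont_nll = 0.5 * float(np.sum(resid ** 2)) / n + 0.5 * LOG_2PI * pc
    else:
        resid = np.zeros((n, 0))
        cont_nll = 0.0
    # discrete conditionals
    disc_nll = 0.0
    S = None
    if data.levels:
        S = params.alpha_d + data.Xc @ params.rho + data.D @ params.phi
        for j in range(len(data.levels)):
            sl = params.cols(j)
            Sj = S[:, sl]
            lse = logsumexp(Sj, axis=1)
            truth = Sj[np.arange(n), data.codes[:, j]]
            disc_nll += float(np.sum(lse - truth)) / n
    return cont_nll + disc_nll, resid, S


def negative_pseudo_loglik(params: MGMParameters, dataset: MixedDataset | _MGMData) -> float:
    """Average negative log pseudo-likelihood (no penalty).

    Continuous columns are expected to be standardized by the caller (as
    :func:`fit_mgm` does internally); the value is a sum over node
    conditionals divided by the sample size.
    """
    data = dataset if isinstance(dataset, _MGMData) else prepare_mgm_data(dataset)
    _check_shapes(params, data)
    val, _, _ = _nll_parts(params, data)
    return val


def pseudo_loglik_gradient(
    params: MGMParameters, dataset: MixedDataset | _MGMData
) -> MGMParameters:
    """Exact analytic gradient of :func:`negative_pseudo_loglik`.

    Symmetric blocks (beta, phi) and the shared rho block accumulate the
    contributions of both node conditionals they appear in.
    """
    data = dataset if isinstance(dataset, _MGMData) else prepare_mgm_data(dataset)
    _check_shapes(params, data)
    n = data.n
    _, resid, S = _nll_parts(params, data)
    g = MGMParameters.zeros(data.cont_names, data.disc_names, data.levels)

    if len(data.cont_names):
        g.alpha_c = resid.sum(axis=0) / n
        G = resid.T @ data.Xc / n
        g.beta = G + G.T
        np.fill_diagonal(g.beta, 0.0)

    if data.levels:
        # softmax residuals P - onehot, scaled by 1/n
        U = np.zeros_like(data.D)
        for j in range(len(data.levels)):
            sl = params.cols(j)
            Sj = S[:, sl]
            Pj = np.exp(Sj - logsumexp(Sj, axis=1, keepdims=True))
            U[:, sl] = Pj
        U -= data.D
        U /= n
        g.alpha_d = U.sum(axis=0)
        if len(data.cont_names):
            g.rho = resid.T @ data.D / n + data.Xc.T @ U
        Gp = data.D.T @ U
        g.phi = Gp + Gp.T
        off = params.offsets
        for j in range(len(data.levels)):  # zero diagonal blocks
            sl = slice(off[j], off[j + 1])
            g.phi[sl, sl] = 0.0
    return g


def penalty_value(params: MGMParameters, lambdas: LambdaTriple) -> float:
    lcc, lcd, ldd = lambdas
    val = lcc * float(np.sum(np.abs(np.triu(params.beta, 1))))
    pd_ = len(params.levels)
    for s in range(len(params.cont_names)):
        for j in range(pd_):
            val += lcd * float(np.linalg.norm(params.rho_block(s, j)))
    for r in range(pd_):
        for j in range(r + 1, pd_):
            val += ldd * float(np.linalg.norm(params.phi_block(r, j)))
    return val


# ---------------------------------------------------------------------------
# proximal operator
# ---------------------------------------------------------------------------

def proximal_operator(
    params: MGMParameters, lambdas: LambdaTriple, step: float
) -> MGMParameters:
    """Blockwise group soft-thresholding; intercepts are unpenalized.

    beta entries are soft-thresholded at step*lambda_cc; each rho_sj vector
    is l2-shrunk at step*lambda_cd; each phi_rj block is Frobenius-shrunk at
    step*lambda_dd.  Blocks whose norm falls below the threshold become
    exactly zero, so the sparsity pattern of the solution is exact.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    lcc, lcd, ldd = LambdaTriple(*lambdas).validate()
    out = params.copy()
    t = step * lcc
    out.beta = np.sign(out.beta) * np.maximum(np.abs(out.beta) - t, 0.0)
    np.fill_diagonal(out.beta, 0.0)
    pd_ = len(params.levels)
    for s in range(len(params.cont_names)):
        for j in range(pd_):
            blk = out.rho[s, out.cols(j)]
            nrm = np.linalg.norm(blk)
            scale = max(1.0 - step * lcd / nrm, 0.0) if nrm > 0 else 0.0
            out.rho[s, out.cols(j)] = blk * scale
    for r in range(pd_):
        for j in range(r + 1, pd_):
            blk = out.phi[out.cols(r), out.cols(j)]
            nrm = np.linalg.norm(blk)
            scale = max(1.0 - step * ldd / nrm, 0.0) if nrm > 0 else 0.0
            blk = blk * scale
            out.phi[out.cols(r), out.cols(j)] = blk
            out.phi[out.cols(j), out.cols(r)] = blk.T
    return out


def _center_identifiable(params: MGMParameters) -> MGMParameters:
    """Project rho/phi blocks onto their identifiable (centered) form.

    Mean shifts are absorbed into the intercepts, leaving every node
    conditional unchanged; block norms can only decrease.
    """
    out = params.copy()
    pd_ = len(out.levels)
    for s in range(len(out.cont_names)):
        for j in range(pd_):
            blk = out.rho[s, out.cols(j)]
            m = blk.mean()
            if m != 0.0:
                out.rho[s, out.cols(j)] = blk - m
                out.alpha_c[s] += m
    for r in range(pd_):
        for j in range(r + 1, pd_):
            blk = out.phi[out.cols(r), out.cols(j)]
            rm = blk.mean(axis=1)
            cm = blk.mean(axis=0)
            g = blk.mean()
            if np.any(rm != 0) or np.any(cm != 0):
                blk = blk - rm[:, None] - cm[None, :] + g
                out.phi[out.cols(r), out.cols(j)] = blk
                out.phi[out.cols(j), out.cols(r)] = blk.T
                out.alpha_d[out.cols(j)] += cm
                out.alpha_d[out.cols(r)] += rm
    return out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class MGMFit:
    """Result of a proximal-gradient fit."""

    params: MGMParameters
    objective_trace: list[float]
    converged: bool
    iterations: int
    lambdas: LambdaTriple


def fit_mgm(
    dataset: MixedDataset,
    lambdas: Sequence[float] | LambdaTriple = (0.25, 0.25, 0.25),
    tol: float = 1e-5,
    max_iter: int = 1000,
    accelerate: bool = True,
    init: MGMParameters | None = None,
) -> MGMFit:
    """Fit the penalized pseudo-likelihood by (accelerated) proximal gradient.

    Continuous columns are standardized internally.  Backtracking line
    search halves the step until the quadratic majorization holds; with
    acceleration, a monotone restart falls back to a plain proximal step
    whenever the momentum step would increase the penalized objective, so
    ``objective_trace`` is non-increasing by construction.  Convergence is
    declared when the relative objective change drops below ``tol``.
    """
    lambdas = LambdaTriple(*lambdas).validate()
    data = prepare_mgm_data(dataset, standardize=True)
    if data.n < 2:
        raise ValueError("need n >= 2 samples")

    def smooth(p: MGMParameters) -> float:
        return negative_pseudo_loglik(p, data)

    def obj(p: MGMParameters) -> float:
        return smooth(p) + penalty_value(p, lambdas)

    x = init.copy() if init is not None else \
        MGMParameters.zeros(data.cont_names, data.disc_names, data.levels)
    y = x.copy()
    t_mom = 1.0
    step = 1.0
    fx = obj(x)
    trace = [fx]
    converged = False
    it = 0

    def prox_step(point: MGMParameters, step0: float) -> tuple[MGMParameters, float]:
        """One backtracked proximal step from `point`; returns (z, step)."""
        fy = smooth(point)
        gy = pseudo_loglik_gradient(point, data)
        s = step0
        for _ in range(60):
            cand = proximal_operator(_combine(point, gy, 1.0, -s), lambdas, s)
            cand = _center_identifiable(cand)
            diff = _sqdist(cand, point)
            lin = _inner(gy, _combine(cand, point, 1.0, -1.0))
            if smooth(cand) <= fy + lin + diff / (2.0 * s) + 1e-12:
                return cand, s
            s *= 0.5
        raise RuntimeError("line search failed to find a valid step")

    for it in range(1, max_iter + 1):
        if accelerate and not np.isfinite(smooth(y)):
            y = x.copy()  # momentum overshot into overflow: hard restart
            t_mom = 1.0
        z, step = prox_step(y if accelerate else x, min(step * 1.25, 1e4))
        fz = obj(z)
        if accelerate and (not np.isfinite(fz) or fz > fx + 1e-12):
            # monotone restart: plain proximal step from the best iterate
            z, step = prox_step(x, step)
            fz = obj(z)
            t_mom = 1.0
        if not np.isfinite(fz):
            raise FloatingPointError(f"non-finite objective at iteration {it}")
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom ** 2))
        y = _combine(z, _combine(z, x, 1.0, -1.0), 1.0, (t_mom - 1.0) / t_next) \
            if accelerate else z
        rel = abs(fx - fz) / max(1.0, abs(fx))
        x, fx, t_mom = z, fz, t_next
        trace.append(fx)
        if rel < tol:
            converged = True
            break

    return MGMFit(params=x, objective_trace=trace, converged=converged,
                  iterations=it, lambdas=lambdas)


def fit_mgm_path(
    dataset: MixedDataset,
    grid: Sequence[float],
    tol: float = 1e-5,
    max_iter: int = 1000,
) -> list[MGMFit]:
    """Fit the model along a penalty grid (same value for all three edge
    types), warm-starting each fit from the previous solution.

    Fits run from the sparsest (largest) penalty down; the returned list
    matches the order of ``grid``.
    """
    order = np.argsort(grid)[::-1]  # largest lambda first
    fits: list[MGMFit | None] = [None] * len(grid)
    init = None
    for k in order:
        lam = float(grid[k])
        fit = fit_mgm(dataset, lambdas=(lam, lam, lam), tol=tol,
                      max_iter=max_iter, init=init)
        init = fit.params
        fits[k] = fit
    return fits  # type: ignore[return-value]


def extract_graph(
    params: MGMParameters,
    eps: float = 1e-8,
    extra_nodes: Sequence[str] = (),
) -> EndpointGraph:
    """Undirected graph of the nonzero pairwise blocks.

    An edge s-t is present iff the corresponding block norm (|beta_st|,
    ||rho_sj||_2 or ||phi_rj||_F) exceeds ``eps``.  ``extra_nodes`` adds
    isolated nodes (e.g. constant columns excluded from the fit).
    """
    if eps < 0:
        raise ValueError("eps must be >= 0")
    g = EndpointGraph(list(params.cont_names) + list(params.disc_names) + list(extra_nodes))
    pc, pd_ = len(params.cont_names), len(params.levels)
    for s in range(pc):
        for t in range(s + 1, pc):
            if abs(params.beta[s, t]) > eps:
                g.add_edge(params.cont_names[s], params.cont_names[t])
        for j in range(pd_):
            if np.linalg.norm(params.rho_block(s, j)) > eps:
                g.add_edge(params.cont_names[s], params.disc_names[j])
    for r in range(pd_):
        for j in range(r + 1, pd_):
            if np.linalg.norm(params.phi_block(r, j)) > eps:
                g.add_edge(params.disc_names[r], params.disc_names[j])
    return g


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class MGM(BaseEstimator):
    """Sparse mixed graphical model estimator (scikit-learn style).

    Parameters
    ----------
    lambda_cc, lambda_cd, lambda_dd : float
        Sparsity penalties for continuous-continuous, continuous-discrete
        and discrete-discrete edges.  The default 0.25 is an arbitrary
        mid-grid value; stability-based selection (see
        :class:`causalmix.steps.StEPS`) is recommended.
    tol : float
        Relative objective-change convergence threshold.
    max_iter : int
        Proximal-gradient iteration cap.
    accelerate : bool
        FISTA momentum with monotone restart.
    nonparanormal : bool
        Apply the rank-based Gaussianization to continuous columns before
        fitting.
    eps : float
        Block-norm threshold for edge extraction.
    max_levels : int
        Integer-coded columns with at most this many distinct values are
        treated as categorical when coercing plain arrays/DataFrames.

    Attributes
    ----------
    params_ : MGMParameters
    graph_ : EndpointGraph
    objective_trace_ : list of float
    converged_ : bool
    n_iter_ : int
    dropped_ : list of str
        Constant columns excluded from the fit (isolated in ``graph_``).
    """

    def __init__(self, lambda_cc=0.25, lambda_cd=0.25, lambda_dd=0.25,
                 tol=1e-5, max_iter=1000, accelerate=True,
                 nonparanormal=False, eps=1e-8, max_levels=5):
        self.lambda_cc = lambda_cc
        self.lambda_cd = lambda_cd
        self.lambda_dd = lambda_dd
        self.tol = tol
        self.max_iter = max_iter
        self.accelerate = accelerate
        self.nonparanormal = nonparanormal
        self.eps = eps
        self.max_levels = max_levels

    def fit(self, X, y=None):
        from .dataset import nonparanormal_transform

        ds = as_mixed_dataset(X, max_levels=self.max_levels)
        dropped = ds.constant_columns()
        if dropped:
            warnings.warn(
                f"constant columns excluded from the model: {dropped}",
                UserWarning, stacklevel=2,
            )
            keep = [n for n in ds.names if n not in dropped]
            ds = ds.subset(keep)
        if self.nonparanormal:
            ds = nonparanormal_transform(ds)
        fit = fit_mgm(
            ds,
            lambdas=(self.lambda_cc, self.lambda_cd, self.lambda_dd),
            tol=self.tol, max_iter=self.max_iter, accelerate=self.accelerate,
        )
        self.params_ = fit.params
        self.objective_trace_ = fit.objective_trace
        self.converged_ = fit.converged
        self.n_iter_ = fit.iterations
        self.dropped_ = dropped
        self.graph_ = extract_graph(fit.params, eps=self.eps, extra_nodes=dropped)
        return self
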