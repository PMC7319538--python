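"""Regression-based conditional-independence tests for mixed data.

Testing X ⟂ Y | Z dispatches on variable types:

* at least one of X, Y continuous — the continuous one (the
  lexicographically later name when both are) becomes the response of an
  ordinary least-squares regression on [X, Z]; the test is the two-sided
  t-test on the coefficient of X, or the partial F-test of X's dummy-column
  group when X is categorical with more than two levels (identical to the
  squared t-test when the group has one column);
* both categorical — a likelihood-ratio test between multinomial logistic
  regressions of Y on [X, Z] and on [Z] alone, referred to a chi-square
  distribution with (L_Y − 1) · (X design columns) degrees of freedom.

Categorical predictors are dummy-encoded against their first level.
Collinear (aliased) columns are dropped with a warning; if every X column
is aliased the test returns p = 1.  When the residual degrees of freedom
are non-positive the pair is untestable: the result keeps the edge
(``independent=False``) and carries a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .dataset import MixedDataset

_GRAD_TOL = 1e-8
_RIDGE = 1e-8


@dataclass
class CITestResult:
    """Outcome of one conditional-independence test."""

    p_value: float
    statistic: float
    test_kind: str  # linear_t | linear_F | multinomial_lrt
    dof: int
    independent: bool
    warning: str | None = None


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _encode(dataset: MixedDataset, name: str) -> np.ndarray:
    """Columns contributed by one variable: the raw column for continuous,
    first-level-reference dummies for categorical."""
    spec = dataset.spec(name)
    col = dataset.column(name)
    if spec.is_continuous:
        return col.astype(float).reshape(-1, 1)
    codes = col.astype(int)
    out = np.zeros((len(codes), spec.n_levels - 1))
    for l in range(1, spec.n_levels):
        out[:, l - 1] = codes == l
    return out


def _greedy_independent(base: np.ndarray, cols: np.ndarray, tol: float = 1e-9):
    """Indices of ``cols`` columns that are linearly independent of ``base``
    and of each other (greedy, in column order)."""
    kept: list[int] = []
    work = base
    rank = np.linalg.matrix_rank(work) if work.size else 0
    for k in range(cols.shape[1]):
        cand = np.column_stack([work, cols[:, k]])
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            kept.append(k)
            work, rank = cand, r
    return kept, work


# ---------------------------------------------------------------------------
# linear test
# ---------------------------------------------------------------------------

def regression_test_linear(
    dataset: MixedDataset,
    response: str,
    x: str,
    Z: Sequence[str] = (),
    alpha: float = 0.05,
) -> CITestResult:
    """OLS of a continuous response on [X, Z]; t-test on X's coefficient or
    partial F-test on X's dummy-column group."""
    if not dataset.spec(response).is_continuous:
        raise ValueError("response must be continuous")
    y = dataset.column(response).astype(float)
    n = len(y)
    warn = None

    base_cols = [np.ones((n, 1))]
    for z in sorted(Z):
        base_cols.append(_encode(dataset, z))
    base_raw = np.column_stack(base_cols)
    kept_base, base = _greedy_independent(base_raw[:, :1], base_raw[:, 1:])
    # base always retains the intercept; aliased Z columns silently dropped

    xcols = _encode(dataset, x)
    kept_x, full = _greedy_independent(base, xcols)
    if len(kept_x) < xcols.shape[1]:
        warn = f"aliased design columns dropped for {x!r}"
        warnings.warn(warn, UserWarning, stacklevel=2)
    m = len(kept_x)
    if m == 0:
        return CITestResult(1.0, 0.0, "linear_t", 0, True, warn)

    dof = n - full.shape[1]
    if dof <= 0:
        w = "insufficient residual degrees of freedom; edge kept"
        warnings.warn(w, UserWarning, stacklevel=2)
        return CITestResult(0.0, np.inf, "linear_t", 0, False, w)

    coef, _, _, _ = np.linalg.lstsq(full, y, rcond=None)
    resid = y - full @ coef
    rss1 = float(resid @ resid)
    sigma2 = rss1 / dof

    if m == 1:
        xtx_inv = np.linalg.pinv(full.T @ full)
        j = full.shape[1] - 1  # x column is last
        se = np.sqrt(sigma2 * xtx_inv[j, j])
        if se == 0:
            return CITestResult(0.0, np.inf, "linear_t", dof, False, warn)
        t = float(coef[j] / se)
        p = float(2.0 * stats.t.sf(abs(t), dof))
        return CITestResult(p, t, "linear_t", dof, p > alpha, warn)

    coef0, _, _, _ = np.linalg.lstsq(base, y, rcond=None)
    resid0 = y - base @ coef0
    rss0 = float(resid0 @ resid0)
    f = ((rss0 - rss1) / m) / sigma2 if sigma2 > 0 else np.inf
    f = max(f, 0.0)
    p = float(stats.f.sf(f, m, dof))
    return CITestResult(p, f, "linear_F", dof, p > alpha, warn)


# ---------------------------------------------------------------------------
# multinomial logistic MLE (damped Newton, ridge-stabilized fallback)
# ---------------------------------------------------------------------------

def _mnl_nll_grad(W: np.ndarray, X: np.ndarray, onehot: np.ndarray, ridge: float):
    """Mean NLL, mean gradient, class probabilities (reference coding).

    W is (d, L-1); level 0 has score 0.  Everything is scaled by 1/n so
    tolerances are sample-size free.
    """
    n = X.shape[0]
    scores = np.column_stack([np.zeros(n), X @ W])
    zmax = scores.max(axis=1, keepdims=True)
    ez = np.exp(scores - zmax)
    denom = ez.sum(axis=1, keepdims=True)
    P = ez / denom
    ll = float(np.sum(scores[onehot.astype(bool)]) - np.sum(np.log(denom) + zmax))
    nll = -ll / n + 0.5 * ridge * float(np.sum(W * W))
    G = X.T @ (P[:, 1:] - onehot[:, 1:]) / n + ridge * W
    return nll, G, P


def _fit_multinomial(
    X: np.ndarray, codes: np.ndarray, L: int, ridge: float = 0.0,
    max_iter: int = 200,
) -> tuple[float, bool]:
    """Maximum-likelihood multinomial logistic fit.

    Returns (log-likelihood at the optimum, converged).  Damped Newton with
    a Fisher-information Hessian; convergence at gradient sup-norm 1e-8.
    """
    n, d = X.shape
    onehot = np.zeros((n, L))
    onehot[np.arange(n), codes] = 1.0
    W = np.zeros((d, L - 1))
    nll, G, P = _mnl_nll_grad(W, X, onehot, ridge)
    for _ in range(max_iter):
        if np.max(np.abs(G)) < _GRAD_TOL:
            break
        # mean Hessian: H[(a,k),(b,l)] = mean_i X_ia X_ib (P_ik d_kl - P_ik P_il)
        Pk = P[:, 1:]
        V = np.einsum("nk,kl->nkl", Pk, np.eye(L - 1)) - np.einsum(
            "nk,nl->nkl", Pk, Pk
        )
        H = np.einsum("ni,nj,nkl->ikjl", X, X, V).reshape(
            d * (L - 1), d * (L - 1)
        ) / n
        H += (ridge + 1e-12) * np.eye(d * (L - 1))
        try:
            step = np.linalg.solve(H, G.reshape(-1)).reshape(d, L - 1)
        except np.linalg.LinAlgError:
            return -np.inf, False
        t = 1.0
        for _ in range(40):
            W_new = W - t * step
            nll_new, G_new, P_new = _mnl_nll_grad(W_new, X, onehot, ridge)
            if nll_new <= nll + 1e-15:
                break
            t *= 0.5
        else:
            break
        if np.max(np.abs(W_new - W)) < 1e-12:
            W, nll, G, P = W_new, nll_new, G_new, P_new
            break
        W, nll, G, P = W_new, nll_new, G_new, P_new
    converged = bool(np.max(np.abs(G)) < max(_GRAD_TOL, 1e3 * ridge))
    ll = -n * (nll - 0.5 * ridge * float(np.sum(W * W)))
    return ll, converged


def _fit_multinomial_stable(X, codes, L) -> tuple[float, str | None]:
    ll, ok = _fit_multinomial(X, codes, L, ridge=0.0)
    if ok and np.isfinite(ll):
        return ll, None
    w = "multinomial fit did not converge; ridge-stabilized refit"
    warnings.warn(w, UserWarning, stacklevel=2)
    ll, _ = _fit_multinomial(X, codes, L, ridge=_RIDGE, max_iter=500)
    return ll, w


def multinomial_lrt(
    dataset: MixedDataset,
    y: str,
    x: str,
    Z: Sequence[str] = (),
    alpha: float = 0.05,
) -> CITestResult:
    """Likelihood-ratio test of X in the multinomial logistic regression of
    a categorical Y on [X, Z] against the [Z]-only model."""
    spec_y = dataset.spec(y)
    if not spec_y.is_categorical:
        raise ValueError("response must be categorical")
    codes = dataset.column(y).astype(int)
    L = spec_y.n_levels
    n = len(codes)

    base_cols = [np.ones((n, 1))]
    for z in sorted(Z):
        base_cols.append(_encode(dataset, z))
    base_raw = np.column_stack(base_cols)
    _, base = _greedy_independent(base_raw[:, :1], base_raw[:, 1:])
    xcols = _encode(dataset, x)
    kept_x, full = _greedy_independent(base, xcols)

    warn = None
    if len(kept_x) < xcols.shape[1]:
        warn = f"aliased design columns dropped for {x!r}"
        warnings.warn(warn, UserWarning, stacklevel=2)
    m = len(kept_x)
    if m == 0:
        return CITestResult(1.0, 0.0, "multinomial_lrt", 0, True, warn)
    dof = (L - 1) * m
    if n - full.shape[1] * (L - 1) <= 0:
        w = "insufficient degrees of freedom; edge kept"
        warnings.warn(w, UserWarning, stacklevel=2)
        return CITestResult(0.0, np.inf, "multinomial_lrt", dof, False, w)

    ll_null, w0 = _fit_multinomial_stable(base, codes, L)
    ll_full, w1 = _fit_multinomial_stable(full, codes, L)
    warn = warn or w0 or w1
    stat = max(2.0 * (ll_full - ll_null), 0.0)
    p = float(stats.chi2.sf(stat, dof))
    return CITestResult(p, stat, "multinomial_lrt", dof, p > alpha, warn)


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------

def ci_test(
    dataset: MixedDataset,
    x: str,
    y: str,
    Z: Sequence[str] = (),
    alpha: float = 0.05,
) -> CITestResult:
    """Test X ⟂ Y | Z, dispatching on the types of X and Y.

    When both are continuous the lexicographically later name is the
    regression response (the t-test on either regression tests the same
    partial correlation, so the choice only fixes floating-point
    determinism).  When exactly one is continuous it is the response.  When
    both are categorical the test is the multinomial LRT.
    """
    if x == y:
        raise ValueError("x and y must differ")
    if x in Z or y in Z:
        raise ValueError("Z must exclude x and y")
    cx = dataset.spec(x).is_continuous
    cy = dataset.spec(y).is_continuous
    if cx and cy:
        resp, pred = (x, y) if x > y else (y, x)
        return regression_test_linear(dataset, resp, pred, Z, alpha)
    if cy and not cx:
        return regression_test_linear(dataset, y, x, Z, alpha)
    if cx and not cy:
        return regression_test_linear(dataset, x, y, Z, alpha)
    resp, pred = (x, y) if x > y else (y, x)
    return multinomial_lrt(dataset, resp, pred, Z, alpha)
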