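"""Stable edge-specific penalty selection (StEPS).

The three MGM penalties (lambda_cc, lambda_cd, lambda_dd) are chosen from
the stability of their edge types across subsample fits.  For a candidate
penalty triple, the model is fitted on N subsamples (drawn without
replacement, size min(10*sqrt(n), 0.75*n) by default) and each edge type's
instability is the average over its possible variable pairs of
2*theta*(1-theta), where theta is the fraction of subsample graphs
containing the pair.  Starting from the smallest grid value applied to all
three types, any type whose instability exceeds the bound gamma has its
lambda advanced to the next grid value; a type at or below gamma is frozen
at its current lambda.  The loop repeats — refitting all subsamples at the
current mixed triple — until every type is frozen or the grid is
exhausted (then the largest grid value is used, with a warning).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .dataset import MixedDataset, as_mixed_dataset
from .graph import EndpointGraph
from .mgm import LambdaTriple, MGM, MGMParameters, extract_graph, fit_mgm

EDGE_TYPES = ("CC", "CD", "DD")


def default_lambda_grid(lo: float = 0.05, hi: float = 0.9, size: int = 30) -> np.ndarray:
    """Log-spaced penalty grid, ascending (densest model first)."""
    return np.geomspace(lo, hi, size)


def subsample_indices(
    n: int, b: int | None = None, N: int = 20, seed: int = 0
) -> list[np.ndarray]:
    """N seeded subsamples of size b drawn without replacement.

    Default b = min(floor(10*sqrt(n)), floor(0.75*n)).
    """
    if b is None:
        b = min(int(10 * np.sqrt(n)), int(0.75 * n))
        b = max(b, 1)
    if not (1 <= b <= n):
        raise ValueError(f"subsample size {b} not in [1, {n}]")
    rng = np.random.default_rng(seed)
    return [np.sort(rng.choice(n, size=b, replace=False)) for _ in range(N)]


def _pairs_of_type(edge_type: str, continuous: Sequence[str], discrete: Sequence[str]):
    cont, disc = sorted(continuous), sorted(discrete)
    if edge_type == "CC":
        return [(cont[i], cont[j]) for i in range(len(cont)) for j in range(i + 1, len(cont))]
    if edge_type == "CD":
        return [(c, d) for c in cont for d in disc]
    if edge_type == "DD":
        return [(disc[i], disc[j]) for i in range(len(disc)) for j in range(i + 1, len(disc))]
    raise ValueError(f"unknown edge type {edge_type!r}")


def edge_instability(
    graphs: Sequence[EndpointGraph],
    edge_type: str,
    continuous: Sequence[str],
    discrete: Sequence[str],
) -> float | None:
    """Average 2*theta*(1-theta) over the possible pairs of one edge type;
    None when the type has no possible pairs."""
    pairs = _pairs_of_type(edge_type, continuous, discrete)
    if not pairs:
        return None
    N = len(graphs)
    vals = []
    for u, v in pairs:
        theta = sum(g.has_edge(u, v) for g in graphs) / N
        vals.append(2.0 * theta * (1.0 - theta))
    return float(np.mean(vals))


@dataclass
class StabilityProfile:
    """Full record of a StEPS run."""

    lambda_grid: list[float]
    instability: dict[str, dict[float, float]]
    monotonized: dict[str, dict[float, float]]
    chosen: LambdaTriple
    flags: list[str] = field(default_factory=list)


def steps_select(
    dataset: MixedDataset,
    lambda_grid: Sequence[float] | None = None,
    gamma: float = 0.05,
    N: int = 20,
    seed: int = 0,
    b: int | None = None,
    tol: float = 1e-4,
    max_iter: int = 500,
    index_sets: Sequence[np.ndarray] | None = None,
) -> StabilityProfile:
    """Select the penalty triple by per-edge-type subsample stability.

    ``index_sets`` overrides the internal subsampling (used for testing);
    subsample fits are warm-started across grid steps.
    """
    if not (0.0 < gamma < 0.5):
        raise ValueError("gamma must be in (0, 0.5)")
    grid = np.asarray(
        default_lambda_grid() if lambda_grid is None else lambda_grid, dtype=float
    )
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("lambda grid must be strictly ascending")

    cont = dataset.continuous_names
    disc = dataset.categorical_names
    if index_sets is None:
        index_sets = subsample_indices(dataset.n, b=b, N=N, seed=seed)
    subsets = [dataset.frame.iloc[idx].reset_index(drop=True) for idx in index_sets]
    subdata = [MixedDataset(specs=list(dataset.specs), frame=f) for f in subsets]

    idx = {t: 0 for t in EDGE_TYPES}
    inst_hist: dict[str, dict[float, float]] = {t: {} for t in EDGE_TYPES}
    flags: list[str] = []
    warm: dict[int, MGMParameters] = {}

    # types with no possible pairs cannot be measured: their lambda stays
    # at the smallest grid value
    measurable = []
    capped: set[str] = set()
    for t in EDGE_TYPES:
        if _pairs_of_type(t, cont, disc):
            measurable.append(t)
        else:
            flags.append(f"{t}: no possible pairs; lambda fixed at grid minimum")

    # advance each type until its instability meets gamma *at the current
    # triple*; because the types are coupled through the joint fit, a type
    # that met the bound earlier is re-certified whenever another type
    # moves, and advances again if the bound no longer holds
    while True:
        lam = LambdaTriple(*(float(grid[idx[t]]) for t in EDGE_TYPES))
        graphs = []
        for i, sub in enumerate(subdata):
            fit = fit_mgm(sub, lambdas=lam, tol=tol, max_iter=max_iter,
                          init=warm.get(i))
            warm[i] = fit.params
            graphs.append(extract_graph(fit.params))
        unstable = []
        for t in measurable:
            cur = float(grid[idx[t]])
            inst = edge_instability(graphs, t, cont, disc)
            inst_hist[t][cur] = inst
            if inst > gamma and t not in capped:
                unstable.append(t)
        if not unstable:
            break
        progressed = False
        for t in unstable:
            if idx[t] + 1 < len(grid):
                idx[t] += 1
                progressed = True
            else:
                capped.add(t)
                msg = (f"{t}: no grid lambda met the stability bound; "
                       f"using the largest grid value")
                flags.append(msg)
                warnings.warn(msg, UserWarning, stacklevel=2)
        if not progressed:
            break
    frozen = {t: float(grid[idx[t]]) for t in EDGE_TYPES}

    # reverse running max over the visited lambdas (sparse end downward)
    mono: dict[str, dict[float, float]] = {}
    for t in EDGE_TYPES:
        lams = sorted(inst_hist[t])
        running = {}
        cur = -np.inf
        for lam_v in reversed(lams):
            cur = max(cur, inst_hist[t][lam_v])
            running[lam_v] = cur
        mono[t] = {lam_v: running[lam_v] for lam_v in lams}

    chosen = LambdaTriple(frozen["CC"], frozen["CD"], frozen["DD"])
    return StabilityProfile(
        lambda_grid=[float(v) for v in grid],
        instability=inst_hist,
        monotonized=mono,
        chosen=chosen,
        flags=flags,
    )


class StEPS(BaseEstimator):
    """Stability-based penalty selection estimator.

    ``fit`` runs the subsampling selection and, by default, refits the
    mixed graphical model on the full data at the chosen triple.

    Attributes
    ----------
    lambdas_ : LambdaTriple
    profile_ : StabilityProfile
    mgm_ : MGM (when ``refit``)
    graph_ : EndpointGraph (when ``refit``)
    """

    def __init__(self, grid_min=0.05, grid_max=0.9, grid_size=30, gamma=0.05,
                 n_subsamples=20, subsample_size=None, tol=1e-4,
                 max_iter=500, refit=True, random_state=0, max_levels=5):
        self.grid_min = grid_min
        self.grid_max = grid_max
        self.grid_size = grid_size
        self.gamma = gamma
        self.n_subsamples = n_subsamples
        self.subsample_size = subsample_size
        self.tol = tol
        self.max_iter = max_iter
        self.refit = refit
        self.random_state = random_state
        self.max_levels = max_levels

    def fit(self, X, y=None):
        ds = as_mixed_dataset(X, max_levels=self.max_levels)
        profile = steps_select(
            ds,
            lambda_grid=default_lambda_grid(self.grid_min, self.grid_max, self.grid_size),
            gamma=self.gamma, N=self.n_subsamples, seed=self.random_state,
            b=self.subsample_size, tol=self.tol, max_iter=self.max_iter,
        )
        self.profile_ = profile
        self.lambdas_ = profile.chosen
        if self.refit:
            lcc, lcd, ldd = profile.chosen
            self.mgm_ = MGM(lambda_cc=lcc, lambda_cd=lcd, lambda_dd=ldd,
                            max_levels=self.max_levels).fit(ds)
            self.graph_ = self.mgm_.graph_
        return self
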