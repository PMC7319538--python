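"""Preferential-diversity feature pre-selection.

Given a target variable, rank continuous candidates by association with the
target (|Pearson r| for a continuous target; 1 − p from a logistic /
multinomial LRT for a categorical target), then sweep them best-first,
"marking" any candidate whose |Pearson r| with an already-selected variable
reaches the redundancy threshold tau.  Marked variables are either dropped
or attached to the cluster of the earliest-selected variable they are
redundant with; unmarked variables are selected.  The working list is
refilled with the next-best unused candidates until the requested number of
representatives is selected or candidates run out.  Categorical candidates
and user-kept variables bypass scoring and are always part of the result.

The threshold tau can be chosen by subsampling stability: over half-sample
subsamples, a pair is "similar" at tau when |r| >= tau; the instability of
a threshold is the average over pairs of 2·theta·(1−theta), theta being the
fraction of subsamples declaring the pair similar, and the chosen tau is
the smallest grid value whose sparse-end-monotonized instability stays
within the bound gamma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .citests import multinomial_lrt
from .dataset import MixedDataset, as_mixed_dataset

_TAU_GRID = np.round(np.arange(0.10, 0.9001, 0.05), 10)


@dataclass
class PrefDivConfig:
    """Settings for :func:`prefdiv_select`."""

    target: str
    num_select: int
    cluster: bool = False
    tau: float | str = "auto"
    keep: tuple[str, ...] = ()
    # stability-threshold settings (used when tau == "auto")
    n_subsamples: int = 20
    gamma: float = 0.05
    seed: int = 0

    def validate(self, dataset: MixedDataset) -> "PrefDivConfig":
        if self.target not in dataset.names:
            raise KeyError(f"target {self.target!r} not in dataset")
        if not (1 <= self.num_select <= dataset.p - 1):
            raise ValueError("num_select must be in [1, p-1]")
        if isinstance(self.tau, str):
            if self.tau != "auto":
                raise ValueError("tau must be a number or 'auto'")
        elif not (0.0 <= float(self.tau) <= 1.0):
            raise ValueError("numeric tau must be in [0, 1]")
        for k in self.keep:
            if k not in dataset.names:
                raise KeyError(f"kept variable {k!r} not in dataset")
        return self


@dataclass
class PrefDivResult:
    """Selected representatives, their clusters, and association scores."""

    selected: list[str]
    clusters: dict[str, list[str]]
    scores: dict[str, float]
    tau: float


# ---------------------------------------------------------------------------
# association and similarity
# ---------------------------------------------------------------------------

def _abs_pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    r = float(np.corrcoef(a, b)[0, 1])
    return min(abs(r), 1.0)


def target_association(dataset: MixedDataset, var: str, target: str) -> float:
    """Association score in [0, 1] between a continuous candidate and the
    target: |Pearson r| (continuous target) or 1 − p from the LRT of a
    logistic/multinomial regression of the target on the candidate."""
    if var == target:
        raise ValueError("var must differ from target")
    if not dataset.spec(var).is_continuous:
        raise ValueError("only continuous candidates are scored")
    v = dataset.column(var).astype(float)
    if v.std() == 0:
        warnings.warn(f"constant candidate {var!r}; score 0", UserWarning, stacklevel=2)
        return 0.0
    if dataset.spec(target).is_continuous:
        return _abs_pearson(v, dataset.column(target).astype(float))
    res = multinomial_lrt(dataset, y=target, x=var, Z=())
    return float(np.clip(1.0 - res.p_value, 0.0, 1.0))


def pairwise_similarity(dataset: MixedDataset, var_i: str, var_j: str) -> float:
    """|Pearson r| between two continuous variables (0 for constants)."""
    si, sj = dataset.spec(var_i), dataset.spec(var_j)
    if not (si.is_continuous and sj.is_continuous):
        raise ValueError("similarity is defined for continuous pairs only")
    a = dataset.column(var_i).astype(float)
    b = dataset.column(var_j).astype(float)
    if a.std() == 0 or b.std() == 0:
        warnings.warn("constant column in similarity; score 0", UserWarning, stacklevel=2)
        return 0.0
    return _abs_pearson(a, b)


# ---------------------------------------------------------------------------
# stability-based threshold
# ---------------------------------------------------------------------------

def pair_instability(theta: np.ndarray) -> float:
    """Mean over pairs of 2·theta·(1−theta) — 0 for always/never similar
    pairs, maximal (0.5) at theta = 1/2."""
    return float(np.mean(2.0 * theta * (1.0 - theta)))


def stability_threshold(
    dataset: MixedDataset,
    candidates: Sequence[str],
    B: int = 20,
    gamma: float = 0.05,
    seed: int = 0,
    grid: Sequence[float] | None = None,
) -> float:
    """Choose the redundancy threshold tau by half-sample stability.

    Returns the smallest grid tau whose monotonized instability (running
    max from the sparse, large-tau end) is at most gamma; 0.9 with a
    warning when no threshold qualifies.
    """
    cands = [c for c in candidates if dataset.spec(c).is_continuous]
    if len(cands) < 2:
        raise ValueError("need >= 2 continuous candidates")
    if B < 10:
        raise ValueError("need B >= 10 subsamples")
    grid = np.asarray(_TAU_GRID if grid is None else grid, dtype=float)
    rng = np.random.default_rng(seed)
    n = dataset.n
    half = max(2, n // 2)
    X = np.column_stack([dataset.column(c).astype(float) for c in cands])
    iu = np.triu_indices(len(cands), 1)

    absr = np.empty((B, len(iu[0])))
    for b in range(B):
        idx = rng.choice(n, size=half, replace=False)
        sub = X[idx]
        sd = sub.std(axis=0)
        sd[sd == 0] = 1.0
        c = np.corrcoef(sub, rowvar=False)
        c = np.nan_to_num(c, nan=0.0)
        absr[b] = np.abs(c[iu])

    inst = np.array([
        pair_instability((absr >= tau).mean(axis=0)) for tau in grid
    ])
    mono = np.maximum.accumulate(inst[::-1])[::-1]  # running max from large tau
    ok = np.nonzero(mono <= gamma)[0]
    if len(ok) == 0:
        warnings.warn(
            "no threshold met the instability bound; using tau=0.9",
            UserWarning, stacklevel=2,
        )
        return float(grid[-1])
    return float(grid[ok[0]])


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def prefdiv_select(dataset: MixedDataset, config: PrefDivConfig) -> PrefDivResult:
    """Run the select/mark/cluster sweep and return the reduced variable set."""
    config.validate(dataset)
    target = config.target
    if len(np.unique(dataset.column(target))) <= 1:
        raise ValueError(f"target {target!r} is constant")

    keep = [k for k in config.keep if k != target]
    categorical_auto = [
        c for c in dataset.categorical_names if c != target and c not in keep
    ]
    cont_candidates = [
        c for c in dataset.continuous_names if c != target and c not in keep
    ]

    scores = {c: target_association(dataset, c, target) for c in cont_candidates}
    ranked = sorted(cont_candidates, key=lambda c: (-scores[c], c))

    if config.tau == "auto":
        tau = stability_threshold(
            dataset, cont_candidates, B=config.n_subsamples,
            gamma=config.gamma, seed=config.seed,
        ) if len(cont_candidates) >= 2 else 1.0
    else:
        tau = float(config.tau)

    # representatives available for similarity comparison: user-kept
    # continuous variables count as already selected but not toward quota
    reps: list[str] = [k for k in keep if dataset.spec(k).is_continuous]
    selected_cont: list[str] = []
    clusters: dict[str, list[str]] = {}
    unused = list(ranked)

    while len(selected_cont) < config.num_select and unused:
        batch, unused = unused[:config.num_select], unused[config.num_select:]
        for pos, var in enumerate(batch):
            if len(selected_cont) >= config.num_select:
                unused = batch[pos:] + unused  # quota reached mid-batch
                break
            hit = None
            for rep in reps:  # earliest-selected representative wins
                if pairwise_similarity(dataset, var, rep) >= tau:
                    hit = rep
                    break
            if hit is None:
                reps.append(var)
                selected_cont.append(var)
            elif config.cluster:
                clusters.setdefault(hit, []).append(var)

    if len(selected_cont) < config.num_select:
        warnings.warn(
            f"candidates exhausted: selected {len(selected_cont)} of "
            f"{config.num_select} requested",
            UserWarning, stacklevel=2,
        )

    selected = sorted(categorical_auto) + list(keep) + selected_cont
    if config.cluster:
        for rep in selected_cont:
            clusters.setdefault(rep, [])
    return PrefDivResult(selected=selected, clusters=clusters, scores=scores, tau=tau)


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class PrefDiv(BaseEstimator):
    """Feature pre-selection estimator (scikit-learn style).

    Parameters mirror :class:`PrefDivConfig`; ``fit`` computes the
    selection on a mixed table that contains the target column and
    ``transform`` returns the reduced table (selected variables plus the
    target).

    Attributes
    ----------
    selected_ : list of str
    clusters_ : dict mapping representative -> clustered members
    scores_ : dict mapping continuous candidate -> association score
    tau_ : float
        The redundancy threshold actually used.
    """

    def __init__(self, target, n_select=10, cluster=False, tau="auto",
                 keep=(), n_subsamples=20, gamma=0.05, random_state=0,
                 max_levels=5):
        self.target = target
        self.n_select = n_select
        self.cluster = cluster
        self.tau = tau
        self.keep = keep
        self.n_subsamples = n_subsamples
        self.gamma = gamma
        self.random_state = random_state
        self.max_levels = max_levels

    def _config(self) -> PrefDivConfig:
        return PrefDivConfig(
            target=self.target, num_select=self.n_select, cluster=self.cluster,
            tau=self.tau, keep=tuple(self.keep),
            n_subsamples=self.n_subsamples, gamma=self.gamma,
            seed=self.random_state,
        )

    def fit(self, X, y=None):
        ds = as_mixed_dataset(X, max_levels=self.max_levels)
        res = prefdiv_select(ds, self._config())
        self.result_ = res
        self.selected_ = res.selected
        self.clusters_ = res.clusters
        self.scores_ = res.scores
        self.tau_ = res.tau
        return self

    def transform(self, X):
        if not hasattr(self, "selected_"):
            raise RuntimeError("PrefDiv is not fitted")
        ds = as_mixed_dataset(X, max_levels=self.max_levels)
        cols = [n for n in ds.names if n in set(self.selected_) or n == self.target]
        return ds.subset(cols)

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)
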