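"""Synthetic mixed graphical models and data sampled from them.

Two kinds of ground truth are generated:

* :func:`random_mixed_graph` — an Erdős–Rényi *undirected* pairwise mixed
  graphical model in the Lee–Hastie parameterization (the benchmark model
  for undirected structure recovery).  Data are drawn by Gibbs sampling
  from the node conditionals.
* :func:`dag_model_for_pc` — a random *DAG* with linear-Gaussian structural
  equations for continuous nodes and multinomial-logistic equations for
  categorical nodes, sampled ancestrally.  Used to score orientations.

Edge effect magnitudes are drawn uniformly from ±[0.5, 1.0]·effect_scale.
Continuous-discrete vectors are mean-centered and discrete-discrete blocks
doubly centered (the identifiable form), with the drawn magnitude placed
on the centered component (RMS entry in [0.5, 1]·effect_scale) so every
graph edge carries a recoverable effect.  Continuous conditional variances
are fixed at 1.  Because independent ±[0.5, 1] draws do not guarantee a
positive-definite joint precision over the continuous block, the
continuous-continuous couplings are rescaled (once, at model construction)
whenever the minimum eigenvalue of I − B falls below 0.4 — equivalently,
no continuous variable's conditional-variance inflation exceeds 2.5×, so
relations are strong but never near-deterministic and skeletons remain
statistically recoverable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd

from .dataset import CATEGORICAL, CONTINUOUS, MixedDataset, VariableSpec
from .graph import EndpointGraph
from .mgm import MGMParameters


@dataclass
class SimulationConfig:
    """Settings for :func:`random_mixed_graph` + :func:`sample_mixed_data`."""

    p_continuous: int = 10
    p_discrete: int = 10
    levels: int = 3
    expected_degree: float = 2.0
    n: int = 500
    effect_scale: float = 1.0
    burn_in: int = 200
    thin: int = 10
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.p_continuous < 0 or self.p_discrete < 0:
            raise ValueError("variable counts must be >= 0")
        if self.p_continuous + self.p_discrete < 1:
            raise ValueError("need at least one variable")
        if self.levels < 2 and self.p_discrete > 0:
            raise ValueError("discrete variables need >= 2 levels")
        if self.expected_degree < 0:
            raise ValueError("expected_degree must be >= 0")
        p = self.p_continuous + self.p_discrete
        if p > 1 and self.expected_degree >= p:
            raise ValueError("expected_degree must be < p")
        if self.effect_scale <= 0:
            raise ValueError("effect_scale must be > 0")
        return self


@dataclass
class SEMParameters:
    """Structural-equation weights of a DAG model.

    ``weights`` maps (parent, child) name pairs to a scalar (cont→cont), a
    centered vector (cat→cont over parent levels, or cont→cat over child
    levels) or a doubly centered matrix (cat→cat, parent levels × child
    levels).  ``order`` is a topological order of the node names.
    """

    weights: dict[tuple[str, str], np.ndarray]
    order: list[str]


@dataclass
class GroundTruthModel:
    """Simulator output: the true graph plus its generating parameters."""

    graph: EndpointGraph
    params: Union[MGMParameters, SEMParameters]
    specs: list[VariableSpec]
    seed: int

    @property
    def is_dag(self) -> bool:
        return isinstance(self.params, SEMParameters)


def _names(p_continuous: int, p_discrete: int) -> tuple[list[str], list[str]]:
    wc = max(2, len(str(max(p_continuous, 1))))
    wd = max(2, len(str(max(p_discrete, 1))))
    cont = [f"C{i + 1:0{wc}d}" for i in range(p_continuous)]
    disc = [f"D{i + 1:0{wd}d}" for i in range(p_discrete)]
    return cont, disc


def _draw_magnitudes(rng: np.random.Generator, shape, scale: float) -> np.ndarray:
    mag = rng.uniform(0.5, 1.0, size=shape) * scale
    sign = rng.choice([-1.0, 1.0], size=shape)
    return mag * sign


def _center_vector(rng: np.random.Generator, L: int, scale: float) -> np.ndarray:
    """Zero-sum level-effect vector with RMS entry in [0.5, 1]*scale.

    The effect magnitude is placed on the centered (identifiable)
    component: centering a raw +-[0.5, 1] draw can cancel it almost
    entirely when the entries share a sign, which would create graph edges
    with no recoverable effect.
    """
    v = _draw_magnitudes(rng, L, scale)
    v = v - v.mean()
    target = float(rng.uniform(0.5, 1.0)) * scale * np.sqrt(L)
    nrm = np.linalg.norm(v)
    if nrm < 1e-12:
        v = np.zeros(L)
        v[0], v[1] = 1.0, -1.0
        nrm = np.linalg.norm(v)
    return v / nrm * target


def _center_matrix(rng: np.random.Generator, Lr: int, Lj: int, scale: float) -> np.ndarray:
    """Doubly centered interaction matrix with RMS entry in [0.5, 1]*scale."""
    m = _draw_magnitudes(rng, (Lr, Lj), scale)
    m = m - m.mean(axis=1, keepdims=True) - m.mean(axis=0) + m.mean()
    target = float(rng.uniform(0.5, 1.0)) * scale * np.sqrt(Lr * Lj)
    nrm = np.linalg.norm(m)
    if nrm < 1e-12:
        m = np.zeros((Lr, Lj))
        m[0, 0] = m[1, 1] = 1.0
        m[0, 1] = m[1, 0] = -1.0
        nrm = np.linalg.norm(m)
    return m / nrm * target


def random_mixed_graph(config: SimulationConfig) -> GroundTruthModel:
    """Erdős–Rényi undirected mixed model with edge probability
    expected_degree/(p−1) and Lee–Hastie-style pairwise potentials."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    cont, disc = _names(config.p_continuous, config.p_discrete)
    levels = [config.levels] * config.p_discrete
    params = MGMParameters.zeros(cont, disc, levels)
    p = config.p_continuous + config.p_discrete
    prob = 0.0 if p <= 1 else config.expected_degree / (p - 1)

    graph = EndpointGraph(cont + disc)
    all_nodes = cont + disc
    # iterate pairs in a fixed order so the draw sequence is reproducible
    for i in range(p):
        for j in range(i + 1, p):
            if rng.random() >= prob:
                continue
            u, v = all_nodes[i], all_nodes[j]
            graph.add_edge(u, v)
            iu, iv = i < config.p_continuous, j < config.p_continuous
            if iu and iv:
                w = float(_draw_magnitudes(rng, (), config.effect_scale))
                params.beta[i, j] = params.beta[j, i] = w
            elif iu and not iv:
                jd = j - config.p_continuous
                params.rho[i, params.cols(jd)] = _center_vector(
                    rng, config.levels, config.effect_scale
                )
            else:
                rd, jd = i - config.p_continuous, j - config.p_continuous
                m = _center_matrix(
                    rng, config.levels, config.levels, config.effect_scale
                )
                params.phi[params.cols(rd), params.cols(jd)] = m
                params.phi[params.cols(jd), params.cols(rd)] = m.T

    # keep the continuous block jointly Gaussian and well-conditioned:
    # min eig of I - B >= 0.4 (variance inflation at most 2.5x)
    if config.p_continuous > 1 and np.any(params.beta):
        eigs = np.linalg.eigvalsh(params.beta)
        if 1.0 - eigs[-1] < 0.4:
            params.beta *= 0.6 / eigs[-1]

    specs = [VariableSpec(c, CONTINUOUS) for c in cont] + [
        VariableSpec(d, CATEGORICAL, tuple(str(l) for l in range(config.levels)))
        for d in disc
    ]
    return GroundTruthModel(graph=graph, params=params, specs=specs, seed=config.seed)


def continuous_precision(model: GroundTruthModel) -> np.ndarray:
    """Joint precision matrix of the continuous block (given the discrete
    variables), I − B, under unit conditional variances."""
    beta = model.params.beta
    return np.eye(beta.shape[0]) - beta


# ---------------------------------------------------------------------------
# Gibbs sampling from an undirected model
# ---------------------------------------------------------------------------

def _softmax_sample(rng: np.random.Generator, scores: np.ndarray) -> np.ndarray:
    if not np.all(np.isfinite(scores)):
        raise FloatingPointError(
            "non-finite linear predictor during sampling (parameter scale too large)"
        )
    z = scores - scores.max(axis=1, keepdims=True)
    probs = np.exp(z)
    probs /= probs.sum(axis=1, keepdims=True)
    u = rng.random(scores.shape[0])
    return (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)


def _gibbs_sample(
    model: GroundTruthModel, n: int, burn_in: int, thin: int,
    seed: int, n_chains: int | None,
) -> pd.DataFrame:
    params: MGMParameters = model.params
    rng = np.random.default_rng(seed)
    pc = len(params.cont_names)
    pd_ = len(params.disc_names)
    levels = params.levels
    off = params.offsets
    ltot = int(off[-1])

    if n_chains is None:
        n_chains = min(n, 1024)
    n_chains = max(1, min(n_chains, n))
    per_chain = math.ceil(n / n_chains)

    Xc = np.zeros((n_chains, pc))
    codes = np.column_stack(
        [rng.integers(0, levels[j], size=n_chains) for j in range(pd_)]
    ) if pd_ else np.zeros((n_chains, 0), dtype=int)

    # running sums kept up to date incrementally:
    #   R[c, s]   = sum_j rho[s, off_j + code_j]   (discrete -> continuous)
    #   M[c, :]   = Xc @ rho                       (continuous -> discrete)
    #   A[c, :]   = sum_r phi[off_r + code_r, :]   (discrete -> discrete)
    R = np.zeros((n_chains, pc))
    for j in range(pd_):
        R += params.rho[:, off[j] + codes[:, j]].T
    M = Xc @ params.rho
    A = np.zeros((n_chains, ltot))
    for j in range(pd_):
        A += params.phi[off[j] + codes[:, j], :]

    def sweep() -> None:
        nonlocal Xc, codes, R, M, A
        for s in range(pc):
            mean = params.alpha_c[s] + Xc @ params.beta[s] + R[:, s]
            if not np.all(np.isfinite(mean)):
                raise FloatingPointError(
                    "non-finite linear predictor (parameter scale too large)"
                )
            new = mean + rng.standard_normal(n_chains)
            M += np.outer(new - Xc[:, s], params.rho[s])
            Xc[:, s] = new
        for j in range(pd_):
            sl = slice(off[j], off[j + 1])
            scores = params.alpha_d[sl] + M[:, sl] + A[:, sl]
            # phi's diagonal blocks are zero, so A needs no self-exclusion
            new = _softmax_sample(rng, scores)
            old_rows = off[j] + codes[:, j]
            new_rows = off[j] + new
            A += params.phi[new_rows, :] - params.phi[old_rows, :]
            R += (params.rho[:, new_rows] - params.rho[:, old_rows]).T
            codes[:, j] = new

    for _ in range(burn_in):
        sweep()
    draws_x, draws_c = [], []
    for k in range(per_chain):
        if k > 0:
            for _ in range(thin):
                sweep()
        draws_x.append(Xc.copy())
        draws_c.append(codes.copy())

    X = np.concatenate(draws_x, axis=0)[:n]
    C = np.concatenate(draws_c, axis=0)[:n]
    data = {name: X[:, s] for s, name in enumerate(params.cont_names)}
    data.update({name: C[:, j] for j, name in enumerate(params.disc_names)})
    cols = [s.name for s in model.specs]
    return pd.DataFrame(data)[cols]


# ---------------------------------------------------------------------------
# DAG models and ancestral sampling
# ---------------------------------------------------------------------------

def dag_model_for_pc(
    p_continuous: int,
    p_discrete: int = 0,
    levels: int = 2,
    expected_degree: float = 2.0,
    effect_scale: float = 1.0,
    seed: int = 0,
) -> GroundTruthModel:
    """Random DAG with mixed-type structural equations.

    A random node order is drawn; each earlier->later pair receives an edge
    with probability expected_degree/(p−1).  Continuous children follow
    linear-Gaussian equations (unit noise variance); categorical children
    follow multinomial-logistic equations.
    """
    p = p_continuous + p_discrete
    if p < 2:
        raise ValueError("need p >= 2")
    if expected_degree < 0 or expected_degree >= p:
        raise ValueError("expected_degree must be in [0, p)")
    rng = np.random.default_rng(seed)
    cont, disc = _names(p_continuous, p_discrete)
    nodes = cont + disc
    is_cont = {name: (name in set(cont)) for name in nodes}
    n_levels = {name: (0 if is_cont[name] else levels) for name in nodes}
    order = [nodes[i] for i in rng.permutation(p)]
    prob = expected_degree / (p - 1)

    graph = EndpointGraph(nodes)
    weights: dict[tuple[str, str], np.ndarray] = {}
    for i in range(p):
        for j in range(i + 1, p):
            if rng.random() >= prob:
                continue
            par, chi = order[i], order[j]
            graph.add_directed(par, chi)
            if is_cont[par] and is_cont[chi]:
                w = np.asarray(_draw_magnitudes(rng, (), effect_scale))
            elif not is_cont[par] and is_cont[chi]:
                w = _center_vector(rng, n_levels[par], effect_scale)
            elif is_cont[par] and not is_cont[chi]:
                w = _center_vector(rng, n_levels[chi], effect_scale)
            else:
                w = _center_matrix(rng, n_levels[par], n_levels[chi], effect_scale)
            weights[(par, chi)] = w

    specs = [VariableSpec(c, CONTINUOUS) for c in cont] + [
        VariableSpec(d, CATEGORICAL, tuple(str(l) for l in range(levels))) for d in disc
    ]
    params = SEMParameters(weights=weights, order=order)
    return GroundTruthModel(graph=graph, params=params, specs=specs, seed=seed)


def _ancestral_sample(model: GroundTruthModel, n: int, seed: int) -> pd.DataFrame:
    params: SEMParameters = model.params
    rng = np.random.default_rng(seed)
    spec_by_name = {s.name: s for s in model.specs}
    values: dict[str, np.ndarray] = {}

    def parent_signal(par: str) -> np.ndarray:
        # continuous parents enter on a standardized scale so variance does
        # not accumulate along the topological order (bounded signal/noise)
        pv = values[par]
        if spec_by_name[par].is_continuous:
            sd = pv.std()
            return (pv - pv.mean()) / sd if sd > 0 else pv - pv.mean()
        return pv

    for node in params.order:
        spec = spec_by_name[node]
        parents = [(p, w) for (p, c), w in params.weights.items() if c == node]
        if spec.is_continuous:
            mean = np.zeros(n)
            for par, w in parents:
                pv = parent_signal(par)
                if spec_by_name[par].is_continuous:
                    mean += float(w) * pv
                else:
                    mean += np.asarray(w)[pv.astype(int)]
            values[node] = mean + rng.standard_normal(n)
        else:
            scores = np.zeros((n, spec.n_levels))
            for par, w in parents:
                pv = parent_signal(par)
                if spec_by_name[par].is_continuous:
                    scores += pv[:, None] * np.asarray(w)[None, :]
                else:
                    scores += np.asarray(w)[pv.astype(int), :]
            values[node] = _softmax_sample(rng, scores)
    cols = [s.name for s in model.specs]
    return pd.DataFrame({c: values[c] for c in cols})[cols]


# ---------------------------------------------------------------------------
# public sampling entry point
# ---------------------------------------------------------------------------

def sample_mixed_data(
    model: GroundTruthModel,
    n: int,
    burn_in: int = 200,
    thin: int = 10,
    seed: int = 0,
    n_chains: int | None = None,
) -> MixedDataset:
    """Draw ``n`` samples from a ground-truth model.

    Undirected models are sampled by Gibbs sweeps over the node
    conditionals, run as many short parallel chains (vectorized across
    chains): each chain is burned in for ``burn_in`` sweeps and then
    contributes one draw every ``thin`` sweeps until ``n`` rows are
    collected.  DAG models are sampled ancestrally in topological order
    (``burn_in``/``thin`` are ignored).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if model.is_dag:
        frame = _ancestral_sample(model, n, seed)
    else:
        frame = _gibbs_sample(model, n, burn_in, thin, seed, n_chains)
    frame = frame.copy()
    for s in model.specs:
        if s.is_categorical:
            frame[s.name] = frame[s.name].astype(int)
    return MixedDataset(specs=list(model.specs), frame=frame)
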