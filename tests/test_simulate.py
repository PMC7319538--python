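"""Ground-truth generators and samplers."""

import numpy as np
import pytest
from scipy import stats

from causalmix.citests import ci_test
from causalmix.dataset import CONTINUOUS, VariableSpec
from causalmix.graph import EndpointGraph
from causalmix.mgm import MGMParameters
from causalmix.simulate import (
    GroundTruthModel,
    SimulationConfig,
    continuous_precision,
    dag_model_for_pc,
    random_mixed_graph,
    sample_mixed_data,
)


def two_node_model(beta):
    params = MGMParameters.zeros(["A", "B"], [], [])
    params.beta[0, 1] = params.beta[1, 0] = beta
    g = EndpointGraph(["A", "B"])
    g.add_edge("A", "B")
    specs = [VariableSpec("A", CONTINUOUS), VariableSpec("B", CONTINUOUS)]
    return GroundTruthModel(graph=g, params=params, specs=specs, seed=0)


class TestRandomMixedGraph:
    def test_zero_degree_gives_empty_graph(self):
        cfg = SimulationConfig(p_continuous=5, p_discrete=5, expected_degree=0, seed=1)
        m = random_mixed_graph(cfg)
        assert m.graph.n_edges == 0
        assert not np.any(m.params.beta)
        assert not np.any(m.params.rho)
        assert not np.any(m.params.phi)

    def test_mean_degree_matches_expectation(self):
        # mean realized degree = 2 * E[edges] / p should estimate
        # expected_degree; check within 3 standard errors over 50 seeds
        target = 2.0
        degrees = []
        for seed in range(50):
            cfg = SimulationConfig(p_continuous=8, p_discrete=4,
                                   expected_degree=target, seed=seed)
            m = random_mixed_graph(cfg)
            degrees.append(2 * m.graph.n_edges / 12)
        se = np.std(degrees, ddof=1) / np.sqrt(len(degrees))
        assert abs(np.mean(degrees) - target) < 3 * se + 1e-12

    def test_supports_500_variables(self):
        cfg = SimulationConfig(p_continuous=250, p_discrete=250, levels=2,
                               expected_degree=2, seed=0)
        m = random_mixed_graph(cfg)
        assert len(m.specs) == 500
        assert m.graph.n_edges > 0

    def test_blocks_nonzero_exactly_on_edges(self):
        cfg = SimulationConfig(p_continuous=5, p_discrete=5, levels=3,
                               expected_degree=3, seed=2)
        m = random_mixed_graph(cfg)
        p = m.params
        names = list(p.cont_names) + list(p.disc_names)
        for i, u in enumerate(names):
            for j in range(i + 1, len(names)):
                v = names[j]
                if u.startswith("C") and v.startswith("C"):
                    nz = p.beta[i, j] != 0
                elif u.startswith("C"):
                    nz = np.any(p.rho_block(i, j - 5))
                else:
                    nz = np.any(p.phi_block(i - 5, j - 5))
                assert nz == m.graph.has_edge(u, v)

    def test_centered_blocks(self):
        cfg = SimulationConfig(p_continuous=4, p_discrete=4, levels=3,
                               expected_degree=3, seed=3)
        p = random_mixed_graph(cfg).params
        for s in range(4):
            for j in range(4):
                blk = p.rho_block(s, j)
                if np.any(blk):
                    assert abs(blk.sum()) < 1e-10
        for r in range(4):
            for j in range(r + 1, 4):
                blk = p.phi_block(r, j)
                if np.any(blk):
                    assert np.all(np.abs(blk.sum(axis=0)) < 1e-10)
                    assert np.all(np.abs(blk.sum(axis=1)) < 1e-10)

    def test_precision_well_conditioned(self):
        for seed in range(5):
            cfg = SimulationConfig(p_continuous=10, p_discrete=0,
                                   expected_degree=3, seed=seed)
            m = random_mixed_graph(cfg)
            assert np.linalg.eigvalsh(continuous_precision(m))[0] >= 0.4 - 1e-9

    def test_excessive_degree_errors(self):
        with pytest.raises(ValueError):
            SimulationConfig(p_continuous=3, p_discrete=0,
                             expected_degree=3).validate()


class TestGibbsSampler:
    def test_seeded_determinism(self):
        cfg = SimulationConfig(p_continuous=3, p_discrete=2, expected_degree=2, seed=4)
        m = random_mixed_graph(cfg)
        d1 = sample_mixed_data(m, n=50, seed=5)
        d2 = sample_mixed_data(m, n=50, seed=5)
        assert d1.frame.equals(d2.frame)

    def test_empty_graph_independence(self):
        cfg = SimulationConfig(p_continuous=4, p_discrete=3, levels=3,
                               expected_degree=0, seed=6)
        m = random_mixed_graph(cfg)
        d = sample_mixed_data(m, n=5000, seed=7)
        X = np.column_stack([d.column(c) for c in d.continuous_names])
        corr = np.corrcoef(X, rowvar=False)
        assert np.max(np.abs(corr - np.eye(4))) < 0.05
        # discrete pairs: chi-square tests non-significant at Bonferroni level
        disc = d.categorical_names
        n_pairs = len(disc) * (len(disc) - 1) // 2
        for i, a in enumerate(disc):
            for b in disc[i + 1:]:
                tab = np.zeros((3, 3))
                for u, v in zip(d.column(a), d.column(b)):
                    tab[int(u), int(v)] += 1
                p = stats.chi2_contingency(tab)[1]
                assert p > 0.05 / n_pairs

    def test_two_node_correlation_matches_precision(self):
        beta = 0.5
        m = two_node_model(beta)
        d = sample_mixed_data(m, n=10_000, seed=8)
        r = np.corrcoef(d.column("A"), d.column("B"))[0, 1]
        sigma = np.linalg.inv(continuous_precision(m))
        expected = sigma[0, 1] / np.sqrt(sigma[0, 0] * sigma[1, 1])
        assert abs(r - expected) < 0.03

    def test_covariance_matches_inverse_precision(self):
        cfg = SimulationConfig(p_continuous=6, p_discrete=0,
                               expected_degree=2, effect_scale=0.6, seed=9)
        m = random_mixed_graph(cfg)
        d = sample_mixed_data(m, n=10_000, seed=10)
        X = np.column_stack([d.column(c) for c in d.continuous_names])
        sigma = np.linalg.inv(continuous_precision(m))
        assert np.max(np.abs(np.cov(X, rowvar=False) - sigma)) < 0.05

    def test_supports_n_20000(self):
        cfg = SimulationConfig(p_continuous=3, p_discrete=2, expected_degree=1, seed=11)
        m = random_mixed_graph(cfg)
        d = sample_mixed_data(m, n=20_000, seed=12)
        assert d.n == 20_000
        assert np.isfinite(d.frame.to_numpy(dtype=float)).all()

    def test_oversized_parameters_raise(self):
        m = two_node_model(1e200)
        with pytest.raises(FloatingPointError):
            sample_mixed_data(m, n=10, seed=0)


class TestDagModels:
    def test_collider_marginal_vs_conditional_dependence(self):
        # X -> Z <- Y: X,Y marginally independent, dependent given Z
        for seed in range(3):
            m = dag_model_for_pc(3, expected_degree=0, seed=seed)
        # build the collider explicitly instead of rejection sampling
        from causalmix.simulate import SEMParameters

        g = EndpointGraph(["X", "Y", "Z"])
        g.add_directed("X", "Z")
        g.add_directed("Y", "Z")
        params = SEMParameters(
            weights={("X", "Z"): np.asarray(0.8), ("Y", "Z"): np.asarray(0.8)},
            order=["X", "Y", "Z"],
        )
        specs = [VariableSpec(v, CONTINUOUS) for v in ["X", "Y", "Z"]]
        model = GroundTruthModel(graph=g, params=params, specs=specs, seed=0)
        d = sample_mixed_data(model, n=5000, seed=13)
        assert ci_test(d, "X", "Y").independent
        assert not ci_test(d, "X", "Y", ("Z",)).independent

    def test_chain_conditional_independence_rejection_rate(self):
        # X -> Y -> Z: X indep Z | Y; rejection rate ~ alpha over replicates
        from causalmix.simulate import SEMParameters

        g = EndpointGraph(["X", "Y", "Z"])
        g.add_directed("X", "Y")
        g.add_directed("Y", "Z")
        params = SEMParameters(
            weights={("X", "Y"): np.asarray(0.8), ("Y", "Z"): np.asarray(0.8)},
            order=["X", "Y", "Z"],
        )
        specs = [VariableSpec(v, CONTINUOUS) for v in ["X", "Y", "Z"]]
        model = GroundTruthModel(graph=g, params=params, specs=specs, seed=0)
        rej = 0
        reps = 200
        for r in range(reps):
            d = sample_mixed_data(model, n=500, seed=1000 + r)
            rej += not ci_test(d, "X", "Z", ("Y",)).independent
        assert 0.005 <= rej / reps <= 0.11

    def test_two_independent_columns(self):
        m = dag_model_for_pc(2, expected_degree=0, seed=14)
        assert m.graph.n_edges == 0
        d = sample_mixed_data(m, n=2000, seed=15)
        assert ci_test(d, *sorted(d.names)).independent

    def test_dag_is_acyclic_and_mixed(self):
        import networkx as nx

        m = dag_model_for_pc(6, p_discrete=3, levels=3, expected_degree=2, seed=16)
        assert nx.is_directed_acyclic_graph(m.graph.directed_subgraph())
        d = sample_mixed_data(m, n=100, seed=17)
        assert len(d.categorical_names) == 3

    def test_dsep_structure_on_four_node_motif(self):
        # diamond A -> B, A -> C, B -> D, C -> D:
        # B indep C | A; A indep D | {B, C}
        from causalmix.simulate import SEMParameters

        g = EndpointGraph(["A", "B", "C", "D"])
        for u, v in [("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")]:
            g.add_directed(u, v)
        params = SEMParameters(
            weights={k: np.asarray(0.7) for k in
                     [("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")]},
            order=["A", "B", "C", "D"],
        )
        specs = [VariableSpec(v, CONTINUOUS) for v in "ABCD"]
        model = GroundTruthModel(graph=g, params=params, specs=specs, seed=0)
        d = sample_mixed_data(model, n=5000, seed=18)
        assert ci_test(d, "B", "C", ("A",), alpha=0.01).independent
        assert ci_test(d, "A", "D", ("B", "C"), alpha=0.01).independent
        assert not ci_test(d, "A", "D", ("B",)).independent
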