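"""Structure learners: scores, searches, equivalence classes, consensus."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cardioresp.discovery import (
    DERIVED_PAIR_MASK,
    bic_score,
    cam_learn,
    consensus,
    gc_graph,
    generalized_correlation,
    ges_learn,
    hc_learn,
    tabu_learn,
)
from cardioresp.discovery.ges import dag_to_cpdag
from cardioresp.synthetic import SCMSpec, generate_scm_table
from cardioresp.types import CausalGraph, ParameterTable


def _chain_table(n=5000, seed=0, nodes=("A", "B", "C")):
    spec = SCMSpec(
        node_names=nodes,
        edges=((nodes[0], nodes[1], ("linear", 1.0)),
               (nodes[1], nodes[2], ("linear", 1.0))),
        noise_sd=1.0, n=n, seed=seed,
    )
    return generate_scm_table(spec)[0]


def _collider_table(n=5000, seed=0):
    spec = SCMSpec(
        node_names=("X", "Y", "Z"),
        edges=(("X", "Z", ("linear", 1.0)), ("Y", "Z", ("linear", 1.0))),
        noise_sd=1.0, n=n, seed=seed,
    )
    return generate_scm_table(spec)[0]


class TestGeneralizedCorrelation:
    def test_identity_symmetric_and_undecided(self):
        x = np.random.default_rng(0).normal(size=200)
        pair = generalized_correlation(x, x.copy(), seed=0)
        assert pair.gmc_y_given_x > 0.99
        assert pair.gmc_x_given_y > 0.99
        assert pair.direction == "undecided"

    def test_cubic_mechanism_oriented_with_spline_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 500)
        y = x ** 3 + rng.normal(0, 0.5, 500)
        pair = generalized_correlation(x, y, seed=3)
        assert abs(pair.rstar_y_given_x) > abs(pair.rstar_x_given_y)
        assert pair.direction == "x_causes_y"
        # independent oracle: cubic-spline regressions of each conditional
        from scipy.interpolate import UnivariateSpline

        def spline_gmc(a, b):
            order = np.argsort(a)
            spl = UnivariateSpline(a[order], b[order], k=3, s=len(a) * np.var(b) * 0.05)
            resid = b - spl(a)
            return 1.0 - np.mean(resid ** 2) / np.var(b)

        assert spline_gmc(x, y) > spline_gmc(y, x)
        assert pair.gmc_y_given_x == pytest.approx(spline_gmc(x, y), abs=0.1)

    def test_independent_pairs_mostly_undecided(self):
        rng = np.random.default_rng(11)
        undecided = 0
        reps = 10
        for rep in range(reps):
            x, y = rng.normal(size=(2, 300))
            pair = generalized_correlation(x, y, seed=rep, n_boot=200)
            undecided += pair.direction == "undecided"
        assert undecided >= 9

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            generalized_correlation(np.ones(100), np.random.default_rng(0).normal(size=100))


class TestBicScore:
    def test_markov_equivalence_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=500)
        y = x + 0.1 * rng.normal(size=500)
        table = pd.DataFrame({"X": x, "Y": y})
        assert bic_score(table, [("X", "Y")]) == pytest.approx(
            bic_score(table, [("Y", "X")]), abs=1e-8
        )

    def test_true_edge_improves_empty_graph(self):
        spec = SCMSpec(node_names=("X", "Y"), edges=(("X", "Y", ("linear", 1.0)),),
                       n=1000, seed=6)
        table, _ = generate_scm_table(spec)
        assert bic_score(table, [("X", "Y")]) > bic_score(table, [])

    def test_null_data_prefers_empty_graph(self):
        wins = 0
        for seed in range(20):
            spec = SCMSpec(node_names=("X", "Y"), edges=(), n=500, seed=seed)
            table, _ = generate_scm_table(spec)
            wins += bic_score(table, []) > bic_score(table, [("X", "Y")])
        assert wins >= 19

    def test_cyclic_graph_rejected(self):
        table = pd.DataFrame(np.random.default_rng(0).normal(size=(50, 2)),
                             columns=["X", "Y"])
        with pytest.raises(ValueError, match="cycle"):
            bic_score(table, [("X", "Y"), ("Y", "X")])


class TestHillClimbingAndTabu:
    def test_independent_columns_give_empty_graph(self):
        spec = SCMSpec(node_names=("X", "Y"), edges=(), n=1000, seed=1)
        table, _ = generate_scm_table(spec)
        assert hc_learn(table).edges == ()

    def test_chain_skeleton_recovered_without_shortcut(self):
        hits = 0
        for seed in range(10):
            graph = hc_learn(_chain_table(seed=seed))
            want = {frozenset(("A", "B")), frozenset(("B", "C"))}
            hits += graph.skeleton == want
        assert hits >= 9

    def test_single_column_empty(self):
        table = pd.DataFrame({"X": np.random.default_rng(0).normal(size=100)})
        assert hc_learn(table).edges == ()

    def test_tabu_never_below_hill_climbing(self):
        for seed in range(5):
            spec = SCMSpec(
                node_names=("A", "B", "C", "D"),
                edges=(("A", "B", ("linear", 1.0)), ("B", "C", ("linear", 0.8)),
                       ("A", "D", ("linear", 0.6))),
                n=300, seed=seed,
            )
            table, _ = generate_scm_table(spec)
            assert tabu_learn(table, seed=seed).score >= hc_learn(table, seed=seed).score - 1e-9

    def test_degenerate_tabu_equals_hill_climbing(self):
        table = _chain_table(n=800, seed=5)
        assert tabu_learn(table, tabu_len=0, max_iter=0).edges == hc_learn(table).edges

    def test_learners_are_acyclic_and_deterministic(self):
        table = _chain_table(n=1000, seed=2)
        g1, g2 = hc_learn(table, seed=7), hc_learn(table, seed=7)
        assert g1.edges == g2.edges
        assert not g1.has_directed_cycle()
        t1 = tabu_learn(table, seed=7)
        assert not t1.has_directed_cycle()

    def test_row_order_and_affine_invariance(self):
        table = _chain_table(n=1000, seed=3)
        base = hc_learn(table)
        shuffled = table.data.sample(frac=1.0, random_state=0)
        rescaled = shuffled * np.array([3.0, 0.5, 10.0]) + np.array([1.0, -2.0, 7.0])
        assert hc_learn(ParameterTable(rescaled)).edges == base.edges

    def test_masked_pair_never_appears(self):
        spec = SCMSpec(
            node_names=("RMSSD", "lnRMSSD", "HR"),
            edges=(("RMSSD", "lnRMSSD", ("linear", 1.0)),),
            noise_sd={"RMSSD": 1.0, "lnRMSSD": 0.05, "HR": 1.0},
            n=500, seed=0,
        )
        table, _ = generate_scm_table(spec)
        graph = hc_learn(table, mask=DERIVED_PAIR_MASK)
        assert frozenset(("RMSSD", "lnRMSSD")) not in graph.skeleton


class TestGES:
    def test_collider_oriented(self):
        hits = 0
        for seed in range(10):
            graph = ges_learn(_collider_table(seed=seed))
            hits += (set(graph.directed_edges) == {("X", "Z"), ("Y", "Z")}
                     and not graph.undirected_edges)
        assert hits >= 9

    def test_chain_left_undirected(self):
        graph = ges_learn(_chain_table(n=5000, seed=8, nodes=("X", "Y", "Z")))
        assert not graph.directed_edges
        assert set(graph.undirected_edges) == {("X", "Y"), ("Y", "Z")}

    def test_matches_exhaustive_three_node_search(self):
        nodes = ["A", "B", "C"]
        pairs = [(a, b) for a in nodes for b in nodes if a != b]

        def all_dags():
            out = []
            for r in range(len(pairs) + 1):
                for combo in itertools.combinations(pairs, r):
                    if any((b, a) in combo for a, b in combo):
                        continue
                    g = nx.DiGraph()
                    g.add_nodes_from(nodes)
                    g.add_edges_from(combo)
                    if nx.is_directed_acyclic_graph(g):
                        out.append(combo)
            return out

        dags = all_dags()
        assert len(dags) == 25
        rng = np.random.default_rng(42)
        agree = 0
        reps = 10
        for _ in range(reps):
            k = int(rng.integers(0, 4))
            g = nx.DiGraph()
            g.add_nodes_from(nodes)
            edges = []
            candidates = list(pairs)
            while len(edges) < k and candidates:
                a, b = candidates.pop(int(rng.integers(0, len(candidates))))
                if not g.has_edge(b, a) and not nx.has_path(g, b, a):
                    g.add_edge(a, b)
                    coef = float(rng.uniform(0.5, 1.5)) * float(rng.choice([-1, 1]))
                    edges.append((a, b, ("linear", coef)))
            spec = SCMSpec(node_names=tuple(nodes), edges=tuple(edges),
                           noise_sd=1.0, n=2000, seed=int(rng.integers(0, 2**30)))
            table, _ = generate_scm_table(spec)
            best = max(dags, key=lambda d: bic_score(table, d))
            best_dir, best_und = dag_to_cpdag(nodes, set(best))
            learned = ges_learn(table)
            agree += (set(learned.directed_edges) == best_dir
                      and {frozenset(e) for e in learned.undirected_edges} == best_und)
        assert agree >= reps - 1

    def test_output_is_valid_cpdag(self):
        graph = ges_learn(_collider_table(seed=1))
        assert not graph.has_directed_cycle()


class TestCAM:
    def test_sine_mechanism_recovered_with_direction(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 1.5, 500)
            y = np.sin(2 * x) + rng.normal(0, 0.2, 500)
            graph = cam_learn(pd.DataFrame({"X": x, "Y": y}))
            hits += graph.edges == (("X", "Y", "directed"),)
        assert hits >= 8

    def test_independent_columns_empty(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            table = pd.DataFrame({"X": rng.normal(size=300), "Y": rng.normal(size=300)})
            hits += len(cam_learn(table).edges) == 0
        assert hits >= 8

    def test_linear_gaussian_skeleton_only(self):
        # direction not identifiable for linear-Gaussian pairs: assert skeleton
        spec = SCMSpec(node_names=("X", "Y"), edges=(("X", "Y", ("linear", 1.0)),),
                       n=500, seed=2)
        table, _ = generate_scm_table(spec)
        graph = cam_learn(table)
        assert graph.skeleton == {frozenset(("X", "Y"))}

    def test_too_few_rows_rejected(self):
        table = pd.DataFrame(np.random.default_rng(0).normal(size=(30, 2)),
                             columns=["X", "Y"])
        with pytest.raises(ValueError):
            cam_learn(table)

    def test_acyclic(self):
        table = _chain_table(n=400, seed=9)
        assert not cam_learn(table).has_directed_cycle()


class TestConsensus:
    def _graph(self, edges, method="HC"):
        return CausalGraph(nodes=("A", "B", "C"), edges=tuple(edges), method=method)

    def test_identical_graphs_full_support(self):
        graphs = [self._graph([("A", "B", "directed")], m) for m in "vwxyz"]
        report = consensus(graphs, min_support=5)
        assert report.support[("A", "B")] == 5

    def test_conflicting_directions_counted_separately(self):
        graphs = (
            [self._graph([("A", "B", "directed")], f"m{i}") for i in range(3)]
            + [self._graph([("B", "A", "directed")], "m3")]
        )
        report = consensus(graphs, min_support=3)
        assert report.support[("A", "B")] == 3
        assert report.support[("B", "A")] == 1

    def test_undirected_edges_give_half_support(self):
        graphs = [self._graph([("A", "B", "undirected")], "GES")]
        report = consensus(graphs, min_support=1)
        assert report.support[("A", "B")] == 0.5
        assert report.support[("B", "A")] == 0.5

    def test_chain_path_extracted(self):
        chain = [("A", "B", "directed"), ("B", "C", "directed")]
        graphs = [self._graph(chain, m) for m in ("GC", "HC", "TABU", "CAM")]
        report = consensus(graphs, min_support=3)
        assert ("A", "B", "C") in report.paths

    def test_node_mismatch_rejected(self):
        g1 = self._graph([])
        g2 = CausalGraph(nodes=("A", "B"), edges=(), method="HC")
        with pytest.raises(ValueError):
            consensus([g1, g2])


class TestGcGraph:
    def test_masked_pair_absent_and_cycles_allowed(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 200)
        table = ParameterTable(pd.DataFrame({
            "RMSSD": x, "lnRMSSD": x + 0.01 * rng.normal(size=200),
            "HR": rng.normal(size=200),
        }))
        graph = gc_graph(table, mask=DERIVED_PAIR_MASK, n_boot=100, seed=0)
        assert frozenset(("RMSSD", "lnRMSSD")) not in graph.skeleton

    def test_nonlinear_chain_recovered(self):
        hits_xy = 0
        reps = 5
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 1, 800)
            y = x ** 3 + rng.normal(0, 0.5, 800)
            z = y ** 3 / 10 + rng.normal(0, 0.5, 800) * np.std(y ** 3 / 10)
            table = ParameterTable(pd.DataFrame({"X": x, "Y": y, "Z": z}))
            graph = gc_graph(table, n_boot=200, seed=seed)
            hits_xy += ("X", "Y") in graph.directed_edges
        assert hits_xy >= 4
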