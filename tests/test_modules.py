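"""Weighted-network integration, greedy module search, Monte-Carlo significance."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from integratome.modules import (
    EpigeneticModule,
    ModuleRejected,
    WeightedNetwork,
    detect_modules,
    greedy_module_search,
    integrate_statistics,
    module_significance,
    shared_genes,
)


def _stats(d):
    return pd.DataFrame({"statistic": pd.Series(d)}).rename_axis("gene")


def _wnet_from_weights(edges, node_w):
    """Build a WeightedNetwork directly from chosen node weights."""
    g = nx.Graph()
    for n, w in node_w.items():
        g.add_node(
            n, meth_w=w, expr_w=w, meth_sign=1, expr_sign=1, node_w=w,
            missing_meth=False, missing_expr=False,
        )
    for u, v in edges:
        g.add_edge(u, v, edge_w=0.5 * (node_w[u] + node_w[v]))
    return WeightedNetwork(g)


class TestIntegrateStatistics:
    def test_equal_statistics_give_equal_node_weights(self):
        net = nx.Graph([("A", "B"), ("B", "C")])
        meth = _stats({"A": 2.0, "B": -2.0, "C": 2.0})
        expr = _stats({"A": 1.0, "B": 1.0, "C": -1.0})
        w = integrate_statistics(meth, expr, net)
        assert w.node_w("A") == w.node_w("B") == w.node_w("C") == 0.5

    def test_hand_computed_path_weights(self):
        # |t| ranks 1..4 -> weights (0.125, 0.375, 0.625, 0.875) in both layers
        net = nx.Graph([("A", "B"), ("B", "C"), ("C", "D")])
        t = {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}
        w = integrate_statistics(_stats(t), _stats(t), net)
        expected = {"A": 0.125, "B": 0.375, "C": 0.625, "D": 0.875}
        for g, e in expected.items():
            assert w.node_w(g) == pytest.approx(e)
        assert w.graph.edges[("A", "B")]["edge_w"] == pytest.approx(0.25)
        assert w.graph.edges[("C", "D")]["edge_w"] == pytest.approx(0.75)
        w.verify_edge_weights()

    def test_rank_invariance_under_monotone_transform(self):
        net = nx.Graph([("A", "B"), ("B", "C"), ("C", "D")])
        t = {"A": 0.5, "B": 1.5, "C": 2.0, "D": 4.0}
        t2 = {k: np.exp(v) for k, v in t.items()}  # monotone in |t|
        w1 = integrate_statistics(_stats(t), _stats(t), net)
        w2 = integrate_statistics(_stats(t2), _stats(t2), net)
        for g in net.nodes:
            assert w1.node_w(g) == pytest.approx(w2.node_w(g))

    def test_missing_layer_scores_zero_and_flagged(self):
        net = nx.Graph([("A", "B"), ("B", "C")])
        meth = _stats({"A": 2.0, "B": 1.0, "C": 3.0})
        expr = _stats({"A": 1.0, "B": 1.0})  # C missing
        w = integrate_statistics(meth, expr, net)
        assert w.graph.nodes["C"]["expr_w"] == 0.0
        assert w.graph.nodes["C"]["missing_expr"]

    def test_low_coverage_rejected_unless_overridden(self):
        net = nx.path_graph(10)
        net = nx.relabel_nodes(net, {i: f"G{i}" for i in range(10)})
        meth = _stats({"G0": 1.0})
        expr = _stats({"G0": 1.0})
        with pytest.raises(ValueError, match="coverage"):
            integrate_statistics(meth, expr, net)
        w = integrate_statistics(meth, expr, net, allow_low_coverage=True)
        assert w.node_w("G5") == 0.0


def exhaustive_best_score(wnet, max_size):
    """Best mean-edge-weight over all connected subgraphs with >=2 nodes."""
    g = wnet.graph
    nodes = list(g.nodes)
    best = -np.inf
    for r in range(2, min(len(nodes), max_size) + 1):
        for combo in itertools.combinations(nodes, r):
            sub = g.subgraph(combo)
            if not nx.is_connected(sub):
                continue
            ws = [d["edge_w"] for _, _, d in sub.edges(data=True)]
            best = max(best, float(np.mean(ws)))
    return best


class TestGreedySearch:
    def test_triangle_keeps_heavy_pair(self):
        w = _wnet_from_weights(
            [("A", "B"), ("B", "C"), ("A", "C")], {"A": 0.9, "B": 0.9, "C": 0.1}
        )
        mod = greedy_module_search(w, "A", min_size=2, max_size=10)
        assert mod.members == frozenset({"A", "B"})
        assert mod.score == pytest.approx(0.9)

    def test_uniform_weights_stop_at_seed_plus_tiebreak_neighbor(self):
        g = nx.Graph([("B", "A"), ("B", "C"), ("B", "D")])
        w = _wnet_from_weights(g.edges, {n: 0.5 for n in g.nodes})
        mod = greedy_module_search(w, "B", min_size=2, max_size=10)
        assert mod.members == frozenset({"B", "A"})  # lexicographic tie-break

    def test_deterministic_given_seed_gene(self, rng):
        g = nx.gnm_random_graph(15, 30, seed=4)
        g = nx.relabel_nodes(g, {i: f"G{i:02d}" for i in range(15)})
        weights = {n: float(w) for n, w in zip(sorted(g.nodes), rng.random(15))}
        w = _wnet_from_weights(g.edges, weights)
        mods = [greedy_module_search(w, "G03", 2, 8) for _ in range(3)]
        assert len({m.members for m in mods}) == 1

    def test_isolated_seed_rejected(self):
        g = nx.Graph([("A", "B")])
        g.add_node("Z")
        w = _wnet_from_weights([("A", "B")], {"A": 0.5, "B": 0.5, "Z": 0.5})
        with pytest.raises(ModuleRejected, match="isolated"):
            greedy_module_search(w, "Z", 2, 8)

    def test_greedy_never_beats_exhaustive_and_matches_easy_instances(self, rng):
        # random small graphs: greedy <= exhaustive optimum
        for i in range(30):
            n = int(rng.integers(5, 10))
            g = nx.gnm_random_graph(n, min(2 * n, n * (n - 1) // 2), seed=100 + i)
            g = nx.relabel_nodes(g, {j: f"G{j}" for j in range(n)})
            weights = {m: float(x) for m, x in zip(sorted(g.nodes), rng.random(n))}
            w = _wnet_from_weights(g.edges, weights)
            best = exhaustive_best_score(w, max_size=n)
            for seed_gene in sorted(g.nodes):
                try:
                    mod = greedy_module_search(w, seed_gene, 2, n)
                except ModuleRejected:
                    continue
                assert mod.score <= best + 1e-12
        # designed instance: the heavy pair is the global optimum and greedy finds it
        w = _wnet_from_weights(
            [("A", "B"), ("B", "C"), ("A", "C")], {"A": 0.9, "B": 0.9, "C": 0.1}
        )
        mod = greedy_module_search(w, "B", 2, 3)
        assert mod.score == pytest.approx(exhaustive_best_score(w, 3))


class TestModuleSignificance:
    def test_uniform_weights_give_p_one(self):
        g = nx.cycle_graph(8)
        g = nx.relabel_nodes(g, {i: f"G{i}" for i in range(8)})
        w = _wnet_from_weights(g.edges, {n: 0.4 for n in g.nodes})
        mod = greedy_module_search(w, "G0", 2, 5)
        p = module_significance(w, mod, B=100, seed=1, min_size=2, max_size=5)
        assert p == 1.0

    def test_p_never_below_add_one_bound(self, small_study):
        from integratome import moderated_t, probe_differential, summarize_gene_methylation

        d = small_study
        de = moderated_t(d.expression["SAT"], d.sheet, "SAT")
        gm = summarize_gene_methylation(
            probe_differential(d.beta["SAT"], d.sheet, "SAT"), d.annotation
        )
        w = integrate_statistics(gm, de, d.network["SAT"])
        seed_gene = max(w.graph.nodes, key=lambda g: (w.node_w(g), g))
        mod = greedy_module_search(w, seed_gene)
        p = module_significance(w, mod, B=199, seed=5)
        assert p >= 1 / 200

    def test_planted_module_significant_at_b999(self, small_study):
        from integratome import moderated_t, probe_differential, summarize_gene_methylation

        d = small_study
        de = moderated_t(d.expression["SAT"], d.sheet, "SAT")
        gm = summarize_gene_methylation(
            probe_differential(d.beta["SAT"], d.sheet, "SAT"), d.annotation
        )
        w = integrate_statistics(gm, de, d.network["SAT"])
        planted = sorted(d.truth.module_genes["SAT"])
        seed_gene = max(planted, key=lambda g: w.node_w(g))
        mod = greedy_module_search(w, seed_gene)
        p = module_significance(w, mod, B=999, seed=17)
        assert p <= 0.01


class TestDetectModules:
    def _weighted(self, study, tissue="SAT"):
        from integratome import moderated_t, probe_differential, summarize_gene_methylation

        de = moderated_t(study.expression[tissue], study.sheet, tissue)
        gm = summarize_gene_methylation(
            probe_differential(study.beta[tissue], study.sheet, tissue),
            study.annotation,
        )
        return integrate_statistics(gm, de, study.network[tissue])

    def test_planted_module_recovered(self, small_study):
        w = self._weighted(small_study)
        mods = detect_modules(w, n_seeds=10, B=200, seed=3, tissue="SAT")
        assert len(mods) >= 1
        planted = set(small_study.truth.module_genes["SAT"])
        best = max(
            mods, key=lambda m: len(m.members & planted) / len(m.members | planted)
        )
        jac = len(best.members & planted) / len(best.members | planted)
        assert jac >= 0.6

    def test_pure_noise_rarely_yields_modules(self):
        g = nx.barabasi_albert_graph(120, 2, seed=1)
        g = nx.relabel_nodes(g, {i: f"G{i:03d}" for i in range(120)})
        rng = np.random.default_rng(0)
        n_with_modules = 0
        for rep in range(20):
            weights = {n: float(x) for n, x in zip(sorted(g.nodes), rng.random(120))}
            w = _wnet_from_weights(g.edges, weights)
            mods = detect_modules(w, n_seeds=10, B=199, seed=rep, tissue="SAT")
            n_with_modules += bool(mods)
        assert n_with_modules <= 2  # >=90% of replicates empty

    def test_identical_overlapping_modules_merge_to_one(self):
        # two seeds inside one heavy clique produce the same module
        clique = ["A", "B", "C", "D"]
        edges = list(itertools.combinations(clique, 2)) + [("D", "E"), ("E", "F")]
        weights = {**{n: 0.95 for n in clique}, "E": 0.1, "F": 0.1}
        w = _wnet_from_weights(edges, weights)
        m1 = greedy_module_search(w, "A", 2, 6)
        m2 = greedy_module_search(w, "B", 2, 6)
        assert m1.members == m2.members
        mods = detect_modules(w, n_seeds=2, min_size=2, max_size=6, B=199, seed=0)
        assert len(mods) <= 1


class TestSharedGenes:
    def _mod(self, genes, tissue="SAT"):
        return EpigeneticModule(
            tissue=tissue,
            seed_gene=sorted(genes)[0],
            members=frozenset(genes),
            score=0.5,
            n_genes=len(genes),
        )

    def test_disjoint_memberships_share_nothing(self):
        assert shared_genes([self._mod({"A", "B"})], [self._mod({"C"})]) == set()

    def test_identical_module_shares_itself(self):
        assert shared_genes([self._mod({"A", "B"})], [self._mod({"A", "B"})]) == {"A", "B"}

    def test_matches_set_oracle_on_random_fixtures(self, rng):
        genes = [f"G{i}" for i in range(40)]
        for _ in range(20):
            a = [self._mod(set(rng.choice(genes, 8, replace=False))) for _ in range(3)]
            b = [self._mod(set(rng.choice(genes, 8, replace=False)), "VAT") for _ in range(3)]
            ua = set().union(*(m.members for m in a))
            ub = set().union(*(m.members for m in b))
            assert shared_genes(a, b) == ua & ub
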