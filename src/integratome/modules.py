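"""Functional epigenetic module discovery on statistic-weighted networks.

The integrative core of the pipeline: differential-methylation and
differential-expression statistics are rank-normalized to [0, 1], averaged
into node weights on a tissue-specific regulatory network, and every edge
carries the average of its endpoint node weights (so edge width in a module
plot is the average statistic of the genes comprising the edge).  Modules
are grown greedily from high-weight seed genes, scored by the mean edge
weight of the induced subgraph, and assessed by a Monte-Carlo permutation of
the per-gene weight pairs over the nodes (preserving each gene's pairing of
methylation and expression weights, which keeps the null honest when the two
layers are correlated).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .diffexpr import bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "WeightedNetwork",
    "EpigeneticModule",
    "ModuleRejected",
    "integrate_statistics",
    "greedy_module_search",
    "module_significance",
    "detect_modules",
    "shared_genes",
    "modules_to_frame",
]


class ModuleRejected(ValueError):
    """Raised when a seed gene cannot anchor a valid module."""


@dataclass(frozen=True)
class WeightedNetwork:
    """Regulatory network annotated with per-gene statistic weights.

    Node attributes: ``meth_w``, ``expr_w`` (rank-normalized |statistic| in
    [0, 1], 0 when the gene lacks that data layer), ``meth_sign``,
    ``expr_sign`` in {-1, 0, +1}, ``node_w = (meth_w + expr_w) / 2`` and
    ``missing_meth`` / ``missing_expr`` flags.  Edge attribute ``edge_w``
    always equals the average of the endpoint node weights.
    """

    graph: nx.Graph

    def node_w(self, gene) -> float:
        return self.graph.nodes[gene]["node_w"]

    def verify_edge_weights(self, atol: float = 1e-12) -> None:
        """Assert the edge-weight contract after any (re)construction."""
        for u, v, data in self.graph.edges(data=True):
            expected = 0.5 * (self.node_w(u) + self.node_w(v))
            if abs(data["edge_w"] - expected) > atol:
                raise AssertionError(
                    f"edge ({u}, {v}) weight {data['edge_w']} != "
                    f"mean of node weights {expected}"
                )

    def induced_score(self, members) -> float:
        """Mean edge weight over the induced subgraph (nan if no edges)."""
        sub = self.graph.subgraph(members)
        weights = [d["edge_w"] for _, _, d in sub.edges(data=True)]
        return float(np.mean(weights)) if weights else float("nan")


@dataclass(frozen=True)
class EpigeneticModule:
    """A connected module: seed gene, members, score and significance."""

    tissue: str
    seed_gene: str
    members: frozenset
    score: float
    n_genes: int
    p_mc: float | None = None
    q: float | None = None


def _rank_weights(values: pd.Series) -> pd.Series:
    """Midrank-based normalization of |statistic| to (0, 1): (rank-0.5)/m."""
    ranks = sps.rankdata(values.abs().to_numpy(), method="average")
    return pd.Series((ranks - 0.5) / len(values), index=values.index)


def integrate_statistics(
    meth_gene_stats: pd.DataFrame,
    expr_gene_stats: pd.DataFrame,
    network: nx.Graph,
    min_coverage: float = 0.5,
    allow_low_coverage: bool = False,
) -> WeightedNetwork:
    """Build the statistic-weighted network from gene-level statistics.

    Both statistics frames are indexed by gene with a ``statistic`` column.
    For each layer, |statistic| is rank-transformed to (rank - 0.5) / m over
    the genes present in the network; genes missing a layer get weight 0 for
    it and are flagged.  Errors if fewer than ``min_coverage`` of network
    genes carry any statistic (override with ``allow_low_coverage``).
    """
    if network.number_of_nodes() == 0:
        raise ValueError("network is empty")
    nodes = sorted(network.nodes)
    meth = meth_gene_stats.loc[meth_gene_stats.index.intersection(nodes), "statistic"]
    expr = expr_gene_stats.loc[expr_gene_stats.index.intersection(nodes), "statistic"]
    covered = set(meth.index) | set(expr.index)
    coverage = len(covered) / len(nodes)
    if coverage < min_coverage and not allow_low_coverage:
        raise ValueError(
            f"only {coverage:.1%} of network genes carry any statistic "
            f"(< {min_coverage:.0%}); pass allow_low_coverage=True to override"
        )
    meth_w = _rank_weights(meth) if len(meth) else pd.Series(dtype=float)
    expr_w = _rank_weights(expr) if len(expr) else pd.Series(dtype=float)
    graph = nx.Graph()
    for gene in nodes:
        mw = float(meth_w.get(gene, 0.0))
        ew = float(expr_w.get(gene, 0.0))
        graph.add_node(
            gene,
            meth_w=mw,
            expr_w=ew,
            meth_sign=int(np.sign(meth.get(gene, 0.0))),
            expr_sign=int(np.sign(expr.get(gene, 0.0))),
            node_w=0.5 * (mw + ew),
            missing_meth=gene not in meth.index,
            missing_expr=gene not in expr.index,
        )
    for u, v in network.edges:
        graph.add_edge(
            u, v, edge_w=0.5 * (graph.nodes[u]["node_w"] + graph.nodes[v]["node_w"])
        )
    wnet = WeightedNetwork(graph)
    wnet.verify_edge_weights()
    return wnet


def _greedy(
    adjacency: dict,
    node_w: dict,
    seed: str,
    min_size: int,
    max_size: int,
) -> tuple[list, float]:
    """Greedy hill-climbing on mean edge weight from a single seed.

    Edge weight is derived from node weights ((w_u + w_v)/2), so the same
    routine serves both the observed network and weight permutations.
    Fully deterministic: ties broken by higher node weight, then
    lexicographic gene id.
    """
    if not adjacency.get(seed):
        raise ModuleRejected(f"seed {seed!r} is isolated in the network")
    members = {seed}
    order = [seed]
    edge_sum, edge_cnt = 0.0, 0
    score = float("-inf")  # first addition always accepted
    # candidate -> (sum of edge weights into module, count)
    cand: dict = {}
    for v in adjacency[seed]:
        w = 0.5 * (node_w[seed] + node_w[v])
        cand[v] = [w, 1]
    while len(members) < max_size and cand:
        best, best_key = None, None
        for v in cand:
            s, c = cand[v]
            new_score = (edge_sum + s) / (edge_cnt + c)
            key = (new_score, node_w[v])
            if best is None or key > best_key or (key == best_key and v < best):
                best, best_key = v, key
        best_score = best_key[0]
        if len(members) >= min_size and best_score <= score:
            break
        s, c = cand.pop(best)
        edge_sum += s
        edge_cnt += c
        score = best_score
        members.add(best)
        order.append(best)
        for v in adjacency[best]:
            if v in members:
                continue
            w = 0.5 * (node_w[best] + node_w[v])
            if v in cand:
                cand[v][0] += w
                cand[v][1] += 1
            else:
                cand[v] = [w, 1]
    if len(members) < min_size:
        raise ModuleRejected(
            f"component around seed {seed!r} has fewer than min_size={min_size} genes"
        )
    return order, score


def _adjacency(graph: nx.Graph) -> dict:
    return {n: sorted(graph.neighbors(n)) for n in graph.nodes}


def greedy_module_search(
    wnet: WeightedNetwork,
    seed_gene: str,
    min_size: int = 4,
    max_size: int = 50,
    tissue: str = "",
) -> EpigeneticModule:
    """Grow a module from ``seed_gene`` by greedy mean-edge-weight ascent.

    Starting from the seed, the neighbor maximizing the new module score
    (mean edge weight over induced edges; the best incident edge on the
    first step) is added repeatedly; growth stops when no addition increases
    the score once ``min_size`` is reached, or at ``max_size``.
    """
    if seed_gene not in wnet.graph:
        raise ModuleRejected(f"seed {seed_gene!r} not in network")
    adjacency = _adjacency(wnet.graph)
    node_w = {n: wnet.graph.nodes[n]["node_w"] for n in wnet.graph.nodes}
    members, score = _greedy(adjacency, node_w, seed_gene, min_size, max_size)
    return EpigeneticModule(
        tissue=tissue,
        seed_gene=seed_gene,
        members=frozenset(members),
        score=score,
        n_genes=len(members),
    )


def module_significance(
    wnet: WeightedNetwork,
    module: EpigeneticModule,
    B: int = 999,
    seed: int = 0,
    min_size: int = 4,
    max_size: int = 50,
) -> float:
    """Monte-Carlo p-value for a module score.

    ``B`` times, the per-gene (meth_w, expr_w) weight pairs are jointly
    permuted across all non-seed nodes (preserving each gene's pairing),
    edge weights are rebuilt implicitly, and the greedy search is rerun from
    the same seed gene; ``p = (1 + #{null score >= observed}) / (B + 1)``.

    The seed keeps its own weights: seeds are chosen as top-weight genes, so
    a high seed weight is a selection artifact, not module evidence; fixing
    it makes the null scores exchangeable with the observed score when the
    remaining weights carry no signal.
    """
    if B < 100:
        raise ValueError(f"B must be >= 100, got {B}")
    rng = np.random.default_rng(seed)
    adjacency = _adjacency(wnet.graph)
    nodes = sorted(n for n in wnet.graph.nodes if n != module.seed_gene)
    weights = np.array([wnet.graph.nodes[n]["node_w"] for n in nodes])
    seed_w = wnet.graph.nodes[module.seed_gene]["node_w"]
    exceed = 0
    for _ in range(B):
        perm = rng.permutation(len(nodes))
        node_w = {n: weights[j] for n, j in zip(nodes, perm)}
        node_w[module.seed_gene] = seed_w
        try:
            _, null_score = _greedy(
                adjacency, node_w, module.seed_gene, min_size, max_size
            )
        except ModuleRejected:  # pragma: no cover - seed isolated handled earlier
            continue
        if null_score >= module.score:
            exceed += 1
    return (1.0 + exceed) / (B + 1.0)


def detect_modules(
    wnet: WeightedNetwork,
    n_seeds: int = 10,
    min_size: int = 4,
    max_size: int = 50,
    B: int = 999,
    q_threshold: float = 0.1,
    seed: int = 0,
    tissue: str = "",
    merge_jaccard: float = 0.5,
) -> list[EpigeneticModule]:
    """Seeded module discovery with Monte-Carlo significance and BH control.

    Seeds are the ``n_seeds`` genes with highest node weight.  One module is
    grown per seed (isolated seeds are skipped with a log entry), each gets
    a Monte-Carlo p, BH is applied across seeds, and surviving modules whose
    memberships overlap (Jaccard > ``merge_jaccard``) are merged by union of
    members (score recomputed on the union; the best-scoring constituent's
    seed and significance are kept).
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    nodes = sorted(wnet.graph.nodes)
    ranked = sorted(nodes, key=lambda g: (-wnet.node_w(g), g))
    seeds = ranked[:n_seeds]
    modules = []
    for i, s in enumerate(seeds):
        try:
            mod = greedy_module_search(wnet, s, min_size, max_size, tissue=tissue)
        except ModuleRejected as exc:
            logger.info("detect_modules: seed %r rejected (%s)", s, exc)
            continue
        p = module_significance(
            wnet, mod, B=B, seed=int(np.random.default_rng([seed, i]).integers(2**31)),
            min_size=min_size, max_size=max_size,
        )
        modules.append(replace(mod, p_mc=p))
    if not modules:
        return []
    q = bh_fdr(np.array([m.p_mc for m in modules]))
    modules = [replace(m, q=float(qc)) for m, qc in zip(modules, q)]
    surviving = [m for m in modules if m.q < q_threshold]
    if not surviving:
        return []
    # merge by connected components of the Jaccard-overlap graph
    n = len(surviving)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = surviving[i].members, surviving[j].members
            jac = len(a & b) / len(a | b)
            if jac > merge_jaccard:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    comps: dict[int, list[EpigeneticModule]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(surviving[i])
    merged = []
    for members_list in comps.values():
        if len(members_list) == 1:
            merged.append(members_list[0])
            continue
        best = max(members_list, key=lambda m: (m.score, m.seed_gene))
        union: set = set()
        for m in members_list:
            union |= m.members
        merged.append(
            EpigeneticModule(
                tissue=tissue,
                seed_gene=best.seed_gene,
                members=frozenset(union),
                score=wnet.induced_score(union),
                n_genes=len(union),
                p_mc=min(m.p_mc for m in members_list),
                q=min(m.q for m in members_list),
            )
        )
    merged.sort(key=lambda m: (-m.score, m.seed_gene))
    return merged


def shared_genes(modules_a, modules_b) -> set:
    """Genes common to the module memberships of two tissues."""
    union_a: set = set()
    for m in modules_a:
        union_a |= m.members
    union_b: set = set()
    for m in modules_b:
        union_b |= m.members
    return union_a & union_b


def modules_to_frame(modules) -> pd.DataFrame:
    rows = [
        {
            "tissue": m.tissue,
            "seed_gene": m.seed_gene,
            "n_genes": m.n_genes,
            "score": m.score,
            "p_mc": m.p_mc,
            "q": m.q,
            "members": ",".join(sorted(m.members)),
        }
        for m in modules
    ]
    return pd.DataFrame(
        rows, columns=["tissue", "seed_gene", "n_genes", "score", "p_mc", "q", "members"]
    )
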