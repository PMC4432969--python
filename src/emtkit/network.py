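"""Network-module detection from differential-expression p-values.

Node scoring follows the beta-uniform mixture (BUM) approach: the p-value
distribution is modelled as f(p) = lam + (1-lam) * a * p^(a-1) (uniform
nulls plus a Beta(a, 1) signal component), fitted by maximum likelihood.
Given a target FDR, the threshold tau is the largest p-value at which the
BUM-estimated FDR does not exceed it, and each gene scores
s(p) = (a - 1) * (ln p - ln tau): positive below tau, negative above.

The top-scoring connected subnetwork is found by a deterministic greedy
heuristic (contract positive components, connect them through
minimum-penalty paths while the net gain is positive, prune negative
leaves), with an exact enumeration oracle for small graphs.  Subnetworks
from two stimuli are merged on their union with per-node origin flags and
degrees computed on the merged graph.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
from scipy.optimize import brentq, minimize

from .io import InputError, NumericalError

__all__ = [
    "BumFit",
    "NodeScores",
    "Subnetwork",
    "MergedNetwork",
    "fit_bum",
    "bum_density",
    "score_nodes",
    "find_max_subnetwork",
    "exhaustive_max_subnetwork",
    "merge_networks",
]

P_CLAMP = 1e-300  # CuffDiff emits exact zeros; clamp before taking logs


# ---------------------------------------------------------------------------
# Beta-uniform mixture
# ---------------------------------------------------------------------------

@dataclass
class BumFit:
    """Fitted mixture f(p) = lam + (1-lam)*a*p^(a-1) on (0, 1]."""

    lam: float
    a: float
    log_likelihood: float
    n: int

    def density(self, p) -> np.ndarray:
        return bum_density(p, self.lam, self.a)

    def cdf(self, p) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        return self.lam * p + (1.0 - self.lam) * p ** self.a

    @property
    def pi_upper(self) -> float:
        """Density at p = 1: the uniform-floor estimate lam + (1-lam)*a."""
        return self.lam + (1.0 - self.lam) * self.a


def bum_density(p, lam: float, a: float) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    return lam + (1.0 - lam) * a * p ** (a - 1.0)


_START_GRID = tuple(itertools.product((0.1, 0.5, 0.9), (0.1, 0.3, 0.5, 0.7)))


def fit_bum(pvalues, eps: float = P_CLAMP) -> BumFit:
    """Maximum-likelihood BUM fit by bounded multi-start optimization.

    P-values of exactly zero are clamped to ``eps`` before log-likelihood
    evaluation.  The fit is deterministic given the fixed start grid.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise InputError("no p-values to fit")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise InputError("p-values must be finite and within [0, 1]")
    p = np.clip(p, eps, 1.0)
    if np.ptp(p) == 0.0:
        raise NumericalError("all p-values identical: degenerate BUM fit")
    logp = np.log(p)

    def nll(theta):
        lam, a = theta
        dens = lam + (1.0 - lam) * a * np.exp((a - 1.0) * logp)
        return -float(np.sum(np.log(np.maximum(dens, 1e-320))))

    bounds = ((1e-6, 1.0 - 1e-6), (1e-6, 1.0 - 1e-6))
    best = None
    for start in _START_GRID:
        res = minimize(nll, x0=start, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    lam, a = best.x
    return BumFit(lam=float(lam), a=float(a),
                  log_likelihood=-float(best.fun), n=int(p.size))


# ---------------------------------------------------------------------------
# Node scores
# ---------------------------------------------------------------------------

@dataclass
class NodeScores:
    """Per-gene scores s(p) = (a-1)*(ln p - ln tau); s(tau) = 0 and s is
    strictly decreasing in p for a < 1."""

    tau: float
    fdr_level: float
    a: float
    scores: dict = field(repr=False)

    def __getitem__(self, gene: str) -> float:
        return self.scores[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self.scores

    def items(self):
        return self.scores.items()


def _bum_fdr(fit: BumFit, t: float) -> float:
    """Estimated FDR when calling p <= t significant: uniform-floor mass
    over the mixture CDF."""
    return fit.pi_upper * t / float(fit.cdf(t))


def score_nodes(fit: BumFit, fdr_level: float,
                pvalues: Mapping[str, float],
                eps: float = P_CLAMP) -> NodeScores:
    """Score genes from a BUM fit at a target FDR.

    tau is the largest threshold whose BUM-estimated FDR does not exceed
    ``fdr_level``; genes without p-values are simply absent from the score
    map.
    """
    if not (0.0 < fdr_level < 1.0):
        raise InputError("fdr_level must lie in (0, 1)")
    lo = 1e-12
    if _bum_fdr(fit, lo) > fdr_level:
        raise NumericalError(
            f"no threshold achieves FDR {fdr_level}; increase fdr_level")
    if _bum_fdr(fit, 1.0) <= fdr_level:
        tau = 1.0
    else:
        tau = float(brentq(lambda t: _bum_fdr(fit, t) - fdr_level, lo, 1.0,
                           xtol=1e-15))
    ln_tau = math.log(tau)
    scores = {gene: (fit.a - 1.0) * (math.log(max(float(p), eps)) - ln_tau)
              for gene, p in pvalues.items()}
    return NodeScores(tau=tau, fdr_level=fdr_level, a=fit.a, scores=scores)


# ---------------------------------------------------------------------------
# Subnetwork search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Subnetwork:
    """A connected node set and its exact summed score."""

    nodes: tuple
    total_score: float
    connected: bool = True

    def __len__(self):
        return len(self.nodes)


def _score_map(scores) -> dict:
    return dict(scores.items()) if hasattr(scores, "items") else dict(scores)


def _make_subnetwork(nodes, smap) -> Subnetwork:
    nodes = tuple(sorted(nodes))
    return Subnetwork(nodes=nodes,
                      total_score=float(sum(smap[v] for v in nodes)))


def find_max_subnetwork(network: nx.Graph, scores) -> Subnetwork:
    """Greedy approximate maximum-score connected subgraph.

    Restricted to scored nodes, the heuristic (i) contracts each maximal
    connected component of positive-score nodes into a super-node with the
    summed score, (ii) greedily connects super-nodes through
    minimum-penalty paths (path cost = the summed negated negative scores
    along it), accepting a connection only when the net gain is positive,
    and (iii) prunes degree-1 negative-score nodes while the total score
    improves.  The result always scores at least as well as the best single
    node.  Deterministic: components are processed in (score desc, node
    asc) order and all ties break lexicographically.
    """
    smap = _score_map(scores)
    if network.number_of_nodes() == 0:
        raise InputError("empty network")
    graph = network.subgraph([v for v in network.nodes if v in smap])
    if graph.number_of_nodes() == 0:
        raise InputError("no network node carries a score")

    positive = [v for v in graph.nodes if smap[v] > 0]
    if not positive:
        best = min(graph.nodes, key=lambda v: (-smap[v], v))
        return _make_subnetwork([best], smap)

    if nx.is_forest(graph):
        # exact linear-time dynamic program; the greedy is only needed on
        # graphs with cycles
        return _tree_max_subnetwork(graph, smap)

    comps = [frozenset(c)
             for c in nx.connected_components(graph.subgraph(positive))]
    comp_score = {c: sum(smap[v] for v in c) for c in comps}
    comps.sort(key=lambda c: (-comp_score[c], min(c)))

    current = set(comps[0])
    remaining = [c for c in comps[1:]]
    penalty = {v: max(0.0, -smap[v]) for v in graph.nodes}

    def edge_cost(u, v, d):
        return 0.0 if v in current else penalty[v]

    while remaining:
        dist, paths = nx.multi_source_dijkstra(graph, sources=set(current),
                                               weight=edge_cost)
        best_choice = None  # (net gain, min node, comp, path nodes)
        for comp in remaining:
            entry = min((v for v in comp if v in dist),
                        key=lambda v: (dist[v], v), default=None)
            if entry is None:
                continue
            cost = dist[entry]
            gain = comp_score[comp] - cost
            key = (-gain, min(comp))
            if best_choice is None or key < best_choice[0]:
                best_choice = (key, comp, paths[entry])
        if best_choice is None or -best_choice[0][0] <= 0:
            break
        _, comp, path = best_choice
        current |= set(path) | set(comp)
        remaining = [c for c in remaining if not c <= current]

    # prune negative-score leaves of the induced subgraph
    changed = True
    while changed and len(current) > 1:
        changed = False
        sub = graph.subgraph(current)
        for v in sorted(current):
            if smap[v] < 0 and sub.degree(v) <= 1 and len(current) > 1:
                current.remove(v)
                changed = True
                sub = graph.subgraph(current)
    return _make_subnetwork(current, smap)


def _tree_max_subnetwork(graph: nx.Graph, smap: dict) -> Subnetwork:
    """Exact maximum-score connected subgraph of a forest.

    Rooting each tree, dp[v] = w(v) + sum over children of max(0, dp[c]);
    every connected subgraph has a unique highest node, so the optimum is
    max_v dp[v], recovered by descending into children with dp > 0.
    """
    dp = {}
    children = {}
    for comp in nx.connected_components(graph):
        root = min(comp)
        order = list(nx.dfs_postorder_nodes(graph, root))
        parent = nx.dfs_predecessors(graph, root)
        for v in order:
            kids = [u for u in graph.neighbors(v) if parent.get(u) == v]
            children[v] = kids
            dp[v] = smap[v] + sum(max(0.0, dp[u]) for u in kids)
    best = min(dp, key=lambda v: (-dp[v], v))
    nodes = []
    stack = [best]
    while stack:
        v = stack.pop()
        nodes.append(v)
        stack.extend(u for u in children[v] if dp[u] > 0)
    return _make_subnetwork(nodes, smap)


def exhaustive_max_subnetwork(network: nx.Graph, scores,
                              max_nodes: int = 15) -> Subnetwork:
    """Exact optimum by enumeration of all connected node subsets.

    Test oracle for the greedy heuristic; refuses graphs above
    ``max_nodes``.  Ties break by higher score, then smaller subset, then
    lexicographically smallest sorted node tuple.
    """
    smap = _score_map(scores)
    nodes = sorted(v for v in network.nodes if v in smap)
    if not nodes:
        raise InputError("no network node carries a score")
    if len(nodes) > max_nodes:
        raise InputError(f"exhaustive search limited to {max_nodes} nodes")
    idx = {v: i for i, v in enumerate(nodes)}
    adj = [0] * len(nodes)
    sub = network.subgraph(nodes)
    for u, v in sub.edges:
        adj[idx[u]] |= 1 << idx[v]
        adj[idx[v]] |= 1 << idx[u]

    def connected(mask: int) -> bool:
        start = mask & -mask
        seen = start
        frontier = start
        while frontier:
            nxt = 0
            m = frontier
            while m:
                low = m & -m
                nxt |= adj[low.bit_length() - 1]
                m ^= low
            frontier = nxt & mask & ~seen
            seen |= frontier
        return seen == mask

    best = None  # (-score, size, tuple)
    for mask in range(1, 1 << len(nodes)):
        if not connected(mask):
            continue
        members = [nodes[i] for i in range(len(nodes)) if mask >> i & 1]
        score = sum(smap[v] for v in members)
        key = (-score, len(members), tuple(members))
        if best is None or key < best:
            best = key
    return Subnetwork(nodes=best[2], total_score=-best[0])


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

@dataclass
class MergedNetwork:
    """Union of two stimulus subnetworks with parent-induced edges.

    ``origin`` maps each node to the stimulus label(s) it came from
    (``label_a``, ``label_b`` or ``"both"``); ``degree`` counts neighbours
    in the merged graph.
    """

    graph: nx.Graph
    origin: dict
    degree: dict

    @property
    def nodes(self):
        return self.graph.nodes


def merge_networks(sub_a: Subnetwork, sub_b: Subnetwork, parent: nx.Graph,
                   label_a: str = "EGF", label_b: str = "HPX"
                   ) -> MergedNetwork:
    """Merge two subnetworks on their node union with parent-induced edges."""
    set_a, set_b = set(sub_a.nodes), set(sub_b.nodes)
    stray = (set_a | set_b) - set(parent.nodes)
    if stray:
        raise InputError(f"nodes not in parent network: {sorted(stray)[:5]}")
    union = set_a | set_b
    graph = parent.subgraph(union).copy()
    origin = {}
    for v in union:
        if v in set_a and v in set_b:
            origin[v] = "both"
        elif v in set_a:
            origin[v] = label_a
        else:
            origin[v] = label_b
    nx.set_node_attributes(graph, origin, "origin")
    degree = {v: int(graph.degree(v)) for v in graph.nodes}
    return MergedNetwork(graph=graph, origin=origin, degree=degree)
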