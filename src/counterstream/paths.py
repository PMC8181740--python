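"""Shortest paths, edge betweenness, convergence degree and the relaxed
weighted-path parameter optimisation.

The convergence degree (CD) of a directed edge summarises whether the
shortest-path traffic through it funnels information from many origins into
few targets (convergent, CD > 0) or spreads it from few origins to many
targets (divergent, CD < 0):

    CD(i, j) = (|In(i, j)| - |Out(i, j)|) / |In(i, j) u Out(i, j)|

where In/Out are the sets of origins/termini of all retained shortest paths
traversing the edge.  On binary graphs the retained set is *all*
minimum-hop paths.  On weighted connectomes a relaxed scheme is used: the
cost of traversing an edge is (dist / FLN) ** alpha — distance raises the
cost, anatomical strength lowers it, and the exponent alpha trades the
influence of the weights against the number of hops (alpha = 0 recovers
binary hop counting) — and the k cheapest loopless paths are retained per
ordered pair instead of a single winner, restoring the tied-path structure
that makes CD informative on real-valued costs.

Edge betweenness (EB) on a retained path set generalises the classic
definition: each ordered pair contributes, per edge, the fraction of its
retained paths that traverse the edge.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .connectome import BinaryNetwork, WeightedConnectome

__all__ = [
    "PathSet",
    "EdgeMetrics",
    "NodeCDProfile",
    "binary_shortest_paths",
    "relaxed_weighted_paths",
    "truncate_paths",
    "edge_betweenness",
    "convergence_degree",
    "edge_metrics",
    "node_reduced_cd",
    "optimize_alpha",
    "optimize_k",
]

#: relative tolerance for detecting cost ties between floating-point paths
COST_TIE_RTOL = 1e-9


@dataclass
class PathSet:
    """Retained shortest paths per ordered node pair.

    ``paths[(s, t)]`` is a list of ``(node_index_tuple, cost)`` entries in
    non-decreasing cost order; unreachable pairs are absent (treated as an
    empty list).  ``mode`` is ``"binary"`` or ``"weighted"``.
    """

    nodes: list[str]
    paths: dict[tuple[int, int], list[tuple[tuple[int, ...], float]]]
    mode: str = "binary"
    alpha: float | None = None
    k: int | None = None

    def pair(self, s, t):
        """Paths for an ordered pair given as labels or indices."""
        if isinstance(s, str):
            s = self.nodes.index(s)
        if isinstance(t, str):
            t = self.nodes.index(t)
        return self.paths.get((s, t), [])

    def n_paths(self) -> int:
        return sum(len(v) for v in self.paths.values())

    def to_records(self) -> pd.DataFrame:
        rows = []
        for (s, t), plist in sorted(self.paths.items()):
            for nodes_seq, cost in plist:
                rows.append(
                    {
                        "source": self.nodes[s],
                        "target": self.nodes[t],
                        "path": "->".join(self.nodes[i] for i in nodes_seq),
                        "cost": cost,
                    }
                )
        return pd.DataFrame(rows)


def _adjacency_lists(A: np.ndarray):
    return [np.nonzero(A[i])[0].tolist() for i in range(A.shape[0])]


def binary_shortest_paths(net: BinaryNetwork) -> PathSet:
    """Enumerate all minimum-hop paths for every ordered pair.

    A BFS from each source yields distances and the shortest-path
    predecessor DAG; paths are read off the DAG in lexicographic node-index
    order.  Unreachable pairs carry no entry (disconnection is represented,
    not an error).
    """
    A = net.adjacency
    n = net.n
    succ = _adjacency_lists(A)
    paths: dict[tuple[int, int], list[tuple[tuple[int, ...], float]]] = {}
    for s in range(n):
        dist = np.full(n, -1)
        dist[s] = 0
        preds: list[list[int]] = [[] for _ in range(n)]
        q = deque([s])
        while q:
            u = q.popleft()
            for v in succ[u]:
                if dist[v] == -1:
                    dist[v] = dist[u] + 1
                    preds[v] = [u]
                    q.append(v)
                elif dist[v] == dist[u] + 1:
                    preds[v].append(u)
        for t in range(n):
            if t == s or dist[t] == -1:
                continue
            # backtrack the predecessor DAG
            out: list[tuple[int, ...]] = []
            stack = [(t, (t,))]
            while stack:
                u, suffix = stack.pop()
                if u == s:
                    out.append(suffix)
                    continue
                for p in preds[u]:
                    stack.append((p, (p,) + suffix))
            out.sort()
            paths[(s, t)] = [(p, float(dist[t])) for p in out]
    return PathSet(list(net.nodes), paths, mode="binary")


def _edge_costs(net: WeightedConnectome, alpha: float) -> np.ndarray:
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    with np.errstate(invalid="ignore"):
        base = net.dist / net.fln
    return np.where(net.mask, base**alpha, np.nan)


def relaxed_weighted_paths(
    net: WeightedConnectome, alpha: float, k: int = 1
) -> PathSet:
    """k cheapest loopless paths per ordered pair under cost (dist/FLN)**alpha.

    Paths are found with Yen's algorithm (via networkx
    ``shortest_simple_paths``); cost ties at the k-th rank are broken by
    lexicographic node-sequence order so the output is deterministic.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    cost = _edge_costs(net, alpha)
    G = nx.DiGraph()
    G.add_nodes_from(range(net.n))
    for i, j in zip(*np.nonzero(net.mask)):
        G.add_edge(int(i), int(j), cost=float(cost[i, j]))
    paths: dict[tuple[int, int], list[tuple[tuple[int, ...], float]]] = {}
    for s in range(net.n):
        reach = nx.single_source_dijkstra_path_length(G, s, weight="cost")
        for t in range(net.n):
            if t == s or t not in reach:
                continue
            cand: list[tuple[float, tuple[int, ...]]] = []
            kth_cost = None
            for p in nx.shortest_simple_paths(G, s, t, weight="cost"):
                c = sum(G[u][v]["cost"] for u, v in zip(p, p[1:]))
                if kth_cost is not None and c > kth_cost * (1 + COST_TIE_RTOL) + 1e-300:
                    break
                cand.append((c, tuple(p)))
                if len(cand) >= k and kth_cost is None:
                    kth_cost = sorted(x[0] for x in cand)[k - 1]
            paths[(s, t)] = _select_k(cand, k)
    return PathSet(list(net.nodes), paths, mode="weighted", alpha=alpha, k=k)


def _select_k(cand, k):
    """Keep the k cheapest candidates, breaking rank-k ties lexicographically."""
    cand = sorted(cand, key=lambda x: x[0])
    if len(cand) > k:
        kth = cand[k - 1][0]
        tol = COST_TIE_RTOL * max(abs(kth), 1.0)
        below = [x for x in cand if x[0] < kth - tol]
        tied = sorted(
            (x for x in cand if abs(x[0] - kth) <= tol), key=lambda x: x[1]
        )
        cand = below + tied[: k - len(below)]
    return [(p, c) for c, p in cand]


def truncate_paths(ps: PathSet, k: int) -> PathSet:
    """Restrict a weighted PathSet to its k cheapest paths per pair.

    Valid because edge costs do not depend on k: the k-path set is a prefix
    of any k'-path set with k' >= k (up to the deterministic tie-break).
    """
    if ps.mode != "weighted":
        raise ValueError("truncate_paths applies to weighted path sets")
    out = {}
    for key, plist in ps.paths.items():
        cand = [(c, p) for p, c in plist]
        out[key] = _select_k(cand, k)
    return PathSet(list(ps.nodes), out, mode="weighted", alpha=ps.alpha, k=k)


@dataclass
class EdgeMetrics:
    """Per-edge metrics on a retained path structure.

    ``table`` has one row per existing edge with columns source, target,
    eb, eb_nontrivial (the pair's own one-edge path excluded), cd,
    in_set_size, out_set_size.
    """

    nodes: list[str]
    table: pd.DataFrame

    def matrix(self, column: str) -> np.ndarray:
        n = len(self.nodes)
        idx = {v: i for i, v in enumerate(self.nodes)}
        M = np.full((n, n), np.nan)
        for _, r in self.table.iterrows():
            M[idx[r["source"]], idx[r["target"]]] = r[column]
        return M


def _edge_list(net) -> list[tuple[int, int]]:
    if isinstance(net, BinaryNetwork):
        return [(int(i), int(j)) for i, j in zip(*np.nonzero(net.adjacency))]
    return [(int(i), int(j)) for i, j in zip(*np.nonzero(net.mask))]


def edge_metrics(paths: PathSet, net) -> EdgeMetrics:
    """Edge betweenness and convergence degree from a retained path set.

    EB(e) = sum over ordered pairs of (retained paths through e) /
    (retained paths of the pair); pairs with no path contribute 0.
    CD follows the In/Out-set definition; an edge traversed by no retained
    path other than (possibly) its own one-edge path has In = {i},
    Out = {j} and CD = 0.
    """
    edges = _edge_list(net)
    eb = {e: 0.0 for e in edges}
    ebn = {e: 0.0 for e in edges}
    ins = {e: set() for e in edges}
    outs = {e: set() for e in edges}
    for (s, t), plist in paths.paths.items():
        if not plist:
            continue
        frac = 1.0 / len(plist)
        for node_seq, _cost in plist:
            trivial = len(node_seq) == 2
            for u, v in zip(node_seq, node_seq[1:]):
                e = (u, v)
                eb[e] += frac
                if not trivial:
                    ebn[e] += frac
                ins[e].add(s)
                outs[e].add(t)
    rows = []
    for (i, j) in edges:
        I, O = ins[(i, j)], outs[(i, j)]
        if not I:  # edge unused by any retained path
            I, O = {i}, {j}
        cd = (len(I) - len(O)) / len(I | O)
        rows.append(
            {
                "source": paths.nodes[i],
                "target": paths.nodes[j],
                "eb": eb[(i, j)],
                "eb_nontrivial": ebn[(i, j)],
                "cd": cd,
                "in_set_size": len(I),
                "out_set_size": len(O),
            }
        )
    return EdgeMetrics(list(paths.nodes), pd.DataFrame(rows))


def edge_betweenness(paths: PathSet, net) -> EdgeMetrics:
    return edge_metrics(paths, net)


def convergence_degree(paths: PathSet, net) -> EdgeMetrics:
    return edge_metrics(paths, net)


@dataclass
class NodeCDProfile:
    """Node-reduced CD sums (each normalised by n - 1) and CD-flow."""

    table: pd.DataFrame  # node, nrcd_in_plus, nrcd_in_minus, nrcd_out_plus,
    #                      nrcd_out_minus, cd_flow


def node_reduced_cd(metrics: EdgeMetrics, net) -> NodeCDProfile:
    """Reduce edge CDs to four signed per-node sums and the CD-flow.

    The CD-flow of a node, Phi(i) = mean CD of outgoing edges minus mean CD
    of incoming edges, is a topological hierarchy index: source-like areas
    (convergent input, divergent output) sit at the bottom, allocating areas
    at the top.  Nodes with no in- or out-edges contribute 0 to the
    corresponding mean.
    """
    n = len(metrics.nodes)
    cd = metrics.matrix("cd")
    rows = []
    for i, node in enumerate(metrics.nodes):
        inc = cd[:, i][np.isfinite(cd[:, i])]
        out = cd[i, :][np.isfinite(cd[i, :])]
        rows.append(
            {
                "node": node,
                "nrcd_in_plus": inc[inc > 0].sum() / (n - 1),
                "nrcd_in_minus": inc[inc < 0].sum() / (n - 1),
                "nrcd_out_plus": out[out > 0].sum() / (n - 1),
                "nrcd_out_minus": out[out < 0].sum() / (n - 1),
                "cd_flow": (out.mean() if out.size else 0.0)
                - (inc.mean() if inc.size else 0.0),
            }
        )
    return NodeCDProfile(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# alpha / k joint optimisation
# ---------------------------------------------------------------------------


def optimize_alpha(
    net: WeightedConnectome,
    alpha_grid,
    k: int = 1,
    count_trivial: bool = False,
    zero_tol: int = 0,
    max_eb_rtol: float = 0.05,
):
    """Pick alpha: largest grid value on the joint-minimum plateau of the
    number of unused edges and the maximum EB.

    An edge is "unused" when no retained path of any pair other than its
    own endpoints traverses it (``count_trivial=True`` instead counts plain
    EB == 0).  The plateau is the set of grid points whose unused-edge count
    is within ``zero_tol`` of the grid minimum and whose max EB is within a
    relative ``max_eb_rtol`` of the grid minimum; among those the largest
    alpha is returned, keeping the influence of the empirical weights as
    high as possible.
    """
    alpha_grid = list(alpha_grid)
    if not alpha_grid:
        raise ValueError("alpha grid is empty")
    if sorted(alpha_grid) != alpha_grid:
        raise ValueError("alpha grid must be sorted ascending")
    rows = []
    for a in alpha_grid:
        em = edge_metrics(relaxed_weighted_paths(net, a, k), net)
        col = "eb" if count_trivial else "eb_nontrivial"
        rows.append(
            {
                "alpha": a,
                "n_zero_eb": int((em.table[col] == 0).sum()),
                "max_eb": float(em.table["eb"].max()),
            }
        )
    diag = pd.DataFrame(rows)
    zmin = diag["n_zero_eb"].min()
    mmin = diag["max_eb"].min()
    on_plateau = (diag["n_zero_eb"] <= zmin + zero_tol) & (
        diag["max_eb"] <= mmin * (1 + max_eb_rtol)
    )
    chosen = float(diag.loc[on_plateau, "alpha"].max())
    return chosen, diag


def optimize_k(net: WeightedConnectome, alpha: float, k_grid):
    """Pick k: joint minimum of EB-distribution excess kurtosis and the
    number of zero-CD edges, each min-max normalised over the grid."""
    k_grid = sorted(int(k) for k in k_grid)
    if not k_grid or k_grid[0] < 1:
        raise ValueError("k grid must contain positive integers")
    full = relaxed_weighted_paths(net, alpha, max(k_grid))
    rows = []
    for k in k_grid:
        em = edge_metrics(truncate_paths(full, k), net)
        with np.errstate(invalid="ignore"):
            kurt = float(stats.kurtosis(em.table["eb"], fisher=True, bias=True))
        rows.append(
            {
                "k": k,
                # a degenerate (constant) EB distribution carries no signal
                "eb_kurtosis": kurt if np.isfinite(kurt) else 0.0,
                "n_zero_cd": int((em.table["cd"] == 0).sum()),
            }
        )
    diag = pd.DataFrame(rows)

    def _norm(x):
        x = np.asarray(x, dtype=float)
        rng = x.max() - x.min()
        return np.zeros_like(x) if rng == 0 else (x - x.min()) / rng

    score = _norm(diag["eb_kurtosis"]) + _norm(diag["n_zero_cd"])
    diag["score"] = score
    chosen = int(diag.loc[int(np.argmin(score)), "k"])
    return chosen, diag
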