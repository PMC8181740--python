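"""Independent brute-force oracles for small graphs.

Everything here enumerates exhaustively and is written without reference
to the package's path machinery, so it can arbitrate correctness on
digraphs small enough for a full path census.
"""

from itertools import permutations

import numpy as np


def all_simple_paths(A: np.ndarray):
    """Every loopless directed path, grouped per ordered (s, t) pair."""
    n = A.shape[0]
    out = {}
    for s in range(n):
        stack = [(s, (s,))]
        while stack:
            u, path = stack.pop()
            for v in range(n):
                if A[u, v] and v not in path:
                    newp = path + (v,)
                    out.setdefault((s, v), []).append(newp)
                    stack.append((v, newp))
    return out


def min_hop_paths(A: np.ndarray):
    """All minimum-hop paths per ordered pair."""
    allp = all_simple_paths(A)
    out = {}
    for pair, plist in allp.items():
        d = min(len(p) for p in plist)
        out[pair] = sorted(p for p in plist if len(p) == d)
    return out


def k_cheapest_paths(A: np.ndarray, cost: np.ndarray, k: int, rtol=1e-9):
    """k lowest-cost loopless paths per pair; rank-k ties broken by
    lexicographic node order."""
    allp = all_simple_paths(A)
    out = {}
    for pair, plist in allp.items():
        scored = sorted(
            (sum(cost[u, v] for u, v in zip(p, p[1:])), p) for p in plist
        )
        if len(scored) > k:
            kth = scored[k - 1][0]
            tol = rtol * max(abs(kth), 1.0)
            below = [x for x in scored if x[0] < kth - tol]
            tied = sorted(
                (x for x in scored if abs(x[0] - kth) <= tol), key=lambda x: x[1]
            )
            scored = below + tied[: k - len(below)]
        out[pair] = [(p, c) for c, p in scored]
    return out


def eb_cd_bruteforce(paths: dict, edges):
    """EB and CD per edge from an explicit retained-path census.

    ``paths`` maps (s, t) -> list of node tuples.  Returns dicts
    edge -> eb and edge -> cd.
    """
    eb = {e: 0.0 for e in edges}
    ins = {e: set() for e in edges}
    outs = {e: set() for e in edges}
    for (s, t), plist in paths.items():
        if not plist:
            continue
        for p in plist:
            for e in zip(p, p[1:]):
                eb[e] += 1.0 / len(plist)
                ins[e].add(s)
                outs[e].add(t)
    cd = {}
    for e in edges:
        I, O = ins[e], outs[e]
        if not I:
            I, O = {e[0]}, {e[1]}
        cd[e] = (len(I) - len(O)) / len(I | O)
    return eb, cd


def random_digraph(n: int, p: float, rng) -> np.ndarray:
    A = rng.random((n, n)) < p
    np.fill_diagonal(A, False)
    return A
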