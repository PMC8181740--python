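"""Targeted and random edge-removal experiments.

Edges are deleted one at a time according to a strategy — descending edge
betweenness (EB), descending CD (maxCD, convergent edges first), ascending
CD (minCD, divergent edges first), descending |CD| (absCD) or uniformly at
random — and after every removal all edge measures are recomputed on the
current graph before the next edge is chosen.  A full summary snapshot of
the post-removal graph is recorded at each step, so trajectories of
transitivity, strong connectedness, ASP, diameter and the Laplacian
spectral measures can be compared across strategies and against randomized
control ensembles (Erdos-Renyi matched on n and m, or degree-preserving
rewirings of the reference network).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectome import BinaryNetwork
from .metrics import summarize
from .paths import binary_shortest_paths, edge_metrics
from .synth import generate_binary

__all__ = [
    "RemovalTrajectory",
    "ControlEnsemble",
    "remove_edges",
    "make_controls",
    "trajectory_ensemble",
]

STRATEGIES = ("maxCD", "minCD", "absCD", "EB", "random")

_METRIC_COLS = [
    "transitivity",
    "n_scc",
    "asp",
    "diameter",
    "lambda2",
    "lambda_max",
    "eigenratio",
]


@dataclass
class RemovalTrajectory:
    strategy: str
    removed: list[tuple[str, str]]
    table: pd.DataFrame  # one row per step: step, source, target, metrics


def _rank_edges(net: BinaryNetwork, strategy: str):
    """Edges best-first under the strategy; ties lexicographic by labels."""
    ps = binary_shortest_paths(net)
    em = edge_metrics(ps, net).table
    if strategy == "EB":
        key = -em["eb"]
    elif strategy == "maxCD":
        key = -em["cd"]
    elif strategy == "minCD":
        key = em["cd"]
    elif strategy == "absCD":
        key = -em["cd"].abs()
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    order = em.assign(_key=key).sort_values(
        ["_key", "source", "target"], kind="mergesort"
    )
    return list(zip(order["source"], order["target"]))


def remove_edges(
    net: BinaryNetwork,
    strategy: str,
    n_steps: int | None = None,
    recompute: bool = True,
    seed: int = 0,
    convention: str = "directed",
) -> RemovalTrajectory:
    """Attack ``n_steps`` edges (default: all) and snapshot the graph after
    each removal.

    With ``recompute=True`` (the reference semantics) the criterion is
    re-evaluated on the current graph before every deletion; with
    ``recompute=False`` the initial ranking is fixed and consumed in order.
    The ``random`` strategy is reproducible from ``seed``.  ``convention``
    selects the Laplacian flavour for the spectral snapshot metrics; the
    symmetric ``"mean"`` convention guarantees a monotone lambda2 decay,
    the ``"directed"`` default does not.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"strategy must be one of {STRATEGIES}")
    if n_steps is None:
        n_steps = net.m
    if n_steps > net.m:
        raise ValueError(f"n_steps={n_steps} exceeds edge count {net.m}")
    rng = np.random.default_rng(seed)
    cur = net.copy()
    idx = {v: i for i, v in enumerate(cur.nodes)}
    fixed_order = None
    if strategy == "random":
        edges = cur.edges()
        fixed_order = [edges[i] for i in rng.permutation(len(edges))]
    elif not recompute:
        fixed_order = _rank_edges(cur, strategy)
    removed = []
    rows = []
    for step in range(n_steps):
        if fixed_order is not None:
            u, v = fixed_order[step]
        else:
            u, v = _rank_edges(cur, strategy)[0]
        cur.adjacency[idx[u], idx[v]] = False
        removed.append((u, v))
        if cur.m > 0:
            snap = summarize(cur, convention).as_dict()
        else:
            snap = {c: np.nan for c in _METRIC_COLS}
            snap["n_scc"] = cur.n
        rows.append({"step": step + 1, "source": u, "target": v, **{
            c: snap[c] for c in _METRIC_COLS}})
    return RemovalTrajectory(strategy, removed, pd.DataFrame(rows))


@dataclass
class ControlEnsemble:
    kind: str  # "er" | "rewired"
    instances: list[BinaryNetwork]

    @property
    def n_instances(self) -> int:
        return len(self.instances)


def _rewire(net: BinaryNetwork, rng) -> BinaryNetwork:
    """Degree-preserving randomization by directed double-edge swaps.

    Swapping (u, v), (x, y) -> (u, y), (x, v) preserves every in- and
    out-degree; swaps creating self-loops or duplicate edges are rejected.
    10 * m swap attempts are made.
    """
    A = net.adjacency.copy()
    edges = list(zip(*np.nonzero(A)))
    attempts = 10 * len(edges)
    for _ in range(attempts):
        a, b = rng.integers(0, len(edges), size=2)
        if a == b:
            continue
        (u, v), (x, y) = edges[a], edges[b]
        if u == y or x == v or A[u, y] or A[x, v]:
            continue
        A[u, v] = A[x, y] = False
        A[u, y] = A[x, v] = True
        edges[a], edges[b] = (u, y), (x, v)
    return BinaryNetwork(list(net.nodes), A)


def make_controls(
    net: BinaryNetwork, kind: str, n_instances: int = 30, seed: int = 0
) -> ControlEnsemble:
    """Randomized control networks: ``er`` shares n and m with the
    reference, ``rewired`` shares its exact in- and out-degree sequences."""
    rng = np.random.default_rng(seed)
    instances = []
    for i in range(n_instances):
        if kind == "er":
            instances.append(
                generate_binary(net.n, net.m, seed=int(rng.integers(2**31)))
            )
        elif kind == "rewired":
            instances.append(_rewire(net, rng))
        else:
            raise ValueError(f"unknown control kind {kind!r}")
    return ControlEnsemble(kind, instances)


def trajectory_ensemble(
    ensemble: ControlEnsemble, strategy: str, n_steps: int, seed: int = 0,
    convention: str = "directed",
) -> pd.DataFrame:
    """Per-step mean and standard deviation of every snapshot metric across
    the ensemble instances."""
    rng = np.random.default_rng(seed)
    tables = []
    for inst in ensemble.instances:
        if n_steps > inst.m:
            raise ValueError("n_steps exceeds an instance's edge count")
        traj = remove_edges(
            inst, strategy, n_steps, seed=int(rng.integers(2**31)),
            convention=convention,
        )
        tables.append(traj.table[_METRIC_COLS])
    stack = np.stack([t.to_numpy(dtype=float) for t in tables])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=0)
    out = {"step": np.arange(1, n_steps + 1)}
    for j, c in enumerate(_METRIC_COLS):
        out[f"{c}_mean"] = mean[:, j]
        out[f"{c}_sd"] = sd[:, j]
    return pd.DataFrame(out)
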