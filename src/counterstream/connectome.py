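"""Domain types, validation and I/O for directed cortical connectomes.

Two graph flavours are used throughout the package:

* :class:`BinaryNetwork` — a directed, unweighted graph of cortical areas
  (e.g. a 44-area visuo-tactile network), stored as a boolean adjacency
  matrix whose entry ``(i, j)`` is True iff the projection ``i -> j`` exists.
* :class:`WeightedConnectome` — a directed graph carrying three per-edge
  attributes from retrograde tract tracing: FLN (fraction of labelled
  neurons, the anatomical weight, normalised per injected target area),
  SLN (fraction of supragranular labelled neurons, the laminar hierarchy
  index, 1 = pure feedforward, 0 = pure feedback) and the projection
  distance in millimetres.

Absent edges are represented by a structural mask, never by zero-valued
weights: an observed projection always has FLN > 0, so FLN == 0 in an input
matrix is read as "no edge".  Node order is the file's row order; matrices
are indexed 0-based internally and external reports use area labels only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BinaryNetwork",
    "WeightedConnectome",
    "ConnectomeError",
    "load_binary",
    "save_binary",
    "load_weighted",
    "save_weighted",
    "to_edge_table",
    "from_edge_table",
    "extract_subgraph",
]


class ConnectomeError(ValueError):
    """Raised on malformed or inconsistent connectome data."""


def _check_labels(nodes):
    nodes = [str(a) for a in nodes]
    if len(set(nodes)) != len(nodes):
        raise ConnectomeError("node labels must be unique")
    return nodes


@dataclass
class BinaryNetwork:
    """Node-labelled directed unweighted graph without self-loops."""

    nodes: list[str]
    adjacency: np.ndarray

    def __post_init__(self):
        self.nodes = _check_labels(self.nodes)
        A = np.asarray(self.adjacency)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ConnectomeError(f"adjacency must be square, got shape {A.shape}")
        if A.shape[0] != len(self.nodes):
            raise ConnectomeError("adjacency side must equal number of node labels")
        if A.dtype != bool:
            vals = np.unique(A)
            if not np.all(np.isin(vals, [0, 1])):
                raise ConnectomeError("binary adjacency entries must be 0 or 1")
            A = A.astype(bool)
        if A.diagonal().any():
            raise ConnectomeError("self-loops are not allowed (nonzero diagonal)")
        self.adjacency = A

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def m(self) -> int:
        """Number of directed edges."""
        return int(self.adjacency.sum())

    def edges(self) -> list[tuple[str, str]]:
        i, j = np.nonzero(self.adjacency)
        return [(self.nodes[a], self.nodes[b]) for a, b in zip(i, j)]

    def to_networkx(self):
        import networkx as nx

        G = nx.DiGraph()
        G.add_nodes_from(self.nodes)
        G.add_edges_from(self.edges())
        return G

    @classmethod
    def from_networkx(cls, G) -> "BinaryNetwork":
        nodes = [str(v) for v in G.nodes()]
        idx = {v: i for i, v in enumerate(nodes)}
        A = np.zeros((len(nodes), len(nodes)), dtype=bool)
        for u, v in G.edges():
            A[idx[str(u)], idx[str(v)]] = True
        return cls(nodes, A)

    def copy(self) -> "BinaryNetwork":
        return BinaryNetwork(list(self.nodes), self.adjacency.copy())


@dataclass
class WeightedConnectome:
    """Directed graph with per-edge FLN, SLN and distance (mm).

    The three attribute matrices share one edge-existence ``mask``; entries
    off the mask are NaN.  Optional ``supra``/``infra`` labelled-neuron
    counts, when present, must reproduce SLN = supra / (supra + infra).
    """

    nodes: list[str]
    fln: np.ndarray
    sln: np.ndarray
    dist: np.ndarray
    supra: np.ndarray | None = None
    infra: np.ndarray | None = None
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.nodes = _check_labels(self.nodes)
        n = len(self.nodes)
        mats = {"fln": self.fln, "sln": self.sln, "dist": self.dist}
        for name, M in mats.items():
            M = np.asarray(M, dtype=float)
            if M.shape != (n, n):
                raise ConnectomeError(f"{name} matrix must be {n}x{n}, got {M.shape}")
            setattr(self, name, M)
        if self.mask is None:
            self.mask = np.isfinite(self.fln) & (self.fln > 0)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.diagonal().any():
            raise ConnectomeError("self-loops are not allowed")
        for name in ("fln", "sln", "dist"):
            M = getattr(self, name)
            defined = np.isfinite(M) & ~np.eye(n, dtype=bool) if name != "fln" else (
                np.isfinite(M) & (M != 0)
            )
            # attribute defined exactly on the mask
            if name == "fln":
                if not np.array_equal(defined, self.mask):
                    raise ConnectomeError("FLN defined off the edge mask (or missing on it)")
            else:
                if not np.array_equal(np.isfinite(M) & self.mask, self.mask) or np.any(
                    np.isfinite(M) & ~self.mask & ~np.isnan(M)
                ):
                    raise ConnectomeError(f"{name} mask differs from the FLN edge mask")
            out = np.where(self.mask, M, np.nan)
            setattr(self, name, out)
        if np.any(self.fln[self.mask] <= 0):
            raise ConnectomeError("FLN must be > 0 on every edge")
        s = self.sln[self.mask]
        if np.any((s < 0) | (s > 1)):
            raise ConnectomeError("SLN must lie in [0, 1]")
        if np.any(self.dist[self.mask] <= 0):
            raise ConnectomeError("distances must be positive")
        if (self.supra is None) != (self.infra is None):
            raise ConnectomeError("supra and infra counts must be given together")
        if self.supra is not None:
            self.supra = np.where(self.mask, np.asarray(self.supra, float), np.nan)
            self.infra = np.where(self.mask, np.asarray(self.infra, float), np.nan)
            tot = self.supra + self.infra
            ok = np.abs(self.sln[self.mask] - (self.supra / tot)[self.mask]) <= 1e-9
            if not np.all(ok):
                raise ConnectomeError("SLN inconsistent with supra/(supra+infra) counts")

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def m(self) -> int:
        return int(self.mask.sum())

    def edges(self) -> list[tuple[str, str]]:
        i, j = np.nonzero(self.mask)
        return [(self.nodes[a], self.nodes[b]) for a, b in zip(i, j)]

    def binary(self) -> BinaryNetwork:
        """Binary backbone: keep the edge set, drop the attributes."""
        return BinaryNetwork(list(self.nodes), self.mask.copy())

    def to_networkx(self):
        import networkx as nx

        G = nx.DiGraph()
        G.add_nodes_from(self.nodes)
        for a, b in zip(*np.nonzero(self.mask)):
            G.add_edge(
                self.nodes[a],
                self.nodes[b],
                fln=float(self.fln[a, b]),
                sln=float(self.sln[a, b]),
                dist_mm=float(self.dist[a, b]),
            )
        return G

    def copy(self) -> "WeightedConnectome":
        return WeightedConnectome(
            list(self.nodes),
            self.fln.copy(),
            self.sln.copy(),
            self.dist.copy(),
            None if self.supra is None else self.supra.copy(),
            None if self.infra is None else self.infra.copy(),
            self.mask.copy(),
        )


# ---------------------------------------------------------------------------
# I/O.  Canonical interchange: CSV square matrix (header row + header column
# of area labels) and a TSV edge table; GraphML and read-only XLSX supported.
# ---------------------------------------------------------------------------


def _read_matrix_csv(path, orientation="source-rows"):
    df = pd.read_csv(path, index_col=0)
    rows = [str(r) for r in df.index]
    cols = [str(c) for c in df.columns]
    if rows != cols:
        raise ConnectomeError("matrix CSV row and column labels must match")
    M = df.to_numpy(dtype=float)
    if orientation == "target-rows":
        M = M.T
    elif orientation != "source-rows":
        raise ConnectomeError(f"unknown orientation {orientation!r}")
    return rows, M


def load_binary(path, dialect="matrix-csv", orientation="source-rows") -> BinaryNetwork:
    """Load a :class:`BinaryNetwork`.

    ``dialect`` is one of ``matrix-csv`` (labelled square matrix),
    ``edgelist-tsv`` (columns source, target), ``graphml`` or ``xlsx``
    (first sheet read as a labelled square matrix).  ``orientation``
    declares whether rows are projection sources (default) or targets;
    supplementary-style files do not state this, so it is explicit here.
    """
    if dialect == "matrix-csv":
        nodes, M = _read_matrix_csv(path, orientation)
    elif dialect == "xlsx":
        df = pd.read_excel(path, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        nodes = list(df.index)
        if nodes != list(df.columns):
            raise ConnectomeError("matrix sheet row and column labels must match")
        M = df.to_numpy(dtype=float)
        if orientation == "target-rows":
            M = M.T
    elif dialect == "edgelist-tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        nodes = list(dict.fromkeys(list(df["source"]) + list(df["target"])))
        idx = {v: i for i, v in enumerate(nodes)}
        M = np.zeros((len(nodes), len(nodes)))
        for _, r in df.iterrows():
            M[idx[r["source"]], idx[r["target"]]] = 1
    elif dialect == "graphml":
        import networkx as nx

        return BinaryNetwork.from_networkx(nx.read_graphml(path))
    else:
        raise ConnectomeError(f"unknown dialect {dialect!r}")
    if not np.all(np.isin(np.unique(M[np.isfinite(M)]), [0, 1])) or not np.all(
        np.isfinite(M)
    ):
        raise ConnectomeError("binary matrix entries must be 0 or 1")
    return BinaryNetwork(nodes, M)


def save_binary(net: BinaryNetwork, path, dialect="matrix-csv") -> None:
    if dialect == "matrix-csv":
        pd.DataFrame(
            net.adjacency.astype(int), index=net.nodes, columns=net.nodes
        ).to_csv(path)
    elif dialect == "edgelist-tsv":
        pd.DataFrame(net.edges(), columns=["source", "target"]).to_csv(
            path, sep="\t", index=False
        )
    elif dialect == "graphml":
        import networkx as nx

        nx.write_graphml(net.to_networkx(), path)
    else:
        raise ConnectomeError(f"unknown dialect {dialect!r}")


_WEIGHTED_PARTS = {"fln": "fln", "sln": "sln", "dist": "dist"}


def load_weighted(path, orientation="source-rows") -> WeightedConnectome:
    """Load a :class:`WeightedConnectome`.

    ``path`` is either a directory containing ``fln.csv``, ``sln.csv`` and
    ``dist.csv`` labelled square matrices, or an ``.xlsx`` workbook with
    sheets named FLN, SLN and DIST (case-insensitive).  The edge mask is the
    set of positions where FLN > 0; SLN and distance must be defined exactly
    there.
    """
    import os

    mats = {}
    if str(path).endswith((".xlsx", ".xls")):
        book = pd.read_excel(path, sheet_name=None, index_col=0)
        sheets = {k.lower(): v for k, v in book.items()}
        for key in _WEIGHTED_PARTS:
            cand = [s for s in sheets if key in s]
            if not cand:
                raise ConnectomeError(f"workbook is missing a {key.upper()} sheet")
            df = sheets[cand[0]]
            df.index = df.index.astype(str)
            df.columns = df.columns.astype(str)
            mats[key] = (list(df.index), df.to_numpy(dtype=float))
    else:
        for key in _WEIGHTED_PARTS:
            f = os.path.join(path, f"{key}.csv")
            if not os.path.exists(f):
                raise ConnectomeError(f"missing {key}.csv in {path}")
            mats[key] = _read_matrix_csv(f, "source-rows")
    nodes = mats["fln"][0]
    arrs = {}
    for key, (labels, M) in mats.items():
        if labels != nodes:
            raise ConnectomeError("FLN/SLN/distance sheets must share area ordering")
        if orientation == "target-rows":
            M = M.T
        arrs[key] = M
    fln = arrs["fln"]
    mask = np.isfinite(fln) & (fln > 0)
    for key in ("sln", "dist"):
        M = arrs[key]
        defined = np.isfinite(M)
        if key == "dist":
            # distance tables are often dense/symmetric; restrict to the mask
            defined = defined & (M > 0)
            arrs[key] = np.where(mask, M, np.nan)
            if not np.all(defined[mask]):
                raise ConnectomeError("distance missing on an existing edge")
        else:
            if not np.all(defined[mask]):
                raise ConnectomeError(f"{key} missing where FLN > 0")
            arrs[key] = np.where(mask, M, np.nan)
    return WeightedConnectome(
        nodes, np.where(mask, fln, np.nan), arrs["sln"], arrs["dist"], mask=mask
    )


def save_weighted(net: WeightedConnectome, path) -> None:
    """Write fln.csv / sln.csv / dist.csv plus an edges.tsv table to a directory."""
    import os

    os.makedirs(path, exist_ok=True)
    for key in _WEIGHTED_PARTS:
        M = getattr(net, key)
        out = np.where(net.mask, M, 0.0 if key == "fln" else np.nan)
        pd.DataFrame(out, index=net.nodes, columns=net.nodes).to_csv(
            os.path.join(path, f"{key}.csv")
        )
    to_edge_table(net).to_csv(os.path.join(path, "edges.tsv"), sep="\t", index=False)


def to_edge_table(net: WeightedConnectome) -> pd.DataFrame:
    """Long-form edge table: one row per edge, columns source/target/fln/sln/dist_mm."""
    i, j = np.nonzero(net.mask)
    return pd.DataFrame(
        {
            "source": [net.nodes[a] for a in i],
            "target": [net.nodes[b] for b in j],
            "fln": net.fln[i, j],
            "sln": net.sln[i, j],
            "dist_mm": net.dist[i, j],
        }
    )


def from_edge_table(table: pd.DataFrame, nodes=None) -> WeightedConnectome:
    """Inverse of :func:`to_edge_table`; ``nodes`` fixes the area order."""
    if table.duplicated(subset=["source", "target"]).any():
        raise ConnectomeError("duplicate (source, target) rows in edge table")
    if nodes is None:
        nodes = list(dict.fromkeys(list(table["source"]) + list(table["target"])))
    idx = {str(v): i for i, v in enumerate(nodes)}
    n = len(nodes)
    fln = np.full((n, n), np.nan)
    sln = np.full((n, n), np.nan)
    dist = np.full((n, n), np.nan)
    for _, r in table.iterrows():
        a, b = idx[str(r["source"])], idx[str(r["target"])]
        fln[a, b], sln[a, b], dist[a, b] = r["fln"], r["sln"], r["dist_mm"]
    return WeightedConnectome(list(nodes), fln, sln, dist)


def extract_subgraph(net, areas):
    """Induced subgraph on ``areas`` (order follows the request).

    Works for both graph flavours; all edge attributes are restricted to the
    induced edge set.  Unknown labels raise ``KeyError``.
    """
    idx = {v: i for i, v in enumerate(net.nodes)}
    try:
        sel = [idx[str(a)] for a in areas]
    except KeyError as e:
        raise KeyError(f"unknown area label {e.args[0]!r}") from None
    if len(set(sel)) != len(sel):
        raise ConnectomeError("requested area list contains duplicates")
    sub = np.ix_(sel, sel)
    labels = [net.nodes[i] for i in sel]
    if isinstance(net, BinaryNetwork):
        return BinaryNetwork(labels, net.adjacency[sub])
    return WeightedConnectome(
        labels,
        net.fln[sub],
        net.sln[sub],
        net.dist[sub],
        None if net.supra is None else net.supra[sub],
        None if net.infra is None else net.infra[sub],
        net.mask[sub],
    )
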