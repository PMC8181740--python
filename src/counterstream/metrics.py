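"""Scalar graph descriptors: density, reciprocity, ASP, diameter,
transitivity, strong components and Laplacian spectral measures.

Synchronizability is read off the spectrum of the graph Laplacian
L = D - A.  The default convention keeps the directed adjacency
(out-degree diagonal); L then has zero row sums, so 0 is always an
eigenvalue with eigenvector [1, ..., 1]^T, and by Gershgorin every
eigenvalue has non-negative real part — the spectrum is reported as the
sorted real parts (for cortical graphs, whose reciprocity is high, the
imaginary parts are small).  The algebraic connectivity lambda_2 measures
how close the network is to disconnection and the eigenratio
lambda_2 / lambda_max indicates how stable a synchronous state can be
(closer to 1 = more stable).  A symmetrised convention W = (A + A^T) / 2
("mean") is also available; it is genuinely PSD, and single-edge removal
can only lower its eigenvalues (interlacing), which the directed
convention does not guarantee.  The directed default is the convention
that reproduces the data-free Erdos-Renyi reference statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np

from .connectome import BinaryNetwork

__all__ = ["GraphSummary", "summarize", "laplacian_spectrum"]

_ZERO_EIG_TOL = 1e-8


@dataclass
class GraphSummary:
    density: float
    reciprocity: float
    asp: float
    diameter: int
    transitivity: float
    n_scc: int
    lambda2: float
    lambda_max: float
    eigenratio: float

    def as_dict(self) -> dict:
        return asdict(self)


def laplacian_spectrum(net: BinaryNetwork, convention: str = "directed") -> np.ndarray:
    """Ascending Laplacian eigenvalues.

    ``directed`` (default): L = D_out - A; eigenvalues may be complex and
    the sorted real parts are returned (all >= 0 by Gershgorin).
    ``mean``: W = (A + A^T)/2, L = D - W, symmetric PSD.
    ``union``: W = max(A, A^T).
    Values below 1e-8 in magnitude are clamped to exactly 0.
    """
    A = net.adjacency.astype(float)
    if convention == "directed":
        L = np.diag(A.sum(axis=1)) - A
        eig = np.linalg.eigvals(L).real
    elif convention in ("mean", "union"):
        W = (A + A.T) / 2.0 if convention == "mean" else np.maximum(A, A.T)
        L = np.diag(W.sum(axis=1)) - W
        eig = np.linalg.eigvalsh(L)
    else:
        raise ValueError(f"unknown Laplacian convention {convention!r}")
    eig[np.abs(eig) < _ZERO_EIG_TOL] = 0.0
    return np.sort(eig)


def _asp_and_diameter(G: nx.DiGraph):
    """ASP over reachable ordered pairs; diameter as the largest directed
    diameter over strongly connected components (per-component rule when
    the graph is not strongly connected)."""
    total = 0
    count = 0
    ecc_max = 0
    lengths = dict(nx.all_pairs_shortest_path_length(G))
    for s, dd in lengths.items():
        for t, d in dd.items():
            if s != t:
                total += d
                count += 1
    if count == 0:
        return float("nan"), 0
    if nx.is_strongly_connected(G):
        ecc_max = max(max(dd.values()) for dd in lengths.values())
    else:
        for comp in nx.strongly_connected_components(G):
            if len(comp) < 2:
                continue
            sub = G.subgraph(comp)
            ecc_max = max(ecc_max, nx.diameter(sub))
    return total / count, int(ecc_max)


def summarize(net: BinaryNetwork, convention: str = "directed") -> GraphSummary:
    """All scalar descriptors of a binary directed network.

    ASP averages shortest-path lengths over ordered pairs that are
    reachable (equal to the all-pairs average only when the graph is
    strongly connected).  Transitivity is the global triangles-to-triples
    ratio of the undirected projection.  Reciprocity is the fraction of
    directed edges whose reverse also exists.
    """
    if net.n == 0 or net.m == 0:
        raise ValueError("summarize needs a non-empty graph with edges")
    G = net.to_networkx()
    asp, diameter = _asp_and_diameter(G)
    eig = laplacian_spectrum(net, convention)
    lam2, lam_max = float(eig[1]), float(eig[-1])
    return GraphSummary(
        density=net.m / (net.n * (net.n - 1)),
        reciprocity=float(nx.overall_reciprocity(G)),
        asp=float(asp),
        diameter=diameter,
        transitivity=float(nx.transitivity(G.to_undirected())),
        n_scc=int(nx.number_strongly_connected_components(G)),
        lambda2=lam2,
        lambda_max=lam_max,
        eigenratio=lam2 / lam_max if lam_max > 0 else 0.0,
    )
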