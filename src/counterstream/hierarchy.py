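"""SLN-based anatomical hierarchy.

Each projection's supragranular labelled-neuron fraction (SLN) carries
ordinal information about the hierarchical relation of its endpoints:
feedforward projections (up the hierarchy) originate mostly in
supragranular layers (SLN -> 1), feedback projections mostly in
infragranular layers (SLN -> 0).  Area levels ``h_i`` are estimated by a
generalized linear model with a beta-binomial response and a logit link:

    E[SLN(i -> j)] = logistic(h_j - h_i)

maximising the beta-binomial likelihood of the supragranular counts with a
common dispersion (precision) parameter.  Levels are identified up to an
additive constant only, so one reference area is pinned at level 0.
A probit link is available behind a flag and yields rank-identical
hierarchies in practice.

The anatomical hierarchical distance of two areas is |h_i - h_j|; the sum
of hierarchical distances (SHD) of an area set is the sum over its
unordered pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import expit

from .connectome import WeightedConnectome

__all__ = [
    "HierarchyFit",
    "HierarchicalDistances",
    "fit_hierarchy",
    "hierarchical_distances",
]


class HierarchyFitError(RuntimeError):
    """Optimization failed; carries the optimizer trace in ``trace``."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


@dataclass
class HierarchyFit:
    levels: dict[str, float]
    dispersion: float
    loglik: float
    converged: bool
    reference: str
    link: str = "logit"

    def level_array(self, areas=None) -> np.ndarray:
        areas = list(self.levels) if areas is None else list(areas)
        return np.array([self.levels[a] for a in areas])


@dataclass
class HierarchicalDistances:
    areas: list[str]
    matrix: np.ndarray  # |h_i - h_j|, symmetric, zero diagonal
    shd: float


def _edge_counts(net: WeightedConnectome, count_scale_effective: int):
    """Supragranular / total trial counts per edge.

    Observed counts are used when present; otherwise pseudo-counts are
    derived from FLN, n_ij = max(1, round(cse * FLN_ij * n_areas)), so an
    average-weight edge carries about ``cse`` trials after the per-target
    FLN normalisation.
    """
    i, j = np.nonzero(net.mask)
    if net.supra is not None:
        total = np.round(net.supra[i, j] + net.infra[i, j]).astype(int)
        supra = np.round(net.supra[i, j]).astype(int)
    else:
        total = np.maximum(
            1, np.round(count_scale_effective * net.fln[i, j] * net.n)
        ).astype(int)
        supra = np.round(net.sln[i, j] * total).astype(int)
    supra = np.clip(supra, 0, total)
    return i, j, supra, total


def _check_connected(net: WeightedConnectome):
    import networkx as nx

    G = nx.Graph()
    G.add_nodes_from(range(net.n))
    G.add_edges_from(zip(*np.nonzero(net.mask)))
    if not nx.is_connected(G):
        raise HierarchyFitError(
            "SLN graph is not weakly connected: levels are not identifiable"
        )


def default_reference(net: WeightedConnectome) -> str:
    """Area with the lowest incoming-SLN sum (bottom of the hierarchy:
    its afferents are predominantly feedback)."""
    sln = np.where(net.mask, net.sln, 0.0)
    return net.nodes[int(np.argmin(sln.sum(axis=0)))]


def fit_hierarchy(
    net: WeightedConnectome,
    reference_area: str | None = None,
    link: str = "logit",
    count_scale_effective: int = 1000,
    n_starts: int = 3,
    max_iter: int = 2000,
    seed: int = 0,
) -> HierarchyFit:
    """Maximum-likelihood hierarchy levels with the reference pinned at 0.

    Optimises the free levels and the log precision jointly (L-BFGS,
    multi-start to guard against local optima, tolerance 1e-8 on the
    log-likelihood).  Raises :class:`HierarchyFitError` on non-convergence
    or an unidentifiable (disconnected) SLN graph.
    """
    _check_connected(net)
    if reference_area is None:
        reference_area = default_reference(net)
    if reference_area not in net.nodes:
        raise KeyError(f"unknown reference area {reference_area!r}")
    ref = net.nodes.index(reference_area)
    free = [i for i in range(net.n) if i != ref]
    src, tgt, supra, total = _edge_counts(net, count_scale_effective)

    if link == "logit":
        linkinv = expit
    elif link == "probit":
        linkinv = stats.norm.cdf
    else:
        raise ValueError("link must be 'logit' or 'probit'")

    def negloglik(theta):
        h = np.zeros(net.n)
        h[free] = theta[:-1]
        nu = np.exp(theta[-1])
        p = np.clip(linkinv(h[tgt] - h[src]), 1e-9, 1 - 1e-9)
        ll = stats.betabinom.logpmf(supra, total, p * nu, (1 - p) * nu)
        out = -float(ll.sum())
        return out if np.isfinite(out) else 1e12

    rng = np.random.default_rng(seed)
    # moment start: level ~ mean logit of afferent minus efferent SLN
    obs = np.log((supra + 0.5) / (total - supra + 0.5))
    h0 = np.zeros(net.n)
    for i in range(net.n):
        inc = obs[tgt == i]
        out = obs[src == i]
        h0[i] = (inc.sum() - out.sum()) / max(1, len(inc) + len(out))
    h0 -= h0[ref]
    starts = [np.concatenate([h0[free], [np.log(10.0)]])]
    for _ in range(n_starts - 1):
        starts.append(
            np.concatenate(
                [h0[free] + rng.normal(0, 0.5, len(free)), [rng.normal(2, 1)]]
            )
        )
    best = None
    traces = []
    for x0 in starts:
        # the precision is bounded: above ~e^12 trials the beta-binomial is
        # numerically binomial and the likelihood is flat in log(nu)
        bounds = [(None, None)] * len(free) + [(-10.0, 12.0)]
        res = optimize.minimize(
            negloglik,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": 1e-8, "gtol": 1e-10},
        )
        traces.append(res)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise HierarchyFitError("hierarchy fit failed to converge", traces)
    h = np.zeros(net.n)
    h[free] = best.x[:-1]
    return HierarchyFit(
        levels={a: float(v) for a, v in zip(net.nodes, h)},
        dispersion=float(np.exp(-best.x[-1])),  # 1 / precision
        loglik=-float(best.fun),
        converged=bool(best.success),
        reference=reference_area,
        link=link,
    )


def hierarchical_distances(fit: HierarchyFit, areas=None) -> HierarchicalDistances:
    """Pairwise |h_i - h_j| on ``areas`` (default: all fitted areas) and
    the SHD, their sum over unordered pairs."""
    areas = list(fit.levels) if areas is None else [str(a) for a in areas]
    missing = [a for a in areas if a not in fit.levels]
    if missing:
        raise KeyError(f"areas not in fit: {missing}")
    h = fit.level_array(areas)
    M = np.abs(h[:, None] - h[None, :])
    shd = float(M[np.triu_indices(len(areas), k=1)].sum())
    return HierarchicalDistances(areas, M, shd)
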