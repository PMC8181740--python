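"""Subgraph correlation experiments.

Relates the topological hierarchy index invCDw (the additive inverse of
the weighted convergence degree, so that feedforward-like divergent edges
carry positive values like high SLN), the anatomical index SLN, and the
functional index mDAI on fixed or randomly sampled area subsets.

By default the convergence degree of a subgraph's edges is taken from the
full-graph relaxed path structure (the topological context of the whole
network is preserved) and only restricted to the induced edge set; a flag
recomputes it within the induced subgraph instead.  Dynamics for
per-sample mDAI are simulated on the induced subgraph in isolation, which
keeps the cost of the causality estimates bounded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .causality import conditional_spectral_gc, dai_from_gc
from .connectome import WeightedConnectome, extract_subgraph
from .dynamics import LaminarModelConfig, simulate
from .hierarchy import HierarchyFit, fit_hierarchy, hierarchical_distances
from .paths import edge_metrics, relaxed_weighted_paths

__all__ = [
    "SubgraphSample",
    "edge_correlation",
    "invcd_matrix",
    "mdai_matrix",
    "gc_from_rates",
    "sample_subgraphs",
    "alpha_k_sweep",
]


def edge_correlation(x: np.ndarray, y: np.ndarray, exclude_extreme: np.ndarray | None = None):
    """Pearson correlation across ordered-pair edges.

    ``x`` and ``y`` are (n, n) matrices, NaN where no edge exists.  When
    ``exclude_extreme`` is given (typically the SLN matrix), edges where it
    equals exactly 0 or 1 are dropped, mirroring the practice of excluding
    pure-feedforward/pure-feedback projections.  Returns ``(r, p, n_edges)``.
    """
    sel = np.isfinite(x) & np.isfinite(y)
    if exclude_extreme is not None:
        sel &= ~np.isin(exclude_extreme, (0.0, 1.0))
    if sel.sum() < 4:
        raise ValueError("need at least 4 paired edge values")
    r, p = stats.pearsonr(x[sel], y[sel])
    return float(r), float(p), int(sel.sum())


def invcd_matrix(net: WeightedConnectome, alpha: float, k: int) -> np.ndarray:
    """invCDw = -CD on the full-graph relaxed path structure, as a matrix."""
    em = edge_metrics(relaxed_weighted_paths(net, alpha, k), net)
    return -em.matrix("cd")


def _decimate_to(x: np.ndarray, fs: float, fs_target: float):
    """Anti-aliased downsampling of (time, channels) data to ~fs_target."""
    from scipy.signal import decimate

    q = int(round(fs / fs_target))
    while q > 1:
        step = min(q, 10)
        x = decimate(x, step, axis=0, zero_phase=True)
        fs /= step
        q //= step
    return x, fs


#: laminar weights of the default LFP-like recording proxy
#: (supraE, supraI, infraE, infraI); deep layers dominate field potentials,
#: and the mix must expose the intrinsic infragranular alpha rhythm of the
#: *source* area for feedback alpha-band causality to be measurable at all
LFP_MIX = (0.3, 0.0, 0.7, 0.0)


def gc_from_rates(ts, signal="lfp", fs_target: float = 250.0,
                  freq_max: float = 100.0, segment_s: float = 1.0,
                  bandwidth_hz: float = 4.0):
    """Conditional spectral GC between areas from a laminar simulation.

    ``signal`` selects the per-area recording proxy: ``"lfp"`` (default), a
    fixed laminar mix of the excitatory rates (:data:`LFP_MIX`), one of the
    population names (e.g. ``"supraE"``), or an explicit 4-vector of
    weights.  Rates are decimated to about ``fs_target`` Hz before spectral
    estimation — the analysis bands end at 70 Hz, so nothing of interest is
    lost and the factorizations shrink.
    """
    from .dynamics import POPULATIONS

    if isinstance(signal, str):
        if signal == "lfp":
            w = np.asarray(LFP_MIX)
        elif signal in POPULATIONS:
            w = np.eye(4)[POPULATIONS.index(signal)]
        else:
            raise ValueError(f"unknown signal {signal!r}")
    else:
        w = np.asarray(signal, dtype=float)
    x, fs = _decimate_to(ts.rates @ w, ts.fs, fs_target)
    return conditional_spectral_gc(
        x, fs, labels=ts.areas, freq_max=freq_max,
        segment_s=segment_s, bandwidth_hz=bandwidth_hz,
    )


def mdai_matrix(net: WeightedConnectome, config: LaminarModelConfig | None = None,
                segment_s: float = 1.0, bandwidth_hz: float = 4.0) -> np.ndarray:
    """mDAI between all area pairs from a simulation of ``net``.

    Simulates the laminar model, estimates conditional spectral GC between
    the areas' LFP-like laminar-mixed rates, and reduces the DAI spectra to
    the multifrequency-band index.
    """
    config = config or LaminarModelConfig.default()
    ts = simulate(net, config)
    res = gc_from_rates(ts, segment_s=segment_s, bandwidth_hz=bandwidth_hz)
    return dai_from_gc(res).mdai


@dataclass
class SubgraphSample:
    areas: list[str]
    r_invcd_sln: float
    shd: float
    n_edges: int
    r_invcd_mdai: float | None = None
    r_sln_mdai: float | None = None


def _restrict(M: np.ndarray, idx: list[int]) -> np.ndarray:
    return M[np.ix_(idx, idx)]


def sample_subgraphs(
    net: WeightedConnectome,
    size: int = 8,
    n_samples: int = 100,
    unique: bool = True,
    exclusions=(),
    seed: int = 0,
    alpha: float = 0.07,
    k: int = 8,
    cd_scope: str = "full",
    fit: HierarchyFit | None = None,
    compute_mdai: bool = False,
    dynamics_config: LaminarModelConfig | None = None,
    forced_areas=None,
) -> list[SubgraphSample]:
    """Random area subsets with their per-sample correlations and SHD.

    Subsets of ``size`` areas are drawn uniformly from the areas not listed
    in ``exclusions`` (rejection sampling enforces uniqueness when
    ``unique``).  Per sample the Pearson correlation of invCDw with SLN is
    computed over the induced edges, along with the sum of hierarchical
    distances (SHD) of the subset; with ``compute_mdai`` the induced
    subgraph is additionally simulated in isolation and the invCDw x mDAI
    and SLN x mDAI correlations recorded.  ``forced_areas`` pins the first
    sample to a given area list (the fixed reference subgraph is the
    special case ``n_samples=1``).
    """
    rng = np.random.default_rng(seed)
    pool = [a for a in net.nodes if a not in set(exclusions)]
    if size > len(pool):
        raise ValueError("subgraph size exceeds the available area pool")
    from math import comb

    if unique and n_samples > comb(len(pool), size):
        raise ValueError("more unique samples requested than distinct subsets")
    if fit is None:
        fit = fit_hierarchy(net)
    if cd_scope not in ("full", "induced"):
        raise ValueError("cd_scope must be 'full' or 'induced'")
    invcd_full = invcd_matrix(net, alpha, k) if cd_scope == "full" else None
    idx_of = {a: i for i, a in enumerate(net.nodes)}

    seen = set()
    samples: list[SubgraphSample] = []
    while len(samples) < n_samples:
        if forced_areas is not None and not samples:
            areas = [str(a) for a in forced_areas]
        else:
            areas = sorted(rng.choice(pool, size=size, replace=False).tolist())
        key = frozenset(areas)
        if unique and key in seen:
            continue
        seen.add(key)
        idx = [idx_of[a] for a in areas]
        sln = _restrict(net.sln, idx)
        if cd_scope == "full":
            invcd = _restrict(invcd_full, idx)
        else:
            invcd = invcd_matrix(extract_subgraph(net, areas), alpha, k)
        try:
            r, _, ne = edge_correlation(invcd, sln, exclude_extreme=sln)
        except ValueError:
            continue  # too few edges in this subset; draw another
        shd = hierarchical_distances(fit, areas).shd
        sample = SubgraphSample(areas, r, shd, ne)
        if compute_mdai:
            sub = extract_subgraph(net, areas)
            cfg = dynamics_config or LaminarModelConfig.default()
            cfg = type(cfg)(**{**cfg.__dict__, "seed": int(rng.integers(2**31))})
            mdai = mdai_matrix(sub, cfg)
            sample.r_invcd_mdai = edge_correlation(invcd, mdai, exclude_extreme=sln)[0]
            sample.r_sln_mdai = edge_correlation(sln, mdai, exclude_extreme=sln)[0]
        samples.append(sample)
    return samples


def alpha_k_sweep(net: WeightedConnectome, areas, alpha_grid, k_grid,
                  target: np.ndarray) -> pd.DataFrame:
    """Pearson correlation surface of invCDw (restricted to the induced
    subgraph on ``areas``) against a per-edge target matrix (SLN or mDAI),
    over a grid of (alpha, k) path parameters.

    The target matrix is full-size (n x n); extreme SLN handling is the
    caller's concern here — entries to skip should be NaN.
    """
    from .paths import truncate_paths

    if len(alpha_grid) == 0 or len(k_grid) == 0:
        raise ValueError("grids must be non-empty")
    idx = [net.nodes.index(str(a)) for a in areas]
    tgt = _restrict(np.asarray(target, dtype=float), idx)
    k_grid = sorted(int(k) for k in k_grid)
    rows = []
    for a in alpha_grid:
        full = relaxed_weighted_paths(net, a, max(k_grid))
        for k in k_grid:
            em = edge_metrics(truncate_paths(full, k), net)
            invcd = _restrict(-em.matrix("cd"), idx)
            r, p, ne = edge_correlation(invcd, tgt)
            rows.append({"alpha": a, "k": k, "r": r, "p": p, "n_edges": ne})
    return pd.DataFrame(rows)
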