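"""Synthetic connectome generation.

Generates directed weighted connectomes with the statistical structure the
downstream analyses assume, so that every stage of the pipeline is testable
without tract-tracing data:

* areas are embedded uniformly in a 2-D box and connection probability
  decays exponentially with distance (an exponential-distance-rule prior,
  a modelling choice reflecting the coupling of weight and distance in
  cortical connectomes);
* a tunable reciprocity bias completes reciprocal pairs;
* FLN weights are log-normal, then normalised over sources per target area
  (column-stochastic), mirroring the per-injection definition of the
  fraction of labelled neurons;
* SLN values arise from a latent hierarchy ``h`` through a beta-binomial
  logistic model: the expected supragranular fraction of the projection
  ``i -> j`` is ``logistic(slope * (h_j - h_i))``, so projections running up
  the hierarchy look feedforward (SLN > 0.5) and projections running down
  look feedback.  This matches the generative model assumed by the
  hierarchy-fitting module, enabling parameter-recovery tests.

``bb_dispersion = 0`` is the noiseless limit: SLN equals its expectation
exactly and the stored counts are the (possibly non-integer) expected
supragranular/infragranular splits of ``count_scale`` neurons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .connectome import BinaryNetwork, WeightedConnectome

__all__ = ["SyntheticSpec", "generate", "generate_binary"]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic weighted connectome generator.

    Defaults emulate a macaque-like inter-areal network: 29 areas, edge
    density 0.64 (the empirical 29-area visual graph has 536/812 ~ 0.66),
    strong reciprocity, a 40 mm cortical sheet, log-normal FLN spanning
    several orders of magnitude, and latent hierarchy levels spread over
    about two logit units as in SLN-based cortical hierarchies.
    """

    n_areas: int = 29
    target_density: float = 0.64
    reciprocity_bias: float = 0.7
    box_size: float = 40.0  # mm
    edr_lambda: float = 0.08  # 1/mm
    fln_log_mean: float = -4.0
    fln_log_sd: float = 2.0
    hierarchy_levels: np.ndarray | None = None  # default: linspace(0, 2, n)
    sln_slope: float = 1.5
    count_scale: int = 1000
    bb_dispersion: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.target_density < 1:
            raise ValueError("target_density must lie in (0, 1)")
        if not 0 <= self.reciprocity_bias <= 1:
            raise ValueError("reciprocity_bias must lie in [0, 1]")
        if self.n_areas < 2:
            raise ValueError("need at least two areas")
        if self.hierarchy_levels is None:
            self.hierarchy_levels = np.linspace(0.0, 2.0, self.n_areas)
        self.hierarchy_levels = np.asarray(self.hierarchy_levels, dtype=float)
        if self.hierarchy_levels.shape != (self.n_areas,):
            raise ValueError("hierarchy_levels must have one entry per area")


def _placement_probability(spec: SyntheticSpec, decay: np.ndarray) -> np.ndarray:
    """Per-ordered-pair direct placement probability, rescaled so the
    expected density (including reciprocal completion) hits the target."""
    r = spec.reciprocity_bias
    off = ~np.eye(spec.n_areas, dtype=bool)

    def expected_density(c):
        p = np.minimum(1.0, c * decay)
        q = p + (1.0 - p) * p.T * r  # placed directly, or completed
        return q[off].mean()

    hi = 1.0
    while expected_density(hi) < spec.target_density:
        hi *= 2.0
        if hi > 1e12:
            raise ValueError(
                "target_density unreachable for this distance decay"
            )
    c = brentq(lambda c: expected_density(c) - spec.target_density, 0.0, hi)
    return np.minimum(1.0, c * decay)


def generate(spec: SyntheticSpec):
    """Draw one synthetic connectome.

    Returns ``(connectome, levels)`` where ``connectome`` is a
    :class:`~counterstream.connectome.WeightedConnectome` carrying
    supragranular/infragranular counts and ``levels`` maps area label to its
    true latent hierarchy level.  Identical spec + seed give bit-identical
    output.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_areas
    nodes = [f"A{i:02d}" for i in range(n)]
    h = spec.hierarchy_levels

    pos = rng.uniform(0.0, spec.box_size, size=(n, 2))
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    np.fill_diagonal(dist, np.nan)

    decay = np.exp(-spec.edr_lambda * dist)
    decay = np.where(np.isnan(decay), 0.0, decay)
    p = _placement_probability(spec, decay)
    mask = rng.random((n, n)) < p
    np.fill_diagonal(mask, False)
    # reciprocal completion
    completion = rng.random((n, n)) < spec.reciprocity_bias
    mask |= mask.T & completion
    np.fill_diagonal(mask, False)

    # log-normal FLN, normalised over sources per target (column-stochastic)
    raw = rng.lognormal(spec.fln_log_mean, spec.fln_log_sd, size=(n, n))
    raw = np.where(mask, raw, 0.0)
    colsum = raw.sum(axis=0)
    fln = np.divide(raw, colsum, out=np.zeros_like(raw), where=colsum > 0)
    fln = np.where(mask, fln, np.nan)

    # SLN from the latent hierarchy via the beta-binomial logistic model
    mean_sln = expit(spec.sln_slope * (h[None, :] - h[:, None]))
    if spec.bb_dispersion > 0:
        nu = 1.0 / spec.bb_dispersion
        a = np.clip(mean_sln * nu, 1e-12, None)
        b = np.clip((1.0 - mean_sln) * nu, 1e-12, None)
        q = rng.beta(a, b)
        supra = rng.binomial(spec.count_scale, q).astype(float)
    else:
        supra = mean_sln * spec.count_scale
    infra = spec.count_scale - supra
    sln = supra / spec.count_scale
    supra = np.where(mask, supra, np.nan)
    infra = np.where(mask, infra, np.nan)
    sln = np.where(mask, sln, np.nan)

    net = WeightedConnectome(
        nodes,
        fln,
        sln,
        np.where(mask, dist, np.nan),
        supra,
        infra,
        mask,
    )
    return net, {a: float(v) for a, v in zip(nodes, h)}


def generate_binary(n: int, m: int, mode: str = "er", seed: int = 0,
                    weighted: WeightedConnectome | None = None) -> BinaryNetwork:
    """Random binary directed graph.

    ``er`` draws exactly ``m`` distinct directed non-loop edges uniformly
    (the directed G(n, m) model).  ``from-weighted`` returns the binary
    backbone of a supplied weighted connectome.
    """
    if mode == "from-weighted":
        if weighted is None:
            raise ValueError("from-weighted mode needs a weighted connectome")
        return weighted.binary()
    if mode != "er":
        raise ValueError(f"unknown mode {mode!r}")
    if m > n * (n - 1):
        raise ValueError(f"m={m} exceeds the {n * (n - 1)} possible directed edges")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n * (n - 1), size=m, replace=False)
    A = np.zeros((n, n), dtype=bool)
    # enumerate the n(n-1) ordered non-loop pairs row by row
    row, col = np.divmod(chosen, n - 1)
    col = col + (col >= row)  # skip the diagonal slot
    A[row, col] = True
    return BinaryNetwork([f"N{i:02d}" for i in range(n)], A)
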