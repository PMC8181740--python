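"""Bilaminar Wilson-Cowan dynamics on a weighted connectome.

Each cortical area is modelled as two laminar excitatory-inhibitory rate
circuits: a supragranular pair tuned to resonate in the gamma range
(30-70 Hz) and an infragranular pair tuned to the alpha/low-beta range
(6-18 Hz).  Within an area the supragranular excitatory population drives
the infragranular excitatory population, while the infragranular
excitatory population projects onto supragranular inhibition.  Between
areas, connections are purely excitatory and split by the laminar origin
index SLN of the edge: the feedforward component (weight proportional to
SLN) runs from the source's supragranular excitatory population to the
target's supragranular excitatory population; the feedback component
(weight proportional to 1 - SLN) originates in the source's infragranular
excitatory population and contacts excitatory and inhibitory populations
of both laminae of the target.  The overall strength of an edge scales
with g(FLN) = G * FLN**eta, and its conduction delay is the projection
distance divided by a conduction velocity (rounded to a whole number of
integration steps).

The rate equations,

    tau_p dr_p/dt = -r_p + f(I_p),   f(x) = x / (1 - exp(-x)),

are integrated with Euler-Maruyama; additive Gaussian noise enters each
population with amplitude sigma_p * sqrt(2 * dt / tau_p).  Noise streams
are seeded per area (from the run seed and a hash of the area label), so
an area's stream does not depend on which other areas are simulated: with
all inter-areal weights zero, every area reproduces its isolated
simulation to machine precision.

All numeric parameters live in the versioned ``laminar_defaults.json``
shipped with the package; the simulator refuses to run if a required value
is absent rather than guessing.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
from scipy import signal

from .connectome import WeightedConnectome

__all__ = [
    "LaminarModelConfig",
    "LaminarTimeSeries",
    "StabilityError",
    "simulate",
    "power_spectrum",
]

POPULATIONS = ("supraE", "supraI", "infraE", "infraI")
LAYERS = ("supra", "infra")


class StabilityError(RuntimeError):
    """A population's rate exceeded the configured stability bound."""


_REQUIRED = [
    "tau_ms",
    "j_local",
    "background_drive",
    "noise_sigma",
    "interareal_gain",
    "fln_exponent",
    "ff_targets",
    "fb_targets",
    "conduction_velocity_mm_ms",
    "dt_ms",
    "duration_ms",
    "transient_ms",
    "stability_bound",
]


@dataclass
class LaminarModelConfig:
    tau_ms: np.ndarray
    j_local: np.ndarray
    background_drive: np.ndarray
    noise_sigma: np.ndarray
    interareal_gain: float
    fln_exponent: float
    ff_targets: np.ndarray
    fb_targets: np.ndarray
    conduction_velocity_mm_ms: float
    dt_ms: float = 0.2
    duration_ms: float = 11000.0
    transient_ms: float = 1000.0
    stability_bound: float = 1e6
    seed: int = 0
    external_drive: dict = field(default_factory=dict)  # area -> 4-vector

    def __post_init__(self):
        for name in ("tau_ms", "background_drive", "noise_sigma", "ff_targets",
                     "fb_targets"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (4,):
                raise ValueError(f"{name} must have one entry per population")
            setattr(self, name, v)
        self.j_local = np.asarray(self.j_local, dtype=float)
        if self.j_local.shape != (4, 4):
            raise ValueError("j_local must be 4x4")
        if np.any(self.tau_ms <= 0):
            raise ValueError("time constants must be positive")
        if self.dt_ms <= 0:
            raise ValueError("dt must be positive")
        if self.duration_ms <= self.transient_ms:
            raise ValueError("duration must exceed the transient")

    @classmethod
    def default(cls, **overrides) -> "LaminarModelConfig":
        """Load the versioned default parameter file, failing loudly if any
        required entry is missing."""
        text = resources.files("counterstream").joinpath(
            "laminar_defaults.json"
        ).read_text()
        raw = json.loads(text)
        missing = [k for k in _REQUIRED if k not in raw]
        if missing:
            raise KeyError(f"laminar_defaults.json lacks required entries: {missing}")
        kwargs = {k: raw[k]["value"] for k in _REQUIRED}
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class LaminarTimeSeries:
    """Rates with shape (time, area, population); population order
    (supraE, supraI, infraE, infraI).  The transient is already discarded."""

    areas: list[str]
    rates: np.ndarray
    dt_ms: float
    seed: int

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        return 1000.0 / self.dt_ms

    def get(self, area: str, layer: str = "supra", population: str = "E"):
        a = self.areas.index(area)
        p = POPULATIONS.index(f"{layer}{population}")
        return self.rates[:, a, p]


def transfer(x):
    """f(x) = x / (1 - exp(-x)): smooth, monotone non-decreasing, f(0) = 1."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-8
    out[small] = 1.0 + x[small] / 2.0
    xs = x[~small]
    out[~small] = xs / (1.0 - np.exp(-xs))
    return out


def _area_rng(seed: int, label: str):
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(label.encode())])


def edge_delays(net: WeightedConnectome, config: LaminarModelConfig):
    """Per-edge conduction delays.

    Returns (source indices, target indices, delay in integration steps).
    Delays are dist / velocity rounded to the nearest multiple of dt, with
    a floor of one step (coupling is never instantaneous).
    """
    src, tgt = np.nonzero(net.mask)
    lag = np.round(
        net.dist[src, tgt] / config.conduction_velocity_mm_ms / config.dt_ms
    ).astype(int)
    return src, tgt, np.maximum(1, lag)


def simulate(net: WeightedConnectome, config: LaminarModelConfig) -> LaminarTimeSeries:
    """Integrate the full-network laminar rate model.

    Returns the post-transient rate time series.  Raises
    :class:`StabilityError` (naming the first offending population) if any
    rate magnitude exceeds ``config.stability_bound``.
    """
    n = net.n
    dt = config.dt_ms
    n_steps = int(round(config.duration_ms / dt))
    n_keep = n_steps - int(round(config.transient_ms / dt))

    # inter-areal edge arrays
    src, tgt = np.nonzero(net.mask)
    w = config.interareal_gain * net.fln[src, tgt] ** config.fln_exponent
    sln = net.sln[src, tgt]
    w_ff = sln * w
    w_fb = (1.0 - sln) * w
    lag = edge_delays(net, config)[2]
    max_lag = int(lag.max()) if len(lag) else 1

    # per-area noise streams (independent of network composition)
    noise = np.empty((n_steps, n, 4))
    for i, label in enumerate(net.nodes):
        rng = _area_rng(config.seed, label)
        noise[:, i, :] = rng.standard_normal((n_steps, 4))
    tau = config.tau_ms
    noise *= config.noise_sigma * np.sqrt(2.0 * dt / tau)

    drive = np.tile(config.background_drive, (n, 1))
    for area, extra in config.external_drive.items():
        drive[net.nodes.index(area)] += np.asarray(extra, dtype=float)

    J = config.j_local
    ffc = config.ff_targets
    fbc = config.fb_targets
    hist = np.ones((max_lag + 1, n, 4))  # ring buffer of past rates
    r = np.ones((n, 4))
    out = np.empty((n_keep, n, 4))
    a = dt / tau
    for t in range(n_steps):
        if len(src):
            h = hist[(t - lag) % (max_lag + 1)]
            ff_in = np.bincount(tgt, weights=w_ff * h[np.arange(len(src)), src, 0],
                                minlength=n)
            fb_in = np.bincount(tgt, weights=w_fb * h[np.arange(len(src)), src, 2],
                                minlength=n)
            inter = np.outer(ff_in, ffc) + np.outer(fb_in, fbc)
        else:
            inter = 0.0
        I = r @ J.T + drive + inter
        r = r + a * (transfer(I) - r) + noise[t]
        if np.any(np.abs(r) > config.stability_bound):
            i, p = np.argwhere(np.abs(r) > config.stability_bound)[0]
            raise StabilityError(
                f"rate diverged at t={t * dt:.1f} ms in area "
                f"{net.nodes[i]} population {POPULATIONS[p]}"
            )
        hist[t % (max_lag + 1)] = r
        if t >= n_steps - n_keep:
            out[t - (n_steps - n_keep)] = r
    return LaminarTimeSeries(list(net.nodes), out, dt, config.seed)


def power_spectrum(series: LaminarTimeSeries, area: str, layer: str = "supra",
                   population: str = "E", resolution_hz: float = 1.0):
    """Welch power spectrum of one population's rate.

    Requires at least 2 s of simulated time; frequency resolution defaults
    to <= 1 Hz.
    """
    x = series.get(area, layer, population)
    fs = series.fs
    if len(x) < 2 * fs:
        raise ValueError("need at least 2 s of simulated time")
    nperseg = int(fs / resolution_hz)
    f, p = signal.welch(x - x.mean(), fs=fs, nperseg=min(nperseg, len(x)))
    return f, p
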