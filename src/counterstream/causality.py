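"""Conditional spectral Granger causality and the directed influence
asymmetry index (DAI).

Granger causality (GC) measures directed predictive influence between
time series; its spectral form resolves that influence by frequency, and
the *conditional* form removes influences mediated by the remaining
recorded series (a pairwise spectral comparison of more than two series
would include such indirect effects).  The estimator here is
nonparametric: a multitaper cross-spectral density matrix is factorized
into a causal (minimum-phase) transfer function and an innovation
covariance by Wilson's algorithm, and conditional GC is obtained by the
two-factorization partition scheme — the reduced system (target plus
conditioning set, source excluded) is factorized separately and its
transfer embedded and inverted against the full system.  A parametric
route computing the exact spectral GC of a known VAR is provided for
cross-checks.

From the GC spectra the functional-hierarchy indices follow:

    DAI_{s->t}(f) = (GC_{s->t}(f) - GC_{t->s}(f)) / (GC_{s->t}(f) + GC_{t->s}(f))

which is antisymmetric by construction, band DAI values are averages over
the alpha/low-beta (6-18 Hz) and gamma (30-70 Hz) bands, and the
multifrequency-band index combines the gamma band with the sign-inverted
alpha band in the same direction:

    mDAI(i->j) = (DAI_gamma(i->j) - DAI_alpha(i->j)) / 2.

Feedforward projections are expected to carry positive gamma-band DAI and
negative alpha-band DAI, so mDAI is a scalar feedforward index per ordered
pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.signal.windows import dpss

__all__ = [
    "SpectralGCResult",
    "multitaper_csd",
    "wilson_factorize",
    "conditional_spectral_gc",
    "pairwise_spectral_gc",
    "var_spectral_matrix",
    "var_spectral_gc",
    "dai_from_gc",
    "frequency_correlation",
    "ALPHA_BAND",
    "GAMMA_BAND",
]

ALPHA_BAND = (6.0, 18.0)
GAMMA_BAND = (30.0, 70.0)


# ---------------------------------------------------------------------------
# spectral estimation
# ---------------------------------------------------------------------------


def multitaper_csd(x: np.ndarray, fs: float, segment_s: float = 1.0,
                   bandwidth_hz: float = 4.0):
    """Multitaper cross-spectral density matrix.

    ``x`` has shape (time, channels).  The series is cut into
    non-overlapping segments of ``segment_s`` seconds; each segment is
    detrended, tapered with the DPSS family of half-bandwidth
    ``bandwidth_hz`` and Fourier transformed; cross-products are averaged
    over tapers and segments.  Returns ``(freqs, S)`` with ``S`` of shape
    (n_freqs, n_channels, n_channels), Hermitian at every frequency.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("x must be (time, channels)")
    nper = int(round(segment_s * fs))
    n_seg = x.shape[0] // nper
    if n_seg < 1:
        raise ValueError("series shorter than one segment")
    nw = bandwidth_hz * segment_s  # time-halfbandwidth product
    n_tapers = max(1, int(2 * nw) - 1)
    tapers = dpss(nper, nw, n_tapers)  # (n_tapers, nper)
    segs = x[: n_seg * nper].reshape(n_seg, nper, x.shape[1])
    segs = segs - segs.mean(axis=1, keepdims=True)
    # (n_seg, n_tapers, nper, ch)
    tapered = segs[:, None, :, :] * tapers[None, :, :, None]
    F = np.fft.rfft(tapered, axis=2)  # (n_seg, n_tapers, n_freq, ch)
    S = np.einsum("stfi,stfj->fij", F, np.conj(F)) / (n_seg * n_tapers * fs * nper)
    freqs = np.fft.rfftfreq(nper, d=1.0 / fs)
    return freqs, S


# ---------------------------------------------------------------------------
# Wilson spectral matrix factorization: S(f) = H(f) Sigma H(f)^dagger
# ---------------------------------------------------------------------------


class FactorizationError(RuntimeError):
    """Wilson iteration failed to converge; ``trace`` holds the error path."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


def _plus_operator(g: np.ndarray) -> np.ndarray:
    """Causal part of a two-sided spectral function (freq axis first):
    zero the negative-lag coefficients, halve and upper-triangularise the
    zero-lag coefficient."""
    nfft = g.shape[0]
    gam = np.fft.ifft(g, axis=0)
    beta0 = 0.5 * gam[0]
    gam[0] = np.triu(beta0)
    gam[nfft // 2 + 1:] = 0.0
    return np.fft.fft(gam, axis=0)


def wilson_factorize(S: np.ndarray, tol: float = 1e-8, max_iter: int = 100):
    """Factorize a one-sided CSD array (n_freqs, n, n) sampled on a uniform
    grid from 0 to Nyquist into a minimum-phase transfer function H and
    innovation covariance Sigma with S = H Sigma H^dagger.

    Raises :class:`FactorizationError` if the iteration does not converge
    within ``max_iter`` steps.
    """
    S = np.asarray(S, dtype=complex)
    nf, n, _ = S.shape
    nfft = 2 * (nf - 1)
    # two-sided extension, S(-f) = conj(S(f))
    S2 = np.empty((nfft, n, n), dtype=complex)
    S2[:nf] = S
    S2[nf:] = np.conj(S[-2:0:-1])

    gamma0 = np.real(np.fft.ifft(S2, axis=0)[0])
    try:
        psi0 = np.linalg.cholesky(gamma0).conj().T  # upper triangular
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(gamma0)
        psi0 = (V * np.sqrt(np.clip(w, 1e-12, None))) @ V.conj().T
    psi = np.broadcast_to(psi0.astype(complex), (nfft, n, n)).copy()

    I = np.eye(n)
    errs = []
    for _ in range(max_iter):
        psi_inv = np.linalg.inv(psi)
        g = psi_inv @ S2 @ np.conj(np.transpose(psi_inv, (0, 2, 1))) + I
        gp = _plus_operator(g)
        psi_new = psi @ gp
        err = np.max(np.abs(psi_new - psi)) / max(np.max(np.abs(psi)), 1e-300)
        errs.append(err)
        psi = psi_new
        if err < tol:
            break
        # the iteration converges to a floor set by the finite frequency
        # grid; accept a plateau provided it is already small
        if len(errs) >= 10 and err > 0.99 * min(errs[:-9]):
            if err < 1e-2:
                break
            raise FactorizationError(
                f"Wilson factorization stalled at relative change {err:.2e}",
                errs,
            )
    else:
        raise FactorizationError(
            f"Wilson factorization did not converge in {max_iter} iterations "
            f"(last relative change {errs[-1]:.2e})",
            errs,
        )
    A0 = np.real(np.fft.ifft(psi, axis=0)[0])
    sigma = A0 @ A0.T
    H = psi[:nf] @ np.linalg.inv(A0)
    return H, sigma


# ---------------------------------------------------------------------------
# Granger causality
# ---------------------------------------------------------------------------


def _partial_var(sigma: np.ndarray, keep: int, given: list[int]) -> float:
    """sigma[keep, keep] partialled on the ``given`` indices."""
    if not given:
        return float(np.real(sigma[keep, keep]))
    Sgg = sigma[np.ix_(given, given)]
    Skg = sigma[keep, given]
    return float(
        np.real(sigma[keep, keep] - Skg @ np.linalg.solve(Sgg, Skg.conj()))
    )


def _bivariate_gc(S, H, sigma, x: int, y: int):
    """Geweke's unconditional spectral GC y -> x from a factorized system."""
    sxx = np.real(S[:, x, x])
    syy_px = _partial_var(sigma, y, [x])
    intrinsic = sxx - np.abs(H[:, x, y]) ** 2 * syy_px
    return np.log(sxx / np.clip(intrinsic, 1e-300, None))


def pairwise_spectral_gc(S: np.ndarray, tol: float = 1e-8,
                         max_iter: int = 100) -> np.ndarray:
    """Unconditional spectral GC for every ordered pair from one full
    factorization of the bivariate sub-spectra."""
    nf, n, _ = S.shape
    gc = np.zeros((n, n, nf))
    for i in range(n):
        for j in range(i + 1, n):
            sub = S[:, [i, j]][:, :, [i, j]]
            H, sig = wilson_factorize(sub, tol, max_iter)
            gc[j, i] = _bivariate_gc(sub, H, sig, 0, 1)
            gc[i, j] = _bivariate_gc(sub, H, sig, 1, 0)
    return gc


@dataclass
class SpectralGCResult:
    """Frequency-resolved conditional GC and derived hierarchy indices.

    ``gc[s, t, f]`` is the causality from series s to series t at
    frequency ``freqs[f]``; the diagonal is zero.  ``dai``, ``band_dai``
    and ``mdai`` are filled by :func:`dai_from_gc`.
    """

    labels: list[str]
    freqs: np.ndarray
    gc: np.ndarray
    conditional: bool
    dai: np.ndarray | None = None
    dai_zero_mask: np.ndarray | None = None
    band_dai: dict = field(default_factory=dict)
    mdai: np.ndarray | None = None

    def pair(self, s, t):
        return self.gc[self.labels.index(s), self.labels.index(t)]


def conditional_spectral_gc(
    x: np.ndarray,
    fs: float,
    labels=None,
    freq_max: float | None = None,
    segment_s: float = 1.0,
    bandwidth_hz: float = 4.0,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> SpectralGCResult:
    """Conditional spectral GC between all ordered pairs of columns of ``x``.

    For every ordered pair (s, t) the causality is conditioned on all
    remaining series: the full spectral matrix and the reduced matrix
    excluding s are each factorized (Wilson), the reduced transfer is
    embedded with an identity row for s and inverted against the full
    transfer, and the Geweke log-ratio is taken on the transformed system.
    With exactly two series the unconditional bivariate measure is
    returned.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[1]
    if labels is None:
        labels = [f"s{i}" for i in range(n)]
    if n < 2:
        raise ValueError("need at least two series")
    freqs, S = multitaper_csd(x, fs, segment_s, bandwidth_hz)
    if freq_max is not None:
        keep = freqs <= freq_max
        # keep the full grid for factorization; restrict output later
    H, sigma = wilson_factorize(S, tol, max_iter)
    nf = len(freqs)
    gc = np.zeros((n, n, nf))
    if n == 2:
        gc[1, 0] = _bivariate_gc(S, H, sigma, 0, 1)
        gc[0, 1] = _bivariate_gc(S, H, sigma, 1, 0)
    else:
        for s in range(n):
            rest = [i for i in range(n) if i != s]
            Sr = S[:, rest][:, :, rest]
            G, sigma_r = wilson_factorize(Sr, tol, max_iter)
            # embed the reduced transfer with an identity row/column for s
            Gbar = np.zeros((nf, n, n), dtype=complex)
            Gbar[:, s, s] = 1.0
            Gbar[:, np.ix_(rest, rest)[0], np.ix_(rest, rest)[1]] = G
            Q = np.linalg.solve(Gbar, H)
            Sq = Q @ sigma @ np.conj(np.transpose(Q, (0, 2, 1)))
            for t_pos, t in enumerate(rest):
                syy_p = _partial_var(sigma, s, rest)
                total = np.real(Sq[:, t, t])
                intrinsic = total - np.abs(Q[:, t, s]) ** 2 * syy_p
                gc[s, t] = np.log(
                    np.clip(total, 1e-300, None)
                    / np.clip(intrinsic, 1e-300, None)
                )
    gc = np.clip(gc, 0.0, None)
    if freq_max is not None:
        freqs, gc = freqs[keep], gc[:, :, keep]
    return SpectralGCResult([str(l) for l in labels], freqs, gc, n > 2)


# ---------------------------------------------------------------------------
# parametric VAR route (exact spectra for oracles and cross-checks)
# ---------------------------------------------------------------------------


def var_spectral_matrix(coefs: np.ndarray, sigma: np.ndarray, freqs, fs: float):
    """Exact spectral matrix and transfer function of a VAR process.

    ``coefs`` has shape (p, n, n) with x_t = sum_k A_k x_{t-k} + e_t.
    Returns (S, H) on the given frequency grid.
    """
    coefs = np.asarray(coefs, dtype=float)
    p, n, _ = coefs.shape
    freqs = np.asarray(freqs, dtype=float)
    z = np.exp(-2j * np.pi * np.outer(freqs, np.arange(1, p + 1)) / fs)
    A = np.eye(n) - np.einsum("fk,kij->fij", z, coefs)
    H = np.linalg.inv(A)
    S = H @ sigma @ np.conj(np.transpose(H, (0, 2, 1))) / fs
    return S, H


def var_spectral_gc(coefs, sigma, freqs, fs, source: int, target: int):
    """Closed-form unconditional spectral GC source -> target of a known
    bivariate VAR (Geweke), for use as an oracle."""
    _, H = var_spectral_matrix(coefs, sigma, freqs, fs)
    sub = [target, source]
    sigma_sub = np.asarray(sigma, dtype=float)[np.ix_(sub, sub)]
    Hsub = H[:, sub][:, :, sub]
    # spectrum on the same scale as sigma (the common factor cancels in GC)
    Ssub = Hsub @ sigma_sub @ np.conj(np.transpose(Hsub, (0, 2, 1)))
    return _bivariate_gc(Ssub, Hsub, sigma_sub, 0, 1)


# ---------------------------------------------------------------------------
# DAI / mDAI
# ---------------------------------------------------------------------------


def _band_average(values: np.ndarray, freqs: np.ndarray, band) -> np.ndarray:
    lo, hi = band
    sel = (freqs >= lo) & (freqs <= hi)
    if not sel.any():
        raise ValueError(f"no frequencies inside band {band}")
    return values[..., sel].mean(axis=-1)


def dai_from_gc(result: SpectralGCResult, alpha_band=ALPHA_BAND,
                gamma_band=GAMMA_BAND) -> SpectralGCResult:
    """Fill the DAI spectrum, band DAIs and mDAI on a GC result.

    Frequencies where both directional GCs vanish get DAI = 0 and are
    flagged in ``dai_zero_mask``.  Band DAI is the average of the DAI
    spectrum over the band (the normalisation keeps it in [-1, 1] and is
    immaterial for correlations).
    """
    gc = result.gc
    num = gc - np.transpose(gc, (1, 0, 2))
    den = gc + np.transpose(gc, (1, 0, 2))
    zero = den <= 0
    dai = np.where(zero, 0.0, num / np.where(zero, 1.0, den))
    band_dai = {
        "alpha": _band_average(dai, result.freqs, alpha_band),
        "gamma": _band_average(dai, result.freqs, gamma_band),
    }
    result.dai = dai
    result.dai_zero_mask = zero
    result.band_dai = band_dai
    result.mdai = (band_dai["gamma"] - band_dai["alpha"]) / 2.0
    return result


def frequency_correlation(edge_values: np.ndarray, result: SpectralGCResult,
                          what: str = "dai"):
    """Spearman rank correlation, per frequency, between a per-edge scalar
    and the DAI (or GC) across ordered pairs.

    ``edge_values`` is an (n, n) matrix with NaN where a pair should be
    skipped.  Returns (freqs, r, p).
    """
    arr = result.dai if what == "dai" else result.gc
    if arr is None:
        raise ValueError("run dai_from_gc first")
    n = len(result.labels)
    pairs = [
        (i, j)
        for i in range(n)
        for j in range(n)
        if i != j and np.isfinite(edge_values[i, j])
    ]
    if len(pairs) < 4:
        raise ValueError("need at least 4 ordered pairs for a correlation")
    xv = np.array([edge_values[i, j] for i, j in pairs])
    r = np.empty(len(result.freqs))
    p = np.empty(len(result.freqs))
    for k in range(len(result.freqs)):
        yv = np.array([arr[i, j, k] for i, j in pairs])
        r[k], p[k] = stats.spearmanr(xv, yv)
    return result.freqs, r, p
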