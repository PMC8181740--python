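import numpy as np
import pytest

from counterstream import (
    ALPHA_BAND,
    GAMMA_BAND,
    SpectralGCResult,
    conditional_spectral_gc,
    dai_from_gc,
    frequency_correlation,
    multitaper_csd,
    pairwise_spectral_gc,
    var_spectral_gc,
    var_spectral_matrix,
    wilson_factorize,
)

FS = 200.0


def oscillatory_var(n, couplings, seed=0, T=60000, a1=0.55, a2=-0.8):
    """Simulate a VAR(2) of damped oscillators with given directed
    couplings {(source, target): strength} at lag 1."""
    A = np.zeros((2, n, n))
    for i in range(n):
        A[0, i, i], A[1, i, i] = a1, a2
    for (s, t), c in couplings.items():
        A[0, t, s] = c
    rng = np.random.default_rng(seed)
    x = np.zeros((T, n))
    e = rng.standard_normal((T, n))
    for t in range(2, T):
        x[t] = A[0] @ x[t - 1] + A[1] @ x[t - 2] + e[t]
    return A, x[2000:]


class TestWilsonFactorization:
    def test_exact_var_spectrum_recovered(self):
        A, _ = oscillatory_var(2, {(0, 1): 0.5}, T=10)
        freqs = np.linspace(0, FS / 2, 129)
        S, _ = var_spectral_matrix(A, np.eye(2), freqs, FS)
        H, sigma = wilson_factorize(S)
        rec = H @ sigma @ np.conj(np.transpose(H, (0, 2, 1)))
        assert np.max(np.abs(rec - S)) < 1e-5
        # innovations recovered up to the 1/fs spectral scaling
        assert np.allclose(sigma * FS, np.eye(2), atol=1e-4)

    def test_sigma_hermitian_positive(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((20000, 3))
        _, S = multitaper_csd(x, FS, segment_s=2.0)
        _, sigma = wilson_factorize(S)
        assert np.allclose(sigma, sigma.T, atol=1e-10)
        assert np.all(np.linalg.eigvalsh(sigma) > 0)


class TestConditionalSpectralGC:
    def test_independent_noise_has_near_zero_gc(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((40000, 3))
        res = conditional_spectral_gc(x, FS, segment_s=2.0)
        assert res.gc.mean(axis=2).max() < 0.01
        assert np.all(res.gc >= 0)

    def test_longer_series_shrinks_noise_floor(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((80000, 3))
        short = conditional_spectral_gc(x[:20000], FS, segment_s=2.0)
        long = conditional_spectral_gc(x, FS, segment_s=2.0)
        assert long.gc.mean() < short.gc.mean()

    def test_bivariate_matches_var_oracle_in_band(self):
        A, x = oscillatory_var(2, {(0, 1): 0.5}, seed=4, T=122000)
        res = conditional_spectral_gc(
            x, FS, labels=["x", "y"], segment_s=5.0, bandwidth_hz=1.0
        )
        oracle = var_spectral_gc(A, np.eye(2), res.freqs, FS, source=0, target=1)
        band = (res.freqs > 5) & (res.freqs < 60)
        est = res.pair("x", "y")
        assert est[band].mean() == pytest.approx(oracle[band].mean(), rel=0.10)
        # no causality in the reverse direction
        assert res.pair("y", "x").mean() < 0.01

    def test_geweke_identity_within_five_percent(self):
        """The frequency average of spectral GC matches time-domain GC
        estimated independently by OLS AR fits."""
        A, x = oscillatory_var(2, {(0, 1): 0.5}, seed=5, T=122000)
        res = conditional_spectral_gc(
            x, FS, labels=["x", "y"], segment_s=5.0, bandwidth_hz=1.0
        )
        f_avg = res.pair("x", "y").mean()

        def ar_residual_var(y_t, pasts, p=30):
            cols = [np.ones(len(y_t) - p)]
            for past in pasts:
                for k in range(1, p + 1):
                    cols.append(past[p - k : len(y_t) - k])
            X = np.column_stack(cols)
            tgt = y_t[p:]
            beta, *_ = np.linalg.lstsq(X, tgt, rcond=None)
            return np.var(tgt - X @ beta)

        v_red = ar_residual_var(x[:, 1], [x[:, 1]])
        v_full = ar_residual_var(x[:, 1], [x[:, 1], x[:, 0]])
        f_time = np.log(v_red / v_full)
        assert f_avg == pytest.approx(f_time, rel=0.05)

    def test_chain_conditional_suppresses_mediated_link(self):
        """x -> y -> z: conditional GC(x -> z | y) vanishes while pairwise
        GC(x -> z) stays clearly positive."""
        _, x = oscillatory_var(3, {(0, 1): 0.5, (1, 2): 0.5}, seed=6, T=62000)
        res = conditional_spectral_gc(x, FS, labels=list("xyz"), segment_s=2.0,
                                      bandwidth_hz=3.0)
        _, S = multitaper_csd(x, FS, segment_s=2.0, bandwidth_hz=3.0)
        pw = pairwise_spectral_gc(S)
        assert pw[0, 2].mean() > 0.05
        assert res.pair("x", "z").mean() < 0.2 * pw[0, 2].mean()
        assert res.pair("x", "y").mean() > 0.05
        assert res.pair("y", "z").mean() > 0.05

    def test_single_series_rejected(self):
        with pytest.raises(ValueError):
            conditional_spectral_gc(np.zeros((1000, 1)), FS)


class TestDAI:
    def synthetic_result(self, gc):
        nf = gc.shape[2]
        return SpectralGCResult(
            labels=["a", "b"],
            freqs=np.linspace(0, 100, nf),
            gc=gc,
            conditional=False,
        )

    def test_symmetric_gc_gives_zero_dai(self):
        gc = np.ones((2, 2, 50))
        gc[0, 0] = gc[1, 1] = 0
        res = dai_from_gc(self.synthetic_result(gc))
        assert np.allclose(res.dai, 0.0)
        assert np.allclose(res.mdai, 0.0)

    def test_three_to_one_ratio_gives_half(self):
        gc = np.zeros((2, 2, 50))
        gc[0, 1] = 3.0
        gc[1, 0] = 1.0
        res = dai_from_gc(self.synthetic_result(gc))
        assert np.allclose(res.dai[0, 1], 0.5)
        assert np.allclose(res.dai[1, 0], -0.5)

    def test_mdai_combines_gamma_and_inverted_alpha(self):
        nf = 101
        freqs = np.linspace(0, 100, nf)
        gc = np.zeros((2, 2, nf))
        alpha = (freqs >= ALPHA_BAND[0]) & (freqs <= ALPHA_BAND[1])
        gamma = (freqs >= GAMMA_BAND[0]) & (freqs <= GAMMA_BAND[1])
        # direction a->b: DAI = +0.6 in gamma, -0.4 in alpha
        gc[0, 1, gamma] = 4.0
        gc[1, 0, gamma] = 1.0
        gc[0, 1, alpha] = 3.0
        gc[1, 0, alpha] = 7.0
        res = SpectralGCResult(["a", "b"], freqs, gc, False)
        res = dai_from_gc(res)
        assert res.band_dai["gamma"][0, 1] == pytest.approx(0.6)
        assert res.band_dai["alpha"][0, 1] == pytest.approx(-0.4)
        assert res.mdai[0, 1] == pytest.approx(0.5)

    def test_exact_antisymmetry(self):
        rng = np.random.default_rng(7)
        gc = rng.random((4, 4, 64))
        for i in range(4):
            gc[i, i] = 0
        res = dai_from_gc(
            SpectralGCResult(list("abcd"), np.linspace(0, 100, 64), gc, True)
        )
        assert np.array_equal(res.dai, -np.transpose(res.dai, (1, 0, 2)))
        assert np.allclose(res.mdai, -res.mdai.T)
        assert np.all(np.abs(res.dai) <= 1.0)

    def test_zero_denominator_flagged(self):
        gc = np.zeros((2, 2, 10))
        res = dai_from_gc(self.synthetic_result(gc))
        assert np.allclose(res.dai, 0.0)
        assert res.dai_zero_mask[0, 1].all()


class TestFrequencyCorrelation:
    def test_identical_scalar_gives_perfect_rank_correlation(self):
        rng = np.random.default_rng(8)
        gc = rng.random((4, 4, 8))
        res = dai_from_gc(
            SpectralGCResult(list("abcd"), np.linspace(1, 80, 8), gc, True)
        )
        edge = res.dai[:, :, 3].copy()
        f, r, p = frequency_correlation(edge, res)
        assert r[3] == pytest.approx(1.0)

    def test_too_few_pairs_rejected(self):
        gc = np.zeros((2, 2, 4))
        res = dai_from_gc(
            SpectralGCResult(["a", "b"], np.linspace(1, 50, 4), gc, False)
        )
        edge = np.full((2, 2), np.nan)
        edge[0, 1] = 1.0
        with pytest.raises(ValueError, match="4"):
            frequency_correlation(edge, res)

    def test_permuted_scalar_uncorrelated(self):
        rng = np.random.default_rng(9)
        gc = rng.random((6, 6, 5))
        res = dai_from_gc(
            SpectralGCResult(list("abcdef"), np.linspace(1, 50, 5), gc, True)
        )
        rs = []
        for _ in range(100):
            edge = rng.normal(size=(6, 6))
            _, r, p = frequency_correlation(edge, res)
            rs.append(np.abs(r).mean())
        assert np.mean(rs) < 0.25
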