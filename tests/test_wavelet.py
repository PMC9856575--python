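import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from coiscal.wavelet import (
    COIBoundary,
    FrequencyGrid,
    Signal,
    WaveletParams,
    compute_coi,
    convolve,
    cwt_scalogram,
    morlet,
    quality_beta,
    quality_rho,
    wavelet_footprint,
)


def direct_convolution(x, h):
    """Brute-force full convolution sum (independent oracle)."""
    n, ell = len(x), len(h)
    out = np.zeros(n + ell - 1, dtype=np.result_type(x, h))
    for i in range(n):
        for j in range(ell):
            out[i + j] += x[i] * h[j]
    return out


class TestMorlet:
    def test_value_at_zero_is_real_envelope_peak(self, params):
        t = np.linspace(-1, 1, 401)
        psi = morlet(t, params, 10.0)
        peak = psi[200]
        assert peak.imag == pytest.approx(0.0, abs=1e-12)
        assert peak.real == pytest.approx(np.abs(psi).max())

    def test_envelope_is_even(self, params):
        t = np.linspace(-0.5, 0.5, 201)
        psi = morlet(t, params, 12.0)
        assert np.allclose(np.abs(psi), np.abs(psi[::-1]))

    @pytest.mark.parametrize("f0,cycles", [(5.0, 3.0), (10.0, 6.0), (37.0, 7.5)])
    def test_unit_energy(self, f0, cycles):
        params = WaveletParams(cycles=cycles)
        half = 5 * params.sigma_t(f0)
        t = np.arange(-half, half, 1e-4)
        psi = morlet(t, params, f0)
        energy = np.sum(np.abs(psi) ** 2) * 1e-4
        assert energy == pytest.approx(1.0, rel=1e-6)

    def test_invalid_parameters_raise(self, params):
        with pytest.raises(ValueError):
            morlet(np.linspace(-1, 1, 11), params, -1.0)
        with pytest.raises(ValueError):
            WaveletParams(cycles=0.0)
        with pytest.raises(ValueError):
            WaveletParams(truncation="nope")


class TestConvolve:
    def test_hand_example_full_and_valid(self):
        # oracle: direct convolution sum by hand
        assert convolve([1, 2, 3], [1, 1], "full").tolist() == [1, 3, 5, 3]
        assert convolve([1, 2, 3], [1, 1], "valid").tolist() == [3, 5]

    @pytest.mark.parametrize("mode", ["full", "same", "valid"])
    def test_identity_kernel(self, mode, rng):
        x = rng.standard_normal(17)
        assert np.allclose(convolve(x, [1.0], mode), x)

    @given(
        x=hnp.arrays(float, st.integers(2, 30),
                     elements=st.floats(-10, 10)),
        h=hnp.arrays(float, st.integers(1, 10),
                     elements=st.floats(-10, 10)),
    )
    @settings(max_examples=50, deadline=None)
    def test_mode_algebra_against_direct_sum(self, x, h):
        full = direct_convolution(x, h)
        n, ell = len(x), len(h)
        assert np.allclose(convolve(x, h, "full"), full, atol=1e-9)
        start = (ell - 1) // 2
        assert np.allclose(convolve(x, h, "same"), full[start : start + n])
        if ell <= n:
            assert np.allclose(convolve(x, h, "valid"), full[ell - 1 : n])

    def test_valid_longer_kernel_raises(self):
        with pytest.raises(ValueError):
            convolve([1, 2], [1, 2, 3], "valid")


class TestScalogram:
    def test_same_mode_shape(self, small_grid, params, rng):
        sig = Signal(rng.standard_normal(100), 100.0)
        W, scal = cwt_scalogram(sig, small_grid, params)
        assert W.W.shape == (small_grid.J, 100)
        assert scal.G.shape == (small_grid.J, 100)

    def test_all_zero_signal(self, small_grid, params):
        _, scal = cwt_scalogram(Signal(np.zeros(64), 100.0), small_grid, params)
        assert np.all(scal.G == 0)

    def test_power_is_amplitude_squared(self, small_grid, params, rng):
        sig = Signal(rng.standard_normal(80), 100.0)
        _, power = cwt_scalogram(sig, small_grid, params, kind="power")
        _, amp = cwt_scalogram(sig, small_grid, params, kind="amplitude")
        assert np.allclose(power.G, amp.G**2)

    def test_doubling_amplitude_quadruples_power(self, small_grid, params, rng):
        x = rng.standard_normal(80)
        _, g1 = cwt_scalogram(Signal(x, 100.0), small_grid, params)
        _, g2 = cwt_scalogram(Signal(2 * x, 100.0), small_grid, params)
        assert np.allclose(g2.G, 4 * g1.G)

    def test_sinusoid_peaks_at_nearest_band(self, small_grid, params):
        f_star = float(small_grid.frequencies[10])
        t = np.arange(300) / 100.0
        sig = Signal(np.sin(2 * np.pi * f_star * t), 100.0)
        _, scal = cwt_scalogram(sig, small_grid, params)
        coi = compute_coi(small_grid, sig.n, sig.fs, params)
        mask = coi.mask().astype(bool)
        mean_power = np.array(
            [
                scal.G[f][mask[f]].mean() if mask[f].any() else -np.inf
                for f in range(small_grid.J)
            ]
        )
        # unit-energy normalization: band response scales with sqrt(sigma),
        # so compare per-band response relative to white-noise calibration
        best = int(np.argmax(mean_power))
        nearest = int(np.argmin(np.abs(small_grid.frequencies - f_star)))
        assert best == nearest

    def test_aliasing_band_raises(self, params):
        grid = FrequencyGrid(np.array([10.0, 80.0]))
        with pytest.raises(ValueError, match="alias"):
            cwt_scalogram(Signal(np.zeros(50), 100.0), grid, params)

    def test_coi_valid_equivalence(self, small_grid, params, rng):
        """In-COI same-mode coefficients equal valid-mode outputs."""
        from coiscal.wavelet import _band_kernel

        sig = Signal(rng.standard_normal(100), 100.0)
        W, _ = cwt_scalogram(sig, small_grid, params, "same")
        coi = compute_coi(small_grid, sig.n, sig.fs, params)
        f_ref = float(np.max(small_grid.frequencies))
        for f, f0 in enumerate(small_grid.frequencies):
            if coi.Nf[f] == 0:
                continue
            kernel = _band_kernel(float(f0), sig.fs, params)
            valid = convolve(sig.samples, np.conj(kernel[::-1]), "valid")
            valid = valid / np.sqrt(f_ref / float(f0))
            inside = W.W[f, coi.n_start[f] : coi.n_end[f]]
            assert np.allclose(inside, valid, rtol=1e-9)


class TestCOI:
    def test_pointlike_footprint_full_row(self):
        coi = COIBoundary.from_counts([10], 10)  # Nf = N -> L = 1
        assert coi.footprint[0] == 1
        assert coi.Nf[0] == 10

    def test_footprint_four_gives_seven(self, params):
        # oracle: length of valid convolution with a length-4 kernel
        coi = COIBoundary.from_counts([7], 10)
        assert coi.footprint[0] == 4
        assert len(convolve(np.zeros(10), np.zeros(4), "valid")) == 7

    def test_nf_monotone_in_frequency(self, small_grid, params):
        coi = compute_coi(small_grid, 100, 100.0, params)
        # ascending frequencies -> footprints shrink -> Nf non-decreasing
        assert np.all(np.diff(coi.Nf) >= 0)

    def test_oversized_footprint_gives_empty_interval(self, params):
        grid = FrequencyGrid(np.array([0.5]))  # enormous footprint
        coi = compute_coi(grid, 10, 100.0, params)
        assert coi.Nf[0] == 0

    def test_valid_interval_matches_valid_length(self, small_grid, params):
        N = 100
        coi = compute_coi(small_grid, N, 100.0, params)
        for f in range(small_grid.J):
            L = wavelet_footprint(
                float(small_grid.frequencies[f]), 100.0, params
            )
            assert coi.Nf[f] == max(0, N - L + 1)


class TestQualityRatios:
    def test_rho_hand_count(self):
        coi = COIBoundary.from_counts([4, 2, 0], 4)
        assert quality_rho(coi) == pytest.approx(6 / 12)

    def test_rho_full_coverage(self):
        coi = COIBoundary.from_counts([8, 8, 8], 8)
        assert quality_rho(coi) == 1.0

    def test_rho_grows_with_n(self, small_grid, params):
        rhos = [
            quality_rho(compute_coi(small_grid, n, 100.0, params))
            for n in (100, 400, 1600, 6400)
        ]
        assert all(b > a for a, b in zip(rhos, rhos[1:]))
        assert rhos[-1] > 0.95

    def test_rho_empty_raises(self):
        coi = COIBoundary.from_counts([1], 1)
        with pytest.raises(ValueError):
            quality_rho(coi, J=0, N=0)

    def test_beta_all_power_inside(self, rng):
        coi = COIBoundary.from_counts([6, 6], 6)
        W = rng.standard_normal((2, 6))
        assert quality_beta(W, coi) == pytest.approx(1.0)

    def test_beta_zero_outside_coi(self):
        coi = COIBoundary.from_counts([4, 4], 6)
        W = np.ones((2, 6)) * coi.mask()
        assert quality_beta(W, coi) == pytest.approx(1.0)

    def test_beta_toy_matrix_direct_sums(self):
        # 2x3 matrix, 1-sample exclusion per row, brute-force oracle
        coi = COIBoundary(
            np.array([1, 1]), np.array([3, 3]), np.array([2, 2]), 3
        )
        W = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        inside = 2.0**2 + 3.0**2 + 5.0**2 + 6.0**2
        total = (W**2).sum()
        assert quality_beta(W, coi) == pytest.approx(inside / total)

    def test_beta_zero_power_warns(self):
        coi = COIBoundary.from_counts([3], 4)
        with pytest.warns(RuntimeWarning):
            assert quality_beta(np.zeros((1, 4)), coi) == 0.0

    def test_beta_shape_mismatch_raises(self, rng):
        coi = COIBoundary.from_counts([3], 4)
        with pytest.raises(ValueError):
            quality_beta(rng.standard_normal((2, 4)), coi)


class TestSignalValidation:
    def test_too_short(self):
        with pytest.raises(ValueError):
            Signal(np.array([1.0]), 100.0)

    def test_nonfinite(self):
        with pytest.raises(ValueError):
            Signal(np.array([1.0, np.nan]), 100.0)

    def test_grid_monotonicity(self):
        with pytest.raises(ValueError):
            FrequencyGrid(np.array([1.0, 3.0, 2.0]))
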