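"""Mexican-hat CWT, scale/frequency mapping, and scalogram rendering."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.signal import find_peaks

import afwave
from afwave.errors import ConfigError
from afwave.timefreq import (
    MEXH_CENTER_FREQUENCY,
    ScaleGrid,
    Scalogram,
    cwt,
    frequency_to_scale,
    mexh,
    render_scalogram,
    scale_to_frequency,
)


class TestMexh:
    def test_zeros_at_plus_minus_one(self):
        np.testing.assert_allclose(mexh(np.array([-1.0, 1.0])), 0.0, atol=1e-15)

    def test_value_at_origin(self):
        assert mexh(0.0) == pytest.approx(2.0 / (np.sqrt(3.0) * np.pi**0.25), abs=1e-12)

    def test_zero_mean_by_quadrature(self):
        integral, _ = quad(mexh, -8, 8)
        assert abs(integral) < 1e-6

    def test_even_symmetry(self, rng):
        t = rng.normal(size=100)
        np.testing.assert_allclose(mexh(t), mexh(-t))

    def test_toolbox_center_frequency_convention(self):
        pywt = pytest.importorskip("pywt")
        assert pywt.central_frequency("mexh") == pytest.approx(
            MEXH_CENTER_FREQUENCY, abs=1e-6
        )


class TestScaleFrequencyMap:
    def test_direct_substitution(self):
        assert scale_to_frequency(7.5, Fc=0.25, fs=300.0) == pytest.approx(10.0)

    def test_doubling_scale_halves_frequency(self):
        f1 = scale_to_frequency(4.0, fs=100.0)
        f2 = scale_to_frequency(8.0, fs=100.0)
        assert f1 == pytest.approx(2 * f2)

    def test_inverse_map_roundtrip(self, rng):
        a = rng.uniform(0.5, 100, size=20)
        back = frequency_to_scale(scale_to_frequency(a, fs=300.0), fs=300.0)
        np.testing.assert_allclose(back, a)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ConfigError):
            scale_to_frequency(0.0)

    def test_grid_frequencies_monotone_decreasing_in_scale(self):
        grid = ScaleGrid.log_spaced(fs=300.0, n_scales=16)
        assert np.all(np.diff(grid.scales) > 0)
        assert np.all(np.diff(grid.pseudo_frequencies) < 0)


def _riemann_cwt(x, scales):
    """Brute-force evaluation of T(a,b) = (1/sqrt(a)) sum_j x[j] psi((j-b)/a)."""
    n = len(x)
    j = np.arange(n)
    rows = []
    for a in scales:
        M = mexh((j[None, :] - j[:, None]) / a) / np.sqrt(a)
        rows.append(M @ x)
    return np.array(rows)


class TestCwt:
    def test_constant_signal_transforms_to_zero(self):
        grid = ScaleGrid.log_spaced(fs=300.0, n_scales=8, fmin=5, fmax=50)
        s = cwt(np.full(512, 3.7), grid)
        assert np.abs(s.signed).max() < 1e-6

    def test_linearity_of_signed_coefficients(self, rng):
        grid = ScaleGrid.log_spaced(fs=300.0, n_scales=8, fmin=5, fmax=50)
        x, y = rng.normal(size=(2, 400))
        lhs = cwt(x + y, grid).signed
        rhs = cwt(x, grid).signed + cwt(y, grid).signed
        np.testing.assert_allclose(lhs, rhs, atol=1e-6)

    def test_matches_riemann_sum_oracle(self, rng):
        """Signed coefficients equal the brute-force sum at time points more
        than one kernel support from either edge."""
        grid = ScaleGrid.log_spaced(fs=300.0, n_scales=12, fmin=5, fmax=50)
        for _ in range(5):
            x = rng.normal(size=256)
            impl = cwt(x, grid).signed
            ref = _riemann_cwt(x, grid.scales)
            for i, a in enumerate(grid.scales):
                m = int(np.ceil(8 * a))
                sl = slice(m, 256 - m)
                denom = np.maximum(np.abs(ref[i, sl]), 1e-3 * np.abs(ref[i]).max())
                rel = np.abs(impl[i, sl] - ref[i, sl]) / denom
                assert rel.max() <= 1e-3

    def test_time_shift_covariance(self, rng):
        grid = ScaleGrid.log_spaced(fs=300.0, n_scales=6, fmin=10, fmax=50)
        x = rng.normal(size=600)
        k = 40
        shifted = np.roll(x, k)
        a_max = grid.scales.max()
        m = int(np.ceil(8 * a_max)) + k
        orig = cwt(x, grid).signed
        shif = cwt(shifted, grid).signed
        np.testing.assert_allclose(
            shif[:, m : 600 - m], orig[:, m - k : 600 - m - k], atol=1e-8
        )

    def test_sinusoid_peak_scale_matches_prediction(self):
        """argmax-scale of mean |T| for a pure tone lands within one grid step
        of a = Fc * fs / f0."""
        fs = 300.0
        grid = ScaleGrid.log_spaced(fs=fs, n_scales=64, fmin=1, fmax=50)
        t = np.arange(int(10 * fs)) / fs
        for f0 in (5.0, 10.0, 20.0):
            s = cwt(np.sin(2 * np.pi * f0 * t), grid)
            i_peak = int(s.coefficients.mean(axis=1).argmax())
            i_pred = int(np.abs(grid.scales - frequency_to_scale(f0, fs=fs)).argmin())
            assert abs(i_peak - i_pred) <= 1

    def test_agrees_with_pywavelets_on_shape_of_rows(self, rng):
        """Independent cross-check: per-scale coefficient patterns correlate
        > 0.99 with PyWavelets' mexh CWT (conventions differ only by scale-
        dependent gain, which correlation ignores)."""
        pywt = pytest.importorskip("pywt")
        # moderate scales only: pywt's integrated-wavelet approximation is
        # coarse below a ~ 4, and very large scales leave no interior here
        grid = ScaleGrid.log_spaced(fs=300.0, n_scales=6, fmin=5, fmax=18)
        x = rng.normal(size=512)
        ours = cwt(x, grid).signed
        theirs, _ = pywt.cwt(x, grid.scales, "mexh")
        for i, a in enumerate(grid.scales):
            m = int(np.ceil(8 * a))
            r = np.corrcoef(ours[i, m:-m], theirs[i, m:-m])[0, 1]
            assert r > 0.99

    def test_empty_scale_grid_rejected(self):
        with pytest.raises(ConfigError):
            ScaleGrid(scales=np.array([]), pseudo_frequencies=np.array([]), fs=300.0)


class TestRenderScalogram:
    def _scalogram(self, mat):
        mat = np.asarray(mat, dtype=float)
        n_sc, n_t = mat.shape
        grid = ScaleGrid.log_spaced(fs=300.0, n_scales=n_sc, fmin=1, fmax=50)
        return Scalogram(
            signed=np.asarray(mat, dtype=float),
            scale_grid=grid,
            time_axis=np.arange(n_t) / 300.0,
        )

    def test_minmax_identity_on_binary_matrix(self):
        s = self._scalogram([[0.0, 1.0], [1.0, 0.0]])
        out = render_scalogram(s, (2, 2))
        np.testing.assert_allclose(out.pixels, [[0, 1], [1, 0]])

    def test_output_spans_zero_to_one(self, rng):
        # At the native size (no resampling) normalization is exact min 0 /
        # max 1; after resizing the range can only shrink within [0, 1].
        s = self._scalogram(rng.normal(size=(8, 40)))
        native = render_scalogram(s, (8, 40))
        assert native.pixels.min() == pytest.approx(0.0, abs=1e-12)
        assert native.pixels.max() == pytest.approx(1.0, abs=1e-12)
        resized = render_scalogram(s, (16, 16))
        assert resized.pixels.min() >= 0.0 and resized.pixels.max() <= 1.0

    def test_bilinear_upscale_preserves_corners(self):
        s = self._scalogram([[0.0, 0.2], [0.6, 1.0]])
        out = render_scalogram(s, (4, 4)).pixels
        corners = [out[0, 0], out[0, -1], out[-1, 0], out[-1, -1]]
        np.testing.assert_allclose(corners, [0.0, 0.2, 0.6, 1.0])
        # interior of a bilinear surface: center = mean of corners
        mid = np.interp(1.5, [0, 3], [0, 1])
        assert 0.0 < out[1, 1] < 1.0 and mid  # sanity on interpolation region

    def test_constant_matrix_renders_mid_gray(self):
        s = self._scalogram(np.full((4, 4), 2.0))
        np.testing.assert_allclose(render_scalogram(s, (3, 3)).pixels, 0.5)


class TestRhythmSignature:
    def test_af_ridge_intervals_more_irregular_than_normal(self):
        """On the max-energy scale row of the scalogram, QRS ridge peaks
        arrive irregularly for AF fixtures: their inter-arrival CV exceeds
        the normal fixtures' at the generator defaults."""

        def ridge_cv(trace):
            grid = ScaleGrid.log_spaced(fs=trace.fs, n_scales=32, fmin=1, fmax=50)
            s = cwt(trace, grid)
            row = s.coefficients[int(s.coefficients.mean(axis=1).argmax())]
            peaks, _ = find_peaks(
                row, distance=int(0.3 * trace.fs), height=0.5 * row.max()
            )
            gaps = np.diff(peaks)
            return gaps.std() / gaps.mean()

        for seed in range(3):
            nrm = afwave.generate_ecg(afwave.normal_spec(duration_s=30.0, seed=seed))
            afx = afwave.generate_ecg(afwave.af_spec(duration_s=30.0, seed=seed))
            assert ridge_cv(afx) > ridge_cv(nrm)
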