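"""Tests for Welch segmentation, cross-spectra, bispectra and bicoherence."""

import numpy as np
import pytest
from scipy import stats

import biqpc as bq
from biqpc.spectral import Sector, _extended_coeffs, nearest_power_of_two_fraction

from conftest import gaussian_series


class TestSegmentPlan:
    def test_power_of_two_resolution_rule(self):
        # 500 samples at 100 Hz: experimental 0.2 Hz -> bispectral 0.25 Hz
        plan = bq.SegmentPlan(fs=100.0, segment_length=500)
        assert plan.experimental_delta_f == pytest.approx(0.2)
        assert plan.delta_f == 0.25
        assert plan.dft_length == 400
        assert plan.f_nyquist == 50.0

    @pytest.mark.parametrize(
        "x, expected", [(0.2, 0.25), (0.3, 0.25), (1.0, 1.0), (0.7, 0.5), (3.0, 2.0)]
    )
    def test_nearest_fractional_power_of_two(self, x, expected):
        assert nearest_power_of_two_fraction(x) == expected

    @pytest.mark.parametrize(
        "n_epochs, expected_segments", [(128, 255), (1, 1), (2, 3)]
    )
    def test_sliding_segment_counts(self, plan, n_epochs, expected_segments):
        starts = plan.segment_starts(n_epochs * 500)
        assert len(starts) == expected_segments

    def test_record_shorter_than_segment_rejected(self, plan):
        with pytest.raises(ValueError):
            plan.segment_starts(400)


class TestCrossSpectrum:
    def test_auto_spectrum_real_nonnegative(self, plan, small_series):
        spectra = bq.segment_series(small_series, plan)
        c = bq.cross_spectrum(spectra, 0, 0)
        assert np.allclose(c.imag, 0)
        assert np.all(c.real >= 0)

    def test_hermitian_pair_symmetry(self, plan, small_series):
        spectra = bq.segment_series(small_series, plan)
        np.testing.assert_allclose(
            bq.cross_spectrum(spectra, 0, 1), np.conj(bq.cross_spectrum(spectra, 1, 0))
        )

    def test_independent_noise_decorrelates(self, plan):
        spectra = bq.segment_series(gaussian_series(0, n_epochs=100), plan)
        c01 = bq.cross_spectrum(spectra, 0, 1)
        c00 = bq.cross_spectrum(spectra, 0, 0)
        # magnitude coherence-like ratio shrinks as 1/sqrt(L)
        assert np.median(np.abs(c01) / np.abs(c00)) < 0.2


def _naive_bispectrum(coeffs, plan, i, j, k):
    """Triple-loop reference implementation of the cross-bispectrum."""
    L = coeffs.shape[0]
    m = plan.dft_length
    half = m // 2
    full = np.zeros((L, 3, m), dtype=complex)
    full[:, :, : half + 1] = coeffs
    for ch in range(3):
        for kk in range(half + 1, m):
            full[:, ch, kk] = np.conj(full[:, ch, m - kk])
    out = np.zeros((half, half), dtype=complex)
    for a in range(1, half + 1):
        for b in range(1, half + 1):
            acc = 0.0 + 0.0j
            for s in range(L):
                acc += full[s, i, a] * full[s, j, b] * np.conj(full[s, k, (a + b) % m])
            out[a - 1, b - 1] = acc / L
    return out


class TestCrossBispectrum:
    @pytest.fixture(scope="class")
    def tiny_spectra(self):
        rng = np.random.default_rng(11)
        series = bq.EpochedSeries(data=rng.normal(size=(3, 8, 32)), fs=32.0)
        plan = bq.SegmentPlan(fs=32.0, segment_length=32, delta_f=1.0, dft_length=32)
        return bq.segment_series(series, plan), plan

    def test_matches_naive_triple_loop(self, tiny_spectra):
        spectra, plan = tiny_spectra
        fast = bq.cross_bispectrum(spectra, 0, 1, 2)
        slow = _naive_bispectrum(spectra.coeffs, plan, 0, 1, 2)
        np.testing.assert_allclose(fast, slow, rtol=1e-10, atol=1e-12)

    def test_single_channel_reduces_to_bispectrum(self, tiny_spectra):
        spectra, plan = tiny_spectra
        fast = bq.cross_bispectrum(spectra, 1, 1, 1)
        slow = _naive_bispectrum(spectra.coeffs, plan, 1, 1, 1)
        np.testing.assert_allclose(fast, slow, rtol=1e-10, atol=1e-12)

    def test_gaussian_magnitude_shrinks_with_segments(self, plan):
        # the bispectrum of a linear Gaussian process vanishes as L grows
        small = bq.cross_bispectrum(bq.segment_series(gaussian_series(1, 8), plan), 0, 1, 2)
        large = bq.cross_bispectrum(bq.segment_series(gaussian_series(1, 128), plan), 0, 1, 2)
        assert np.mean(np.abs(large)) < 0.5 * np.mean(np.abs(small))

    def test_product_coupling_peaks_at_carrier_bifrequency(self):
        # noiseless X3 = X1 * X2 with cosine carriers: the product-to-sum
        # identity concentrates the bispectrum at (F1, F2)
        fs, n = 100.0, 500
        t = np.arange(64 * n) / fs
        rng = np.random.default_rng(2)
        f1, f2 = 8.0, 19.0
        phases = rng.uniform(0, 2 * np.pi, size=(2, 64))
        ph1 = np.repeat(phases[0], n)
        ph2 = np.repeat(phases[1], n)
        x1 = np.cos(2 * np.pi * f1 * t + ph1) + 0.05 * rng.normal(size=t.size)
        x2 = np.cos(2 * np.pi * f2 * t + ph2) + 0.05 * rng.normal(size=t.size)
        x3 = x1 * x2
        series = bq.EpochedSeries(
            data=np.stack([x1, x2, x3]).reshape(3, 64, n), fs=fs
        )
        plan = bq.SegmentPlan(fs=fs, segment_length=n)
        b = bq.cross_bispectrum(bq.segment_series(series, plan, per_epoch=True), 0, 1, 2)
        grid = bq.BifrequencyGrid.from_plan(plan)
        a, c = np.unravel_index(np.argmax(np.abs(b)), b.shape)
        assert grid.freqs[a] == pytest.approx(f1, abs=plan.delta_f)
        assert grid.freqs[c] == pytest.approx(f2, abs=plan.delta_f)


class TestCrossBicoherence:
    def test_bounded_by_one(self, plan, small_series):
        bmap = bq.cross_bicoherence(bq.segment_series(small_series, plan), 0, 1, 2)
        assert np.all(bmap.b2 >= 0)
        assert np.all(bmap.b2 <= 1 + 1e-12)

    def test_phase_locked_construction_saturates(self):
        # X3 carries the sum frequency with the summed phases: QPC locked
        fs, n, L = 64.0, 256, 32
        t = np.arange(n) / fs
        rng = np.random.default_rng(9)
        f1, f2 = 8.0, 12.0
        data = np.empty((3, L, n))
        for s in range(L):
            p1, p2 = rng.uniform(0, 2 * np.pi, 2)
            data[0, s] = np.cos(2 * np.pi * f1 * t + p1)
            data[1, s] = np.cos(2 * np.pi * f2 * t + p2)
            data[2, s] = np.cos(2 * np.pi * (f1 + f2) * t + p1 + p2)
        series = bq.EpochedSeries(data=data, fs=fs)
        plan = bq.SegmentPlan(fs=fs, segment_length=n, delta_f=0.25, dft_length=256)
        bmap = bq.cross_bicoherence(bq.segment_series(series, plan, per_epoch=True), 0, 1, 2)
        grid = bmap.grid
        assert bmap.b2[grid.nearest_index(f1), grid.nearest_index(f2)] >= 0.99

    def test_null_mean_scales_as_one_over_L(self, plan):
        spectra = bq.segment_series(gaussian_series(4, n_epochs=101), plan)
        bmap = bq.cross_bicoherence(spectra, 0, 1, 2)
        L = bmap.n_segments
        assert np.mean(bmap.values_in_domain()) == pytest.approx(1.0 / L, rel=0.2)

    def test_null_statistic_is_chi_square(self, plan):
        # 2 L b2 ~ chi2 with 2 dof for L independent segments under the null
        # (50 %-overlap segments are correlated and inflate the scale, which
        # is what the empirical-null mixture fit absorbs downstream)
        spectra = bq.segment_series(gaussian_series(8, n_epochs=200), plan, per_epoch=True)
        bmap = bq.cross_bicoherence(spectra, 0, 1, 2)
        vals = 2 * bmap.n_segments * bmap.values_in_domain()
        sub = vals[:: max(1, vals.size // 2000)]
        res = stats.kstest(sub, stats.chi2(df=2).cdf)
        assert res.pvalue > 0.01

    def test_invariant_to_per_epoch_rescaling(self):
        # per-segment standardization makes b2 scale-free
        base = gaussian_series(5, n_epochs=12)
        scales = np.random.default_rng(0).uniform(0.5, 5.0, size=12)
        scaled = bq.EpochedSeries(
            data=base.data * scales[None, :, None], fs=base.fs
        )
        plan = bq.SegmentPlan(fs=100.0, segment_length=500)
        b_base = bq.cross_bicoherence(bq.segment_series(base, plan, per_epoch=True), 0, 1, 2)
        b_scaled = bq.cross_bicoherence(bq.segment_series(scaled, plan, per_epoch=True), 0, 1, 2)
        np.testing.assert_allclose(b_base.b2, b_scaled.b2, rtol=1e-10)

    def test_extended_coeffs_hermitian(self, plan, small_series):
        spectra = bq.segment_series(small_series, plan)
        full = _extended_coeffs(spectra, 0)
        m = plan.dft_length
        for k in (1, 57, 199):
            np.testing.assert_allclose(full[:, m - k], np.conj(full[:, k]))


class TestSectors:
    @pytest.mark.parametrize(
        "f1, f2, expected",
        [
            (8.5, 10.5, Sector.Q1),  # worked-example bifrequency
            (48.4, 36.6, Sector.Q2),  # Q_II exemplar of the study
            (10.0, 45.0, Sector.Q3),
            (25.0, 25.0, Sector.Q1),  # boundary f1+f2 = Nyquist stays in Q_I
            (26.0, 26.0, Sector.Q3),  # equal frequencies above the boundary
        ],
    )
    def test_classification(self, f1, f2, expected):
        assert bq.classify_sector(f1, f2, 50.0) is expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bq.classify_sector(0.0, 10.0, 50.0)
        with pytest.raises(ValueError):
            bq.classify_sector(10.0, 51.0, 50.0)

    def test_sectors_partition_grid(self, plan):
        grid = bq.BifrequencyGrid.from_plan(plan)
        counts = [(grid.sectors == s).sum() for s in (1, 2, 3)]
        assert sum(counts) == grid.sectors.size == 200 * 200
        assert all(c > 0 for c in counts)
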