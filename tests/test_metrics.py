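import numpy as np
import pytest

from massshiftnet import MSIDataset, Spectrum
from massshiftnet.metrics import (
    SIGMA_MATCH,
    absolute_mass_error,
    background_intensity,
    low_matrix_mask,
    mass_dispersion,
    match_peak,
    mean_spectrum,
    top_peaks,
)

GRID = np.arange(600.0, 800.0, 0.01)


def gauss(mz, center, sigma=SIGMA_MATCH, height=1.0):
    return height * np.exp(-0.5 * ((mz - center) / sigma) ** 2)


def spectrum_with_peaks(centers, heights, sigma=SIGMA_MATCH, spot_id="s", grid=GRID):
    y = np.zeros_like(grid)
    for c, h in zip(centers, heights):
        y += gauss(grid, c, sigma, h)
    return Spectrum(grid, y, spot_id=spot_id)


class TestTopPeaks:
    def test_two_separated_gaussians_both_found(self):
        s = spectrum_with_peaks([650.0, 660.0], [1.0, 0.8])
        peaks = top_peaks(s, n=2)
        assert peaks.size == 2
        assert np.allclose(sorted(peaks), [650.0, 660.0], atol=0.02)

    def test_close_maxima_suppressed(self):
        s = spectrum_with_peaks([650.0, 651.0], [1.0, 0.7])
        peaks = top_peaks(s, n=5, window=3.0)
        assert peaks.size == 1
        assert abs(peaks[0] - 650.0) < 0.02

    def test_ranking_matches_true_amplitudes(self):
        rng = np.random.default_rng(0)
        centers = np.arange(610.0, 790.0, 3.5)
        heights = rng.uniform(0.1, 2.0, centers.size)
        s = spectrum_with_peaks(centers, heights)
        n = 20
        found = top_peaks(s, n=n)
        expected = np.sort(centers[np.argsort(heights)[::-1][:n]])
        np.testing.assert_allclose(found, expected, atol=0.02)


class TestMatchPeak:
    def test_matched_filter_finds_exact_center(self):
        s = spectrum_with_peaks([700.0], [2.0])
        obs = match_peak(s, 700.1)
        assert obs.present
        assert obs.found_mz == pytest.approx(700.0, abs=1e-3)

    def test_zero_spectrum_absent(self):
        s = Spectrum(GRID, np.zeros_like(GRID))
        obs = match_peak(s, 700.0)
        assert not obs.present

    def test_symmetric_tie_broken_to_lower_mz(self):
        s = spectrum_with_peaks([699.8, 700.2], [1.0, 1.0])
        obs = match_peak(s, 700.0)
        assert obs.present
        assert obs.found_mz < 700.0

    def test_target_outside_range_rejected(self):
        s = spectrum_with_peaks([700.0], [1.0])
        with pytest.raises(ValueError, match="outside"):
            match_peak(s, 900.0)

    def test_subgrid_refinement(self):
        # peak centered between grid points is located to sub-grid precision
        s = spectrum_with_peaks([700.0037], [1.0])
        obs = match_peak(s, 700.0)
        assert obs.found_mz == pytest.approx(700.0037, abs=2e-3)


class TestBackground:
    def test_constant_spectrum(self):
        s = Spectrum(GRID, np.full_like(GRID, 3.0))
        assert background_intensity(s, 700.0) == pytest.approx(3.0)

    def test_single_spike_ignored_by_median(self):
        y = np.zeros_like(GRID)
        y[np.argmin(np.abs(GRID - 700.0))] = 100.0
        s = Spectrum(GRID, y)
        assert background_intensity(s, 700.0) == 0.0

    def test_known_window_maxima(self):
        # one impulse per 1.1 Da window, heights 1..n -> background = median;
        # the 200 Da range around 700 truncates to the full (600, 800) grid,
        # so windows are anchored at 600
        edges = np.arange(600.0, 800.0, 1.1)
        y = np.zeros_like(GRID)
        heights = []
        for k, a in enumerate(edges[:-1], start=1):
            c = a + 0.55
            idx = np.argmin(np.abs(GRID - c))
            y[idx] = k
            heights.append(k)
        s = Spectrum(GRID, y)
        got = background_intensity(s, 700.0)
        assert abs(got - np.median(heights)) <= 1.0


def shifted_dataset(n_spots, shift_ppm, seed=0, centers=None, heights=None):
    rng = np.random.default_rng(seed)
    centers = np.arange(620.0, 780.0, 8.0) if centers is None else centers
    heights = np.ones_like(centers) if heights is None else heights
    shifts = rng.normal(0.0, shift_ppm, n_spots) if np.ndim(shift_ppm) == 0 else shift_ppm
    spectra = []
    for i in range(n_spots):
        c = centers * (1 + shifts[i] * 1e-6)
        spectra.append(spectrum_with_peaks(c, heights, spot_id=f"s{i}"))
    return MSIDataset(spectra, (600.0, 800.0)), shifts


class TestMassDispersion:
    def test_aligned_dataset_has_subppm_dispersion(self):
        ds, _ = shifted_dataset(10, 0.0)
        report = mass_dispersion(ds, np.arange(620.0, 780.0, 8.0))
        assert report.median_dispersion_ppm < 1.0

    def test_known_shift_sd_recovered(self):
        ds, _ = shifted_dataset(60, 20.0, seed=1)
        report = mass_dispersion(ds, np.arange(620.0, 780.0, 8.0))
        assert report.median_dispersion_ppm == pytest.approx(20.0, rel=0.35)

    def test_low_coverage_peak_excluded(self):
        ds, _ = shifted_dataset(20, 0.0)
        # add a target where only one spectrum has signal
        lone = 790.0
        ds.spectra[0] = Spectrum(
            GRID, ds[0].intensity + gauss(GRID, lone, height=5.0), spot_id="s0"
        )
        report = mass_dispersion(ds, np.array([650.0, lone]))
        row = report.per_peak.set_index("target_mz").loc[lone]
        assert not row.retained

    def test_invariant_under_intensity_rescaling(self):
        ds, _ = shifted_dataset(15, 10.0, seed=2)
        scaled = MSIDataset(
            [Spectrum(s.mz, s.intensity * 37.0, s.spot_id) for s in ds], ds.mass_range
        )
        targets = np.arange(620.0, 780.0, 8.0)
        r1 = mass_dispersion(ds, targets)
        r2 = mass_dispersion(scaled, targets)
        assert r1.median_dispersion_ppm == pytest.approx(r2.median_dispersion_ppm, rel=1e-9)


class TestAbsoluteMassError:
    def test_zero_shift_near_zero_error(self):
        targets = np.arange(620.0, 780.0, 8.0)
        ds, _ = shifted_dataset(10, 0.0)
        df = absolute_mass_error(ds, targets)
        assert abs(df.attrs["mean_median_ppm"]) < 2.0

    def test_constant_30ppm_recovered(self):
        targets = np.arange(620.0, 780.0, 8.0)
        ds, _ = shifted_dataset(10, np.full(10, 30.0))
        df = absolute_mass_error(ds, targets)
        assert df.attrs["mean_median_ppm"] == pytest.approx(30.0, abs=3.0)

    def test_zero_coverage_target_excluded(self):
        ds, _ = shifted_dataset(10, 0.0)
        df = absolute_mass_error(ds, np.array([652.0, 790.0]))
        row = df.set_index("target_mz").loc[790.0]
        assert not row.retained
        assert np.isfinite(df.attrs["mean_median_ppm"])


class TestLowMatrixMask:
    probes = [644.08, 650.10, 682.09, 700.0]

    def test_identical_spots_none_flagged(self):
        s = spectrum_with_peaks(self.probes, [1.0] * 4)
        ds = MSIDataset(
            [Spectrum(s.mz, s.intensity.copy(), f"s{i}") for i in range(5)], (600.0, 800.0)
        )
        mask = low_matrix_mask(ds, self.probes)
        assert not mask.any()

    def test_one_high_matrix_spot_flags_the_rest(self):
        high = spectrum_with_peaks(self.probes, [5.0] * 4, spot_id="high")
        lows = [Spectrum(GRID, np.zeros_like(GRID), f"s{i}") for i in range(9)]
        ds = MSIDataset([high] + lows, (600.0, 800.0))
        mask = low_matrix_mask(ds, self.probes)
        assert not mask[0]
        assert mask[1:].all()

    def test_zero_matrix_dataset_all_false(self):
        ds = MSIDataset(
            [Spectrum(GRID, np.zeros_like(GRID), f"s{i}") for i in range(4)], (600.0, 800.0)
        )
        assert not low_matrix_mask(ds, self.probes).any()


class TestMeanSpectrum:
    def test_mean_on_shared_grid(self):
        ds, _ = shifted_dataset(4, 0.0)
        m = mean_spectrum(ds)
        np.testing.assert_allclose(
            m.intensity, np.mean([s.intensity for s in ds], axis=0)
        )
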