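import numpy as np
import pytest

from massshiftnet import (
    FitOptions,
    Spectrum,
    apply_shift,
    calibrate,
    fit_model,
    linear_shift,
    matrix_score,
    model_spectrum,
    synthesize_spectrum,
    batch_recalibrate,
)
from massshiftnet import MSIDataset
from massshiftnet.models import sparse_peptide_alpha

FAST = FitOptions(max_iter=900, seed=0)


@pytest.fixture(scope="module")
def fitted_sparse(small_components, sparse_spectrum):
    """One shared fit of the noiseless sparse spectrum distorted by a known
    linear shift (expensive; reused across assertions)."""
    spec, truth = sparse_spectrum
    shift = linear_shift(3e-5, 0.03, (600.0, 750.0))
    distorted, _ = synthesize_spectrum(
        small_components, truth.true_alpha, shift=shift, grid=spec.mz, noise_sd=0.0
    )
    result = fit_model(distorted, small_components, opts=FAST)
    return result, truth, shift


class TestModelSpectrum:
    def test_zero_alpha_gives_zero(self, small_components, small_grid):
        n = sum(c.n_peaks for c in small_components)
        out = model_spectrum(np.zeros(n), None, None, small_components, small_grid)
        assert np.all(out.intensity == 0)

    def test_single_peak_is_gaussian_at_location(self, small_components, small_grid):
        pep, mat = small_components
        alpha = np.zeros(pep.n_peaks + mat.n_peaks)
        alpha[5] = 1.0
        out = model_spectrum(alpha, None, None, small_components, small_grid)
        apex = out.mz[np.argmax(out.intensity)]
        assert abs(apex - pep.peak_mz[5]) <= 0.01

    def test_matches_generator_kernel(self, small_components, small_grid, rng):
        n = sum(c.n_peaks for c in small_components)
        alpha = rng.uniform(0, 1, n)
        shift = linear_shift(1e-5, 0.02, (600.0, 750.0))
        gen, _ = synthesize_spectrum(
            small_components, alpha, shift=shift, grid=small_grid, noise_sd=0.0
        )
        mod = model_spectrum(alpha, shift, None, small_components, small_grid)
        np.testing.assert_allclose(mod.intensity, gen.intensity, atol=1e-9)

    def test_alpha_length_validated(self, small_components, small_grid):
        with pytest.raises(ValueError, match="alpha"):
            model_spectrum(np.ones(2), None, None, small_components, small_grid)


class TestFitRecovery:
    def test_shift_recovered_within_5mda(self, fitted_sparse):
        result, truth, shift = fitted_sparse
        probe = np.linspace(610.0, 745.0, 40)
        err = np.abs(result.shift.delta(probe) - shift(probe))
        assert np.mean(err) < 0.005

    def test_alpha_correlates_with_truth(self, fitted_sparse):
        result, truth, _ = fitted_sparse
        true_pep = truth.alpha_for("peptide")
        fit_pep = result.alpha_for("peptide")
        present = true_pep > 0
        assert np.corrcoef(fit_pep[present], true_pep[present])[0, 1] > 0.99

    def test_absent_peaks_get_near_zero_alpha(self, fitted_sparse):
        result, truth, _ = fitted_sparse
        true_pep = truth.alpha_for("peptide")
        fit_pep = result.alpha_for("peptide")
        assert fit_pep[true_pep == 0].max() < 0.01 * fit_pep.max()

    def test_accepted_objectives_monotone(self, fitted_sparse):
        result, _, _ = fitted_sparse
        acc = result.accepted_objectives
        assert np.all(np.diff(acc) <= 1e-15)

    def test_zero_spectrum_rejected(self, small_components, small_grid):
        z = Spectrum(small_grid, np.zeros_like(small_grid))
        with pytest.raises(ValueError, match="all-zero"):
            fit_model(z, small_components, opts=FAST)


class TestCalibrate:
    def test_zero_shift_identity(self, sparse_spectrum):
        spec, _ = sparse_spectrum
        out = calibrate(spec, linear_shift(0.0, 0.0, (600.0, 750.0)))
        np.testing.assert_array_equal(out.mz, spec.mz)

    def test_inverse_pair(self, sparse_spectrum):
        spec, _ = sparse_spectrum
        fn = linear_shift(0.0, 0.05, (600.0, 750.0))
        back = calibrate(apply_shift(spec, fn), fn)
        np.testing.assert_allclose(back.mz, spec.mz, atol=1e-9)

    def test_constant_shift_subtracts(self, sparse_spectrum):
        spec, _ = sparse_spectrum
        out = calibrate(spec, linear_shift(0.0, 0.05, (600.0, 750.0)))
        np.testing.assert_allclose(spec.mz - out.mz, 0.05)


class TestMatrixScore:
    def make_result(self, small_components, alpha):
        from massshiftnet.modelcal import RecalResult, ShiftNetParams
        pep, mat = small_components
        return RecalResult(
            alpha=alpha,
            shift=ShiftNetParams((600.0, 750.0)),
            baseline=None,
            residual_norm=0.0,
            matrix_score=0.0,
            extracted_shift=None,
            converged=True,
            n_iter=0,
            component_names=["peptide", "matrix"],
            component_slices=[(0, pep.n_peaks), (pep.n_peaks, pep.n_peaks + mat.n_peaks)],
        )

    def test_no_matrix_signal_scores_zero(self, small_components):
        pep, mat = small_components
        alpha = np.concatenate([np.ones(pep.n_peaks), np.zeros(mat.n_peaks)])
        assert matrix_score(self.make_result(small_components, alpha), small_components) == 0.0

    def test_pure_matrix_scores_one(self, small_components):
        pep, mat = small_components
        alpha = np.concatenate([np.zeros(pep.n_peaks), np.ones(mat.n_peaks)])
        assert matrix_score(self.make_result(small_components, alpha), small_components) == 1.0

    def test_invariant_under_uniform_rescaling(self, small_components, rng):
        pep, mat = small_components
        alpha = rng.uniform(0, 1, pep.n_peaks + mat.n_peaks)
        s1 = matrix_score(self.make_result(small_components, alpha), small_components)
        s2 = matrix_score(self.make_result(small_components, alpha * 11.0), small_components)
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_missing_matrix_component_rejected(self, small_components):
        pep, _ = small_components
        res = self.make_result(small_components, np.ones(sum(c.n_peaks for c in small_components)))
        res.component_names = ["peptide", "other"]
        with pytest.raises(ValueError, match="matrix"):
            matrix_score(res, small_components)


@pytest.fixture(scope="module")
def tiny_dataset(small_components, small_grid):
    gen = np.random.default_rng(7)
    pep, mat = small_components
    spectra = []
    for i in range(6):
        pa = sparse_peptide_alpha(pep, occupancy=0.3, rng=gen)
        ma = mat.peak_weight * 0.3 * max(pa.max(), 1e-6)
        spec, _ = synthesize_spectrum(
            small_components, np.concatenate([pa, ma]), grid=small_grid,
            noise_sd=0.0, spot_id=f"spot_{i}",
        )
        spectra.append(spec)
    return MSIDataset(spectra, (600.0, 750.0))


class TestBatchRecalibrate:
    def test_spot_selection_deterministic(self, tiny_dataset, small_components):
        opts = FitOptions(max_iter=30, seed=0)
        r1 = batch_recalibrate(tiny_dataset, small_components, n_spots=3, seed=5, opts=opts)
        r2 = batch_recalibrate(tiny_dataset, small_components, n_spots=3, seed=5, opts=opts)
        assert [c.spot_id for _, c, _ in r1] == [c.spot_id for _, c, _ in r2]

    def test_returns_requested_count_and_matrix_spectra(self, tiny_dataset, small_components):
        opts = FitOptions(max_iter=60, seed=0)
        out = batch_recalibrate(tiny_dataset, small_components, n_spots=2, seed=1, opts=opts)
        assert len(out) == 2
        for result, calibrated, matrix_spec in out:
            assert matrix_spec is not None
            assert len(calibrated) == len(tiny_dataset[0])
            assert result.alpha.min() >= 0

    def test_n_spots_validated(self, tiny_dataset, small_components):
        with pytest.raises(ValueError, match="n_spots"):
            batch_recalibrate(tiny_dataset, small_components, n_spots=99)

    def test_warm_start_not_slower_on_identical_spectra(self, small_components, small_grid):
        gen = np.random.default_rng(11)
        pep, mat = small_components
        pa = sparse_peptide_alpha(pep, occupancy=0.3, rng=gen)
        alpha = np.concatenate([pa, mat.peak_weight * 0.3 * pa.max()])
        spec, _ = synthesize_spectrum(small_components, alpha, grid=small_grid, noise_sd=0.0)
        opts = FitOptions(max_iter=1200, seed=0)
        cold = fit_model(spec, small_components, opts=opts)
        warm = fit_model(spec, small_components, opts=opts, init=cold)
        assert warm.n_iter <= cold.n_iter
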