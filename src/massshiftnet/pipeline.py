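"""End-to-end evaluation pipelines on synthetic data.

Each function runs one self-contained experiment of the validation suite —
generating spectra, running the method, and measuring the outcome — and
returns plain numbers.  They are deliberately deterministic given a seed
and sized for a single CPU; both the test suite and the results script
drive them.

Scaled-down study conditions (defaults): the acquisition window is
600-3200 Da at 0.01 Da sampling; the self-supervised run uses 30
calibrated spectra x 200 simulated shifts (60/10/30 linear/sqrt/perturbed
mixture, matrix augmentation on) with a half-width network on a 64 x 24
histogram; the dispersion study distorts 300 spots by linear-in-mass
shifts of 20 ppm standard deviation.
"""

from __future__ import annotations

import numpy as np

from .kendrick import KendrickConfig, build_histogram
from .metrics import absolute_mass_error, mass_dispersion, mean_spectrum, top_peaks
from .modelcal import FitOptions, fit_model
from .models import (
    chca_component,
    averagine_component,
    gaussian_mixture,
    sparse_peptide_alpha,
    synthesize_dataset,
    synthesize_spectrum,
)
from .msi_io import Spectrum
from .network import (
    NetworkSpec,
    TrainConfig,
    build_network,
    predict_batch,
    recalibrate_dataset,
    smooth_shift_vector,
    train,
)
from .shift_sim import (
    apply_shift,
    linear_shift,
    make_training_set,
    sample_shift_bank,
    tabulated_shift,
)

MASS_RANGE = (600.0, 3200.0)
GRID_STEP = 0.01


def _seed_stream(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, n)]


def model_recovery_experiment(seed: int = 0, mass_range=MASS_RANGE,
                              opts: FitOptions | None = None) -> dict:
    """Fit the decomposition model to a noiseless distorted spectrum.

    A sparse peptide+matrix spectrum over the full acquisition window is
    distorted by a known linear shift (<= 0.1 Da everywhere); the fit must
    recover the shift function and assign near-zero intensity to absent
    peaks.  Components are monoisotopic: at sigma = 0.05 Da the first
    isotopologue of one averagine species is indistinguishable from the
    next species' monoisotopic peak, so per-peak identifiability is only
    defined without that degeneracy.
    """
    rng = np.random.default_rng(seed)
    pep = averagine_component(mass_range, isotopes=1)
    mat = chca_component(mass_range, isotopes=1)
    pep_alpha = sparse_peptide_alpha(pep, occupancy=0.3, log_sigma=1.0, rng=rng)
    mat_alpha = (mat.peak_weight / mat.peak_weight.max()) * 0.5 * pep_alpha.max()
    alpha = np.concatenate([pep_alpha, mat_alpha])
    grid = np.arange(mass_range[0], mass_range[1] + GRID_STEP / 2, GRID_STEP)
    # ~0.094 Da at the top of the range
    shift = linear_shift(2.5e-5, 0.014, mass_range)
    spec, truth = synthesize_spectrum([pep, mat], alpha, shift=shift, grid=grid, noise_sd=0.0)

    result = fit_model(spec, [pep, mat], opts=opts or FitOptions(seed=seed))

    # evaluate the fitted shift where analyte signal supports it
    supported = pep.peak_mz[pep_alpha > 0]
    err = np.abs(result.shift.delta(supported) - shift(supported))
    fit_pep = result.alpha_for("peptide")
    absent_frac = float(fit_pep[pep_alpha == 0].max() / fit_pep.max())
    return {
        "shift_mae_da": float(np.mean(err)),
        "shift_max_err_da": float(np.max(err)),
        "absent_alpha_fraction": absent_frac,
        "alpha_correlation": float(
            np.corrcoef(fit_pep[pep_alpha > 0], pep_alpha[pep_alpha > 0])[0, 1]
        ),
        "matrix_score": result.matrix_score,
        "true_matrix_fraction": float(mat_alpha.sum() / alpha.sum()),
        "n_iter": result.n_iter,
    }


def matrix_score_experiment(seed: int = 0, mass_range=(600.0, 1200.0)) -> dict:
    """Matrix score of matrix-only, peptide-only and 50/50 synthetic spectra."""
    rng = np.random.default_rng(seed)
    pep = averagine_component(mass_range, isotopes=1)
    mat = chca_component(mass_range, isotopes=1)
    grid = np.arange(mass_range[0], mass_range[1] + GRID_STEP / 2, GRID_STEP)
    pep_alpha = sparse_peptide_alpha(pep, occupancy=0.3, log_sigma=0.5, rng=rng)
    mat_alpha = (mat.peak_weight / mat.peak_weight.max()) * pep_alpha.max()
    # equal *total* intensity for the 50/50 mixture
    mat_alpha_eq = mat_alpha * (pep_alpha.sum() / mat_alpha.sum())
    opts = FitOptions(max_iter=1200, seed=seed)

    scores = {}
    for name, a_pep, a_mat in [
        ("matrix_only", np.zeros_like(pep_alpha), mat_alpha),
        ("peptide_only", pep_alpha, np.zeros_like(mat_alpha)),
        ("mixed_50_50", pep_alpha, mat_alpha_eq),
    ]:
        spec, _ = synthesize_spectrum(
            [pep, mat], np.concatenate([a_pep, a_mat]), grid=grid, noise_sd=0.0
        )
        result = fit_model(spec, [pep, mat], opts=opts)
        scores[name] = result.matrix_score
    return scores


def selfsupervised_experiment(
    seed: int = 0,
    n_spectra: int = 30,
    n_shifts: int = 200,
    n_heldout: int = 50,
    epochs: int = 12,
    lr: float = 1e-3,
    mass_range=MASS_RANGE,
    n_defect_bins: int = 64,
    n_mz_bins: int = 24,
) -> dict:
    """Train the shift estimator on simulated distortions and measure
    held-out recovery.

    Returns the trained model plus the held-out RMSE (Da) against the
    injected shifts and the RMSE of the zero-shift predictor.  The network
    is trained per dataset (as in real use), so held-out spectra are other
    spots of the same dataset, distorted by fresh shift functions.
    """
    seeds = _seed_stream(seed, 6)
    dataset, truths, comps = synthesize_dataset(
        n_spectra + n_heldout, mass_range=mass_range, grid_step=GRID_STEP, seed=seeds[0]
    )
    grid = dataset[0].mz
    mat = comps["matrix"]

    # per-spot matrix spectra for augmentation, from the generator's truth
    pairs = []
    for spot, truth in zip(dataset.spectra[:n_spectra], truths[:n_spectra]):
        mat_alpha = truth.alpha_for("matrix")
        mat_spec = Spectrum(
            grid, gaussian_mixture(grid, mat.peak_mz, mat_alpha, 0.05),
            spot_id=spot.spot_id + "_matrix",
        )
        pairs.append((spot, mat_spec))

    # stand-in for shifts extracted from observed spectra: tabulated smooth
    # functions of the same families
    probe = np.linspace(mass_range[0], mass_range[1], 65)
    base = sample_shift_bank(n_spectra, mass_range, mix=(0.7, 0.3, 0.0), rng_seed=seeds[1])
    extracted = [tabulated_shift(probe, f(probe)) for f in base]

    cfg = KendrickConfig(
        n_mz_bins=n_mz_bins, n_defect_bins=n_defect_bins, mass_range=mass_range
    )
    samples = make_training_set(
        pairs, n_shifts, cfg, extracted=extracted, mix=(0.6, 0.1, 0.3), rng_seed=seeds[2]
    )

    spec = NetworkSpec.reduced(n_mz_bins=n_mz_bins, n_defect_bins=n_defect_bins)
    model = build_network(spec, seed=seeds[3])
    history = train(
        model, samples,
        TrainConfig(lr=lr, epochs=epochs, seed=seeds[3], patience=4),
    )

    # held-out: unseen spots of the same dataset, fresh shifts
    held = dataset.spectra[n_spectra:]
    held_bank = sample_shift_bank(
        n_heldout, mass_range, extracted=extracted, mix=(0.6, 0.1, 0.3), rng_seed=seeds[5]
    )
    X, targets = [], []
    for spot, fn in zip(held, held_bank):
        distorted = apply_shift(spot, fn)
        hist = build_histogram(distorted, cfg, normalize="column_sum")
        X.append(hist.values.T[None])
        targets.append(fn(cfg.mz_centers))
    preds = predict_batch(model, np.stack(X).astype(np.float32))
    # the same smoothness-aware inference used by recalibrate_dataset
    preds_da = np.array([smooth_shift_vector(p) for p in preds]) * cfg.lam
    targets = np.stack(targets)
    rmse = float(np.sqrt(np.mean((preds_da - targets) ** 2)))
    zero_rmse = float(np.sqrt(np.mean(targets**2)))
    return {
        "model": model,
        "kendrick_config": cfg,
        "history": history,
        "heldout_rmse_da": rmse,
        "zero_predictor_rmse_da": zero_rmse,
        "n_training_samples": len(samples),
    }


def dispersion_experiment(
    model,
    cfg: KendrickConfig,
    seed: int = 0,
    n_spots: int = 300,
    shift_sd_ppm: float = 20.0,
    n_top_peaks: int = 50,
) -> dict:
    """Recalibrate a dataset with per-spot random shifts; compare dispersion.

    Per-spot distortions are proportional (constant in ppm), drawn from
    N(0, shift_sd_ppm); the median relative mass dispersion of the top
    peaks of the mean spectrum is measured before and after recalibration.
    """
    seeds = _seed_stream(seed, 2)
    rng = np.random.default_rng(seeds[0])
    ppm = rng.normal(0.0, shift_sd_ppm, n_spots)
    shifts = [linear_shift(p * 1e-6, 0.0, cfg.mass_range) for p in ppm]
    dataset, _, _ = synthesize_dataset(
        n_spots, mass_range=cfg.mass_range, grid_step=GRID_STEP,
        shifts=shifts, seed=seeds[1],
    )
    targets = top_peaks(mean_spectrum(dataset), n=n_top_peaks)
    before = mass_dispersion(dataset, targets)
    recal = recalibrate_dataset(model, dataset, cfg)
    after = mass_dispersion(recal, targets)
    return {
        "dispersion_before_ppm": before.median_dispersion_ppm,
        "dispersion_after_ppm": after.median_dispersion_ppm,
        "reduction_fraction": 1.0 - after.median_dispersion_ppm / before.median_dispersion_ppm,
        "n_targets": int(len(targets)),
    }


def metric_oracle_experiment(seed: int = 0, n_spots: int = 500,
                             mass_range=(600.0, 1100.0)) -> dict:
    """Check the two evaluation statistics against known injected errors.

    (a) i.i.d. per-spot proportional shifts of SD 20 ppm -> the median
    dispersion estimate should approach 20 ppm; (b) a constant +30 ppm
    distortion -> the absolute-error statistic should report +30 ppm.
    """
    seeds = _seed_stream(seed, 3)
    rng = np.random.default_rng(seeds[0])

    ppm = rng.normal(0.0, 20.0, n_spots)
    shifts = [linear_shift(p * 1e-6, 0.0, mass_range) for p in ppm]
    ds, _, _ = synthesize_dataset(
        n_spots, mass_range=mass_range, grid_step=GRID_STEP, shifts=shifts,
        seed=seeds[1], matrix_level=0.3,
    )
    targets = top_peaks(mean_spectrum(ds), n=30)
    disp = mass_dispersion(ds, targets)

    const = [linear_shift(30.0e-6, 0.0, mass_range) for _ in range(50)]
    ds2, _, _ = synthesize_dataset(
        50, mass_range=mass_range, grid_step=GRID_STEP, shifts=const,
        seed=seeds[2], matrix_level=1.0,
    )
    mat = chca_component(mass_range, isotopes=1)
    strong = np.sort(mat.peak_mz[np.argsort(mat.peak_weight)[::-1][:9]])
    abs_err = absolute_mass_error(ds2, strong)
    return {
        "dispersion_estimate_ppm": disp.median_dispersion_ppm,
        "dispersion_true_ppm": 20.0,
        "absolute_error_estimate_ppm": float(abs_err.attrs["mean_median_ppm"]),
        "absolute_error_true_ppm": 30.0,
    }
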