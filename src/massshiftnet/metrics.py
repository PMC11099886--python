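"""Evaluation statistics for recalibration quality.

Two complementary views of mass accuracy:

* **relative mass dispersion** — how tightly the same peak aligns across
  the spectra of a dataset: the standard deviation (ppm) of matched peak
  locations for the most intense peaks of the mean spectrum;
* **absolute mass error** — the median ppm offset of measured matrix
  cluster peaks from their theoretically known exact masses.

Peaks are located by a matched filter: the position maximizing the inner
product of the spectrum with a unit-norm Gaussian template (default
fwhm = 0.15 Da, i.e. sigma ~ 0.0637 Da), refined to sub-grid precision by
parabolic interpolation of the correlation maximum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .msi_io import MSIDataset, Spectrum

logger = logging.getLogger(__name__)

#: Gaussian template width equivalent to a 0.15 Da full width at half maximum
SIGMA_MATCH = 0.15 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: m/z values of prominent CHCA matrix peaks used for the low-matrix rule
DEFAULT_MATRIX_PROBES = (644.08, 650.10, 682.09, 855.10)


@dataclass
class PeakObservation:
    """Result of matching one target peak in one spectrum."""

    target_mz: float
    found_mz: float | None
    intensity: float
    spot_id: str

    @property
    def present(self) -> bool:
        return self.found_mz is not None


@dataclass
class DispersionReport:
    """Per-peak coverage and dispersion plus the dataset summary."""

    per_peak: pd.DataFrame  # columns: target_mz, coverage, dispersion_ppm, retained
    median_dispersion_ppm: float

    def to_csv(self, path) -> None:
        self.per_peak.to_csv(path, index=False)


def mean_spectrum(dataset: MSIDataset, n_grid: int | None = None) -> Spectrum:
    """Average intensity on a common grid (the first spot's grid by default)."""
    ref = dataset[0].mz if n_grid is None else np.linspace(
        dataset.mass_range[0], dataset.mass_range[1], n_grid
    )
    total = np.zeros_like(ref, dtype=float)
    for s in dataset:
        if s.mz.shape == ref.shape and np.array_equal(s.mz, ref):
            total += s.intensity
        else:
            total += np.interp(ref, s.mz, s.intensity, left=0.0, right=0.0)
    return Spectrum(ref, total / len(dataset), spot_id="mean")


def top_peaks(mean_spec: Spectrum, n: int = 50, window: float = 3.0) -> np.ndarray:
    """Greedy selection of the n most intense local maxima, suppressing any
    candidate within ``window`` Da of an already selected peak."""
    from scipy.signal import argrelextrema

    y = mean_spec.intensity
    if y.size < 3:
        raise ValueError("mean spectrum too short for peak picking")
    idx = argrelextrema(y, np.greater_equal, order=1)[0]
    # drop plateau duplicates and flat-zero "maxima"
    idx = idx[y[idx] > 0]
    order = idx[np.argsort(y[idx])[::-1]]
    selected: list[float] = []
    for i in order:
        m = mean_spec.mz[i]
        if all(abs(m - s) >= window for s in selected):
            selected.append(float(m))
            if len(selected) == n:
                break
    if len(selected) < n:
        logger.warning("top_peaks: only %d of %d requested maxima found", len(selected), n)
    return np.array(sorted(selected))


from functools import lru_cache


@lru_cache(maxsize=64)
def _gaussian_template_cached(step_key: int, sigma_key: int) -> np.ndarray:
    step, sigma = step_key * 1e-9, sigma_key * 1e-9
    half = max(int(np.ceil(4.0 * sigma / step)), 1)
    u = np.arange(-half, half + 1) * step
    g = np.exp(-0.5 * (u / sigma) ** 2)
    return g / np.linalg.norm(g)


def _gaussian_template(step: float, sigma: float) -> np.ndarray:
    return _gaussian_template_cached(int(round(step * 1e9)), int(round(sigma * 1e9)))


def match_peak(spectrum: Spectrum, target_mz: float, sigma: float = SIGMA_MATCH,
               search_window: float = 0.5) -> PeakObservation:
    """Matched-filter peak location nearest to ``target_mz``.

    The returned location maximizes the inner product with a unit-norm
    Gaussian template within +-``search_window`` Da of the target (ties go
    to the lower m/z); the amplitude is that inner product.  Sub-grid
    refinement by parabolic interpolation of the correlation peak.
    """
    mz, y = spectrum.mz, spectrum.intensity
    if not (mz[0] <= target_mz <= mz[-1]):
        raise ValueError(f"target m/z {target_mz} outside spectrum range")
    step = float(np.median(np.diff(mz)))
    tmpl = _gaussian_template(step, sigma)
    half_t = (tmpl.size - 1) // 2
    lo = np.searchsorted(mz, target_mz - search_window - 4 * sigma)
    hi = np.searchsorted(mz, target_mz + search_window + 4 * sigma)
    seg = y[lo:hi]
    if seg.size < tmpl.size or not np.any(seg > 0):
        return PeakObservation(target_mz, None, 0.0, spectrum.spot_id)
    corr = np.correlate(seg, tmpl, mode="valid")
    centers = mz[lo + half_t : hi - half_t][: corr.size]
    in_win = np.abs(centers - target_mz) <= search_window
    if not np.any(in_win):
        return PeakObservation(target_mz, None, 0.0, spectrum.spot_id)
    corr_w = np.where(in_win, corr, -np.inf)
    best = float(np.max(corr_w))
    # tie rule: lowest m/z among numerically indistinguishable maxima
    k = int(np.nonzero(corr_w >= best - 1e-9 * max(abs(best), 1.0))[0][0])
    amp = float(corr[k])
    if amp <= 0:
        return PeakObservation(target_mz, None, 0.0, spectrum.spot_id)
    loc = float(centers[k])
    if 0 < k < corr.size - 1 and np.isfinite(corr[k - 1]) and np.isfinite(corr[k + 1]):
        a, b, c = corr[k - 1], corr[k], corr[k + 1]
        denom = a - 2 * b + c
        if denom < 0:
            frac = 0.5 * (a - c) / denom
            if abs(frac) <= 0.5:
                loc += frac * step
    return PeakObservation(target_mz, loc, amp, spectrum.spot_id)


def background_intensity(spectrum: Spectrum, target_mz: float, range_width: float = 200.0,
                         window: float = 1.1) -> float:
    """Median of per-window maximum intensities around the target.

    The +-``range_width``/2 Da neighbourhood (truncated at the spectrum
    edges) is divided into ``window``-Da windows; the background is the
    median of each window's maximum.
    """
    mz, y = spectrum.mz, spectrum.intensity
    lo = max(target_mz - range_width / 2.0, mz[0])
    hi = min(target_mz + range_width / 2.0, mz[-1])
    edges = np.append(np.arange(lo, hi, window), hi)
    starts = np.searchsorted(mz, edges[:-1])
    stops = np.searchsorted(mz, edges[1:])
    nonempty = stops > starts
    if not nonempty.any():
        return 0.0
    seg_max = np.maximum.reduceat(y, starts[nonempty])
    # reduceat segments run to the next start; mask out trailing spill-over
    # by recomputing the final segment exactly
    seg_max[-1] = y[starts[nonempty][-1] : stops[nonempty][-1]].max()
    return float(np.median(seg_max))


def _match_dataset(dataset: MSIDataset, targets: np.ndarray, intensity_factor: float,
                   sigma: float, search_window: float):
    """Per-target lists of accepted found positions across all spectra."""
    found: dict[float, list[float]] = {float(t): [] for t in targets}
    for spec in dataset:
        # converts the raw-intensity background threshold to template-amplitude units
        norm_factor = _template_norm_factor(spec, sigma)
        for t in targets:
            t = float(t)
            if not (spec.mz[0] <= t <= spec.mz[-1]):
                continue
            obs = match_peak(spec, t, sigma=sigma, search_window=search_window)
            if not obs.present:
                continue
            bg = background_intensity(spec, t)
            if obs.intensity >= intensity_factor * bg * norm_factor:
                found[t].append(obs.found_mz)
    return found


def _template_norm_factor(spectrum: Spectrum, sigma: float) -> float:
    """Inner product of the unit-norm template with a unit-height peak of the
    same shape: converts a raw-intensity threshold to template-amplitude units."""
    step = float(np.median(np.diff(spectrum.mz)))
    tmpl = _gaussian_template(step, sigma)
    peak = np.exp(-0.5 * ((np.arange(tmpl.size) - (tmpl.size - 1) // 2) * step / sigma) ** 2)
    return float(tmpl @ peak)


def mass_dispersion(dataset: MSIDataset, targets, intensity_factor: float = 2.5,
                    coverage_min: float = 0.10, sigma: float = SIGMA_MATCH,
                    search_window: float = 0.5) -> DispersionReport:
    """Relative mass dispersion of target peaks across a dataset.

    Per target: match in every spectrum; keep matches whose amplitude is at
    least ``intensity_factor`` times the local background; targets with
    coverage below ``coverage_min`` are dropped from the summary.  The
    dispersion is the (n-1)-denominator standard deviation of kept
    locations, in ppm of the target m/z; the summary is the median over
    retained targets.
    """
    targets = np.asarray(targets, dtype=float)
    if targets.size == 0:
        raise ValueError("targets must be non-empty")
    found = _match_dataset(dataset, targets, intensity_factor, sigma, search_window)
    rows = []
    n_total = len(dataset)
    for t in targets:
        locs = np.array(found[float(t)])
        coverage = locs.size / n_total
        retained = coverage >= coverage_min and locs.size >= 2
        disp = float(np.std(locs, ddof=1) / t * 1e6) if locs.size >= 2 else np.nan
        rows.append({"target_mz": float(t), "coverage": coverage,
                     "dispersion_ppm": disp, "retained": retained})
    df = pd.DataFrame(rows)
    retained_disp = df.loc[df.retained, "dispersion_ppm"]
    if retained_disp.empty:
        logger.warning("mass_dispersion: no peaks retained")
        return DispersionReport(df, float("nan"))
    return DispersionReport(df, float(retained_disp.median()))


def absolute_mass_error(dataset: MSIDataset, matrix_targets, intensity_factor: float = 2.5,
                        coverage_min: float = 0.10, sigma: float = SIGMA_MATCH,
                        search_window: float = 0.5) -> pd.DataFrame:
    """Median ppm offset of measured matrix peaks from their exact masses.

    Returns a per-target frame (exact mass, coverage, median shift in ppm,
    retained flag) with the mean of retained medians in ``.attrs['mean_median_ppm']``.
    Targets below the coverage threshold are excluded and logged.
    """
    targets = np.asarray(matrix_targets, dtype=float)
    if targets.size == 0:
        raise ValueError("matrix_targets must be non-empty")
    found = _match_dataset(dataset, targets, intensity_factor, sigma, search_window)
    rows = []
    n_total = len(dataset)
    for t in targets:
        locs = np.array(found[float(t)])
        coverage = locs.size / n_total
        retained = coverage >= coverage_min
        if not retained:
            logger.info("absolute_mass_error: target %.4f excluded (coverage %.1f%%)",
                        t, 100 * coverage)
        med = float(np.median((locs - t) / t * 1e6)) if locs.size else np.nan
        rows.append({"target_mz": float(t), "coverage": coverage,
                     "median_shift_ppm": med, "retained": retained})
    df = pd.DataFrame(rows)
    kept = df.loc[df.retained, "median_shift_ppm"]
    df.attrs["mean_median_ppm"] = float(kept.mean()) if not kept.empty else float("nan")
    return df


def low_matrix_mask(dataset: MSIDataset, matrix_probe_mz=DEFAULT_MATRIX_PROBES,
                    quantile: float = 0.99, fraction: float = 0.60,
                    sigma: float = SIGMA_MATCH, search_window: float = 0.5) -> np.ndarray:
    """Boolean per-spot flag for low matrix signal.

    Per spot: sum of matched-filter amplitudes at the probe masses; the
    threshold is ``fraction`` times the ``quantile`` quantile of the sums
    over all spots; flagged where the sum is strictly below the threshold.
    """
    sums = np.zeros(len(dataset))
    for i, spec in enumerate(dataset):
        total = 0.0
        for t in matrix_probe_mz:
            if spec.mz[0] <= t <= spec.mz[-1]:
                obs = match_peak(spec, float(t), sigma=sigma, search_window=search_window)
                total += obs.intensity
        sums[i] = total
    threshold = fraction * float(np.quantile(sums, quantile))
    return sums < threshold
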