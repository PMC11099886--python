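"""Mass-shift function families and self-supervised training-set assembly.

Shift functions model the smooth, slowly varying m/z-dependent error of
MALDI-TOF measurements.  Three families are supported: linear
``Delta(t) = b1*t + b2``, square-root ``Delta(t) = b1*sqrt(t) + b2``
(both resembling TOF distortions), and tabulated functions (piecewise
linear through knots), used for shifts extracted from real spectra by the
model-based recalibration.  A shift must stay within half a Kendrick
period everywhere on its domain, otherwise it is not identifiable from the
defect map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .kendrick import KendrickConfig, build_histogram, KendrickHistogram, LAMBDA_AVERAGINE
from .msi_io import Spectrum

logger = logging.getLogger(__name__)

_FAMILIES = ("linear", "sqrt", "tabulated")


@dataclass
class MassShiftFunction:
    """Parametric map m/z -> mass shift (Da) on a fixed domain."""

    family: str
    params: tuple
    domain: tuple[float, float]

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown shift family {self.family!r}")
        if not self.domain[0] < self.domain[1]:
            raise ValueError("domain must satisfy m_min < m_max")
        if self.family == "tabulated":
            knots_mz, knots_shift = self.params
            knots_mz = np.asarray(knots_mz, dtype=float)
            knots_shift = np.asarray(knots_shift, dtype=float)
            if knots_mz.size != knots_shift.size or knots_mz.size < 1:
                raise ValueError("tabulated shift needs matching, non-empty knot arrays")
            if knots_mz.size > 1 and np.any(np.diff(knots_mz) <= 0):
                raise ValueError("tabulated knots must be strictly increasing in m/z")
            self.params = (knots_mz, knots_shift)

    def __call__(self, m):
        m = np.asarray(m, dtype=float)
        if self.family == "linear":
            b1, b2 = self.params
            out = b1 * m + b2
        elif self.family == "sqrt":
            b1, b2 = self.params
            out = b1 * np.sqrt(m) + b2
        else:
            knots_mz, knots_shift = self.params
            out = np.interp(m, knots_mz, knots_shift)
        return float(out) if out.ndim == 0 else out

    def max_abs(self, n_probe: int = 257) -> float:
        probe = np.linspace(self.domain[0], self.domain[1], n_probe)
        return float(np.max(np.abs(self(probe))))


def _validate_bound(fn: MassShiftFunction, lam: float) -> MassShiftFunction:
    bound = 0.5 * lam
    if fn.max_abs() >= bound:
        raise ValueError(
            f"shift exceeds half a Kendrick period on its domain "
            f"(max |Delta| = {fn.max_abs():.4f} Da >= {bound:.4f} Da)"
        )
    return fn


def linear_shift(beta1: float, beta2: float, domain: tuple[float, float], lam: float = LAMBDA_AVERAGINE) -> MassShiftFunction:
    """Linear shift Delta(m) = beta1*m + beta2 (Da)."""
    return _validate_bound(MassShiftFunction("linear", (beta1, beta2), domain), lam)


def sqrt_shift(beta1: float, beta2: float, domain: tuple[float, float], lam: float = LAMBDA_AVERAGINE) -> MassShiftFunction:
    """Square-root shift Delta(m) = beta1*sqrt(m) + beta2 (Da)."""
    return _validate_bound(MassShiftFunction("sqrt", (beta1, beta2), domain), lam)


def tabulated_shift(knots_mz, knots_shift, domain: tuple[float, float] | None = None, lam: float = LAMBDA_AVERAGINE) -> MassShiftFunction:
    """Piecewise-linear shift through (m/z, Da) knots; constant beyond the ends."""
    knots_mz = np.asarray(knots_mz, dtype=float)
    if domain is None:
        domain = (float(knots_mz[0]), float(knots_mz[-1]))
    return _validate_bound(MassShiftFunction("tabulated", (knots_mz, knots_shift), domain), lam)


def perturb_shift(base: MassShiftFunction, scale: float, offset: float, lam: float = LAMBDA_AVERAGINE) -> MassShiftFunction:
    """Scaled-and-shifted copy of a shift function: scale*Delta(m) + offset."""
    if base.family in ("linear", "sqrt"):
        b1, b2 = base.params
        fn = MassShiftFunction(base.family, (scale * b1, scale * b2 + offset), base.domain)
    else:
        knots_mz, knots_shift = base.params
        fn = MassShiftFunction(
            "tabulated", (knots_mz.copy(), scale * knots_shift + offset), base.domain
        )
    return _validate_bound(fn, lam)


#: default uniform sampling ranges for random shift parameters; chosen so the
#: maximum |Delta| over the standard 600-3200 Da domain stays below ~0.3 Da,
#: i.e. well inside half a Kendrick period.
DEFAULT_PARAM_RANGES = {
    "linear": {"beta1": (-5e-5, 5e-5), "beta2": (-0.15, 0.15)},
    "sqrt": {"beta1": (-2.5e-3, 2.5e-3), "beta2": (-0.10, 0.10)},
    "perturb": {"scale": (0.5, 1.5), "offset": (-0.05, 0.05)},
}


def sample_shift_bank(
    n: int,
    domain: tuple[float, float],
    extracted: list[MassShiftFunction] | None = None,
    mix: tuple[float, float, float] = (0.6, 0.1, 0.3),
    param_ranges: dict | None = None,
    rng_seed: int = 0,
) -> list[MassShiftFunction]:
    """Draw ``n`` random shift functions: linear / sqrt / perturbed-extracted.

    The mixture follows the training recipe: by default 60% random linear,
    10% random square-root, 30% perturbations (random scale and offset) of
    the shift functions extracted from observed spectra.
    """
    if abs(sum(mix) - 1.0) > 1e-9:
        raise ValueError("mix must sum to 1")
    if mix[2] > 0 and not extracted:
        raise ValueError("perturbation fraction > 0 requires a non-empty extracted list")
    ranges = dict(DEFAULT_PARAM_RANGES)
    if param_ranges:
        ranges.update(param_ranges)
    rng = np.random.default_rng(rng_seed)

    n_linear = int(round(n * mix[0]))
    n_sqrt = int(round(n * mix[1]))
    n_perturb = n - n_linear - n_sqrt

    def draw(family):
        lo1, hi1 = ranges[family]["beta1"]
        lo2, hi2 = ranges[family]["beta2"]
        maker = linear_shift if family == "linear" else sqrt_shift
        for _ in range(100):
            try:
                return maker(rng.uniform(lo1, hi1), rng.uniform(lo2, hi2), domain)
            except ValueError:
                continue
        raise ValueError(f"could not draw a valid {family} shift from param_ranges")

    bank: list[MassShiftFunction] = []
    for _ in range(n_linear):
        bank.append(draw("linear"))
    for _ in range(n_sqrt):
        bank.append(draw("sqrt"))
    for _ in range(n_perturb):
        base = extracted[rng.integers(0, len(extracted))]
        lo_s, hi_s = ranges["perturb"]["scale"]
        lo_o, hi_o = ranges["perturb"]["offset"]
        for _ in range(100):
            try:
                bank.append(perturb_shift(base, rng.uniform(lo_s, hi_s), rng.uniform(lo_o, hi_o)))
                break
            except ValueError:
                continue
        else:
            raise ValueError("could not draw a valid perturbed shift")
    return bank


def apply_shift(spectrum: Spectrum, shift: MassShiftFunction) -> Spectrum:
    """Distort a spectrum: every sample moves m -> m + Delta(m).

    Intensities are untouched.  A shift steep enough to invert the m/z
    ordering is rejected (the mass map must stay monotone).
    """
    new_mz = spectrum.mz + shift(spectrum.mz)
    if new_mz.size > 1 and np.any(np.diff(new_mz) <= 0):
        raise ValueError("shift inverts m/z ordering (non-monotone mass map)")
    return Spectrum(new_mz, spectrum.intensity.copy(), spectrum.spot_id, spectrum.coords)


def centered_defect_units(delta_da, lam: float) -> np.ndarray:
    """Convert a shift in Da to centered Kendrick-defect units in [-0.5, 0.5)."""
    x = np.asarray(delta_da, dtype=float) / lam
    out = x - np.round(x)
    return np.where(out >= 0.5, out - 1.0, out)


@dataclass
class TrainingSample:
    """One (normalized histogram, target shift vector) training pair.

    The target is the shift function evaluated at the K m/z bin centers, in
    Kendrick-defect units (Da divided by the base lambda, wrapped to
    [-0.5, 0.5)) — the scale of the network's bounded output.
    """

    histogram: KendrickHistogram
    target: np.ndarray
    source_spot: str = ""
    matrix_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.target = np.asarray(self.target, dtype=float)
        if self.target.size != self.histogram.n_mz_bins:
            raise ValueError("target length must equal the histogram's number of m/z columns")
        if np.any(np.abs(self.target) > 0.5):
            raise ValueError("targets must lie in [-0.5, 0.5]")


def make_training_set(
    calibrated: list[tuple[Spectrum, Spectrum | None]],
    n_shifts_per_spectrum: int,
    cfg: KendrickConfig,
    extracted: list[MassShiftFunction] | None = None,
    mix: tuple[float, float, float] = (0.6, 0.1, 0.3),
    param_ranges: dict | None = None,
    matrix_aug: tuple[float, float] = (0.0, 1.0),
    rng_seed: int = 0,
) -> list[TrainingSample]:
    """Build the self-supervised training set from calibrated spectra.

    For each calibrated (analyte spectrum, matrix spectrum) pair and each
    sampled shift function: add a random fraction u ~ U(matrix_aug) of the
    matrix spectrum, distort by the shift, histogram + column-normalize,
    and record the target vector Delta(bin centers) in defect units.
    Deterministic for a fixed seed.
    """
    if n_shifts_per_spectrum < 1:
        raise ValueError("n_shifts_per_spectrum must be >= 1")
    rng = np.random.default_rng(rng_seed)
    domain = cfg.mass_range
    centers = cfg.mz_centers
    samples: list[TrainingSample] = []
    for spec_idx, (spectrum, matrix_spectrum) in enumerate(calibrated):
        bank = sample_shift_bank(
            n_shifts_per_spectrum,
            domain,
            extracted=extracted,
            mix=mix,
            param_ranges=param_ranges,
            rng_seed=int(rng.integers(0, 2**31 - 1)),
        )
        for shift in bank:
            if matrix_spectrum is not None:
                u = float(rng.uniform(*matrix_aug))
                if matrix_spectrum.mz.shape != spectrum.mz.shape or not np.allclose(
                    matrix_spectrum.mz, spectrum.mz
                ):
                    add = np.interp(spectrum.mz, matrix_spectrum.mz, matrix_spectrum.intensity)
                else:
                    add = matrix_spectrum.intensity
                combined = Spectrum(
                    spectrum.mz, spectrum.intensity + u * add, spectrum.spot_id, spectrum.coords
                )
            else:
                u = 0.0
                combined = spectrum
            distorted = apply_shift(combined, shift)
            hist = build_histogram(distorted, cfg, normalize="column_sum")
            target = centered_defect_units(shift(centers), cfg.lam)
            samples.append(
                TrainingSample(
                    histogram=hist,
                    target=target,
                    source_spot=spectrum.spot_id,
                    matrix_fraction=u,
                )
            )
    return samples
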