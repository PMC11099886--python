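"""Theoretical component models and the synthetic spectrum generator.

Two component families cover peptide MALDI imaging with a CHCA matrix:

* **averagine peptides** — peptide monoisotopic masses cluster at integer
  multiples of the averagine base ``lambda_av``, spaced a little more than
  1 Da apart, each carrying a carbon-isotope envelope;
* **CHCA matrix clusters** — combinatorial cluster ions ``[nM - pH + qNa +
  rK + sH]+`` (cation-exchange adducts, optional water loss) of the matrix
  monomer C10H7NO3, whose exact masses are computed from monoisotopic
  elemental masses.

The generator produces spectra of the form

    X(t) = b(t) + sum_j alpha_j * G(t - p_j - Delta(t); sigma) + noise

with unit-height Gaussian peaks, a smooth baseline and an optional smooth
mass-shift distortion, mirroring the signal model used by the model-based
recalibration fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kendrick import LAMBDA_AVERAGINE
from .msi_io import MSIDataset, Spectrum

# monoisotopic elemental masses (Da)
ELEMENT_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "S": 31.97207100,
    "Cl": 34.96885268,
}
ELECTRON_MASS = 0.00054857990
#: average spacing between successive isotopologue peaks (Da)
ISOTOPE_SPACING = 1.00336
#: natural abundance of 13C, drives the isotope envelope
P_C13 = 0.0107
#: carbons per Da in the averagine composition (4.9384 C / 111.1254 Da)
AVERAGINE_C_PER_DA = 4.9384 / 111.1254

#: monoisotopic mass of the CHCA monomer C10H7NO3
CHCA_MONOMER_MASS = (
    10 * ELEMENT_MASS["C"] + 7 * ELEMENT_MASS["H"] + ELEMENT_MASS["N"] + 3 * ELEMENT_MASS["O"]
)
CHCA_CARBONS = 10


@dataclass
class ComponentModel:
    """Named list of theoretical peak locations with prior relative weights."""

    name: str
    peak_mz: np.ndarray
    peak_weight: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.peak_mz = np.asarray(self.peak_mz, dtype=float)
        if self.peak_weight is not None:
            self.peak_weight = np.asarray(self.peak_weight, dtype=float)
            if self.peak_weight.shape != self.peak_mz.shape:
                raise ValueError("peak_weight must match peak_mz in shape")
        if self.peak_mz.size > 1 and np.any(np.diff(self.peak_mz) <= 1e-6):
            raise ValueError("peak_mz must be sorted and unique within 1e-6 Da")

    @property
    def n_peaks(self) -> int:
        return self.peak_mz.size


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generator, for tests and evaluation."""

    true_shift: object  # MassShiftFunction or None
    true_alpha: np.ndarray
    true_baseline: np.ndarray
    noise_seed: int | None
    component_names: list[str] = field(default_factory=list)
    component_slices: list[tuple[int, int]] = field(default_factory=list)

    def alpha_for(self, name: str) -> np.ndarray:
        for nm, (a, b) in zip(self.component_names, self.component_slices):
            if nm == name:
                return self.true_alpha[a:b]
        raise KeyError(name)


def _dedupe_sorted_peaks(mz: np.ndarray, weight: np.ndarray, tol: float = 1e-6):
    """Sort peaks, merging any within ``tol`` Da (weights added)."""
    order = np.argsort(mz)
    mz, weight = mz[order], weight[order]
    keep_mz, keep_w = [], []
    for m, w in zip(mz, weight):
        if keep_mz and m - keep_mz[-1] <= tol:
            keep_w[-1] += w
        else:
            keep_mz.append(m)
            keep_w.append(w)
    return np.array(keep_mz), np.array(keep_w)


def _isotope_weights(n_carbons: float, n_isotopes: int) -> np.ndarray:
    """Binomial isotopologue weights from the carbon count, normalized to 1."""
    from scipy.stats import binom

    n = max(int(round(n_carbons)), 1)
    k = np.arange(n_isotopes)
    w = binom.pmf(np.minimum(k, n), n, P_C13)
    s = w.sum()
    return w / s if s > 0 else w


def averagine_component(
    mass_range: tuple[float, float],
    lam_av: float = LAMBDA_AVERAGINE,
    isotopes: int = 3,
) -> ComponentModel:
    """Averagine peptide peak model over ``mass_range``.

    Monoisotopic locations at ``lam_av * n`` for every integer n in range;
    each extended by an isotope envelope at multiples of +1.00336 Da with
    binomial weights from the mass-dependent carbon count (heavier peptides
    get flatter envelopes).
    """
    m_min, m_max = mass_range
    if not (100.0 <= m_min < m_max <= 10000.0):
        raise ValueError("mass_range must be within [100, 10000] with m_min < m_max")
    n_lo = int(np.ceil(m_min / lam_av))
    n_hi = int(np.floor(m_max / lam_av))
    if n_hi < n_lo:
        raise ValueError("mass_range too narrow: no averagine positions inside")
    mono = lam_av * np.arange(n_lo, n_hi + 1, dtype=float)

    all_mz, all_w = [], []
    for m0 in mono:
        w = _isotope_weights(m0 * AVERAGINE_C_PER_DA, isotopes)
        for k in range(isotopes):
            mk = m0 + k * ISOTOPE_SPACING
            if mk <= m_max:
                all_mz.append(mk)
                all_w.append(w[k])
    mz, weight = _dedupe_sorted_peaks(np.array(all_mz), np.array(all_w))
    return ComponentModel(name="peptide", peak_mz=mz, peak_weight=weight)


@dataclass(frozen=True)
class AdductRow:
    """One adduct: elemental composition delta applied to the neutral cluster.

    The row describes a singly charged positive ion; one electron mass is
    subtracted automatically.
    """

    name: str
    elements: tuple[tuple[str, int], ...]

    @property
    def mass_delta(self) -> float:
        total = 0.0
        for sym, count in self.elements:
            if sym not in ELEMENT_MASS:
                raise ValueError(f"unknown element symbol {sym!r} in adduct {self.name!r}")
            total += count * ELEMENT_MASS[sym]
        return total - ELECTRON_MASS


def default_chca_adducts() -> list[AdductRow]:
    """Cation-exchange adducts [nM - pH + qNa + rK + sH]+ plus water loss.

    Enumerates q Na and r K substitutions (q, r <= 3, q + r <= 4) with the
    hydrogen count balancing to net charge +1, covering the matrix cluster
    ions observed in peptide MALDI data (e.g. [3M-2H+2Na+K]+ near m/z 650.1).
    """
    rows = []
    for q in range(4):
        for r in range(4):
            if q + r > 4:
                continue
            h = 1 - q - r
            elements = []
            if h:
                elements.append(("H", h))
            if q:
                elements.append(("Na", q))
            if r:
                elements.append(("K", r))
            parts = []
            if h < 0:
                parts.append(f"-{-h}H" if h < -1 else "-H")
            if q:
                parts.append(f"+{q}Na" if q > 1 else "+Na")
            if r:
                parts.append(f"+{r}K" if r > 1 else "+K")
            if h > 0:
                parts.insert(0, "+H")
            rows.append(AdductRow(name="".join(parts) or "+H", elements=tuple(elements)))
    rows.append(AdductRow(name="+H-H2O", elements=(("H", -1), ("O", -1))))
    return rows


def parse_adduct_table(text: str) -> list[AdductRow]:
    """Parse a plain-text adduct table: one ``name: El:count,El:count`` per line."""
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            name, spec = line.split(":", 1)
        except ValueError:
            raise ValueError(f"adduct table line {lineno}: expected 'name: El:count,...'") from None
        elements = []
        for item in spec.strip().split(","):
            item = item.strip()
            if not item:
                continue
            sym, _, count = item.partition(":")
            sym = sym.strip()
            if sym not in ELEMENT_MASS:
                raise ValueError(f"adduct table line {lineno}: unknown element symbol {sym!r}")
            elements.append((sym, int(count)))
        rows.append(AdductRow(name=name.strip(), elements=tuple(elements)))
    return rows


def chca_component(
    mass_range: tuple[float, float],
    adduct_table: list[AdductRow] | None = None,
    n_max: int = 12,
    isotopes: int = 3,
) -> ComponentModel:
    """CHCA matrix-cluster peak model: exact masses of [nM + adduct]+ ions.

    For each cluster size n = 1..n_max and each adduct row, the exact mass is
    ``n * M(CHCA) + adduct delta``; isotopologues follow at +1.00336 Da with
    binomial weights from the 10n cluster carbons.
    """
    if adduct_table is None:
        adduct_table = default_chca_adducts()
    if not adduct_table:
        raise ValueError("adduct_table must be non-empty")
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    m_min, m_max = mass_range

    all_mz, all_w = [], []
    for n in range(1, n_max + 1):
        base = n * CHCA_MONOMER_MASS
        iso_w = _isotope_weights(n * CHCA_CARBONS, isotopes)
        for row in adduct_table:
            m0 = base + row.mass_delta
            for k in range(isotopes):
                mk = m0 + k * ISOTOPE_SPACING
                if m_min <= mk <= m_max:
                    all_mz.append(mk)
                    all_w.append(iso_w[k])
    if not all_mz:
        raise ValueError("no matrix cluster peaks inside mass_range")
    mz, weight = _dedupe_sorted_peaks(np.array(all_mz), np.array(all_w))
    return ComponentModel(name="matrix", peak_mz=mz, peak_weight=weight)


def gaussian_mixture(
    t_eff: np.ndarray,
    peaks: np.ndarray,
    alpha: np.ndarray,
    sigma: float,
    halfwidth_sigmas: float = 5.0,
) -> np.ndarray:
    """Sum of unit-height Gaussians evaluated sparsely on a sorted axis."""
    if peaks.size == 0:
        return np.zeros_like(t_eff)
    w = halfwidth_sigmas * sigma
    lo = np.searchsorted(t_eff, peaks - w, side="left")
    hi = np.searchsorted(t_eff, peaks + w, side="right")
    counts = hi - lo
    nz = counts > 0
    if not np.any(nz):
        return np.zeros_like(t_eff)
    pk_idx = np.repeat(np.nonzero(nz)[0], counts[nz])
    g_idx = np.concatenate([np.arange(a, b) for a, b in zip(lo[nz], hi[nz])])
    u = t_eff[g_idx] - peaks[pk_idx]
    contrib = alpha[pk_idx] * np.exp(-0.5 * (u / sigma) ** 2)
    return np.bincount(g_idx, weights=contrib, minlength=t_eff.size).astype(float)


def _eval_baseline(baseline_spec, grid: np.ndarray) -> np.ndarray:
    if baseline_spec is None:
        return np.zeros_like(grid)
    if callable(baseline_spec):
        return np.asarray(baseline_spec(grid), dtype=float)
    arr = np.asarray(baseline_spec, dtype=float)
    if arr.ndim == 0:
        return np.full_like(grid, float(arr))
    if arr.shape != grid.shape:
        raise ValueError("baseline array must match grid shape")
    return arr


def synthesize_spectrum(
    components: list[ComponentModel],
    alpha: np.ndarray,
    baseline_spec=None,
    shift=None,
    grid: np.ndarray | None = None,
    sigma_peak: float = 0.05,
    noise_sd: float = 0.0,
    noise_seed: int | None = None,
    spot_id: str = "synthetic",
) -> tuple[Spectrum, SyntheticTruth]:
    """Render a synthetic spectrum from component models.

    ``alpha`` concatenates per-peak intensities across ``components`` in
    order.  The mass-shift distortion enters in the evaluation coordinate,
    G(t - p - Delta(t)), so a later calibration t -> t - Delta(t) restores
    peaks to their theoretical positions.  ``noise_sd`` is additive Gaussian
    noise, in the same (arbitrary) units as ``alpha``.
    """
    if grid is None:
        raise ValueError("an m/z grid is required")
    grid = np.asarray(grid, dtype=float)
    if grid.size > 1 and np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    if sigma_peak <= 0:
        raise ValueError("sigma_peak must be positive")
    peaks = np.concatenate([c.peak_mz for c in components]) if components else np.empty(0)
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != peaks.shape:
        raise ValueError(
            f"alpha has length {alpha.size} but components define {peaks.size} peaks"
        )
    if np.any(alpha < 0):
        raise ValueError("alpha must be non-negative")

    delta = shift(grid) if shift is not None else np.zeros_like(grid)
    t_eff = grid - delta
    order = np.argsort(peaks)
    signal = gaussian_mixture(t_eff, peaks[order], alpha[order], sigma_peak)
    baseline = _eval_baseline(baseline_spec, grid)
    intensity = baseline + signal
    if noise_sd > 0:
        rng = np.random.default_rng(noise_seed)
        intensity = intensity + rng.normal(0.0, noise_sd, size=grid.shape)
    intensity = np.maximum(intensity, 0.0)

    slices, start = [], 0
    for c in components:
        slices.append((start, start + c.n_peaks))
        start += c.n_peaks
    truth = SyntheticTruth(
        true_shift=shift,
        true_alpha=alpha.copy(),
        true_baseline=baseline,
        noise_seed=noise_seed,
        component_names=[c.name for c in components],
        component_slices=slices,
    )
    return Spectrum(grid, intensity, spot_id=spot_id), truth


def sparse_peptide_alpha(
    peptide: ComponentModel,
    occupancy: float = 0.30,
    log_sigma: float = 1.0,
    mean_amplitude: float = 1.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Log-normal abundances on a random subset of averagine positions.

    Occupancy is applied per monoisotopic position (isotopologues of one
    peptide switch on and off together, scaled by their envelope weights).
    """
    rng = np.random.default_rng() if rng is None else rng
    alpha = np.zeros(peptide.n_peaks)
    weights = peptide.peak_weight if peptide.peak_weight is not None else np.ones(peptide.n_peaks)
    nominal = np.round(peptide.peak_mz / LAMBDA_AVERAGINE).astype(int)
    frac = peptide.peak_mz - LAMBDA_AVERAGINE * nominal
    iso_index = np.round(frac / (ISOTOPE_SPACING - LAMBDA_AVERAGINE)).astype(int)
    species = nominal - iso_index  # nominal mass of the monoisotopic parent
    unique_species = np.unique(species)
    on = rng.random(unique_species.size) < occupancy
    amp = mean_amplitude * rng.lognormal(mean=0.0, sigma=log_sigma, size=unique_species.size)
    species_amp = {s: (a if o else 0.0) for s, o, a in zip(unique_species, on, amp)}
    for j in range(peptide.n_peaks):
        alpha[j] = species_amp[species[j]] * weights[j]
    return alpha


def exponential_baseline(amplitude: float, m_min: float, tau: float = 500.0):
    """Smooth decaying baseline typical of MALDI-TOF spectra."""

    def b(t):
        return amplitude * np.exp(-(np.asarray(t) - m_min) / tau)

    return b


def synthesize_dataset(
    n_spots: int,
    mass_range: tuple[float, float] = (600.0, 3200.0),
    grid_step: float = 0.01,
    occupancy: float = 0.30,
    alpha_log_sigma: float = 1.0,
    spot_jitter: float = 0.25,
    matrix_level: float = 0.5,
    baseline_amplitude: float = 0.05,
    noise_sd: float = 0.01,
    shifts=None,
    isotopes: int = 3,
    sigma_peak: float = 0.05,
    seed: int = 0,
    n_max_cluster: int = 12,
):
    """Generate a peptide+matrix MSI dataset with optional per-spot shifts.

    All spots share one sparse peptide template (so dataset-level peak
    statistics are meaningful) with per-spot log-normal intensity jitter and
    a per-spot uniform matrix level in [0, 2*matrix_level].  ``shifts`` is
    an optional list of per-spot mass-shift functions (None = aligned).
    ``noise_sd`` is relative to the template's maximum peak amplitude.

    Returns (dataset, truths, components) where components is the dict of
    generating :class:`ComponentModel` objects.
    """
    if n_spots < 1:
        raise ValueError("n_spots must be >= 1")
    rng = np.random.default_rng(seed)
    peptide = averagine_component(mass_range, isotopes=isotopes)
    matrix = chca_component(mass_range, n_max=n_max_cluster, isotopes=isotopes)
    template = sparse_peptide_alpha(
        peptide, occupancy=occupancy, log_sigma=alpha_log_sigma, rng=rng
    )
    matrix_template = (
        matrix.peak_weight if matrix.peak_weight is not None else np.ones(matrix.n_peaks)
    )
    ref_amp = float(template.max()) if template.max() > 0 else 1.0
    grid = np.arange(mass_range[0], mass_range[1] + 0.5 * grid_step, grid_step)
    baseline = exponential_baseline(baseline_amplitude * ref_amp, mass_range[0])

    spectra, truths = [], []
    for i in range(n_spots):
        pep_alpha = template * rng.lognormal(0.0, spot_jitter, size=template.shape)
        mat_scale = rng.uniform(0.0, 2.0 * matrix_level) * ref_amp
        mat_alpha = matrix_template * mat_scale
        shift = shifts[i] if shifts is not None else None
        spot_seed = int(rng.integers(0, 2**31 - 1))
        spec, truth = synthesize_spectrum(
            [peptide, matrix],
            np.concatenate([pep_alpha, mat_alpha]),
            baseline_spec=baseline,
            shift=shift,
            grid=grid,
            sigma_peak=sigma_peak,
            noise_sd=noise_sd * ref_amp,
            noise_seed=spot_seed,
            spot_id=f"spot_{i}",
        )
        spec.coords = (i % 64, i // 64)
        spectra.append(spec)
        truths.append(truth)
    dataset = MSIDataset(spectra=spectra, mass_range=mass_range, metadata={"seed": seed})
    return dataset, truths, {"peptide": peptide, "matrix": matrix}
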