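"""Centered Kendrick mass-defect maps and their 2D histogram encoding.

For peptide MALDI data the natural Kendrick base is the averagine spacing
``lambda_av ~ 1 + 4.95e-4``: peptide monoisotopic masses cluster at integer
multiples of ``lambda_av``, so their centered defects sit near zero and any
systematic displacement of the cluster reads off the mass-shift function.
The histogram encoding (defect rows x m/z columns) turns a spectrum of
arbitrary length into a fixed-size array, the input of the shift-estimation
network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Averagine Kendrick base: peptide masses are approximately this multiple of
#: their nominal (integer) mass.
LAMBDA_AVERAGINE = 1.0 + 4.95e-4


@dataclass(frozen=True)
class KendrickConfig:
    """Binning configuration for the mass-defect histogram.

    Parameters
    ----------
    lam
        Kendrick base (dimensionless). Default is the averagine base.
    n_mz_bins
        Number of m/z columns ``K``.
    n_defect_bins
        Number of defect rows ``L`` spanning [-0.5, 0.5).
    mass_range
        Inclusive (m_min, m_max) window in Da; samples outside are dropped.
    log_intensity
        If True, intensities are transformed by log1p before accumulation.
    """

    lam: float = LAMBDA_AVERAGINE
    n_mz_bins: int = 24
    n_defect_bins: int = 256
    mass_range: tuple[float, float] = (600.0, 3200.0)
    log_intensity: bool = False

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError("Kendrick base lam must be positive")
        if self.n_mz_bins < 1:
            raise ValueError("n_mz_bins must be >= 1")
        if self.n_defect_bins < 2:
            raise ValueError("n_defect_bins must be >= 2")
        if not self.mass_range[0] < self.mass_range[1]:
            raise ValueError("mass_range must satisfy m_min < m_max")

    @property
    def mz_edges(self) -> np.ndarray:
        return np.linspace(self.mass_range[0], self.mass_range[1], self.n_mz_bins + 1)

    @property
    def mz_centers(self) -> np.ndarray:
        e = self.mz_edges
        return 0.5 * (e[:-1] + e[1:])

    @property
    def defect_edges(self) -> np.ndarray:
        return np.linspace(-0.5, 0.5, self.n_defect_bins + 1)


@dataclass
class KendrickHistogram:
    """L x K intensity grid over (Kendrick defect, m/z).

    The defect axis is circular: row 0 is adjacent to row L-1, because a
    defect crossing +0.5 reappears at -0.5 one nominal mass higher.
    """

    values: np.ndarray
    mz_edges: np.ndarray
    defect_edges: np.ndarray
    total_intensity: float
    lam: float = LAMBDA_AVERAGINE
    normalized: bool = field(default=False)

    @property
    def n_defect_bins(self) -> int:
        return self.values.shape[0]

    @property
    def n_mz_bins(self) -> int:
        return self.values.shape[1]

    @property
    def mz_centers(self) -> np.ndarray:
        return 0.5 * (self.mz_edges[:-1] + self.mz_edges[1:])


def kendrick_defect(m, lam: float = LAMBDA_AVERAGINE):
    """Centered Kendrick mass defect of mass ``m`` to base ``lam``.

    delta = m/lam - floor(m/lam + 1/2), always in [-0.5, 0.5).  Half-integer
    ``m/lam`` maps to the upper nominal mass, giving delta = -0.5.

    Accepts scalars or arrays; masses must be strictly positive.
    """
    m = np.asarray(m, dtype=float)
    if np.any(m <= 0):
        raise ValueError("mass must be positive")
    x = m / lam
    delta = x - np.floor(x + 0.5)
    # floating point can produce delta == 0.5 when x + 0.5 rounds down; fold it
    delta = np.where(delta >= 0.5, delta - 1.0, delta)
    if delta.ndim == 0:
        return float(delta)
    return delta


def nearest_nominal_mass(m, lam: float = LAMBDA_AVERAGINE):
    """Nominal (integer) mass nearest to ``m`` on the Kendrick scale."""
    m = np.asarray(m, dtype=float)
    return np.floor(m / lam + 0.5)


def defect_map(spectrum, lam: float = LAMBDA_AVERAGINE) -> np.ndarray:
    """Mass-defect map of a spectrum: array of (m, delta, intensity) rows."""
    delta = kendrick_defect(spectrum.mz, lam)
    return np.column_stack([spectrum.mz, np.atleast_1d(delta), spectrum.intensity])


def build_histogram(spectrum, cfg: KendrickConfig, normalize: str = "none") -> KendrickHistogram:
    """Accumulate spectral intensities into the (defect, m/z) histogram.

    With ``normalize="none"`` the histogram conserves total in-range
    intensity exactly.  With ``normalize="column_sum"`` each nonzero m/z
    column is divided by its sum (a separate, later step conceptually —
    conservation is defined on the raw histogram).

    Samples outside ``cfg.mass_range`` are excluded; the count is logged.
    """
    if normalize not in ("none", "column_sum"):
        raise ValueError(f"unknown normalize mode: {normalize!r}")
    mz = np.asarray(spectrum.mz, dtype=float)
    intensity = np.asarray(spectrum.intensity, dtype=float)
    m_min, m_max = cfg.mass_range
    in_range = (mz >= m_min) & (mz <= m_max)
    n_excluded = int(mz.size - np.count_nonzero(in_range))
    if n_excluded:
        # routine during shift augmentation (samples drift past the range edge)
        logger.debug("build_histogram: %d samples outside mass range excluded", n_excluded)
    mz = mz[in_range]
    intensity = intensity[in_range]
    if cfg.log_intensity:
        intensity = np.log1p(intensity)

    delta = kendrick_defect(mz, cfg.lam) if mz.size else np.empty(0)
    mz_edges = cfg.mz_edges
    defect_edges = cfg.defect_edges

    # left-closed/right-open binning; m_max folds into the last column
    col = np.searchsorted(mz_edges, mz, side="right") - 1
    col = np.clip(col, 0, cfg.n_mz_bins - 1)
    row = np.floor((np.atleast_1d(delta) + 0.5) * cfg.n_defect_bins).astype(int)
    row = np.clip(row, 0, cfg.n_defect_bins - 1)

    flat = np.bincount(row * cfg.n_mz_bins + col, weights=intensity,
                       minlength=cfg.n_defect_bins * cfg.n_mz_bins)
    values = flat.reshape(cfg.n_defect_bins, cfg.n_mz_bins)
    total = float(values.sum())

    hist = KendrickHistogram(
        values=values,
        mz_edges=mz_edges,
        defect_edges=defect_edges,
        total_intensity=total,
        lam=cfg.lam,
    )
    if normalize == "column_sum":
        hist = normalize_columns(hist)
    return hist


def normalize_columns(hist: KendrickHistogram) -> KendrickHistogram:
    """Scale each m/z column to unit sum; all-zero columns stay zero."""
    col_sums = hist.values.sum(axis=0, keepdims=True)
    safe = np.where(col_sums > 0, col_sums, 1.0)
    return KendrickHistogram(
        values=hist.values / safe,
        mz_edges=hist.mz_edges,
        defect_edges=hist.defect_edges,
        total_intensity=hist.total_intensity,
        lam=hist.lam,
        normalized=True,
    )
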