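"""Model-based auxiliary recalibration by spectral decomposition.

A spectrum ``X(t)`` is approximated by a mixture of theoretical components
(peptide and matrix peak lists) with a smooth mass shift and baseline:

    X(t) ~ b_phi(t) + sum_{i,j} alpha_j^i * G(t - p_j^i - Delta_psi(t); sigma)

where ``G`` is a unit-height Gaussian (sigma = 0.05 Da by default) and both
``Delta_psi`` and ``b_phi`` are one-hidden-layer feed-forward networks of
the m/z coordinate (ReLU hidden units, no final activation for the shift, a
softplus clamp keeping the baseline non-negative).  Minimizing the squared
residual jointly over the non-negative peak intensities alpha and the two
network parameter vectors yields, per spectrum: a calibrated m/z axis, the
extracted mass-shift function, a peptide/matrix decomposition and the
matrix score (matrix fraction of the fitted signal).

This fit is accurate but slow, so it is run on a small subset of spots; its
outputs bootstrap the training set of the fast convolutional estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .models import ComponentModel, gaussian_mixture
from .msi_io import Spectrum, MSIDataset
from .nn import Adam, Parameter, TinyMLP
from .shift_sim import MassShiftFunction, tabulated_shift

logger = logging.getLogger(__name__)


def _softplus(x):
    return np.logaddexp(0.0, x)


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _inv_softplus(y):
    y = np.maximum(y, 1e-8)
    return y + np.log(-np.expm1(-y))


class ShiftNetParams:
    """Feed-forward parametrization of the mass-shift function Delta_psi(t).

    The m/z input is scaled to [0, 1] over ``mass_range``.  The output is
    in Da and unbounded by default; an optional soft cap squashes it to
    ``(-cap, cap)`` via cap*tanh(raw/cap).
    """

    def __init__(self, mass_range: tuple[float, float], hidden: int = 32,
                 cap: float | None = None, rng: np.random.Generator | None = None):
        rng = np.random.default_rng(0) if rng is None else rng
        self.mass_range = mass_range
        self.net = TinyMLP(hidden, rng, out_scale=0.01)
        self.cap = cap

    def _scale(self, t):
        lo, hi = self.mass_range
        return (np.asarray(t, dtype=float) - lo) / (hi - lo)

    def delta(self, t) -> np.ndarray:
        raw = self.net.forward(self._scale(np.atleast_1d(t)))
        if self.cap is not None:
            raw = self.cap * np.tanh(raw / self.cap)
        return raw

    def __call__(self, t):
        out = self.delta(t)
        return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out

    def parameters(self):
        return self.net.parameters()

    def copy_from(self, other: "ShiftNetParams") -> None:
        for p, q in zip(self.net.parameters(), other.net.parameters()):
            p.value[...] = q.value


class BaselineParams:
    """Feed-forward baseline b_phi(t) >= 0 (softplus-clamped output)."""

    def __init__(self, mass_range: tuple[float, float], hidden: int = 32,
                 rng: np.random.Generator | None = None):
        rng = np.random.default_rng(1) if rng is None else rng
        self.mass_range = mass_range
        self.net = TinyMLP(hidden, rng, out_scale=0.01)
        self.net.b2.value[0] = -4.0  # start with a nearly zero baseline

    def _scale(self, t):
        lo, hi = self.mass_range
        return (np.asarray(t, dtype=float) - lo) / (hi - lo)

    def baseline(self, t) -> np.ndarray:
        return _softplus(self.net.forward(self._scale(np.atleast_1d(t))))

    def parameters(self):
        return self.net.parameters()

    def copy_from(self, other: "BaselineParams") -> None:
        for p, q in zip(self.net.parameters(), other.net.parameters()):
            p.value[...] = q.value


@dataclass
class FitOptions:
    """Optimizer settings for the decomposition fit."""

    sigma_peak: float = 0.05          # Gaussian peak width (Da)
    max_iter: int = 2000
    lr: float = 0.02                  # Adam step size (spectrum normalized to max 1)
    warm_lr_factor: float = 0.2       # learning-rate shrink when warm-starting
    tol: float = 1e-5                 # relative best-objective improvement per window
    patience: int = 100               # window length (iterations) for the stopping rule
    hidden: int = 32                  # hidden units of the shift/baseline nets
    shift_penalty: float = 1e-3       # weight of the mean Delta^2 soft penalty
    shift_cap: float | None = None    # optional hard tanh bound on Delta (Da)
    max_expected_shift: float = 0.35  # half-width margin (Da) for peak windows
    knot_spacing: float = 1.0         # Da between net-evaluation knots (smoothness scale)
    fit_baseline: bool = True
    seed: int = 0


@dataclass
class RecalResult:
    """Outcome of fitting the component mixture to one spectrum."""

    alpha: np.ndarray
    shift: ShiftNetParams
    baseline: BaselineParams | None
    residual_norm: float
    matrix_score: float
    extracted_shift: MassShiftFunction
    converged: bool
    n_iter: int
    component_names: list[str] = field(default_factory=list)
    component_slices: list[tuple[int, int]] = field(default_factory=list)
    objective_history: np.ndarray | None = None
    accepted_objectives: np.ndarray | None = None

    def alpha_for(self, name: str) -> np.ndarray:
        for nm, (a, b) in zip(self.component_names, self.component_slices):
            if nm == name:
                return self.alpha[a:b]
        raise KeyError(name)


def _component_peaks(components: list[ComponentModel]):
    peaks = np.concatenate([c.peak_mz for c in components])
    slices, start = [], 0
    for c in components:
        slices.append((start, start + c.n_peaks))
        start += c.n_peaks
    names = [c.name for c in components]
    return peaks, names, slices


def model_spectrum(alpha, shift, baseline, components: list[ComponentModel],
                   grid: np.ndarray, sigma_peak: float = 0.05) -> Spectrum:
    """Evaluate the component-mixture model on an m/z grid.

    ``shift`` may be None, a :class:`MassShiftFunction`, or
    :class:`ShiftNetParams`; ``baseline`` may be None, an array on the grid,
    or :class:`BaselineParams`.
    """
    grid = np.asarray(grid, dtype=float)
    peaks, _, _ = _component_peaks(components)
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != peaks.shape:
        raise ValueError(f"alpha has length {alpha.size}, components define {peaks.size} peaks")
    if sigma_peak <= 0:
        raise ValueError("sigma_peak must be positive")
    if shift is None:
        delta = np.zeros_like(grid)
    elif isinstance(shift, ShiftNetParams):
        delta = shift.delta(grid)
    else:
        delta = np.asarray(shift(grid), dtype=float)
    t_eff = grid - delta
    order = np.argsort(peaks)
    y = gaussian_mixture(t_eff, peaks[order], alpha[order], sigma_peak)
    if baseline is None:
        b = 0.0
    elif isinstance(baseline, BaselineParams):
        b = baseline.baseline(grid)
    else:
        b = np.asarray(baseline, dtype=float)
    return Spectrum(grid, np.maximum(y + b, 0.0))


def fit_model(spectrum: Spectrum, components: list[ComponentModel],
              opts: FitOptions | None = None, init: RecalResult | None = None) -> RecalResult:
    """Fit the mixture + shift + baseline model to one spectrum.

    First-order joint optimization (Adam) of the squared residual over
    (softplus-reparametrized) peak intensities and the two network
    parameter vectors.  ``init`` warm-starts all parameters from a previous
    spectrum's result.  Returns the best (lowest-objective) parameters seen.
    """
    opts = opts or FitOptions()
    t = spectrum.mz
    mass_range = (float(t[0]), float(t[-1]))
    peaks, names, slices = _component_peaks(components)
    order = np.argsort(peaks)
    peaks_sorted = peaks[order]
    sigma = opts.sigma_peak

    scale = float(spectrum.intensity.max())
    if scale <= 0:
        raise ValueError("cannot fit an all-zero spectrum")
    X = spectrum.intensity / scale
    d = X.size

    # fixed sparse (peak, grid) index structure; windows wide enough to keep
    # every plausible shifted position of each peak in view
    w = 5.0 * sigma + opts.max_expected_shift
    lo = np.searchsorted(t, peaks_sorted - w, side="left")
    hi = np.searchsorted(t, peaks_sorted + w, side="right")
    counts = hi - lo
    nz = counts > 0
    pk_idx = np.repeat(np.nonzero(nz)[0], counts[nz])
    g_idx = np.concatenate([np.arange(a, b) for a, b in zip(lo[nz], hi[nz])]) if nz.any() else np.empty(0, int)

    rng = np.random.default_rng(opts.seed)
    shift_net = ShiftNetParams(mass_range, hidden=opts.hidden, cap=opts.shift_cap, rng=rng)
    base_net = BaselineParams(mass_range, hidden=opts.hidden, rng=rng) if opts.fit_baseline else None

    # alpha init: data intensity at each theoretical location
    alpha0 = np.interp(peaks_sorted, t, X)
    u = Parameter(_inv_softplus(np.maximum(alpha0, 1e-3)))

    if init is not None:
        shift_net.copy_from(init.shift)
        if base_net is not None and init.baseline is not None:
            base_net.copy_from(init.baseline)
        if init.alpha.size == peaks.size:
            u.value[...] = _inv_softplus(np.maximum(init.alpha[order] / scale, 1e-6))

    params = [u] + shift_net.parameters() + (base_net.parameters() if base_net else [])
    # a warm start sits near an optimum already; Adam's scale-normalized first
    # steps would kick it away at the cold-start step size
    lr = opts.lr * opts.warm_lr_factor if init is not None else opts.lr
    optim = Adam(params, lr=lr)

    # the shift and baseline vary on the Da scale, far slower than the grid:
    # evaluate both networks on coarse knots and interpolate linearly onto
    # the grid (with the exact adjoint for the backward pass)
    n_knots = max(65, int(np.ceil((mass_range[1] - mass_range[0]) / opts.knot_spacing)) + 1)
    tc = np.linspace(mass_range[0], mass_range[1], n_knots)
    xc = shift_net._scale(tc)
    knot_step = tc[1] - tc[0]
    pos = np.clip((t - tc[0]) / knot_step, 0.0, n_knots - 1.0 - 1e-9)
    i0 = pos.astype(np.intp)
    w1 = pos - i0
    w0 = 1.0 - w1

    def interp_fine(vals_c):
        return w0 * vals_c[i0] + w1 * vals_c[i0 + 1]

    def adjoint_coarse(g_fine):
        return np.bincount(i0, weights=w0 * g_fine, minlength=n_knots) + np.bincount(
            i0 + 1, weights=w1 * g_fine, minlength=n_knots
        )

    def forward():
        raw_c = shift_net.net.forward(xc)
        if opts.shift_cap is not None:
            tanh_arg = np.tanh(raw_c / opts.shift_cap)
            delta_c = opts.shift_cap * tanh_arg
            dchain_c = 1.0 - tanh_arg**2
        else:
            delta_c = raw_c
            dchain_c = None
        delta = interp_fine(delta_c)
        alpha = _softplus(u.value)
        t_eff = t - delta
        uval = t_eff[g_idx] - peaks_sorted[pk_idx]
        gauss = np.exp(-0.5 * (uval / sigma) ** 2)
        contrib = alpha[pk_idx] * gauss
        signal = np.bincount(g_idx, weights=contrib, minlength=d)
        if base_net is not None:
            braw_c = base_net.net.forward(xc)
            b = interp_fine(_softplus(braw_c))
        else:
            braw_c, b = None, 0.0
        model = signal + b
        r = model - X
        F = float(np.mean(r**2) + opts.shift_penalty * np.mean(delta**2))
        return F, (r, delta, dchain_c, alpha, uval, gauss, contrib, braw_c)

    best_F = np.inf
    best_state = None
    history = []
    accepted = []
    n_iter = 0
    converged = False

    for n_iter in range(1, opts.max_iter + 1):
        optim.zero_grad()
        F, (r, delta, dchain_c, alpha, uval, gauss, contrib, braw_c) = forward()
        if not np.isfinite(F):
            raise RuntimeError(
                f"non-finite objective at iteration {n_iter} "
                f"(lr={opts.lr}, last good objective={best_F})"
            )
        history.append(F)
        if F < best_F - 1e-15:
            best_F = F
            best_state = [p.value.copy() for p in params]
        accepted.append(best_F)

        gmodel = (2.0 / d) * r
        gm_at = gmodel[g_idx]
        # alpha
        galpha = np.bincount(pk_idx, weights=gm_at * gauss, minlength=peaks.size)
        u.grad += galpha * _sigmoid(u.value)
        # shift: gradient on the grid, pulled back to the coarse knots
        gdelta = np.bincount(g_idx, weights=gm_at * contrib * uval / sigma**2, minlength=d)
        gdelta += (2.0 * opts.shift_penalty / d) * delta
        gdelta_c = adjoint_coarse(gdelta)
        if dchain_c is not None:
            gdelta_c = gdelta_c * dchain_c
        shift_net.net.backward(gdelta_c)
        # baseline
        if base_net is not None:
            base_net.net.backward(adjoint_coarse(gmodel) * _sigmoid(braw_c))
        optim.step()

        # stop when the best objective has stopped improving over a window
        if n_iter > opts.patience:
            old_best = accepted[-opts.patience - 1]
            if old_best - best_F <= opts.tol * max(old_best, 1e-12):
                converged = True
                break

    if best_state is not None:
        for p, v in zip(params, best_state):
            p.value[...] = v
    final_F, _ = forward()

    alpha_sorted = _softplus(u.value) * scale
    alpha_out = np.empty_like(alpha_sorted)
    alpha_out[order] = alpha_sorted

    knots = np.linspace(mass_range[0], mass_range[1], 65)
    extracted = tabulated_shift(knots, shift_net.delta(knots), domain=mass_range)

    result = RecalResult(
        alpha=alpha_out,
        shift=shift_net,
        baseline=base_net,
        residual_norm=float(final_F),
        matrix_score=0.0,
        extracted_shift=extracted,
        converged=converged,
        n_iter=n_iter,
        component_names=names,
        component_slices=slices,
        objective_history=np.array(history),
        accepted_objectives=np.array(accepted),
    )
    result.matrix_score = matrix_score(result, components)
    return result


def calibrate(spectrum: Spectrum, shift) -> Spectrum:
    """Correct a spectrum: every sample moves m -> m - Delta(m)."""
    if isinstance(shift, ShiftNetParams):
        delta = shift.delta(spectrum.mz)
    else:
        delta = np.asarray(shift(spectrum.mz), dtype=float)
    new_mz = spectrum.mz - delta
    if new_mz.size > 1 and np.any(np.diff(new_mz) <= 0):
        raise ValueError("correction inverts m/z ordering (non-monotone mass map)")
    return Spectrum(new_mz, spectrum.intensity.copy(), spectrum.spot_id, spectrum.coords)


def matrix_score(result: RecalResult, components: list[ComponentModel],
                 spectrum: Spectrum | None = None) -> float:
    """Fraction of the fitted signal attributable to matrix components.

    Numerator: summed fitted matrix intensities; denominator: summed fitted
    intensities of all components (unit-height Gaussians of common width, so
    peak areas are proportional to alpha).  The baseline is excluded.  If
    ``spectrum`` is given, the denominator is instead the spectrum's total
    raw intensity rescaled to peak-amplitude units.
    """
    if "matrix" not in result.component_names:
        raise ValueError("result has no component named 'matrix'")
    num = float(result.alpha_for("matrix").sum())
    if spectrum is not None:
        sigma = 0.05
        area_per_alpha = np.sqrt(2 * np.pi) * sigma
        step = np.median(np.diff(spectrum.mz))
        denom = float(spectrum.intensity.sum() * step / area_per_alpha)
    else:
        denom = float(result.alpha.sum())
    if denom <= 0:
        logger.warning("matrix_score: zero total model intensity; returning 0")
        return 0.0
    return float(np.clip(num / denom, 0.0, 1.0))


def batch_recalibrate(dataset: MSIDataset, components: list[ComponentModel],
                      n_spots: int, selection: str = "random", seed: int = 0,
                      opts: FitOptions | None = None, warm_start: bool = True):
    """Fit a subset of spots sequentially, warm-starting each from the last.

    Returns a list of (RecalResult, calibrated Spectrum, matrix Spectrum)
    triples; the matrix spectrum is the fitted matrix component rendered at
    theoretical positions on the calibrated axis, ready for augmentation.
    Per-spot failures are logged and skipped.
    """
    opts = opts or FitOptions()
    if n_spots > len(dataset):
        raise ValueError("n_spots exceeds dataset size")
    if selection == "random":
        rng = np.random.default_rng(seed)
        indices = np.sort(rng.choice(len(dataset), size=n_spots, replace=False))
    elif selection == "grid":
        indices = np.unique(np.linspace(0, len(dataset) - 1, n_spots).round().astype(int))
    else:
        raise ValueError(f"unknown selection mode: {selection!r}")

    matrix_components = [c for c in components if c.name == "matrix"]
    out = []
    prev = None
    n_failed = 0
    for idx in indices:
        spot = dataset[int(idx)]
        try:
            result = fit_model(spot, components, opts=opts, init=prev if warm_start else None)
        except Exception:
            logger.exception("model-based fit failed for spot %s; skipping", spot.spot_id)
            n_failed += 1
            continue
        calibrated = calibrate(spot, result.shift)
        if matrix_components:
            mat_alpha = result.alpha_for("matrix")
            matrix_spec = model_spectrum(mat_alpha, None, None, matrix_components,
                                         calibrated.mz, opts.sigma_peak)
            matrix_spec.spot_id = f"{spot.spot_id}_matrix"
        else:
            matrix_spec = None
        out.append((result, calibrated, matrix_spec))
        prev = result
    if n_failed:
        logger.warning("batch_recalibrate: %d of %d spots failed", n_failed, len(indices))
    return out
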