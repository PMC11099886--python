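# massshiftnet

Self-supervised mass recalibration for MALDI mass spectrometry imaging
(MSI).

MALDI-TOF imaging spectra carry smooth, pixel-dependent m/z errors Δ(t) of
tens of ppm, caused by surface topography and space-charge effects. This
package estimates Δ(t) per spectrum — without calibrant spray and without
labeled data — and corrects each axis by t → t − Δ(t). It is aimed at MSI
practitioners and methods developers working with peptide (or similarly
structured) data.

## Method

The framework rests on the centered **Kendrick mass defect**
δ_λ(m) = m/λ − ⌊m/λ + 1/2⌋ with the averagine base λ ≈ 1 + 4.95·10⁻⁴:
peptide masses cluster near integer multiples of λ, so in the (m/z, δ)
plane the peptide population forms a band near δ = 0 whose displacement is
the local mass shift. Each spectrum is encoded as an L×K histogram over
(δ, m/z) and a convolutional network f_θ maps the histogram to a length-K
shift vector (one value per m/z bin, in defect units, bounded to
[−0.5, 0.5] by a tanh/2 output).

Training is **self-supervised**: a small subset of spots is calibrated by
a model-based spectral decomposition

    X(t) ≈ b_φ(t) + Σ_{i,j} α_j^i G(t − p_j^i − Δ_ψ(t); σ),   σ = 0.05 Da,

fitted jointly over non-negative peak intensities α (averagine peptide and
CHCA matrix-cluster peak lists) and neural-network-parametrized shift
Δ_ψ and baseline b_φ. The calibrated spectra are then distorted by
thousands of simulated shift functions (linear, square-root, and
perturbed extracted shifts; matrix signal augmented by 0–100%), and the
network learns to regress the known distortion from the histogram —
minimizing the mean squared error min_θ Σ_i ‖f_θ(H_i) − Δ_i‖². Inference
is one forward pass per spectrum, so whole datasets recalibrate quickly.
The decomposition also yields a per-spot **matrix score** (matrix fraction
of the fitted signal), a data-quality map in its own right.

Everything — including the convolutional network and its training loop —
is implemented in numpy/scipy with explicit backpropagation; there is no
deep-learning framework dependency.

## Worked example

```python
import numpy as np
from massshiftnet import (KendrickConfig, build_histogram, linear_shift,
                          apply_shift, averagine_component, chca_component,
                          synthesize_spectrum, fit_model)
from massshiftnet.models import sparse_peptide_alpha

rng = np.random.default_rng(0)
mass_range = (600.0, 750.0)
pep = averagine_component(mass_range, isotopes=1)
mat = chca_component(mass_range, isotopes=1)
alpha = np.concatenate([
    sparse_peptide_alpha(pep, occupancy=0.3, rng=rng),
    0.3 * mat.peak_weight / mat.peak_weight.max(),
])
grid = np.arange(*mass_range, 0.01)
truth = linear_shift(3e-5, 0.03, mass_range)       # +0.051 Da at m/z 700
spec, _ = synthesize_spectrum([pep, mat], alpha, shift=truth, grid=grid)

result = fit_model(spec, [pep, mat])
probe = np.linspace(610, 740, 5)
print(np.round(result.shift.delta(probe), 4))      # fitted shift (Da)
print(np.round(truth(probe), 4))                   # injected shift (Da)
print(round(result.matrix_score, 3))
```

prints

```
[0.0483 0.0491 0.05   0.0509 0.0517]
[0.0483 0.0493 0.0503 0.0512 0.0522]
0.059
```

— the decomposition recovers the injected linear shift to within
0.0005 Da across the window, and reports that ~6% of the fitted signal is
matrix clusters (this example's matrix amplitudes are small). A command-line pipeline (`massshiftnet simulate /
fit-model / make-training / train / apply / evaluate / matrix-score`)
wires the same stages into reproducible runs.

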