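"""The convolutional mass-shift estimator and whole-dataset recalibration.

The estimator maps a column-normalized (L defect rows x K m/z columns)
Kendrick histogram to a length-K vector of per-column mass shifts in
defect units.  Architecture: six per-column 1D convolutions over the
defect axis (independent filter bank per column, circular padding, batch
norm + leaky rectification), four 2D convolutions mixing columns, a 1D
convolution reducing channels to one, and one independent two-layer
perceptron per column with a tanh output scaled by 0.5 — so predictions
always lie in [-0.5, 0.5], one defect period.

Training minimizes the mean squared error between predicted and simulated
shift vectors (Adam, learning rate 1e-4, batch size 64 by default).  A
trained model recalibrates a full dataset with one forward pass per
spectrum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np

from .kendrick import KendrickConfig, KendrickHistogram, build_histogram, normalize_columns
from .msi_io import MSIDataset, save_artifact, load_artifact
from .nn import (
    Adam,
    BatchNorm,
    ColumnConv1d,
    ColumnsToImage,
    Conv2d,
    ImageToColumns,
    LeakyReLU,
    PerBinMLP,
    Sequential,
    ToColumns,
)
from .shift_sim import MassShiftFunction, TrainingSample, tabulated_shift
from .modelcal import calibrate

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters of the shift estimator."""

    n_mz_bins: int = 24
    n_defect_bins: int = 256
    conv1d_channels: tuple[int, ...] = (8, 16, 16, 16, 16, 16)
    conv1d_kernel: int = 9
    conv2d_channels: tuple[int, ...] = (32, 32, 32, 16)
    conv2d_kernel: tuple[int, int] = (3, 3)
    mlp_hidden: int = 64
    leaky_slope: float = 0.01

    def __post_init__(self) -> None:
        if len(self.conv1d_channels) != 6:
            raise ValueError("the 1D feature block has six convolutional layers")
        if len(self.conv2d_channels) != 4:
            raise ValueError("the 2D feature block has four convolutional layers")
        if self.conv1d_kernel > self.n_defect_bins or self.conv2d_kernel[1] > self.n_defect_bins:
            raise ValueError("convolution kernel larger than the defect axis")
        if self.conv1d_kernel % 2 == 0:
            raise ValueError("kernel sizes must be odd")

    @classmethod
    def reduced(cls, n_mz_bins: int = 24, n_defect_bins: int = 64) -> "NetworkSpec":
        """Half-width preset for CPU-scale experiments."""
        return cls(
            n_mz_bins=n_mz_bins,
            n_defect_bins=n_defect_bins,
            conv1d_channels=(4, 8, 8, 8, 8, 8),
            conv1d_kernel=5,
            conv2d_channels=(8, 8, 8, 8),
            conv2d_kernel=(3, 3),
            mlp_hidden=32,
        )


@dataclass
class TrainConfig:
    """Training-loop settings."""

    lr: float = 1e-4
    batch_size: int = 64
    epochs: int = 30
    seed: int = 0
    val_fraction: float = 0.1
    patience: int = 5
    mask_empty_columns: bool = False
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")


class MassShiftNet:
    """Trainable histogram -> shift-vector regressor."""

    def __init__(self, spec: NetworkSpec, seed: int = 0, dtype=np.float32):
        self.spec = spec
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        K, L = spec.n_mz_bins, spec.n_defect_bins
        layers: list = [ToColumns()]
        c_prev = 1
        for c in spec.conv1d_channels:
            # bias omitted where batch norm immediately renormalizes it away
            layers.append(ColumnConv1d(K, c_prev, c, spec.conv1d_kernel, rng,
                                       dtype=dtype, bias=False))
            layers.append(BatchNorm(c, n_columns=K, layout="columns", dtype=dtype))
            layers.append(LeakyReLU(spec.leaky_slope))
            c_prev = c
        layers.append(ColumnsToImage())
        for c in spec.conv2d_channels:
            layers.append(Conv2d(c_prev, c, spec.conv2d_kernel, rng, dtype=dtype, bias=False))
            layers.append(BatchNorm(c, dtype=dtype))
            layers.append(LeakyReLU(spec.leaky_slope))
            c_prev = c
        layers.append(ImageToColumns())
        layers.append(ColumnConv1d(K, c_prev, 1, 1, rng, dtype=dtype))
        layers.append(PerBinMLP(K, L, spec.mlp_hidden, rng, slope=spec.leaky_slope, dtype=dtype))
        self.net = Sequential(layers)
        self.training = True

    def parameters(self):
        return self.net.parameters()

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, 1, K, L) batch of histograms; returns (N, K) shift vectors."""
        return self.net.forward(np.asarray(x, dtype=self.dtype), self.training)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return self.net.backward(gy)

    def eval(self):
        self.training = False
        return self

    def train_mode(self):
        self.training = True
        return self

    # --- persistence -------------------------------------------------------

    def get_state(self) -> dict[str, np.ndarray]:
        state = {}
        for i, p in enumerate(self.parameters()):
            state[f"param_{i:03d}"] = p.value
        for i, layer in enumerate(self.net.layers):
            if isinstance(layer, BatchNorm):
                state[f"bn_{i:03d}_mean"] = layer.running_mean
                state[f"bn_{i:03d}_var"] = layer.running_var
        return state

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.value[...] = state[f"param_{i:03d}"]
        for i, layer in enumerate(self.net.layers):
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = state[f"bn_{i:03d}_mean"]
                layer.running_var[...] = state[f"bn_{i:03d}_var"]


def build_network(spec: NetworkSpec, seed: int = 0) -> MassShiftNet:
    """Instantiate the estimator with seeded (reproducible) initial weights."""
    return MassShiftNet(spec, seed=seed)


def _stack_samples(samples: list[TrainingSample]) -> tuple[np.ndarray, np.ndarray]:
    # histogram values are (L, K); network layout is (N, 1, K, L)
    X = np.stack([s.histogram.values.T for s in samples])[:, None, :, :].astype(np.float32)
    y = np.stack([s.target for s in samples])
    return X, y


def _column_mask(X: np.ndarray) -> np.ndarray:
    # (N, K) weight: 1 where the histogram column has any mass
    return (X.sum(axis=(1, 3)) > 0).astype(float)


def train(model: MassShiftNet, samples: list[TrainingSample], cfg: TrainConfig | None = None,
          augment_fn=None) -> dict:
    """Train on (histogram, target) pairs; returns the loss history.

    The loss is the mean squared error of the predicted shift vector (in
    defect units) against the simulated target.  A validation split is held
    out sample-wise (each simulated shift function appears in exactly one
    sample, so the split separates shift functions); early stopping restores
    the best validation parameters.  ``augment_fn(epoch)``, if given, must
    return a fresh list of training samples for that epoch (used for
    re-drawing the matrix-augmentation fraction every epoch).
    """
    cfg = cfg or TrainConfig()
    if not samples:
        raise ValueError("training requires at least one sample")
    K = model.spec.n_mz_bins
    if samples[0].target.size != K:
        raise ValueError("target length does not match the network's m/z bins")
    rng = np.random.default_rng(cfg.seed)

    n = len(samples)
    n_val = max(1, int(round(cfg.val_fraction * n))) if n > 1 else 0
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    Xall, yall = _stack_samples(samples)
    Xval, yval = Xall[val_idx], yall[val_idx]

    optim = Adam(model.parameters(), lr=cfg.lr)
    history = {"train": [], "val": [], "aborted": False}
    best_val = np.inf
    best_state = None
    stall = 0

    for epoch in range(cfg.epochs):
        if augment_fn is not None:
            fresh = augment_fn(epoch)
            Xf, yf = _stack_samples(fresh)
            Xtr, ytr = Xf[train_idx], yf[train_idx]
        else:
            Xtr, ytr = Xall[train_idx], yall[train_idx]

        model.train_mode()
        order = rng.permutation(len(train_idx))
        epoch_losses = []
        aborted = False
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = Xtr[idx], ytr[idx]
            pred = model.forward(xb)
            diff = pred - yb
            if cfg.mask_empty_columns:
                w = _column_mask(xb)
                denom = max(w.sum(), 1.0)
                loss = float((w * diff**2).sum() / denom)
                gy = 2.0 * w * diff / denom
            else:
                loss = float(np.mean(diff**2))
                gy = 2.0 * diff / diff.size
            if not np.isfinite(loss):
                logger.error(
                    "non-finite training loss at epoch %d; restoring best checkpoint", epoch
                )
                history["aborted"] = True
                aborted = True
                break
            epoch_losses.append(loss)
            optim.zero_grad()
            model.backward(gy)
            optim.step()
        if aborted:
            break

        model.eval()
        if len(val_idx):
            vp = predict_batch(model, Xval)
            val_loss = float(np.mean((vp - yval) ** 2))
        else:
            val_loss = float("nan")
        history["train"].append(float(np.mean(epoch_losses)) if epoch_losses else float("nan"))
        history["val"].append(val_loss)
        if cfg.verbose:
            logger.info("epoch %d: train %.3e val %.3e", epoch, history["train"][-1], val_loss)

        if len(val_idx) and val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = model.get_state()
            stall = 0
        else:
            stall += 1
            if len(val_idx) and stall >= cfg.patience:
                break

    if best_state is not None:
        model.set_state(best_state)
    model.eval()
    return history


def predict_batch(model: MassShiftNet, X: np.ndarray, chunk: int = 256) -> np.ndarray:
    """Evaluation-mode forward pass in chunks; X is (N, 1, K, L)."""
    was_training = model.training
    model.eval()
    outs = [model.forward(X[i : i + chunk]) for i in range(0, X.shape[0], chunk)]
    if was_training:
        model.train_mode()
    return np.concatenate(outs, axis=0)


def predict_shift(model: MassShiftNet, histogram: KendrickHistogram) -> np.ndarray:
    """Predict the length-K shift vector (defect units) for one histogram."""
    K, L = model.spec.n_mz_bins, model.spec.n_defect_bins
    if histogram.values.shape != (L, K):
        raise ValueError(
            f"histogram shape {histogram.values.shape} does not match model ({L}, {K})"
        )
    if not histogram.normalized:
        histogram = normalize_columns(histogram)
    x = histogram.values.T[None, None, :, :]
    return predict_batch(model, x)[0]


def smooth_shift_vector(vector: np.ndarray, window: int = 5) -> np.ndarray:
    """Moving-average filter across m/z columns (edge-replicated).

    Physical shift functions vary smoothly on the ~100 Da column scale while
    the network's per-column errors are nearly independent, so averaging
    neighbouring columns reduces the estimation error without biasing smooth
    shifts.  ``window`` must be odd; 1 disables smoothing.
    """
    vector = np.asarray(vector, dtype=float)
    if window <= 1:
        return vector
    if window % 2 == 0:
        raise ValueError("window must be odd")
    pad = window // 2
    padded = np.pad(vector, pad, mode="edge")
    kernel = np.full(window, 1.0 / window)
    return np.convolve(padded, kernel, mode="valid")


def shift_vector_to_function(vector: np.ndarray, cfg: KendrickConfig) -> MassShiftFunction:
    """Convert a per-column defect-unit shift vector to a shift function in Da.

    Knots at the m/z bin centers with Delta = vector * lambda; piecewise
    linear between knots, constant beyond the first/last center.
    """
    vector = np.asarray(vector, dtype=float)
    if vector.size != cfg.n_mz_bins:
        raise ValueError("vector length must equal the number of m/z bins")
    return tabulated_shift(cfg.mz_centers, vector * cfg.lam, domain=cfg.mass_range)


def recalibrate_dataset(model: MassShiftNet, dataset: MSIDataset, cfg: KendrickConfig,
                        return_shifts: bool = False, smooth_window: int = 5):
    """Histogram -> predict -> smooth -> correct, for every spot of a dataset.

    Predicted shift vectors are averaged over ``smooth_window`` neighbouring
    columns before conversion (see :func:`smooth_shift_vector`; pass 1 to
    disable).  Spots whose prediction or correction fails are passed through
    unchanged (logged).  Returns the recalibrated dataset (and the per-spot
    shift functions if requested).
    """
    K, L = model.spec.n_mz_bins, model.spec.n_defect_bins
    if (cfg.n_mz_bins, cfg.n_defect_bins) != (K, L):
        raise ValueError("KendrickConfig binning does not match the model spec")
    hists = np.empty((len(dataset), 1, K, L))
    for i, spot in enumerate(dataset):
        h = build_histogram(spot, cfg, normalize="column_sum")
        hists[i, 0] = h.values.T
    vectors = predict_batch(model, hists)

    new_spectra = []
    shifts = []
    n_failed = 0
    for spot, vec in zip(dataset, vectors):
        try:
            fn = shift_vector_to_function(smooth_shift_vector(vec, smooth_window), cfg)
            new_spectra.append(calibrate(spot, fn))
            shifts.append(fn)
        except Exception:
            logger.exception("recalibration failed for spot %s; passing through", spot.spot_id)
            new_spectra.append(spot.copy())
            shifts.append(None)
            n_failed += 1
    if n_failed:
        logger.warning("recalibrate_dataset: %d of %d spots passed through", n_failed, len(dataset))
    out = MSIDataset(new_spectra, dataset.mass_range, dict(dataset.metadata))
    if return_shifts:
        return out, shifts
    return out


def save_model(model: MassShiftNet, path, kendrick_cfg: KendrickConfig | None = None,
               extra_meta: dict | None = None) -> None:
    """Persist weights + architecture (+ binning config) to one artifact file."""
    meta = {"network_spec": asdict(model.spec)}
    if kendrick_cfg is not None:
        meta["kendrick"] = {
            "lam": kendrick_cfg.lam,
            "n_mz_bins": kendrick_cfg.n_mz_bins,
            "n_defect_bins": kendrick_cfg.n_defect_bins,
            "mass_range": list(kendrick_cfg.mass_range),
            "log_intensity": kendrick_cfg.log_intensity,
        }
    if extra_meta:
        meta.update(extra_meta)
    save_artifact(path, model.get_state(), meta)


def load_model(path) -> tuple[MassShiftNet, dict]:
    """Load a model artifact; returns (model, metadata)."""
    arrays, meta = load_artifact(path)
    spec_dict = dict(meta["network_spec"])
    spec_dict["conv1d_channels"] = tuple(spec_dict["conv1d_channels"])
    spec_dict["conv2d_channels"] = tuple(spec_dict["conv2d_channels"])
    spec_dict["conv2d_kernel"] = tuple(spec_dict["conv2d_kernel"])
    spec = NetworkSpec(**spec_dict)
    model = MassShiftNet(spec)
    model.set_state(arrays)
    model.eval()
    return model, meta
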