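import numpy as np
import pytest

from massshiftnet import (
    KendrickConfig,
    MSIDataset,
    Spectrum,
    build_network,
    predict_shift,
    recalibrate_dataset,
    shift_vector_to_function,
    train,
    TrainConfig,
    NetworkSpec,
)
from massshiftnet.kendrick import KendrickHistogram
from massshiftnet.network import predict_batch, save_model, load_model
from massshiftnet.shift_sim import TrainingSample

K, L = 8, 16
CFG = KendrickConfig(n_mz_bins=K, n_defect_bins=L, mass_range=(600.0, 700.0))
SPEC = NetworkSpec(
    n_mz_bins=K,
    n_defect_bins=L,
    conv1d_channels=(2, 4, 4, 4, 4, 4),
    conv1d_kernel=3,
    conv2d_channels=(4, 4, 4, 4),
    mlp_hidden=8,
)


def make_sample(rng, target=None):
    vals = rng.random((L, K))
    vals /= vals.sum(axis=0, keepdims=True)
    hist = KendrickHistogram(vals, CFG.mz_edges, CFG.defect_edges, float(vals.sum()),
                             CFG.lam, normalized=True)
    t = np.full(K, 0.1) if target is None else target
    return TrainingSample(histogram=hist, target=t)


class TestBuildNetwork:
    def test_output_shape_and_bound(self):
        rng = np.random.default_rng(0)
        model = build_network(SPEC, seed=1)
        out = model.forward(rng.random((5, 1, K, L)))
        assert out.shape == (5, K)
        assert np.all(np.abs(out) <= 0.5)
        # extreme inputs still bounded
        out2 = model.forward(1e6 * rng.random((2, 1, K, L)))
        assert np.all(np.abs(out2) <= 0.5)

    def test_seed_reproducibility(self):
        m1 = build_network(SPEC, seed=3)
        m2 = build_network(SPEC, seed=3)
        for p, q in zip(m1.parameters(), m2.parameters()):
            np.testing.assert_array_equal(p.value, q.value)

    def test_defect_roll_changes_output(self):
        rng = np.random.default_rng(1)
        model = build_network(SPEC, seed=0).eval()
        x = rng.random((1, 1, K, L)).astype(np.float32)
        y1 = model.forward(x)
        y2 = model.forward(np.roll(x, L // 2, axis=3))
        assert not np.allclose(y1, y2)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            NetworkSpec(n_defect_bins=4, conv1d_kernel=9)
        with pytest.raises(ValueError):
            NetworkSpec(conv1d_channels=(4, 4))


class TestTraining:
    def test_constant_target_is_learned(self):
        """A constant shift vector is trivially learnable."""
        rng = np.random.default_rng(2)
        samples = [make_sample(rng) for _ in range(400)]
        model = build_network(SPEC, seed=0)
        hist = train(model, samples, TrainConfig(lr=1e-2, epochs=50, seed=0, patience=50))
        assert min(hist["val"]) < 1e-4

    def test_zero_targets_zero_model_loss(self):
        rng = np.random.default_rng(3)
        samples = [make_sample(rng, target=np.zeros(K)) for _ in range(8)]
        # the squared-error criterion evaluated at a perfect predictor is 0
        preds = np.zeros((8, K))
        targets = np.stack([s.target for s in samples])
        assert np.mean((preds - targets) ** 2) == 0.0

    def test_loss_history_reproducible(self):
        rng = np.random.default_rng(4)
        samples = [make_sample(rng) for _ in range(64)]
        cfg = TrainConfig(lr=1e-3, epochs=3, seed=9, patience=10)
        m1 = build_network(SPEC, seed=5)
        h1 = train(m1, samples, cfg)
        m2 = build_network(SPEC, seed=5)
        h2 = train(m2, samples, cfg)
        np.testing.assert_allclose(h1["train"], h2["train"], rtol=1e-6)

    def test_descent_on_first_epochs(self):
        rng = np.random.default_rng(5)
        targets = rng.uniform(-0.3, 0.3, size=(300, K))
        samples = [make_sample(rng, target=t) for t in targets]
        model = build_network(SPEC, seed=1)
        hist = train(model, samples, TrainConfig(lr=1e-3, epochs=6, seed=0, patience=10))
        assert hist["train"][-1] <= hist["train"][0]


class TestPredict:
    def test_predict_shift_shape_and_determinism(self):
        rng = np.random.default_rng(6)
        model = build_network(SPEC, seed=0).eval()
        s = make_sample(rng)
        v1 = predict_shift(model, s.histogram)
        v2 = predict_shift(model, s.histogram)
        assert v1.shape == (K,)
        np.testing.assert_array_equal(v1, v2)

    def test_shape_mismatch_rejected(self):
        rng = np.random.default_rng(7)
        model = build_network(SPEC, seed=0)
        bad = KendrickHistogram(rng.random((L + 2, K)), CFG.mz_edges,
                                np.linspace(-0.5, 0.5, L + 3), 1.0)
        with pytest.raises(ValueError, match="shape"):
            predict_shift(model, bad)


class TestShiftVectorConversion:
    def test_zero_vector_zero_function(self):
        fn = shift_vector_to_function(np.zeros(K), CFG)
        assert np.all(fn(np.linspace(600, 700, 13)) == 0)

    def test_constant_vector_constant_da(self):
        fn = shift_vector_to_function(np.full(K, 0.1), CFG)
        np.testing.assert_allclose(fn(np.linspace(600, 700, 13)), 0.1 * CFG.lam)

    def test_midpoint_interpolation(self):
        v = np.zeros(K)
        v[3], v[4] = 0.1, 0.3
        fn = shift_vector_to_function(v, CFG)
        centers = CFG.mz_centers
        mid = 0.5 * (centers[3] + centers[4])
        assert fn(mid) == pytest.approx(0.2 * CFG.lam)


class TestRecalibrateDataset:
    def make_dataset(self, n=3):
        rng = np.random.default_rng(8)
        grid = np.arange(600.0, 700.0, 0.05)
        spectra = [Spectrum(grid, rng.uniform(0, 1, grid.size), f"s{i}") for i in range(n)]
        return MSIDataset(spectra, (600.0, 700.0))

    def test_spot_count_preserved(self):
        model = build_network(SPEC, seed=0).eval()
        ds = self.make_dataset()
        out = recalibrate_dataset(model, ds, CFG)
        assert len(out) == len(ds)

    def test_zero_output_model_is_identity(self):
        model = build_network(SPEC, seed=0).eval()
        # zero the final MLP so the network output is exactly tanh(0)/2 = 0
        mlp = model.net.layers[-1]
        for p in mlp.parameters():
            p.value[...] = 0.0
        ds = self.make_dataset()
        out = recalibrate_dataset(model, ds, CFG)
        for a, b in zip(ds, out):
            np.testing.assert_array_equal(a.mz, b.mz)

    def test_binning_mismatch_rejected(self):
        model = build_network(SPEC, seed=0)
        ds = self.make_dataset()
        other = KendrickConfig(n_mz_bins=K + 1, n_defect_bins=L, mass_range=(600.0, 700.0))
        with pytest.raises(ValueError, match="binning"):
            recalibrate_dataset(model, ds, other)


class TestPersistence:
    def test_checkpoint_round_trip(self, tmp_path):
        rng = np.random.default_rng(9)
        model = build_network(SPEC, seed=2)
        # touch batchnorm running stats
        model.forward(rng.random((4, 1, K, L)))
        model.eval()
        x = rng.random((2, 1, K, L)).astype(np.float32)
        ref = model.forward(x)
        p = tmp_path / "model.msn"
        save_model(model, p, kendrick_cfg=CFG, extra_meta={"seed": 2})
        loaded, meta = load_model(p)
        np.testing.assert_allclose(loaded.forward(x), ref, rtol=1e-6)
        assert meta["kendrick"]["n_mz_bins"] == K
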