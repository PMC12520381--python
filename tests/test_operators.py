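import numpy as np
import pytest

from taainv import evaluate as ev
from taainv import operators as op
from taainv.nn.autograd import Tensor
from taainv.exceptions import DataError, ParameterError


@pytest.fixture(scope="module")
def batch():
    rng = np.random.default_rng(0)
    return rng.uniform(0, 255, (3, 2, 41, 41)).astype(np.float32)


class TestContracts:
    @pytest.mark.parametrize("arch", op.ARCHITECTURES)
    def test_output_shape(self, arch, batch):
        model = op.build_operator(arch, channels=2, tier="reduced", seed=1)
        out = model(Tensor(model.normalize_inputs(batch)))
        assert out.shape == (3, 2, 41, 41)
        assert np.all(np.isfinite(out.data))

    def test_lno_batch20_contract(self):
        # batched field-to-field contract at the full-tier batch size
        model = op.build_operator("lno", channels=2, tier="reduced", seed=0)
        x = np.random.default_rng(1).random((20, 2, 41, 41)).astype(np.float32)
        out = model(Tensor(x))
        assert out.shape == (20, 2, 41, 41)

    def test_single_channel_model_rejects_two_channels(self, batch):
        model = op.build_operator("unet", channels=1, tier="reduced")
        with pytest.raises(DataError):
            model.normalize_inputs(batch)

    def test_odd_embedding_rejected(self):
        with pytest.raises(ParameterError):
            op.build_cnn_deeponet(embed_dim=65)

    def test_unknown_architecture_rejected(self):
        with pytest.raises(ParameterError):
            op.build_operator("fno")


class TestDeepONet:
    def test_zeroed_branch_gives_zero_fields(self, batch):
        model = op.build_cnn_deeponet(channels=2, embed_dim=32,
                                      conv_widths=(4, 8, 8), dense=16,
                                      trunk_width=16, seed=0)
        last = model.branch.fc2
        last.w.data[:] = 0.0
        last.b.data[:] = 0.0
        out = model(Tensor(model.normalize_inputs(batch)))
        assert np.all(out.data == 0.0)

    def test_coordinate_permutation_equivariance(self, batch):
        model = op.build_fnn_deeponet(channels=2, embed_dim=16, hidden=8,
                                      trunk_width=8, seed=3)
        coords = model._coords
        perm = np.random.default_rng(0).permutation(coords.shape[0])
        x = Tensor(model.normalize_inputs(batch))
        base = model(x).data.reshape(3, 2, -1)
        permuted = model(Tensor(model.normalize_inputs(batch)),
                         coords=coords[perm]).data
        assert np.allclose(permuted, base[:, :, perm], atol=1e-6)

    def test_trunk_features_respect_theta_periodicity(self):
        f0 = op._DeepONet.trunk_features(np.array([[0.0, 0.3]]))
        f1 = op._DeepONet.trunk_features(np.array([[1.0, 0.3]]))
        assert np.allclose(f0, f1, atol=1e-6)


class TestUNet:
    def test_full_size_parameter_count_in_expected_ballpark(self):
        model = op.build_unet(channels=2)
        assert 1.5e6 <= model.n_parameters() <= 2.5e6

    def test_spatial_shape_preserved(self, batch):
        model = op.build_operator("unet", channels=2, tier="reduced")
        out = model(Tensor(model.normalize_inputs(batch)))
        assert out.shape[2:] == (41, 41)

    def test_constant_shift_changes_output(self, batch):
        # no spurious shift invariance: the network sees absolute levels
        model = op.build_operator("unet", channels=2, tier="reduced", seed=2)
        a = model(Tensor(model.normalize_inputs(batch))).data
        b = model(Tensor(model.normalize_inputs(batch + 30.0))).data
        assert not np.allclose(a, b, atol=1e-5)


class TestLNO:
    def test_zero_residues_still_finite(self, batch):
        model = op.build_operator("lno", channels=2, tier="reduced", seed=0)
        for layer in model.layers:
            for tr in (layer.along_z, layer.along_theta):
                tr.beta_r.data[:] = 0.0
                tr.beta_i.data[:] = 0.0
        out = model(Tensor(model.normalize_inputs(batch)))
        assert np.all(np.isfinite(out.data))

    def test_steady_response_preserves_input_frequency(self):
        # single-mode sinusoid in, single-mode sinusoid out (pole-residue
        # steady state evaluates the rational kernel at the input frequency)
        from taainv.operators import _LaplaceTransform1D
        rng = np.random.default_rng(0)
        tr = _LaplaceTransform1D(width=1, modes=6, n=40, rng=rng)
        k = 3
        x = np.cos(2 * np.pi * k * np.arange(40) / 40).astype(np.float32)
        v = Tensor(x.reshape(1, 1, 1, 40))
        out = tr.steady(v).data[0, 0, 0]
        spec = np.abs(np.fft.rfft(out))
        others = np.delete(spec, k)
        assert spec[k] > 1e-6
        assert others.max() < 1e-4 * spec[k]

    def test_nyquist_guard(self):
        with pytest.raises(ParameterError):
            op.build_lno(modes=21)


class TestTraining:
    def test_loss_decreases(self, small_arrays):
        X, Y, _ = small_arrays
        model = op.build_operator("fnn_deeponet", channels=2, tier="reduced",
                                  seed=0)
        cfg = op.TrainConfig.for_arch("fnn_deeponet", tier="reduced")
        cfg.n_updates = 150
        cfg.batch_size = 4
        hist = op.train_operator(model, X, Y, cfg)
        assert hist[-1]["train_loss"] < hist[0]["train_loss"]

    @pytest.mark.parametrize("arch,n_updates", [
        ("cnn_deeponet", 1000), ("fnn_deeponet", 2000),
        ("unet", 1500), ("lno", 600)])
    def test_capacity_overfits_five_records(self, arch, n_updates,
                                            small_arrays):
        # sanity oracle: each architecture can memorize five records
        X, Y, _ = small_arrays
        X5, Y5 = X[:5], Y[:5]
        model = op.build_operator(arch, channels=2, tier="reduced", seed=2)
        cfg = op.TrainConfig.for_arch(arch, tier="reduced")
        cfg.n_updates = n_updates
        cfg.batch_size = 5
        cfg.val_fraction = 0.0
        cfg.loss = "relative_l2"
        cfg.schedule = "cosine"
        op.train_operator(model, X5, Y5, cfg)
        pce, pdl = op.predict_insults(model, X5)
        e_ce, _ = ev.relative_l2_aggregate(pce, Y5[:, 0])
        e_dl, _ = ev.relative_l2_aggregate(pdl, Y5[:, 1])
        assert e_ce < 0.05
        assert e_dl < 0.05

    def test_head_swap_symmetry(self, small_arrays):
        # swapping the two ground-truth channels during training swaps the
        # learned heads (same seed, same data)
        X, Y, _ = small_arrays
        cfg = op.TrainConfig.for_arch("fnn_deeponet", tier="reduced")
        cfg.n_updates = 500
        cfg.batch_size = 4
        cfg.loss = "relative_l2"
        m1 = op.build_operator("fnn_deeponet", channels=2, tier="reduced",
                               seed=4)
        op.train_operator(m1, X, Y, cfg)
        m2 = op.build_operator("fnn_deeponet", channels=2, tier="reduced",
                               seed=4)
        # swap channels, rescaled so the cap-normalized targets are exactly
        # the swapped normalized targets of the first run
        caps = op._CAPS
        Yswap = np.stack([Y[:, 1] * (caps[0] / caps[1]),
                          Y[:, 0] * (caps[1] / caps[0])], axis=1)
        op.train_operator(m2, X, Yswap, cfg)
        p1 = m1(Tensor(m1.normalize_inputs(X))).data
        p2 = m2(Tensor(m2.normalize_inputs(X))).data
        corr = np.corrcoef(p1[:, 0].ravel(), p2[:, 1].ravel())[0, 1]
        assert corr > 0.7

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_divergence_raises(self, small_arrays):
        X, Y, _ = small_arrays
        model = op.build_operator("fnn_deeponet", channels=2, tier="reduced",
                                  seed=0)
        cfg = op.TrainConfig.for_arch("fnn_deeponet", tier="reduced")
        cfg.n_updates = 200
        cfg.lr = 1e6  # guaranteed blow-up
        from taainv.exceptions import TaaError
        with pytest.raises(TaaError):
            op.train_operator(model, X, Y, cfg)


class TestPrediction:
    def test_batched_equals_single(self, small_arrays):
        X, _, _ = small_arrays
        model = op.build_operator("unet", channels=2, tier="reduced", seed=1)
        ce_b, dl_b = op.predict_insults(model, X[:3])
        ce_s, dl_s = op.predict_insults(model, X[0])
        assert np.allclose(ce_b[0], ce_s, atol=1e-6)
        assert np.allclose(dl_b[0], dl_s, atol=1e-6)

    def test_deterministic(self, small_arrays):
        X, _, _ = small_arrays
        model = op.build_operator("lno", channels=2, tier="reduced", seed=1)
        a = op.predict_insults(model, X[:2])
        b = op.predict_insults(model, X[:2])
        assert np.array_equal(a[0], b[0])
        assert np.array_equal(a[1], b[1])
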