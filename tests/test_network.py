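"""CPAR network: autodiff correctness, architecture contracts, training laws."""

import numpy as np
import pytest

from aaapulse.autodiff import Tensor
from aaapulse.network import (
    ModelState,
    NetworkConfig,
    TrainingConfig,
    _make_optimizers,
    _supervised_step,
    build_network,
    disturbance_loss,
    input_preprocess,
    label_loss,
    predict_vsi,
    training_step,
)

TINY = NetworkConfig(channels=(4, 6, 8, 8, 8), cbam_reduction=2)


@pytest.fixture
def float64_mode():
    old = Tensor.DTYPE
    Tensor.DTYPE = np.float64
    yield
    Tensor.DTYPE = old


def make_batch(rng, n=3, width=256):
    x = rng.standard_normal((n, 1, 2, width))
    y = rng.uniform(0, 100, n)
    h = rng.standard_normal(n)
    a = rng.standard_normal(n)
    return x, y, h, a


class TestAutodiff:
    def test_full_network_gradients_match_finite_differences(self, float64_mode):
        rng = np.random.default_rng(0)
        st = build_network(TINY, seed=2)
        st.set_training(True)
        x, y, h, a = make_batch(rng)

        def loss_fn():
            pred = st.forward_label(Tensor(x))
            return label_loss(pred, y)

        params = st.params_f() + st.params_l()
        loss = loss_fn()
        loss.backward()
        grads = [p.grad.copy() for p in params]
        check_rng = np.random.default_rng(1)
        for pi, p in enumerate(params):
            flat = p.data.ravel()
            for _ in range(2):
                i = int(check_rng.integers(flat.size))
                eps = 1e-5 * max(1.0, abs(flat[i]))
                old = flat[i]
                flat[i] = old + eps
                lp = float(loss_fn().data)
                flat[i] = old - eps
                lm = float(loss_fn().data)
                flat[i] = old
                fd = (lp - lm) / (2 * eps)
                an = grads[pi].ravel()[i]
                assert abs(fd - an) <= 1e-4 * max(1.0, abs(fd), abs(an))

    def test_adversarial_head_gradients(self, float64_mode):
        rng = np.random.default_rng(3)
        st = build_network(TINY, seed=4)
        st.set_training(True)
        x, _, h, _ = make_batch(rng)

        def loss_fn():
            return disturbance_loss(st.head_height(st.latent(Tensor(x))), h)

        params = st.params_eta_h()
        loss = loss_fn()
        loss.backward()
        grads = [p.grad.copy() for p in params]
        check_rng = np.random.default_rng(5)
        for pi, p in enumerate(params):
            flat = p.data.ravel()
            i = int(check_rng.integers(flat.size))
            eps = 1e-5 * max(1.0, abs(flat[i]))
            old = flat[i]
            flat[i] = old + eps
            lp = float(loss_fn().data)
            flat[i] = old - eps
            lm = float(loss_fn().data)
            flat[i] = old
            fd = (lp - lm) / (2 * eps)
            assert abs(fd - grads[pi].ravel()[i]) <= 1e-4 * max(1.0, abs(fd))


class TestArchitecture:
    def test_latent_shape_and_parameter_counts(self):
        st = build_network(seed=0)  # full-scale default
        assert st.config.latent_shape == (32, 2, 64)
        x = np.random.default_rng(0).standard_normal((2, 1, 2, 256))
        st.set_training(False)
        z = st.extractor(Tensor(x))
        assert z.shape == (2, 32, 2, 64)
        assert st.n_params_head() == 266433
        assert abs(st.n_params_extractor() - 810_000) / 810_000 < 0.10

    def test_row_independence_before_compression(self):
        st = build_network(TINY, seed=1)
        st.set_training(False)
        rng = np.random.default_rng(2)
        x1 = rng.standard_normal((3, 1, 2, 256))
        x2 = x1.copy()
        x2[:, 0, 1, :] = rng.standard_normal((3, 256))  # change only the tibial row
        z1 = st.extractor(Tensor(x1)).data
        z2 = st.extractor(Tensor(x2)).data
        np.testing.assert_allclose(z1[:, :, 0, :], z2[:, :, 0, :], atol=1e-6)
        assert not np.allclose(z1[:, :, 1, :], z2[:, :, 1, :])

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            build_network(NetworkConfig(channels=(8, 8), kernels=(5, 3, 3)))
        with pytest.raises(ValueError):
            build_network(NetworkConfig(input_width=250))


class TestPreprocess:
    def test_shape_and_standardisation(self):
        rng = np.random.default_rng(0)
        b, t = rng.standard_normal(256) * 50 + 100, rng.standard_normal(256)
        x = input_preprocess(b, t)
        assert x.shape == (1, 2, 256)
        for row in range(2):
            assert x[0, row].mean() == pytest.approx(0.0, abs=1e-9)
            assert x[0, row].std() == pytest.approx(1.0, rel=1e-6)

    def test_amplitude_scale_invariance(self):
        rng = np.random.default_rng(1)
        b, t = rng.standard_normal(256), rng.standard_normal(256)
        np.testing.assert_allclose(input_preprocess(10 * b, t),
                                   input_preprocess(b, t), atol=1e-9)

    def test_constant_row_maps_to_zeros(self):
        t = np.random.default_rng(2).standard_normal(256)
        x = input_preprocess(np.full(256, 7.0), t)
        np.testing.assert_array_equal(x[0, 0], np.zeros(256))

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            input_preprocess(np.zeros(100), np.zeros(256))


class TestLosses:
    def test_label_loss_examples(self):
        assert float(label_loss(Tensor([60.0, 20.0]), np.array([80.0, 20.0])).data) == (
            pytest.approx(200.0)
        )
        assert float(label_loss(Tensor([1.0, 2.0]), np.array([1.0, 2.0])).data) == 0.0
        delta = 3.0
        preds = Tensor(np.array([10.0, 50.0, 90.0]) + delta)
        assert float(label_loss(preds, np.array([10.0, 50.0, 90.0])).data) == (
            pytest.approx(delta**2)
        )
        with pytest.raises(ValueError):
            label_loss(Tensor(np.empty(0)), np.empty(0))

    def test_disturbance_loss_properties(self):
        zero = disturbance_loss(Tensor([1.0, -2.0]), np.array([1.0, -2.0]))
        assert float(zero.data) == pytest.approx(0.0, abs=1e-12)
        # large-error asymptote 2|e| - ln 2
        big = disturbance_loss(Tensor([5.0]), np.array([0.0]))
        assert float(big.data) == pytest.approx(2 * 5 - np.log(2), rel=0.01)
        # symmetry in the sign of the error
        lp = disturbance_loss(Tensor([2.3]), np.array([0.0]))
        lm = disturbance_loss(Tensor([-2.3]), np.array([0.0]))
        assert float(lp.data) == pytest.approx(float(lm.data), rel=1e-12)
        # strictly increasing in |e|
        es = [0.1, 0.5, 1.0, 3.0]
        vals = [float(disturbance_loss(Tensor([e]), np.array([0.0])).data) for e in es]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestTrainingLaws:
    def _states_and_batch(self, seed=0):
        rng = np.random.default_rng(seed)
        st = build_network(TINY, seed=7)
        st.set_training(True)
        x, y, h, a = make_batch(rng, n=6)
        return st, (x[:4], y[:4]), (h[:4], a[:4]), (x[4:], h[4:], a[4:])

    def test_parameter_partition(self):
        st, lab, demo, unl = self._states_and_batch()
        cfg = TrainingConfig.for_modality("pvr")
        opts = _make_optimizers(st, cfg)
        before_f = [p.data.copy() for p in st.params_f()]
        before_l = [p.data.copy() for p in st.params_l()]
        # adversary-only update: freeze f and l optimizers by zero step
        opts.opt_f.lr = 0.0
        opts.opt_l.lr = 0.0
        training_step(lab, unl, st, cfg, opts, labeled_demo=demo)
        for p, b in zip(st.params_f(), before_f):
            np.testing.assert_array_equal(p.data, b)
        for p, b in zip(st.params_l(), before_l):
            np.testing.assert_array_equal(p.data, b)

    def test_lambda_zero_matches_supervised(self):
        cfgs = [
            TrainingConfig.for_modality("pvr", lam=0.0, seed=3),
            TrainingConfig.for_modality("pvr", lam=0.0, seed=3),
        ]
        results = []
        for mode in ("cpar", "frozen"):
            st, lab, demo, unl = self._states_and_batch(seed=11)
            cfg = cfgs.pop()
            opts = _make_optimizers(st, cfg)
            for _ in range(4):
                if mode == "cpar":
                    training_step(lab, unl, st, cfg, opts, labeled_demo=demo)
                else:
                    _supervised_step(lab, st, cfg, opts)
            results.append([p.data.copy() for p in st.params_f() + st.params_l()])
        for a, b in zip(results[0], results[1]):
            np.testing.assert_array_equal(a, b)

    def test_overfit_one_batch_drives_label_loss_down(self):
        st, lab, demo, unl = self._states_and_batch(seed=5)
        cfg = TrainingConfig.for_modality("pvr", lam=0.0)
        opts = _make_optimizers(st, cfg)
        losses = [training_step(lab, unl, st, cfg, opts, labeled_demo=demo)[0]
                  for _ in range(60)]
        assert np.mean(losses[-5:]) < 0.2 * np.mean(losses[:5])

    def test_nan_loss_aborts(self):
        st, lab, demo, unl = self._states_and_batch(seed=6)
        cfg = TrainingConfig.for_modality("pvr")
        opts = _make_optimizers(st, cfg)
        bad = (lab[0], np.full_like(lab[1], np.nan))
        with pytest.raises(FloatingPointError):
            training_step(bad, unl, st, cfg, opts, labeled_demo=demo)


class TestPredict:
    def test_untrained_state_rejected(self):
        st = build_network(TINY, seed=0)
        with pytest.raises(RuntimeError):
            predict_vsi(st, np.zeros(256), np.zeros(256))

    def test_deterministic_and_save_load(self, tmp_path):
        st = build_network(TINY, seed=0)
        st.trained = True
        rng = np.random.default_rng(0)
        b, t = rng.standard_normal(256), rng.standard_normal(256)
        v1 = predict_vsi(st, b, t)
        v2 = predict_vsi(st, b, t)
        assert v1 == v2
        path = tmp_path / "model.pkl"
        st.save(path)
        back = ModelState.load(path)
        assert predict_vsi(back, b, t) == pytest.approx(v1, abs=1e-6)
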