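"""CSAE, sparse loss, gradient correctness, transfer, and GRU classifier."""

import numpy as np
import pytest

from szpipe._nn import BatchNorm1d, Conv1d
from szpipe.features import ColumnDesc, FeatureTable
from szpipe.model import (CSAE, ClassifierConfig, CsaeConfig, _back_layers,
                          build_classifier, load_bundle, predict,
                          predict_proba, pretrain_csae, save_bundle,
                          sparse_loss, train_classifier)

TOY_CFG = CsaeConfig(enc_channels=(1, 2, 2), dec_channels=(2, 2, 1),
                     dropout_ae=0.0, lambda_sparse=1e-3)


def _feature_table(X, y, norm_state="unit_interval"):
    cols = [ColumnDesc("ch0", "A5", f"f{i}") for i in range(X.shape[1])]
    return FeatureTable(X, cols, np.asarray(y), np.array(["original"] * len(y)),
                        norm_state=norm_state)


def _blob_tables(blob_data):
    X, y = blob_data
    r = np.random.default_rng(3)
    idx = r.permutation(len(y))
    tr, te = idx[:320], idx[320:]
    return _feature_table(X[tr], y[tr]), _feature_table(X[te], y[te])


class TestSparseLoss:
    def test_perfect_reconstruction_zero_latent_is_zero(self):
        x = np.ones((4, 6))
        assert sparse_loss(x, x, np.zeros((4, 2, 6)), 0.5) == 0.0

    def test_lambda_zero_reduces_to_squared_error(self, rng):
        x = rng.normal(size=(3, 8))
        e = rng.normal(size=(3, 8))
        h = rng.normal(size=(3, 2, 8))
        expect = np.mean(np.sum(e ** 2, axis=1))
        assert sparse_loss(x, x + e, h, 0.0) == pytest.approx(expect, abs=1e-12)

    def test_matches_literal_two_term_evaluation(self, rng):
        x = rng.normal(size=(5, 10))
        xh = rng.normal(size=(5, 10))
        h = rng.normal(size=(5, 3, 10))
        lam = 0.37
        oracle = np.mean([np.sum((x[i] - xh[i]) ** 2) + lam * np.sum(np.abs(h[i]))
                          for i in range(5)])
        assert sparse_loss(x, xh, h, lam) == pytest.approx(oracle, abs=1e-12)

    def test_negative_lambda_rejected(self):
        x = np.zeros((1, 4))
        with pytest.raises(ValueError):
            sparse_loss(x, x, np.zeros((1, 1, 4)), -0.1)


class TestCsaeShapes:
    def test_latent_is_16_channels_times_input_length(self, rng):
        csae = CSAE(24, CsaeConfig(), seed=0)
        h = csae.encode(rng.uniform(size=(5, 24)))
        assert h.shape == (5, 16, 24)

    @pytest.mark.parametrize("d", [24, 552])
    def test_same_padding_preserves_length(self, d, rng):
        csae = CSAE(d, CsaeConfig(), seed=0)
        x = rng.uniform(size=(2, d))
        h = csae.encode(x)
        assert h.shape[2] == d
        assert csae.decode(h).shape == (2, d)

    def test_zero_weights_and_identity_bn_give_zero_latent(self, rng):
        csae = CSAE(10, CsaeConfig(), seed=0)
        for layer in csae.enc:
            if isinstance(layer, Conv1d):
                layer.params["W"][...] = 0.0
                layer.params["b"][...] = 0.0
            if isinstance(layer, BatchNorm1d):  # bypass: identity affine, unit stats
                layer.params["gamma"][...] = 1.0
                layer.params["beta"][...] = 0.0
                layer.running_mean[...] = 0.0
                layer.running_var[...] = 1.0
        assert np.allclose(csae.encode(rng.uniform(size=(3, 10))), 0.0)

    def test_zero_latent_zero_decoder_gives_zero_reconstruction(self):
        csae = CSAE(10, CsaeConfig(), seed=0)
        for layer in csae.dec:
            if isinstance(layer, Conv1d):
                layer.params["W"][...] = 0.0
                layer.params["b"][...] = 0.0
            if isinstance(layer, BatchNorm1d):
                layer.params["beta"][...] = 0.0
                layer.running_mean[...] = 0.0
        assert np.allclose(csae.decode(np.zeros((2, 16, 10))), 0.0)

    def test_latent_shape_mismatch_rejected(self):
        csae = CSAE(10, CsaeConfig(), seed=0)
        with pytest.raises(ValueError, match="latent"):
            csae.decode(np.zeros((2, 16, 9)))

    def test_input_shorter_than_kernel_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            CSAE(2, CsaeConfig(), seed=0)


class TestGradients:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_backprop_matches_finite_differences(self, seed):
        """Central finite differences vs analytic gradient of the sparse loss."""
        csae = CSAE(5, TOY_CFG, seed=seed)
        X = np.random.default_rng(seed + 100).uniform(0.1, 0.9, (3, 5))

        def loss():
            h = csae.encode(X, training=True)
            xh = csae.decode(h, training=True)
            return sparse_loss(X, xh, h, TOY_CFG.lambda_sparse), h, xh

        L, h, xh = loss()
        csae.zero_grads()
        dxhat = 2.0 * (xh - X) / X.shape[0]
        dh = _back_layers(csae.dec, dxhat[:, None, :])
        dh = dh + TOY_CFG.lambda_sparse * np.sign(h) / X.shape[0]
        _back_layers(csae.enc, dh)
        analytic = {k: v.copy() for k, v in csae.grads().items()}

        eps = 1e-6
        for k, p in csae.params().items():
            it = np.nditer(p, flags=["multi_index"])
            for _ in it:
                ix = it.multi_index
                old = p[ix]
                p[ix] = old + eps
                lp = loss()[0]
                p[ix] = old - eps
                lm = loss()[0]
                p[ix] = old
                fd = (lp - lm) / (2 * eps)
                an = analytic[k][ix]
                # conv biases feeding batch-norm are exact null directions, so
                # compare with an absolute floor for the near-zero gradients
                assert abs(fd - an) <= 1e-6 + 1e-4 * abs(an), (k, ix, fd, an)


class TestPretraining:
    def test_loss_descends_and_history_bounded(self, small_table):
        from szpipe.features import apply_normalizer, fit_normalizer
        X = apply_normalizer(small_table, fit_normalizer(small_table)).values
        cfg = CsaeConfig(max_epochs_ae=12, recon_stop_threshold=1e-9)
        _, hist = pretrain_csae(X, cfg, seed=0)
        assert len(hist) <= 12
        assert hist[-1]["loss"] <= hist[0]["loss"]

    def test_early_stop_on_reconstruction_threshold(self, rng):
        X = rng.uniform(0.4, 0.6, size=(64, 8))  # nearly constant, easy to reconstruct
        cfg = CsaeConfig(recon_stop_threshold=0.5)
        _, hist = pretrain_csae(X, cfg, seed=0)
        assert len(hist) < 30
        assert hist[-1]["recon_mse_per_feature"] < 0.5

    def test_identical_seed_gives_identical_parameters(self, rng):
        X = rng.uniform(size=(40, 12))
        cfg = CsaeConfig(max_epochs_ae=3)
        a, _ = pretrain_csae(X, cfg, seed=9)
        b, _ = pretrain_csae(X, cfg, seed=9)
        for k, v in a.params().items():
            assert np.array_equal(v, b.params()[k]), k

    def test_sparsity_pressure_weakly_monotone_in_lambda(self, rng):
        X = np.random.default_rng(7).uniform(size=(120, 24))
        means = []
        for lam in (0.0, 1e-3, 1e-2):
            cfg = CsaeConfig(lambda_sparse=lam, max_epochs_ae=15,
                             recon_stop_threshold=1e-9)
            csae, _ = pretrain_csae(X, cfg, seed=5)
            means.append(np.abs(csae.encode(X)).mean())
        assert means[0] >= means[1] >= means[2]


class TestClassifier:
    def test_transferred_shapes_match_encoder(self):
        csae = CSAE(24, CsaeConfig(), seed=1)
        bundle = build_classifier(csae, ClassifierConfig(seed=1))
        enc_conv = [l for l in csae.enc if isinstance(l, Conv1d)]
        tr_conv = [l for l in bundle.encoder if isinstance(l, Conv1d)]
        for a, b in zip(enc_conv, tr_conv):
            assert a.params["W"].shape == b.params["W"].shape
            assert np.array_equal(a.params["W"], b.params["W"])

    def test_softmax_rows_sum_to_one(self, blob_data):
        train_t, test_t = _blob_tables(blob_data)
        csae, _ = pretrain_csae(train_t.values, CsaeConfig(max_epochs_ae=2), seed=3)
        cfg = ClassifierConfig(seed=3, max_epochs_clf=2)
        bundle = train_classifier(build_classifier(csae, cfg), train_t, cfg)
        proba = predict_proba(bundle, test_t)
        assert proba.shape == (test_t.n_rows, 2)
        assert np.all(proba >= 0) and np.all(proba <= 1)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert np.array_equal(predict(bundle, test_t), np.argmax(proba, axis=1))

    def test_frozen_conv_parameters_bit_identical_after_training(self, blob_data):
        train_t, _ = _blob_tables(blob_data)
        csae, _ = pretrain_csae(train_t.values, CsaeConfig(max_epochs_ae=3), seed=4)
        cfg = ClassifierConfig(seed=4, max_epochs_clf=5, frozen=True)
        bundle = build_classifier(csae, cfg)
        before = {k: v.copy() for k, v in bundle.encoder_params().items()}
        train_classifier(bundle, train_t, cfg)
        after = bundle.encoder_params()
        for k in before:
            assert np.array_equal(before[k], after[k]), k

    def test_learns_separable_blobs(self, blob_data):
        train_t, test_t = _blob_tables(blob_data)
        csae, _ = pretrain_csae(train_t.values, CsaeConfig(), seed=7)
        cfg = ClassifierConfig(seed=7)
        bundle = train_classifier(build_classifier(csae, cfg), train_t, cfg)
        assert len(bundle.history) <= 50
        assert bundle.history[-1]["acc"] >= 0.99
        y_true = (test_t.labels == "ictal").astype(int)
        assert (predict(bundle, test_t) == y_true).mean() >= 0.95
        # seeded descent: 10-epoch moving average of the loss never increases
        losses = np.array([h["loss"] for h in bundle.history])
        ma = np.convolve(losses, np.ones(10) / 10, mode="valid")
        assert np.all(np.diff(ma) <= 1e-6)

    def test_raw_table_rejected_at_predict_time(self, blob_data):
        train_t, test_t = _blob_tables(blob_data)
        csae, _ = pretrain_csae(train_t.values, CsaeConfig(max_epochs_ae=1), seed=0)
        cfg = ClassifierConfig(seed=0, max_epochs_clf=1)
        bundle = train_classifier(build_classifier(csae, cfg), train_t, cfg)
        raw = FeatureTable(test_t.values, test_t.columns, test_t.labels,
                           test_t.provenance, norm_state="raw")
        with pytest.raises(ValueError, match="normalized"):
            predict_proba(bundle, raw)

    def test_single_class_training_rejected(self, rng):
        X = rng.uniform(size=(20, 24))
        t = _feature_table(X, ["ictal"] * 20)
        csae, _ = pretrain_csae(X, CsaeConfig(max_epochs_ae=1), seed=0)
        cfg = ClassifierConfig(seed=0)
        with pytest.raises(ValueError, match="two classes"):
            train_classifier(build_classifier(csae, cfg), t, cfg)

    def test_scalar_sequence_mode_runs(self, blob_data):
        train_t, test_t = _blob_tables(blob_data)
        csae, _ = pretrain_csae(train_t.values, CsaeConfig(max_epochs_ae=1), seed=2)
        cfg = ClassifierConfig(seed=2, max_epochs_clf=1, scalar_sequence=True)
        bundle = train_classifier(build_classifier(csae, cfg), train_t, cfg)
        proba = predict_proba(bundle, test_t)
        assert np.allclose(proba.sum(axis=1), 1.0)


class TestCheckpoint:
    def test_save_load_roundtrip_is_bit_exact(self, tmp_path, blob_data):
        train_t, test_t = _blob_tables(blob_data)
        csae, _ = pretrain_csae(train_t.values, CsaeConfig(max_epochs_ae=2), seed=6)
        cfg = ClassifierConfig(seed=6, max_epochs_clf=3)
        bundle = train_classifier(build_classifier(csae, cfg), train_t, cfg)
        path = tmp_path / "model.npz"
        save_bundle(path, bundle)
        back = load_bundle(path)
        assert np.array_equal(predict_proba(back, test_t), predict_proba(bundle, test_t))
        for k, v in bundle.gru.params.items():
            assert np.array_equal(v, back.gru.params[k])
        assert back.class_labels == bundle.class_labels
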