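import numpy as np
import pytest

from audenc.dcae import (
    ConvAutoencoder,
    dcae_objective,
    filter_spectrum_order,
    reconstruction_pcc,
)
from conftest import sine_mixture_windows


class TestObjective:
    def test_perfect_reconstruction_zero_weights_gives_zero(self):
        x = np.random.default_rng(0).standard_normal((3, 8))
        assert dcae_objective(x, x, [np.zeros((2, 2))], kappa=1.0) == 0.0

    def test_mse_arithmetic(self):
        assert dcae_objective([0.0, 0.0], [1.0, 1.0], [], kappa=0.0) == 1.0

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((2, 5))
        xh = rng.standard_normal((2, 5))
        W = [rng.standard_normal((3, 1, 2)), rng.standard_normal((2, 2, 1))]
        kappa = 0.37
        # independent elementwise summation
        sq = 0.0
        for i in range(2):
            for j in range(5):
                sq += (x[i, j] - xh[i, j]) ** 2
        reg = 0.0
        for w in W:
            for v in w.ravel():
                reg += v * v
        expected = sq / 10 + kappa * reg
        assert dcae_objective(x, xh, W, kappa) == pytest.approx(expected)

    def test_monotone_in_kappa_and_reduces_to_mse(self):
        rng = np.random.default_rng(3)
        x, xh = rng.standard_normal((2, 2, 6))
        W = [rng.standard_normal((3, 1, 1))]
        assert dcae_objective(x, xh, W, 0.0) == pytest.approx(np.mean((x - xh) ** 2))
        vals = [dcae_objective(x, xh, W, k) for k in (0.0, 0.5, 1.0, 2.0)]
        assert np.all(np.diff(vals) >= 0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dcae_objective(np.zeros(3), np.zeros(4), [], 0.0)


class TestModelStructure:
    def test_decoder_mirrors_encoder(self):
        m = ConvAutoencoder(random_state=0)
        m.initialize()
        enc_shapes = [w.shape for w in m.encoder_weights_]
        assert enc_shapes == [(64, 1, 32), (32, 32, 64), (16, 64, 128), (8, 128, 256)]
        dec_shapes = [w.shape for w in m.decoder_weights_]
        assert dec_shapes == [(8, 256, 128), (16, 128, 64), (32, 64, 32), (64, 32, 1)]

    @pytest.mark.parametrize(
        "filters,lengths,pools,t",
        [((4, 8), (8, 4), (1, 2), 64), ((3, 5, 6), (7, 5, 3), (2, 2, 2), 96)],
    )
    def test_reconstruction_preserves_length(self, filters, lengths, pools, t):
        m = ConvAutoencoder(
            filters=filters, filter_lengths=lengths, pool_factors=pools,
            random_state=1,
        )
        m.initialize()
        X = np.random.default_rng(0).standard_normal((2, t))
        assert m.reconstruct(X).shape == (2, t)

    def test_full_model_gradients_match_numeric(self):
        """End-to-end backprop through conv/pool/unpool/deconv stack."""
        rng = np.random.default_rng(4)
        m = ConvAutoencoder(
            filters=(3, 4), filter_lengths=(5, 3), pool_factors=(2, 2),
            l2_weight=1e-3, random_state=0,
        )
        m.initialize()
        xb = rng.standard_normal((2, 16))[:, :, None]

        def objective():
            x_hat, _, _ = m._forward(xb, need_grads=False)
            mse = np.mean((x_hat - xb) ** 2)
            return mse + m.l2_weight * sum(np.sum(w * w) for w in m._all_weights())

        x_hat, _, cache = m._forward(xb, need_grads=True)
        dg = 2.0 * (x_hat - xb) / x_hat.size
        gWe, gbe, gWd, gbd = m._backward(dg, cache)
        for gw, w in zip(gWe + gWd, m.encoder_weights_ + m.decoder_weights_):
            gw += 2 * m.l2_weight * w
        params = (
            m.encoder_weights_ + m.encoder_biases_
            + m.decoder_weights_ + m.decoder_biases_
        )
        grads = gWe + gbe + gWd + gbd
        eps = 1e-6
        for p, g in zip(params, grads):
            for _ in range(6):
                idx = tuple(rng.integers(0, s) for s in p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                lp = objective()
                p[idx] = orig - eps
                lm = objective()
                p[idx] = orig
                assert (lp - lm) / (2 * eps) == pytest.approx(
                    g[idx], rel=1e-4, abs=1e-9
                )


class TestTraining:
    def test_loss_descends_on_toy_data(self):
        X = sine_mixture_windows(200, 512, seed=1)
        m = ConvAutoencoder(
            filters=(4, 8), filter_lengths=(16, 8), pool_factors=(1, 2),
            learning_rate=1e-3, max_epochs=10, patience=10, random_state=0,
        ).fit(X)
        assert m.loss_curve_[-1] < m.loss_curve_[0]
        assert m.loss_curve_[9] < m.loss_curve_[0]  # descent within 10 epochs

    def test_converged_toy_model_reconstructs_heldout(self, toy_ae, toy_windows):
        mean, sd, _ = reconstruction_pcc(toy_ae, toy_windows[200:])
        assert mean > 0.9

    def test_finetuning_changes_weights(self, toy_windows):
        m = ConvAutoencoder(
            filters=(4, 8), filter_lengths=(16, 8), pool_factors=(1, 2),
            max_epochs=3, warm_start=True, random_state=0,
        ).fit(toy_windows[:50])
        before = [w.copy() for w in m.encoder_weights_]
        rng = np.random.default_rng(9)
        m.fit(rng.standard_normal((50, 512)) * 0.5)
        delta = max(
            np.max(np.abs(a - b)) for a, b in zip(before, m.encoder_weights_)
        )
        assert delta > 0

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ConvAutoencoder(filters=(2,), filter_lengths=(3,), pool_factors=(1,)).fit(
                np.empty((0, 32))
            )

    def test_seeded_runs_are_reproducible(self):
        X = sine_mixture_windows(40, 128, seed=2)
        kw = dict(
            filters=(3,), filter_lengths=(5,), pool_factors=(2,),
            max_epochs=5, random_state=7,
        )
        a = ConvAutoencoder(**kw).fit(X)
        b = ConvAutoencoder(**kw).fit(X)
        np.testing.assert_array_equal(
            a.encoder_weights_[0], b.encoder_weights_[0]
        )
        assert a.loss_curve_ == b.loss_curve_


class TestReconstructionPCC:
    def test_identity_reconstruction_scores_one(self, toy_ae, toy_windows, monkeypatch):
        X = toy_windows[:10]
        monkeypatch.setattr(toy_ae.__class__, "reconstruct", lambda self, XX: np.asarray(XX, dtype=float))
        mean, sd, r = reconstruction_pcc(toy_ae, X)
        assert mean == pytest.approx(1.0)
        assert sd == pytest.approx(0.0)

    def test_negated_reconstruction_scores_minus_one(self, toy_ae, toy_windows, monkeypatch):
        monkeypatch.setattr(
            toy_ae.__class__, "reconstruct", lambda self, XX: -np.asarray(XX, dtype=float)
        )
        mean, _, _ = reconstruction_pcc(toy_ae, toy_windows[:10])
        assert mean == pytest.approx(-1.0)

    def test_constant_window_reported_missing(self, toy_ae):
        X = np.vstack([np.zeros(512), sine_mixture_windows(1, 512, seed=3)])
        mean, sd, r = reconstruction_pcc(toy_ae, X)
        assert np.isnan(r[0])
        assert not np.isnan(mean)


class TestFilterSpectra:
    def _model_with_filters(self, bank):
        k = bank.shape[0]
        m = ConvAutoencoder(
            filters=(bank.shape[1],), filter_lengths=(k,), pool_factors=(1,),
            random_state=0,
        )
        m.initialize()
        m.encoder_weights_[0] = bank[:, None, :]
        return m

    def test_pure_tone_filter_peaks_at_its_frequency(self):
        sr, k = 16_000, 128
        t = np.arange(k) / sr
        bank = np.column_stack(
            [np.sin(2 * np.pi * 1000 * t), np.ones(k)]  # 1 kHz tone; DC
        )
        m = self._model_with_filters(bank)
        order, peaks = filter_spectrum_order(m, 1, sample_rate=sr, n_fft=4096)
        bin_width = sr / 4096
        assert peaks[0] == pytest.approx(1000.0, abs=bin_width)
        assert peaks[1] == 0.0
        assert list(order) == [1, 0]

    def test_zero_filter_reported_missing(self):
        bank = np.column_stack([np.zeros(16), np.ones(16)])
        m = self._model_with_filters(bank)
        order, peaks = filter_spectrum_order(m, 1, sample_rate=8000)
        assert np.isnan(peaks[0])
        assert order[-1] == 0  # missing peak sorts last

    def test_order_sorts_peaks_nondecreasing(self):
        rng = np.random.default_rng(5)
        bank = rng.standard_normal((32, 12))
        m = self._model_with_filters(bank)
        order, peaks = filter_spectrum_order(m, 1, sample_rate=16_000)
        sorted_peaks = peaks[order]
        # naive sort oracle
        np.testing.assert_array_equal(np.sort(peaks), sorted_peaks)
        assert np.all(np.diff(sorted_peaks) >= 0)
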