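"""Network layers and the BrainAgeRegressor estimator contract."""

import numpy as np
import pytest
from sklearn.base import clone

from eegage._nn import Adam, AgeNet, attention_pool, softplus
from eegage.filterbank import TriangularFilterbank
from eegage.model import BrainAgeRegressor
from eegage.montage import CANONICAL_19, REGIONS, region_channels


def tiny_net(rng, n_channels=2, n_bins=12, n_filters=3, hidden=4, layers=2):
    freqs = np.linspace(1.0, 40.0, n_bins)
    bank = TriangularFilterbank.create(n_filters, freqs, rng=rng)
    return AgeNet(n_channels=n_channels, fb_mask=bank.mask, hidden_size=hidden,
                  n_gru_layers=layers, rng=rng)


class TestRegions:
    @pytest.mark.parametrize(
        "region,count",
        [("whole", 19), ("frontal", 7), ("central", 3), ("parietal", 3),
         ("occipital", 2), ("temporal", 4)],
    )
    def test_channel_counts(self, region, count):
        assert len(region_channels(region)) == count

    def test_subregions_partition_the_montage(self):
        sub = [set(v) for k, v in REGIONS.items() if k != "whole"]
        union = set().union(*sub)
        assert union == set(CANONICAL_19)
        assert sum(len(s) for s in sub) == 19  # pairwise disjoint

    def test_unknown_region_refused(self):
        with pytest.raises(ValueError, match="unknown region"):
            region_channels("cerebellum")


class TestAttention:
    def test_single_frame_is_identity(self, rng):
        frame = rng.normal(size=(8, 1))
        pooled, scores = attention_pool(frame, rng.normal(size=8))
        assert np.allclose(pooled, frame[:, 0])
        assert scores.shape == (1,) and scores[0] == 1.0

    def test_identical_frames_give_uniform_scores(self, rng):
        frame = rng.normal(size=8)
        frames = np.tile(frame[:, None], (1, 10))
        pooled, scores = attention_pool(frames, rng.normal(size=8))
        assert np.allclose(scores, 0.1)
        assert np.allclose(pooled, frame)

    def test_matches_bruteforce_two_loop(self, rng):
        frames = rng.normal(size=(64, 10))  # (H, T)
        w = rng.normal(size=64)
        pooled, scores = attention_pool(frames, w)
        raw = np.array([np.tanh(w @ frames[:, j]) for j in range(10)])
        expw = np.exp(raw - raw.max())
        rho = expw / expw.sum()
        brute = np.zeros(64)
        for j in range(10):
            brute += rho[j] * frames[:, j]
        assert np.abs(scores - rho).max() < 1e-10
        assert np.abs(pooled - brute).max() < 1e-10

    def test_scores_always_normalized(self, rng):
        frames = rng.normal(size=(5, 7, 16)) * 10.0
        _, scores = attention_pool(frames, rng.normal(size=16))
        assert np.all(scores >= 0)
        assert np.allclose(scores.sum(axis=1), 1.0)


class TestSoftplus:
    def test_reference_values(self):
        assert softplus(0.0) == pytest.approx(np.log(2.0), abs=1e-12)
        assert softplus(100.0) == pytest.approx(100.0, abs=1e-10)
        assert softplus(-100.0) > 0.0

    def test_stable_at_extremes(self):
        assert np.isfinite(softplus(np.array([-1e4, 0.0, 1e4]))).all()


class TestAgeNet:
    def test_outputs_strictly_positive(self, rng):
        net = tiny_net(rng)
        y = net.forward(rng.normal(size=(6, 2, 12, 5)) * 10.0)
        assert np.all(y > 0.0)

    def test_zeroed_head_forces_log_two(self, rng):
        net = tiny_net(rng)
        net.head_w[...] = 0.0
        net.head_b[...] = 0.0
        y = net.forward(rng.normal(size=(4, 2, 12, 5)))
        assert np.allclose(y, np.log(2.0))

    def test_no_cross_sample_coupling(self, rng):
        net = tiny_net(rng)
        x = rng.normal(size=(3, 2, 12, 5))
        single = net.forward(x[1:2])
        doubled = net.forward(np.concatenate([x, x[1:2]]))
        assert np.allclose(doubled[1], single[0])
        assert np.allclose(doubled[-1], single[0])

    def test_forward_deterministic(self, rng):
        net = tiny_net(rng)
        x = rng.normal(size=(4, 2, 12, 5))
        assert np.array_equal(net.forward(x), net.forward(x))

    def test_gradients_match_finite_differences(self, rng):
        net = tiny_net(rng)
        x = rng.normal(size=(3, 2, 12, 5))
        ages = rng.uniform(3.0, 14.0, size=3)
        _, _, grads = net.loss_and_grads(x, ages, loss="mse")
        params = net.parameters()
        for name, p in params.items():
            flat = p.reshape(-1)
            pick = rng.choice(flat.size, size=min(8, flat.size), replace=False)
            for i in pick:
                orig = flat[i]
                h = 1e-6
                flat[i] = orig + h
                up, _, _ = net.loss_and_grads(x, ages, loss="mse")
                flat[i] = orig - h
                down, _, _ = net.loss_and_grads(x, ages, loss="mse")
                flat[i] = orig
                numeric = (up - down) / (2 * h)
                analytic = grads[name].reshape(-1)[i]
                assert abs(numeric - analytic) < 1e-5 * max(1.0, abs(numeric)), name

    def test_one_adam_step_reduces_loss(self, rng):
        net = tiny_net(rng, hidden=8)
        x = rng.normal(size=(8, 2, 12, 5))
        ages = rng.uniform(3.0, 14.0, size=8)
        opt = Adam(net.parameters(), lr=1e-2)
        before, _, grads = net.loss_and_grads(x, ages)
        opt.step(grads)
        after, _, _ = net.loss_and_grads(x, ages)
        assert after < before


class TestBrainAgeRegressor:
    def make_data(self, rng, n=16):
        x = rng.normal(size=(n, 3, 20, 6)) ** 2
        y = rng.uniform(3.0, 14.0, size=n)
        return x, y

    def test_sklearn_contract(self, rng):
        est = BrainAgeRegressor(n_filters=4, hidden_size=8, epochs=2, batch_size=8)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        x, y = self.make_data(rng)
        est.fit(x, y)
        assert est.best_epoch_ in (1, 2)
        preds = est.predict(x)
        assert preds.shape == (16,)
        assert np.all(preds > 0)

    def test_same_seed_same_fit(self, rng):
        x, y = self.make_data(rng)
        kw = dict(n_filters=4, hidden_size=8, epochs=3, batch_size=8, random_state=5)
        a = BrainAgeRegressor(**kw).fit(x, y)
        b = BrainAgeRegressor(**kw).fit(x, y)
        assert np.array_equal(a.predict(x), b.predict(x))
        assert a.history_.to_frame().equals(b.history_.to_frame())

    def test_attention_scores_sum_to_one(self, rng):
        x, y = self.make_data(rng)
        est = BrainAgeRegressor(n_filters=4, hidden_size=8, epochs=1, batch_size=8).fit(x, y)
        scores = est.attention_scores(x[:5])
        assert scores.shape == (5, 6)
        assert np.allclose(scores.sum(axis=1), 1.0)

    def test_checkpoint_roundtrip(self, rng, tmp_path):
        x, y = self.make_data(rng)
        est = BrainAgeRegressor(n_filters=4, hidden_size=8, epochs=2, batch_size=8).fit(x, y)
        path = tmp_path / "model.npz"
        est.save_checkpoint(path)
        loaded = BrainAgeRegressor.load_checkpoint(path)
        assert np.array_equal(loaded.predict(x), est.predict(x))
        assert loaded.best_epoch_ == est.best_epoch_
        assert len(loaded.history_) == len(est.history_)

    def test_sample_count_mismatch_refused(self, rng):
        x, y = self.make_data(rng)
        with pytest.raises(ValueError):
            BrainAgeRegressor(epochs=1).fit(x, y[:-1])
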