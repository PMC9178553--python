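"""Network construction, forward contracts, attention and losses.

Gradient correctness of the underlying tape is established here by
finite-difference checks on a down-sized network.
"""

import numpy as np
import pytest

from yfrag.autodiff import Tensor
from yfrag.encoding import encode_library
from yfrag.model import (
    ModelConfig,
    attention,
    build_model,
    compact_config,
    load_checkpoint,
    loss_mse,
    loss_topk_weighted,
    save_checkpoint,
)
from yfrag.simulate import make_fixture

TINY = ModelConfig(
    hidden_size=5,
    fcn_hidden=(6, 6),
    cnn_channels=(2, 3, 3),
    merge_dim=4,
    head_hidden=7,
    dropout=0.0,
    seed=0,
)


@pytest.fixture(scope="module")
def samples():
    library, _ = make_fixture("paperlike", n_peptides=8, seed=3)
    return encode_library(list(library))


class TestBuildAndForward:
    def test_output_shape_and_finiteness(self, samples):
        model = build_model(TINY)
        out = model.forward(samples)
        assert out.shape == (len(samples), 42)
        assert np.isfinite(out.data).all()

    def test_same_seed_same_parameters_and_outputs(self, samples):
        a, b = build_model(TINY), build_model(TINY)
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert (pa.data == pb.data).all()
        assert (a.forward(samples).data == b.forward(samples).data).all()

    def test_batch_equivariance(self, samples):
        model = build_model(TINY)
        out = model.forward(samples).data
        perm = [3, 0, 2, 1, 7, 5, 6, 4]
        out_perm = model.forward([samples[i] for i in perm]).data
        assert out_perm == pytest.approx(out[perm])

    def test_single_sample(self, samples):
        model = build_model(TINY)
        out = model.forward(samples[:1])
        assert out.shape == (1, 42) and np.isfinite(out.data).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(output_dim=41)
        with pytest.raises(ValueError):
            ModelConfig(hidden_size=0)

    def test_cnn_path_is_live(self, samples):
        model = build_model(TINY)
        base = model.forward(samples[:2]).data
        zeroed = [
            type(s)(**{**s.__dict__, "windows": np.zeros_like(s.windows)})
            for s in samples[:2]
        ]
        assert not np.allclose(model.forward(zeroed).data, base)

    def test_fcn_path_is_live(self, samples):
        model = build_model(TINY)
        base = model.forward(samples[:2]).data
        zeroed = [
            type(s)(**{**s.__dict__, "features": np.zeros_like(s.features)})
            for s in samples[:2]
        ]
        assert not np.allclose(model.forward(zeroed).data, base)

    def test_gradient_reaches_every_parameter(self, samples):
        model = build_model(TINY)
        out = model.forward(samples)
        target = np.stack([s.target for s in samples])
        loss_mse(out, target).backward()
        for p in model.parameters():
            assert p.grad is not None
            assert np.abs(p.grad).sum() > 0


class TestGradientsAgainstFiniteDifferences:
    def test_every_parameter_tensor(self, samples):
        model = build_model(TINY)
        check_rng = np.random.default_rng(7)
        # nudge off ReLU kinks so the two-sided difference is valid
        for p in model.parameters():
            p.data += check_rng.normal(0, 0.05, p.data.shape)
        target = np.stack([s.target for s in samples])
        mask = np.stack([s.mask for s in samples])

        def loss_value():
            return float(
                loss_topk_weighted(model.forward(samples), target, mask, 3, 0.7).data
            )

        loss_topk_weighted(model.forward(samples), target, mask, 3, 0.7).backward()
        for p in model.parameters():
            idx = tuple(check_rng.integers(0, s) for s in p.data.shape)
            eps, orig = 1e-6, p.data[idx]
            p.data[idx] = orig + eps
            up = loss_value()
            p.data[idx] = orig - eps
            down = loss_value()
            p.data[idx] = orig
            numeric = (up - down) / (2 * eps)
            analytic = p.grad[idx]
            assert numeric == pytest.approx(analytic, rel=1e-3, abs=1e-7)


class TestAttention:
    def test_single_key_returns_its_value(self, rng):
        q = Tensor(rng.normal(size=(2, 3, 4)))
        kv = Tensor(rng.normal(size=(2, 1, 4)))
        out = attention(q, kv, kv)
        assert out.data == pytest.approx(np.broadcast_to(kv.data, (2, 3, 4)))

    def test_identical_keys_give_uniform_weights(self, rng):
        q = Tensor(rng.normal(size=(1, 1, 4)))
        key = rng.normal(size=4)
        keys = Tensor(np.tile(key, (1, 5, 1)))
        values = Tensor(rng.normal(size=(1, 5, 4)))
        out = attention(q, keys, values)
        assert out.data[0, 0] == pytest.approx(values.data[0].mean(axis=0))

    def test_weights_sum_to_one(self, rng):
        q = Tensor(rng.normal(size=(3, 2, 6)))
        kv = Tensor(rng.normal(size=(3, 5, 6)))
        scores = (q @ kv.swapaxes(-1, -2)) * (1 / np.sqrt(6))
        weights = scores.softmax(axis=-1).data
        assert weights.sum(axis=-1) == pytest.approx(np.ones((3, 2)), abs=1e-6)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            attention(
                Tensor(rng.normal(size=(1, 2, 4))), Tensor(rng.normal(size=(1, 2, 5))),
                Tensor(rng.normal(size=(1, 2, 5))),
            )


class TestLosses:
    def test_perfect_prediction_zero(self, rng):
        t = rng.random((4, 42))
        assert float(loss_mse(Tensor(t), t).data) == 0.0

    def test_constant_offset_closed_form(self, rng):
        t = rng.random((4, 42))
        loss = loss_mse(Tensor(t + 0.1), t)
        assert float(loss.data) == pytest.approx(0.01)

    def test_matches_bruteforce(self, rng):
        pred, t = rng.normal(size=(5, 42)), rng.normal(size=(5, 42))
        assert float(loss_mse(Tensor(pred), t).data) == pytest.approx(
            ((pred - t) ** 2).mean()
        )

    def test_masked_variant_excludes_infeasible(self, rng):
        t = rng.random((3, 42))
        mask = rng.random((3, 42)) > 0.4
        t[~mask] = -1.0
        pred = rng.normal(size=(3, 42))
        got = float(loss_mse(Tensor(pred), t, mask, mask_infeasible=True).data)
        assert got == pytest.approx(((pred - t)[mask] ** 2).mean())

    def test_topk_zero_weight_equals_mse(self, rng):
        pred, t = rng.normal(size=(4, 42)), rng.random((4, 42))
        mask = np.ones((4, 42), dtype=bool)
        a = float(loss_topk_weighted(Tensor(pred), t, mask, 3, 0.0).data)
        assert a == float(loss_mse(Tensor(pred), t).data)

    def test_topk_matches_bruteforce(self, rng):
        pred, t = rng.normal(size=(6, 42)), rng.random((6, 42))
        mask = rng.random((6, 42)) > 0.3
        t[~mask] = -1.0
        w = 0.8
        got = float(loss_topk_weighted(Tensor(pred), t, mask, 3, w).data)
        base = ((pred - t) ** 2).mean()
        extra = []
        for i in range(6):
            feas = np.flatnonzero(mask[i])
            top = feas[np.argsort(-t[i, feas])[:3]]
            extra.extend(((pred[i, top] - t[i, top]) ** 2).tolist())
        assert got == pytest.approx(base + w * np.mean(extra))

    def test_topk_perfect_prediction_zero(self, rng):
        t = rng.random((2, 42))
        mask = np.ones((2, 42), dtype=bool)
        assert float(loss_topk_weighted(Tensor(t), t, mask, 3, 1.0).data) == 0.0


class TestCheckpoint:
    def test_save_load_reproduces_outputs(self, samples, tmp_path):
        model = build_model(compact_config(seed=4))
        path = str(tmp_path / "ckpt.npz")
        save_checkpoint(model, path)
        loaded = load_checkpoint(path)
        assert (loaded.forward(samples).data == model.forward(samples).data).all()
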