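"""Cross-modality attention fusion: simplex invariants, closed-form softmax
oracles, convexity, weight sharing, permutation equivariance, gradients."""

import numpy as np
import pytest

from gliomark.cmaf import CMAF, CmafConfig, export_attention_maps, fuse
from gliomark.nn import Tensor, as_tensor


def make_cmaf(channels=4, seed=0, **kw):
    return CMAF(CmafConfig(channels=channels, **kw), np.random.default_rng(seed))


def zero_mlp(mod: CMAF):
    for layer in (mod.mlp_in, mod.mlp_out):
        layer.weight.data[...] = 0.0
        layer.bias.data[...] = 0.0


class TestAttention:
    def test_zero_parameters_give_uniform_quarter_weights(self, rng):
        mod = make_cmaf().eval()
        zero_mlp(mod)
        feats = mod.embed_modalities(rng.normal(size=(1, 4, 5, 5, 5)))
        attn = mod.attention_weights(feats)
        np.testing.assert_allclose(attn.data, 0.25, atol=1e-12)

    def test_bias_logit_matches_closed_form_softmax(self, rng):
        # b2 = (log 8, 0, 0, 0) with zero weights -> alpha = (8/11, 1/11, 1/11, 1/11)
        mod = make_cmaf().eval()
        zero_mlp(mod)
        mod.mlp_out.bias.data[0] = np.log(8.0)
        feats = mod.embed_modalities(rng.normal(size=(1, 4, 3, 3, 3)))
        attn = mod.attention_weights(feats).data
        np.testing.assert_allclose(attn[0, 0], 8.0 / 11.0, atol=1e-12)
        np.testing.assert_allclose(attn[0, 1:], 1.0 / 11.0, atol=1e-12)

    def test_weights_sum_to_one_for_random_parameters(self, rng):
        for trial in range(5):
            mod = make_cmaf(seed=trial).eval()
            feats = mod.embed_modalities(rng.normal(size=(2, 4, 4, 4, 4)) * 10)
            attn = mod.attention_weights(feats).data
            assert attn.min() >= 0
            np.testing.assert_allclose(attn.sum(axis=1), 1.0, atol=1e-6)

    def test_dropout_only_active_in_training(self, rng):
        mod = make_cmaf(seed=1)
        x = rng.normal(size=(1, 4, 4, 4, 4))
        mod.eval()
        a = mod(x)[0].data
        b = mod(x)[0].data
        np.testing.assert_array_equal(a, b)  # eval mode deterministic


class TestEmbedding:
    def test_identical_modalities_get_identical_features(self, rng):
        mod = make_cmaf().eval()
        vol = rng.normal(size=(1, 1, 5, 5, 5))
        x = np.concatenate([vol, vol, rng.normal(size=(1, 1, 5, 5, 5)), vol], axis=1)
        feats = mod.embed_modalities(x)
        np.testing.assert_array_equal(feats[0].data, feats[1].data)
        np.testing.assert_array_equal(feats[0].data, feats[3].data)
        assert not np.array_equal(feats[0].data, feats[2].data)

    def test_zero_input_zero_bias_gives_zero_features(self, rng):
        mod = make_cmaf(batchnorm=False).eval()
        mod.embed_conv.bias.data[...] = 0.0
        feats = mod.embed_modalities(np.zeros((1, 4, 4, 4, 4)))
        for f in feats:
            np.testing.assert_array_equal(f.data, 0.0)

    def test_scalar_kernel_matches_hand_computation(self):
        # 1-voxel volume, 1x1x1 kernel, no normalization: relu(w * x + b)
        mod = make_cmaf(channels=1, embed_kernel=1, batchnorm=False, seed=2).eval()
        mod.embed_conv.weight.data[...] = 2.0
        mod.embed_conv.bias.data[...] = -1.0
        x = np.full((1, 4, 1, 1, 1), 3.0)
        feats = mod.embed_modalities(x)
        assert feats[0].data.ravel()[0] == pytest.approx(max(2 * 3 - 1, 0))


class TestFuse:
    def _feats(self, rng, shape=(1, 2, 2, 2, 2)):
        return [as_tensor(rng.normal(size=shape)) for _ in range(4)]

    def test_uniform_attention_gives_arithmetic_mean(self, rng):
        feats = self._feats(rng)
        attn = as_tensor(np.full((1, 4, 2, 2, 2), 0.25))
        out = fuse(feats, attn).data
        np.testing.assert_allclose(out, np.mean([f.data for f in feats], axis=0), atol=1e-12)

    def test_one_hot_attention_selects_single_modality(self, rng):
        feats = self._feats(rng)
        a = np.zeros((1, 4, 2, 2, 2))
        a[:, 1] = 1.0  # select T1ce everywhere
        np.testing.assert_array_equal(fuse(feats, as_tensor(a)).data, feats[1].data)

    def test_matches_per_voxel_loop_oracle(self, rng):
        feats = self._feats(rng)
        logits = rng.normal(size=(1, 4, 2, 2, 2))
        e = np.exp(logits)
        attn = e / e.sum(axis=1, keepdims=True)
        out = fuse(feats, as_tensor(attn)).data
        expect = np.zeros_like(out)
        for i in range(2):
            for j in range(2):
                for k in range(2):
                    for c in range(2):
                        expect[0, c, i, j, k] = sum(
                            attn[0, m, i, j, k] * feats[m].data[0, c, i, j, k]
                            for m in range(4)
                        )
        np.testing.assert_allclose(out, expect, atol=1e-12)

    def test_output_is_convex_combination(self, rng):
        mod = make_cmaf(seed=3).eval()
        x = rng.normal(size=(1, 4, 4, 4, 4))
        feats = mod.embed_modalities(x)
        fused = mod(x)[0].data
        stackf = np.stack([f.data for f in feats], axis=0)
        assert (fused >= stackf.min(axis=0) - 1e-6).all()
        assert (fused <= stackf.max(axis=0) + 1e-6).all()

    def test_invalid_attention_rejected(self, rng):
        feats = self._feats(rng)
        bad = np.full((1, 4, 2, 2, 2), 0.3)  # sums to 1.2
        with pytest.raises(ValueError, match="simplex"):
            fuse(feats, bad)


def test_modality_permutation_equivariance(rng):
    """Permuting modality order along with the matching W1 input blocks and
    output logit rows leaves the fused volume unchanged."""
    mod = make_cmaf(channels=3, seed=4).eval()
    x = rng.normal(size=(1, 4, 3, 3, 3))
    fused, _ = mod(x)

    perm = [2, 0, 3, 1]
    xp = x[:, perm]
    c = mod.cfg.channels
    blocks = np.concatenate([np.arange(p * c, (p + 1) * c) for p in perm])
    mod.mlp_in.weight.data = mod.mlp_in.weight.data[np.ix_(blocks, blocks)]
    mod.mlp_in.bias.data = mod.mlp_in.bias.data[blocks]
    mod.mlp_out.weight.data = mod.mlp_out.weight.data[np.ix_(perm, blocks)]
    mod.mlp_out.bias.data = mod.mlp_out.bias.data[perm]
    fused_p, _ = mod(xp)
    np.testing.assert_allclose(fused_p.data, fused.data, atol=1e-5)


def test_fused_gradient_matches_finite_difference(rng):
    mod = make_cmaf(channels=2, seed=5, batchnorm=False).train()
    mod.drop.rate = 0.0
    x = rng.normal(size=(1, 4, 2, 2, 2))

    def loss():
        return (mod(x)[0] ** 2).mean()

    loss().backward()
    w = mod.mlp_in.weight
    g = w.grad[0, 1]
    eps = 1e-6
    orig = w.data[0, 1]
    w.data[0, 1] = orig + eps
    lp = loss().item()
    w.data[0, 1] = orig - eps
    lm = loss().item()
    w.data[0, 1] = orig
    assert g == pytest.approx((lp - lm) / (2 * eps), rel=1e-3)


class TestExport:
    def test_uniform_field_exports_constant_quarter_maps(self, tmp_path):
        attn = np.full((4, 3, 3, 3), 0.25)
        imgs = export_attention_maps(attn, directory=tmp_path)
        assert set(imgs) == {"t1", "t1ce", "t2", "flair"}
        np.testing.assert_allclose(np.asarray(imgs["t2"].dataobj), 0.25)

    def test_written_maps_reread_sum_to_one(self, tmp_path, rng):
        import nibabel as nib

        logits = rng.normal(size=(4, 3, 3, 3))
        attn = np.exp(logits) / np.exp(logits).sum(axis=0, keepdims=True)
        export_attention_maps(attn, directory=tmp_path, prefix="a")
        total = sum(
            np.asarray(nib.load(tmp_path / f"a_{m}.nii.gz").dataobj)
            for m in ("t1", "t1ce", "t2", "flair")
        )
        np.testing.assert_allclose(total, 1.0, atol=1e-6)

    def test_argmax_map_agrees_with_brute_force(self, rng):
        logits = rng.normal(size=(4, 4, 4, 4))
        attn = np.exp(logits) / np.exp(logits).sum(axis=0, keepdims=True)
        imgs = export_attention_maps(attn)
        stackm = np.stack([np.asarray(imgs[m].dataobj) for m in ("t1", "t1ce", "t2", "flair")])
        am = stackm.argmax(axis=0)
        for i in range(4):
            for j in range(4):
                for k in range(4):
                    assert am[i, j, k] == int(np.argmax(attn[:, i, j, k]))
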