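"""Marker head: segmentation gating, attention pooling, per-marker heads,
threshold optimization."""

import logging

import numpy as np
import pytest

from gliomark.markers import (
    AttentionPool,
    MarkerHead,
    MarkerHeadConfig,
    gate_features,
    optimize_threshold,
)
from gliomark.nn import Tensor, as_tensor


class TestGate:
    def test_all_ones_gate_leaves_latent_unchanged(self, rng):
        latent = rng.normal(size=(1, 4, 2, 2, 2))
        probs = np.zeros((1, 5, 4, 4, 4))
        probs[:, 1] = 1.0  # all-tumor prediction
        gated, gate = gate_features(as_tensor(latent), probs, mode="binary")
        np.testing.assert_allclose(gated.data, latent, atol=1e-12)
        np.testing.assert_array_equal(gate.data, 1.0)

    def test_all_zero_gate_falls_back_with_warning(self, rng, caplog):
        latent = rng.normal(size=(1, 4, 2, 2, 2))
        probs = np.zeros((1, 5, 4, 4, 4))
        probs[:, 0] = 1.0  # pure background
        with caplog.at_level(logging.WARNING, logger="gliomark.markers"):
            gated, gate = gate_features(as_tensor(latent), probs, mode="binary")
        assert gate is None
        np.testing.assert_array_equal(gated.data, latent)
        assert "zero" in caplog.text

    def test_binary_half_mask_matches_hand_multiplication(self, rng):
        latent = rng.normal(size=(1, 3, 2, 2, 2))
        probs = np.zeros((1, 5, 2, 2, 2))
        probs[:, 0] = 1.0
        probs[0, 0, 0] = 0.0
        probs[0, 2, 0] = 1.0  # NETC on the i=0 half (latent already at /1)
        gated, gate = gate_features(as_tensor(latent), probs, mode="binary")
        expect = latent.copy()
        expect[0, :, 1] = 0.0
        np.testing.assert_allclose(gated.data, expect, atol=1e-12)

    def test_soft_gate_is_tumor_probability(self, rng):
        latent = rng.normal(size=(1, 3, 2, 2, 2))
        probs = rng.random(size=(1, 5, 2, 2, 2))
        probs /= probs.sum(axis=1, keepdims=True)
        gated, gate = gate_features(as_tensor(latent), as_tensor(probs), mode="soft")
        np.testing.assert_allclose(gate.data[0, 0], 1 - probs[0, 0], atol=1e-12)


class TestAttentionPool:
    def test_constant_features_are_a_fixed_point(self, rng):
        pool = AttentionPool(3, 4, np.random.default_rng(0))
        v = np.array([1.5, -2.0, 0.25])
        latent = np.tile(v.reshape(1, 3, 1, 1, 1), (1, 1, 3, 3, 3))
        z = pool(as_tensor(latent)).data
        np.testing.assert_allclose(z[0], v, atol=1e-9)

    def test_zero_attention_projection_gives_spatial_mean(self, rng):
        pool = AttentionPool(3, 4, np.random.default_rng(1))
        pool.wa.weight.data[...] = 0.0
        latent = rng.normal(size=(1, 3, 2, 2, 2))
        z = pool(as_tensor(latent)).data
        np.testing.assert_allclose(z[0], latent[0].mean(axis=(1, 2, 3)), atol=1e-9)

    def test_two_voxel_toy_matches_scalar_hand_computation(self):
        pool = AttentionPool(1, 1, np.random.default_rng(2))
        wf, wa = 0.8, 1.5
        pool.wf.weight.data[...] = wf
        pool.wf.bias.data[...] = 0.0
        pool.wa.weight.data[...] = wa
        f0, f1 = 2.0, -1.0
        latent = np.array([f0, f1]).reshape(1, 1, 2, 1, 1)
        z = pool(as_tensor(latent)).data.ravel()[0]
        s0, s1 = wa * np.tanh(wf * f0), wa * np.tanh(wf * f1)
        w0 = np.exp(s0) / (np.exp(s0) + np.exp(s1))
        assert z == pytest.approx(w0 * f0 + (1 - w0) * f1, abs=1e-12)

    def test_pooled_vector_is_convex_combination(self, rng):
        pool = AttentionPool(4, 4, np.random.default_rng(3))
        latent = rng.normal(size=(2, 4, 3, 3, 3))
        z = pool(as_tensor(latent)).data
        for n in range(2):
            lo = latent[n].reshape(4, -1).min(axis=1)
            hi = latent[n].reshape(4, -1).max(axis=1)
            assert (z[n] >= lo - 1e-6).all() and (z[n] <= hi + 1e-6).all()

    def test_gated_out_voxels_contribute_nothing(self, rng):
        pool = AttentionPool(2, 2, np.random.default_rng(4))
        latent = rng.normal(size=(1, 2, 2, 1, 1))
        gate = np.zeros((1, 1, 2, 1, 1))
        gate[0, 0, 0] = 1.0
        gated = as_tensor(latent) * Tensor(gate)
        z = pool(gated, Tensor(gate)).data
        np.testing.assert_allclose(z[0], latent[0, :, 0, 0, 0], atol=1e-12)


class TestHeads:
    def _head(self, seed=0):
        cfg = MarkerHeadConfig(latent_channels=4, attn_hidden=4, head_hidden=4)
        return MarkerHead(cfg, np.random.default_rng(seed))

    def test_zero_weights_give_half_probability(self, rng):
        head = self._head().eval()
        for m in ("idh", "1p19q", "tert"):
            getattr(head, f"fc2_{m}").weight.data[...] = 0.0
            getattr(head, f"fc2_{m}").bias.data[...] = 0.0
        z = as_tensor(rng.normal(size=(1, 4)))
        out = head.predict_markers(z)
        for m, p in out.items():
            assert p.data.ravel()[0] == pytest.approx(0.5)

    def test_bias_log3_gives_three_quarters(self, rng):
        head = self._head().eval()
        getattr(head, "fc2_idh").weight.data[...] = 0.0
        getattr(head, "fc2_idh").bias.data[...] = np.log(3.0)
        out = head.predict_markers(as_tensor(rng.normal(size=(1, 4))))
        assert out["idh"].data.ravel()[0] == pytest.approx(0.75)

    def test_heads_are_independent(self, rng):
        head = self._head().eval()
        for m in ("idh", "1p19q", "tert"):
            getattr(head, f"fc2_{m}").weight.data[...] = rng.normal(size=(1, 4))
        z = as_tensor(rng.normal(size=(1, 4)))
        before = {m: p.data.copy() for m, p in head.predict_markers(z).items()}
        head.fc1_idh.weight.data += 1.0  # perturb only the IDH head
        after = head.predict_markers(z)
        assert not np.allclose(after["idh"].data, before["idh"])
        np.testing.assert_array_equal(after["1p19q"].data, before["1p19q"])
        np.testing.assert_array_equal(after["tert"].data, before["tert"])

    def test_probabilities_strictly_inside_unit_interval(self, rng):
        head = self._head(1).eval()
        out = head.predict_markers(as_tensor(rng.normal(size=(3, 4)) * 50))
        for p in out.values():
            assert (p.data > 0).all() and (p.data < 1).all()

    def test_monotone_in_output_bias(self, rng):
        head = self._head(2).eval()
        z = as_tensor(rng.normal(size=(1, 4)))
        p0 = head.predict_markers(z)["tert"].data.ravel()[0]
        head.fc2_tert.bias.data += 2.0
        p1 = head.predict_markers(z)["tert"].data.ravel()[0]
        assert p1 > p0


class TestThresholds:
    def test_separable_scores_return_midpoint(self):
        t, stats = optimize_threshold([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert t == pytest.approx(0.5)
        assert stats["j"] == pytest.approx(1.0)

    def test_single_class_labels_raise(self):
        with pytest.raises(ValueError, match="class-0"):
            optimize_threshold([0.2, 0.8], [1, 1])

    def test_youden_matches_exhaustive_sweep(self, rng):
        for trial in range(5):
            scores = rng.random(20)
            labels = rng.integers(0, 2, 20)
            if len(np.unique(labels)) < 2:
                continue
            t, stats = optimize_threshold(scores, labels)
            # brute-force sweep over all midpoints and endpoints
            cands = np.concatenate([[0.0, 1.0], scores, (np.sort(scores)[:-1] + np.sort(scores)[1:]) / 2])
            best = -np.inf
            pos = labels == 1
            for c in cands:
                pred = scores >= c
                j = (pred & pos).sum() / pos.sum() + (~pred & ~pos).sum() / (~pos).sum() - 1
                best = max(best, j)
            assert stats["j"] == pytest.approx(best, abs=1e-12)
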