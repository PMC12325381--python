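"""Detector components against trivial fixtures and brute-force oracles."""

import itertools

import numpy as np
import pytest

from keyfg.model import (
    DeformAttnParams,
    KeyFgDetector,
    LossWeights,
    MaskMLP,
    ModelConfig,
    TokenScore,
    assign_min_cost,
    backbone_stage_shapes,
    build_denoising_queries,
    composite_loss,
    dropkey_attention,
    fgsp_scores,
    hungarian_match,
    ms_deform_attn,
    select_foreground_tokens,
)
from keyfg.model.matcher import MatchWeights
from keyfg.model.boxes import cxcywh_to_xyxy, giou_np
from keyfg.nn import Tensor, softmax


# ----------------------------------------------------------------------
class TestBackboneShapes:
    def test_reference_input_chain(self):
        shapes = backbone_stage_shapes(1333, 800)
        chain = [(s.stage, s.height, s.width, s.channels) for s in shapes]
        assert chain == [
            ("conv1", 667, 400, 64),
            ("pool", 334, 200, 64),
            ("conv2_x", 334, 200, 256),
            ("conv3_x", 167, 100, 512),
            ("conv4_x", 84, 50, 1024),
            ("conv5_x", 42, 25, 2048),
        ]

    @pytest.mark.parametrize("hw,final", [((224, 224), (7, 7)), ((32, 32), (1, 1))])
    def test_ceil_division_chain(self, hw, final):
        shapes = backbone_stage_shapes(*hw)
        assert (shapes[-1].height, shapes[-1].width) == final

    def test_minimum_input(self):
        with pytest.raises(ValueError):
            backbone_stage_shapes(31, 100)


# ----------------------------------------------------------------------
class TestFGSP:
    def test_product_rule(self):
        big = 50.0
        scores = fgsp_scores(np.array([[big], [big]]), np.array([big, -big]))
        assert scores[0].product == pytest.approx(1.0)
        assert scores[1].product == pytest.approx(0.0, abs=1e-6)

    def test_direct_product(self):
        s = TokenScore(class_prob=0.8, foreground_prob=0.5)
        assert s.product == pytest.approx(0.4)

    def test_confident_balanced_token_outranks_spiky_one(self):
        a = TokenScore(0.9, 0.9)
        b = TokenScore(0.99, 0.1)
        assert a.product > b.product

    def test_keep_all(self):
        scores = [TokenScore(0.5, 0.5)] * 7
        assert select_foreground_tokens(scores, 1.0).tolist() == list(range(7))

    def test_top_k_selection(self, rng):
        p = rng.random(10)
        scores = [TokenScore(float(v), 1.0) for v in p]
        sel = select_foreground_tokens(scores, 0.3)
        assert len(sel) == 3
        assert set(sel) == set(np.argsort(-p)[:3])

    def test_tie_break_toward_lower_index(self):
        scores = [TokenScore(0.5, 0.5)] * 10
        assert select_foreground_tokens(scores, 0.25).tolist() == [0, 1, 2]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_foreground_tokens([], 0.5)


# ----------------------------------------------------------------------
def _oracle_ms_deform(ref, pyramid, params):
    """Independent dense loop: explicit bilinear interpolation per sample."""
    M, L, K, _ = params.offsets.shape
    C = pyramid[0].shape[2]
    out = np.zeros(C)
    for m in range(M):
        head = np.zeros(np.asarray(params.value_proj[m]).shape[1])
        for l in range(L):
            H, W = pyramid[l].shape[:2]
            for k in range(K):
                px = ref[0] * W - 0.5 + params.offsets[m, l, k, 0]
                py = ref[1] * H - 0.5 + params.offsets[m, l, k, 1]
                v = np.zeros(C)
                fx, fy = px - np.floor(px), py - np.floor(py)
                for (ix, iy, w) in [
                    (int(np.floor(px)), int(np.floor(py)), (1 - fx) * (1 - fy)),
                    (int(np.floor(px)) + 1, int(np.floor(py)), fx * (1 - fy)),
                    (int(np.floor(px)), int(np.floor(py)) + 1, (1 - fx) * fy),
                    (int(np.floor(px)) + 1, int(np.floor(py)) + 1, fx * fy),
                ]:
                    if 0 <= ix < W and 0 <= iy < H:
                        v = v + w * pyramid[l][iy, ix]
                head = head + params.weights[m, l, k] * (v @ params.value_proj[m])
        out = out + head @ params.out_proj[m]
    return out


def _random_params(rng, M, L, K, C):
    w = rng.random((M, L, K))
    w /= w.reshape(M, -1).sum(axis=1).reshape(M, 1, 1)
    return DeformAttnParams(
        offsets=rng.normal(0, 1.5, size=(M, L, K, 2)),
        weights=w,
        value_proj=[rng.normal(size=(C, C // M)) for _ in range(M)],
        out_proj=[rng.normal(size=(C // M, C)) for _ in range(M)],
    )


class TestMSDeformAttn:
    def test_degenerate_single_pixel(self):
        v = np.array([[[3.0, -2.0]]])
        params = DeformAttnParams(
            offsets=np.zeros((1, 1, 1, 2)),
            weights=np.ones((1, 1, 1)),
            value_proj=[np.eye(2)],
            out_proj=[np.eye(2)],
        )
        out = ms_deform_attn(np.array([0.5, 0.5]), [v], params)
        assert np.allclose(out, [3.0, -2.0])

    def test_constant_levels_convexity(self, rng):
        c = 4.2
        pyr = [np.full((4, 4, 2), c), np.full((2, 2, 2), c)]
        w = rng.random((1, 2, 3))
        w /= w.sum()
        params = DeformAttnParams(
            offsets=rng.uniform(-0.4, 0.4, size=(1, 2, 3, 2)),
            weights=w, value_proj=[np.eye(2)], out_proj=[np.eye(2)],
        )
        out = ms_deform_attn(np.array([0.5, 0.5]), pyr, params)
        assert np.allclose(out, c)

    def test_matches_dense_oracle(self, rng):
        for _ in range(100):
            pyr = [rng.normal(size=(4, 4, 4)), rng.normal(size=(2, 2, 4))]
            params = _random_params(rng, M=2, L=2, K=2, C=4)
            ref = rng.random(2)
            got = ms_deform_attn(ref, pyr, params)
            want = _oracle_ms_deform(ref, pyr, params)
            assert np.abs(got - want).max() <= 1e-5

    def test_unnormalised_weights_rejected(self, rng):
        with pytest.raises(ValueError, match="sum to 1"):
            DeformAttnParams(
                offsets=np.zeros((1, 1, 2, 2)),
                weights=np.full((1, 1, 2), 0.9),
                value_proj=[np.eye(2)], out_proj=[np.eye(2)],
            )


# ----------------------------------------------------------------------
class TestDropKey:
    def test_ratio_zero_equals_standard_attention(self, rng):
        q = Tensor(rng.normal(size=(3, 4)))
        k = Tensor(rng.normal(size=(5, 4)))
        v = Tensor(rng.normal(size=(5, 4)))
        out = dropkey_attention(q, k, v, 0.0, rng, training=True)
        ref = softmax((q @ k.transpose()) * 0.5, axis=-1) @ v
        assert np.allclose(out.data, ref.data)

    def test_rows_remain_convex_combinations(self, rng):
        q = Tensor(rng.normal(size=(6, 4)))
        k = Tensor(rng.normal(size=(8, 4)))
        v = Tensor(np.ones((8, 4)))
        out = dropkey_attention(q, k, v, 0.5, rng, training=True)
        assert np.allclose(out.data, 1.0, atol=1e-6)  # weights sum to 1

    def test_inference_ignores_drop_ratio(self, rng):
        q = Tensor(rng.normal(size=(3, 4)))
        k = Tensor(rng.normal(size=(5, 4)))
        v = Tensor(rng.normal(size=(5, 4)))
        a = dropkey_attention(q, k, v, 0.9, rng, training=False)
        b = dropkey_attention(q, k, v, 0.0, rng, training=False)
        assert np.allclose(a.data, b.data)

    def test_empirical_drop_fraction(self):
        rng = np.random.default_rng(2024)
        n = 0
        total = 0
        q = Tensor(np.zeros((100, 2)))
        kv = Tensor(np.zeros((1000, 2)))
        # one call samples 10^5 mask entries
        out = dropkey_attention(q, kv, kv, 0.1, rng, training=True)
        # recount by regenerating the same mask stream
        rng2 = np.random.default_rng(2024)
        mask = rng2.random((100, 1000)) < 0.1
        frac = mask.mean()
        assert abs(frac - 0.1) <= 0.005
        assert out.shape == (100, 2)

    def test_full_row_drop_falls_back(self, caplog, rng):
        q = Tensor(rng.normal(size=(2, 3)))
        k = Tensor(rng.normal(size=(1, 3)))
        v = Tensor(np.array([[7.0, 7.0, 7.0]]))

        class AlwaysDrop:
            def random(self, shape):
                return np.zeros(shape)  # 0 < ratio -> always drop

        out = dropkey_attention(q, k, v, 0.5, AlwaysDrop(), training=True)
        assert np.allclose(out.data, 7.0)


# ----------------------------------------------------------------------
class TestMaskMLP:
    def test_zero_logits_give_half(self, rng):
        m = MaskMLP(4, 8, rng)
        for layer in (m.spatial.layers + m.channel.layers):
            layer.weight.data[:] = 0.0
            layer.bias.data[:] = 0.0
        sm = m(Tensor(rng.normal(size=(3, 3, 4))))
        assert np.allclose(sm.mask.data, 0.5)

    def test_mask_strictly_inside_unit_interval(self, rng):
        m = MaskMLP(4, 8, rng)
        sm = m(Tensor(rng.normal(size=(5, 4, 4))))
        assert np.all(sm.mask.data > 0.0) and np.all(sm.mask.data < 1.0)

    def test_outer_product_saturation(self, rng):
        m = MaskMLP(4, 8, rng)
        sm = m(Tensor(rng.normal(size=(2, 2, 4))))
        # force +10 logits at one location and one channel
        fused = 1 / (1 + np.exp(-(10.0 * 10.0)))
        assert fused >= 0.999999
        # masked features never exceed originals in magnitude
        feat = Tensor(rng.normal(size=(2, 2, 4)))
        masked = m(feat).apply(feat)
        assert np.all(np.abs(masked.data) <= np.abs(feat.data) + 1e-12)


# ----------------------------------------------------------------------
class TestDenoising:
    def test_zero_noise_zero_flip_identity(self, rng):
        boxes = np.array([[0.5, 0.5, 0.2, 0.3], [0.3, 0.7, 0.1, 0.1]])
        labels = np.array([0, 1])
        dn = build_denoising_queries(boxes, labels, n_classes=3,
                                     n_matching_queries=4, box_noise_scale=0.0,
                                     label_flip_prob=0.0, n_groups=2, rng=rng)
        assert np.allclose(dn.boxes, np.tile(boxes, (2, 1)))
        assert np.array_equal(dn.labels, np.tile(labels, 2))

    def test_attention_mask_blocks_leakage(self, rng):
        boxes = np.array([[0.5, 0.5, 0.2, 0.2]] * 3)
        dn = build_denoising_queries(boxes, np.zeros(3, dtype=int), 2,
                                     n_matching_queries=5, n_groups=2, rng=rng)
        m = dn.attn_mask
        assert m.shape == (5 + 6, 5 + 6)
        assert m[:5, 5:].all()            # matching -> any denoising: blocked
        assert not m[:5, :5].any()        # matching -> matching: open
        assert m[5:8, 8:11].all()         # group 0 -> group 1: blocked
        assert m[8:11, 5:8].all()         # group 1 -> group 0: blocked
        assert not m[5:8, 5:8].any()      # within group: open
        assert not m[5:8, :5].any()       # denoising -> matching: open

    def test_flip_fraction_matches_probability(self):
        rng = np.random.default_rng(7)
        boxes = np.tile([[0.5, 0.5, 0.2, 0.2]], (10000, 1))
        labels = np.zeros(10000, dtype=int)
        dn = build_denoising_queries(boxes, labels, n_classes=5,
                                     n_matching_queries=1, label_flip_prob=0.5,
                                     n_groups=1, rng=rng)
        frac = (dn.labels != 0).mean()
        assert abs(frac - 0.5) <= 0.02

    def test_noised_boxes_stay_in_unit_square(self, rng):
        boxes = np.array([[0.05, 0.05, 0.1, 0.1], [0.95, 0.95, 0.1, 0.1]])
        dn = build_denoising_queries(boxes, np.zeros(2, dtype=int), 2,
                                     n_matching_queries=2, box_noise_scale=0.9,
                                     n_groups=10, rng=rng)
        xyxy = cxcywh_to_xyxy(dn.boxes)
        assert dn.boxes[:, 2:].min() > 0


# ----------------------------------------------------------------------
def _brute_force_assignment(cost):
    P, G = cost.shape
    best, best_cost = None, np.inf
    for perm in itertools.permutations(range(P), G):
        c = sum(cost[perm[j], j] for j in range(G))
        if c < best_cost:
            best, best_cost = perm, c
    return np.array(best), best_cost


class TestHungarian:
    def test_diagonal_cost(self):
        assert assign_min_cost(np.array([[0.0, 1.0], [1.0, 0.0]])).tolist() == [0, 1]

    def test_antidiagonal_cost(self):
        assert assign_min_cost(np.array([[1.0, 0.0], [0.0, 1.0]])).tolist() == [1, 0]

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(200):
            P = int(rng.integers(1, 7))
            G = int(rng.integers(1, min(P, 4) + 1))
            cost = rng.random((P, G))
            got = assign_min_cost(cost)
            _, want_cost = _brute_force_assignment(cost)
            got_cost = sum(cost[got[j], j] for j in range(G))
            assert got_cost == pytest.approx(want_cost)

    def test_too_few_predictions_rejected(self):
        with pytest.raises(ValueError):
            assign_min_cost(np.zeros((2, 3)))

    def test_full_cost_prefers_matching_box_and_class(self, rng):
        preds = np.array([[0.5, 0.5, 0.2, 0.2], [0.1, 0.1, 0.05, 0.05]])
        probs = np.array([[0.9], [0.1]])
        gts = np.array([[0.5, 0.5, 0.22, 0.2]])
        idx = hungarian_match(preds, probs, gts, np.array([0]))
        assert idx.tolist() == [0]


# ----------------------------------------------------------------------
class TestCompositeLoss:
    def _outputs(self, rng, n_classes=2):
        logits = Tensor(rng.normal(size=(4, n_classes)), requires_grad=True)
        boxes = Tensor(np.tile([[0.5, 0.5, 0.2, 0.2]], (4, 1)), requires_grad=True)
        return {
            "n_classes": n_classes,
            "decoder_layers": [{"logits": logits, "boxes": boxes,
                                "matched_pred_idx": np.array([0])}],
            "dn": None,
            "enc": None,
            "soft_masks": None,
            "fg_logits": Tensor(rng.normal(size=(6,)), requires_grad=True),
        }

    def _targets(self):
        return {"boxes": np.array([[0.5, 0.5, 0.2, 0.2]]),
                "labels": np.array([0]),
                "fg_labels": np.zeros(6)}

    def test_all_zero_weights_give_zero_total(self, rng):
        lb = composite_loss(self._outputs(rng), self._targets(),
                            LossWeights(0, 0, 0, 0, 0))
        assert lb.total_value == 0.0

    def test_match_only_weights(self, rng):
        out = self._outputs(rng)
        lb = composite_loss(out, self._targets(), LossWeights(1, 0, 0, 0, 0))
        assert lb.total_value == pytest.approx(lb.match)

    def test_total_is_weighted_sum(self, rng):
        out = self._outputs(rng)
        lb = composite_loss(out, self._targets(), LossWeights(1, 1, 1, 1, 1))
        assert lb.total_value == pytest.approx(
            lb.match + lb.dn + lb.mask + lb.fg + lb.enc
        )

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            LossWeights(lam_match=-1.0)


# ----------------------------------------------------------------------
class TestDetectorReduction:
    def test_baseline_flags_disable_all_modules(self, rng):
        cfg = ModelConfig(use_maskmlp=False, use_dn=False, use_dropkey=False,
                          use_fgsp=False, keep_ratio=1.0)
        model = KeyFgDetector(cfg, seed=0)
        img = rng.integers(0, 256, size=(64, 64, 3))
        out = model.forward(img, training=True, rng=rng)
        assert out["soft_masks"] is None
        assert out["dn"] is None
        # with keep_ratio 1 and no fgsp, all tokens are query candidates
        assert out["enc"]["logits"].shape[0] == len(out["token_centers"])

    def test_one_gradient_step_decreases_loss(self):
        from keyfg.nn import Adam
        from keyfg.synthetic import SceneSpec, generate_dataset

        ds = generate_dataset(1, SceneSpec(height=64, width=64, n_objects=1,
                                           alpha=0.8, min_radius=8,
                                           max_radius=12), seed=5)
        cfg = ModelConfig()
        model = KeyFgDetector(cfg, seed=3)
        im = ds.images[0]
        targets = model.prepare_targets(ds.annotations_for(im.id),
                                        (im.height, im.width), masks=ds.masks,
                                        category_index={1: 0})
        img = ds.load_pixels(im.id)
        opt = Adam(model.parameters(), lr=1e-4)
        losses = []
        for _ in range(2):
            model.zero_grad()
            out = model.forward(img, targets, training=True,
                                rng=np.random.default_rng(0))
            lb = composite_loss(out, targets, cfg.loss_weights)
            lb.total.backward()
            opt.step()
            losses.append(lb.total_value)
        assert losses[1] < losses[0]
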