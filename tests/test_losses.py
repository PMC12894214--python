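"""Relational and response-based distillation losses.

Every vectorised loss is cross-checked against an independent scalar
nested-loop reference implementation; the frozen example values were
computed by hand or by high-precision direct evaluation of the defining
formulas.
"""

import math

import numpy as np
import pytest

from irmkd import (
    LossWeights,
    build_irm,
    build_toy_cnn,
    cls_loss,
    combined_kd,
    irm_loss,
    irm_t_loss,
    irm_t_loss_pairs,
    kd_loss,
    logits_loss,
    mtk_loss,
    sample_distance_matrix,
    soft_softmax,
)
from irmkd.autograd import Tensor
from irmkd.features import FeatureTapSet, build_tap_set
from irmkd.losses import IRMTensor, SampleDistanceMatrix


# --------------------------------------------------------------------------
# scalar nested-loop oracles (independent of the vectorised implementations)


def irm_oracle(vecs: np.ndarray) -> np.ndarray:
    n, m, _ = vecs.shape
    out = np.zeros((n, m, m))
    for k in range(n):
        for g in range(m):
            for h in range(m):
                out[k, g, h] = math.sqrt(sum((vecs[k, g] - vecs[k, h]) ** 2))
    return out


def irm_loss_oracle(ht: np.ndarray, hs: np.ndarray) -> float:
    n, m, _ = ht.shape
    acc = 0.0
    for k in range(n):
        for g in range(m):
            for h in range(m):
                acc += (ht[k, g, h] - hs[k, g, h]) ** 2
    return acc / (n * m * m)


def sdm_oracle(layer_vecs: np.ndarray) -> np.ndarray:
    n = len(layer_vecs)
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            out[a, b] = math.sqrt(sum((layer_vecs[a] - layer_vecs[b]) ** 2))
    return out


def irm_t_oracle(tg, th, sg, sh) -> float:
    n = len(tg)
    acc = 0.0
    for a in range(n):
        for b in range(n):
            acc += ((tg[a, b] - th[a, b]) - (sg[a, b] - sh[a, b])) ** 2
    return acc / (n * n)


def logits_oracle(yt: np.ndarray, ys: np.ndarray) -> float:
    acc = 0.0
    for i in range(len(yt)):
        acc += sum((yt[i] - ys[i]) ** 2)
    return acc / len(yt)


def softmax_oracle(row, temperature):
    e = [math.exp(z / temperature) for z in row]
    s = sum(e)
    return [x / s for x in e]


def kd_oracle(yt, ys, temperature) -> float:
    acc = 0.0
    for i in range(len(yt)):
        pt = softmax_oracle(yt[i], temperature)
        ps = softmax_oracle(ys[i], temperature)
        acc += -sum(p * math.log(q) for p, q in zip(pt, ps))
    return temperature**2 * acc / len(yt)


def unit_vectors(rng, n, m, d) -> np.ndarray:
    v = rng.normal(size=(n, m, d))
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def tap_set(vecs: np.ndarray) -> FeatureTapSet:
    names = tuple(f"t{i}" for i in range(vecs.shape[1]))
    return FeatureTapSet(Tensor(vecs), names, canonical_size=int(round(vecs.shape[2] ** 0.5)) or 1)


# --------------------------------------------------------------------------


class TestSoftSoftmax:
    def test_equal_logits_give_uniform(self):
        for t in (1.0, 4.0, 100.0):
            p = soft_softmax(np.zeros((2, 3)), t)
            np.testing.assert_allclose(p.data, 1 / 3, atol=1e-12)

    def test_high_temperature_limit_approaches_uniform(self):
        p = soft_softmax(np.array([[1.0, 2.0, 3.0]]), 1e6)
        np.testing.assert_allclose(p.data, 1 / 3, atol=1e-6)

    def test_frozen_values_at_temperature_one(self):
        p = soft_softmax(np.array([[1.0, 2.0, 3.0]]), 1.0)
        np.testing.assert_allclose(
            p.data[0], [0.09003057, 0.24472847, 0.66524096], atol=1e-8
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_rows_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        p = soft_softmax(rng.normal(scale=10, size=(4, 6)), 3.0)
        np.testing.assert_allclose(p.data.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(p.data > 0) and np.all(p.data < 1)

    def test_extreme_logits_are_stable(self):
        p = soft_softmax(np.array([[1000.0, 0.0, -1000.0]]), 1.0)
        assert np.all(np.isfinite(p.data))

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            soft_softmax(np.zeros((1, 2)), 0.0)


class TestBuildIRM:
    def test_identical_tap_vectors_give_zero_slice(self):
        v = np.tile(np.array([1.0, 0.0, 0.0]), (2, 3, 1))  # all m vectors equal
        irm = build_irm(tap_set(v))
        np.testing.assert_array_equal(irm.values.data, np.zeros((2, 3, 3)))

    def test_orthogonal_unit_vectors_give_sqrt_two(self):
        v = np.array([[[1.0, 0, 0, 0], [0, 1.0, 0, 0]]])
        irm = build_irm(tap_set(v))
        expected = np.array([[[0, math.sqrt(2)], [math.sqrt(2), 0]]])
        np.testing.assert_allclose(irm.values.data, expected, atol=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_nested_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        v = unit_vectors(rng, n=3, m=4, d=9)
        irm = build_irm(tap_set(v))
        np.testing.assert_allclose(irm.values.data, irm_oracle(v), atol=1e-6)

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(7)
        irm = build_irm(tap_set(unit_vectors(rng, 4, 3, 16))).values.data
        np.testing.assert_array_equal(irm, np.swapaxes(irm, 1, 2))
        assert np.all(np.abs(np.diagonal(irm, axis1=1, axis2=2)) == 0)
        assert irm.min() >= 0 and irm.max() <= 2


class TestIRMLoss:
    def test_identity_gives_zero(self):
        rng = np.random.default_rng(0)
        irm = build_irm(tap_set(unit_vectors(rng, 3, 3, 4)))
        assert irm_loss(irm, irm).item() == 0.0

    def test_hand_counted_two_thirds(self):
        off = 1.0 - np.eye(3)
        ht = IRMTensor(Tensor(np.stack([off, off])))
        hs = IRMTensor(Tensor(np.zeros((2, 3, 3))))
        np.testing.assert_allclose(irm_loss(ht, hs).item(), 2.0 / 3.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b = (build_irm(tap_set(unit_vectors(rng, 2, 3, 8))) for _ in range(2))
        np.testing.assert_allclose(
            irm_loss(a, b).item(), irm_loss_oracle(a.values.data, b.values.data), atol=1e-6
        )

    def test_shape_mismatch_rejected(self):
        a = IRMTensor(Tensor(np.zeros((2, 3, 3))))
        b = IRMTensor(Tensor(np.zeros((2, 2, 2))))
        with pytest.raises(ValueError):
            irm_loss(a, b)


class TestSampleDistanceMatrix:
    def test_identical_samples_give_zero_matrix(self):
        v = np.tile(np.array([0.6, 0.8]), (4, 2, 1))
        sdm = sample_distance_matrix(tap_set(v), 0)
        np.testing.assert_array_equal(sdm.values.data, np.zeros((4, 4)))

    def test_orthogonal_pair(self):
        v = np.array([[[1.0, 0.0]], [[0.0, 1.0]]])  # n=2, m=1 layer... need m>=1
        ts = FeatureTapSet(Tensor(v), ("t0",), canonical_size=1)
        sdm = sample_distance_matrix(ts, 0)
        np.testing.assert_allclose(
            sdm.values.data, [[0, math.sqrt(2)], [math.sqrt(2), 0]], atol=1e-12
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pairwise_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        v = unit_vectors(rng, 4, 2, 9)
        sdm = sample_distance_matrix(tap_set(v), 1)
        np.testing.assert_allclose(sdm.values.data, sdm_oracle(v[:, 1]), atol=1e-6)

    def test_layer_out_of_range(self):
        rng = np.random.default_rng(1)
        with pytest.raises(IndexError):
            sample_distance_matrix(tap_set(unit_vectors(rng, 3, 2, 4)), 5)


class TestIRMTLoss:
    def test_equal_flows_give_zero(self):
        rng = np.random.default_rng(0)
        d = sdm_oracle(unit_vectors(rng, 3, 1, 5)[:, 0])
        assert irm_t_loss(d, d * 0.5, d, d * 0.5).item() == 0.0

    def test_hand_counted_half(self):
        flow = 1.0 - np.eye(2)  # teacher flow: ones off-diagonal
        zero = np.zeros((2, 2))
        np.testing.assert_allclose(irm_t_loss(flow, zero, zero, zero).item(), 0.5, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_explicit_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tg, th, sg, sh = rng.random((4, 3, 3))
        np.testing.assert_allclose(
            irm_t_loss(tg, th, sg, sh).item(), irm_t_oracle(tg, th, sg, sh), atol=1e-6
        )

    def test_multi_pair_average(self):
        rng = np.random.default_rng(2)
        vt, vs = unit_vectors(rng, 3, 3, 4), unit_vectors(rng, 3, 3, 4)
        w = LossWeights()
        got = irm_t_loss_pairs(tap_set(vt), tap_set(vs), w).item()
        terms = []
        for g, h in [(0, 1), (1, 2)]:  # default consecutive pairs
            terms.append(
                irm_t_oracle(
                    sdm_oracle(vt[:, g]), sdm_oracle(vt[:, h]), sdm_oracle(vs[:, g]), sdm_oracle(vs[:, h])
                )
            )
        np.testing.assert_allclose(got, np.mean(terms), atol=1e-6)

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            irm_t_loss(np.zeros((2, 2)), np.zeros((2, 2)), np.zeros((3, 3)), np.zeros((3, 3)))


class TestLogitsLoss:
    def test_identity_gives_zero(self):
        y = np.random.default_rng(0).normal(size=(3, 4))
        assert logits_loss(y, y).item() == 0.0

    def test_single_sample_hand_value(self):
        assert logits_loss(np.array([[1.0, 2.0]]), np.array([[0.0, 0.0]])).item() == 5.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        yt, ys = rng.normal(size=(2, 5, 3))
        np.testing.assert_allclose(logits_loss(yt, ys).item(), logits_oracle(yt, ys), atol=1e-6)


class TestKDLoss:
    def test_self_distillation_equals_scaled_entropy(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=(3, 5))
        t = 4.0
        p = soft_softmax(y, t).data
        entropy = float(np.mean(-(p * np.log(p)).sum(axis=1)))
        np.testing.assert_allclose(kd_loss(y, y, t).item(), t**2 * entropy, atol=1e-10)

    def test_uniform_teacher_hand_value(self):
        yt = np.zeros((1, 4))
        ys = np.zeros((1, 4))
        np.testing.assert_allclose(kd_loss(yt, ys, 1.0).item(), math.log(4), atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scalar_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        yt, ys = rng.normal(size=(2, 3, 5))
        np.testing.assert_allclose(kd_loss(yt, ys, 3.0).item(), kd_oracle(yt, ys, 3.0), atol=1e-6)


class TestCombinedKD:
    def test_endpoints_and_arithmetic(self):
        assert combined_kd(2.0, 4.0, alpha=1.0).item() == 2.0
        assert combined_kd(2.0, 4.0, alpha=0.0).item() == 4.0
        assert combined_kd(2.0, 4.0, alpha=0.5).item() == 3.0

    def test_alpha_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            combined_kd(1.0, 1.0, alpha=1.5)

    def test_cls_loss_is_hard_label_cross_entropy(self):
        logits = np.array([[2.0, 0.0, 0.0], [0.0, 3.0, 0.0]])
        labels = [0, 1]
        expected = np.mean(
            [-math.log(softmax_oracle(row, 1.0)[k]) for row, k in zip(logits, labels)]
        )
        np.testing.assert_allclose(cls_loss(logits, labels).item(), expected, atol=1e-10)


class TestMTK:
    def test_zero_components_give_zero(self):
        total, br = mtk_loss(0.0, 0.0, 0.0, 0.0, LossWeights())
        assert total.item() == 0.0 and br.total == 0.0

    def test_weighted_sum_arithmetic(self):
        w = LossWeights(alpha=0.5, beta=1.0, gamma=1.0)
        total, br = mtk_loss(2.0, 4.0, 6.0, 8.0, w)
        assert total.item() == 17.0
        assert (br.irm_t, br.irm, br.logits, br.gt) == (2.0, 4.0, 6.0, 8.0)

    def test_gamma_only_reduces_to_supervised(self):
        w = LossWeights(alpha=0.0, beta=0.0, gamma=1.0)
        total, _ = mtk_loss(123.0, 0.0, 456.0, 7.5, w)
        # alpha=0 removes the IRM-t term, beta=0 the logits term, IRM frozen at 0
        assert total.item() == 7.5

    def test_non_finite_component_named(self):
        with pytest.raises(FloatingPointError, match="logits"):
            mtk_loss(0.0, 0.0, float("nan"), 0.0, LossWeights())

    def test_weight_validation(self):
        with pytest.raises(ValueError):
            LossWeights(alpha=1.5)
        with pytest.raises(ValueError):
            LossWeights(temperature=1.0)
        with pytest.raises(ValueError):
            LossWeights(flow_pairs=((2, 1),))


class TestBatchPermutationEquivariance:
    def test_losses_invariant_and_structures_equivariant(self, tiny_batch):
        teacher = build_toy_cnn([8, 16], 3, seed=0).eval()
        student = build_toy_cnn([4, 8], 3, seed=1).eval()
        x = tiny_batch.images[:6]
        perm = np.random.default_rng(3).permutation(6)

        def all_pieces(images):
            tt, lt = build_tap_set(teacher, images, 8)
            ts, ls = build_tap_set(student, images, 8)
            return {
                "irm_T": build_irm(tt).values.data,
                "sdm_T": sample_distance_matrix(tt, 0).values.data,
                "irm_loss": irm_loss(build_irm(tt), build_irm(ts)).item(),
                "irm_t": irm_t_loss_pairs(tt, ts, LossWeights()).item(),
                "logits": logits_loss(lt, ls).item(),
                "kd": kd_loss(lt.data, ls.data, 4.0).item(),
            }

        base = all_pieces(x)
        shuf = all_pieces(x[perm])
        np.testing.assert_allclose(shuf["irm_T"], base["irm_T"][perm], atol=1e-10)
        np.testing.assert_allclose(shuf["sdm_T"], base["sdm_T"][np.ix_(perm, perm)], atol=1e-10)
        for key in ("irm_loss", "irm_t", "logits", "kd"):
            np.testing.assert_allclose(shuf[key], base[key], atol=1e-10)
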