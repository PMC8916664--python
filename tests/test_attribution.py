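"""SA and LRP maps, common maps, occlusion plans and perturbation."""

import numpy as np
import pytest

from gaitproto import nn
from gaitproto.attribution import (AttributionMap, LRPConfig, attribution_map,
                                   average_components, common_map, lrp_map,
                                   make_occlusion_plan, occlude, occlude_batch,
                                   sensitivity_map)
from gaitproto.encoder import Encoder, EncoderConfig


class TestSensitivity:
    def test_linear_map_gradient_is_weight_magnitude(self, rng):
        """For f(x) = sum w_ij x_ij the sensitivity map is |w|."""
        layer = nn.Dense(12, 1, rng)
        x = rng.normal(size=(1, 12))
        layer.forward(x)
        grad = layer.backward(np.ones((1, 1)))
        np.testing.assert_allclose(np.abs(grad[0]), np.abs(layer.W[:, 0]),
                                   atol=1e-12)

    def test_nonnegative_and_shaped(self, small_encoder64, rng):
        step = rng.normal(size=(12, 28))
        m = sensitivity_map(small_encoder64, step, c=5)
        assert m.data.shape == (12, 28)
        assert np.all(m.data >= 0)

    def test_component_out_of_range(self, small_encoder64, rng):
        with pytest.raises(IndexError):
            sensitivity_map(small_encoder64, rng.normal(size=(12, 28)), c=128)

    def test_matches_finite_differences(self, small_encoder64, rng):
        step = rng.normal(size=(12, 28))
        c = 17
        m = sensitivity_map(small_encoder64, step, c)
        eps = 1e-6
        for _ in range(12):
            t, ch = rng.integers(12), rng.integers(28)
            sp = step.copy(); sp[t, ch] += eps
            sm = step.copy(); sm[t, ch] -= eps
            fd = (small_encoder64.forward(sp[None])[0, c]
                  - small_encoder64.forward(sm[None])[0, c]) / (2 * eps)
            assert abs(m.data[t, ch] - abs(fd)) < 1e-4


def naive_lrp_dense(x, W, z, R, eps):
    """Double-loop epsilon-rule redistribution through one dense layer."""
    n_in, n_out = W.shape
    R_prev = np.zeros(n_in)
    for j in range(n_out):
        denom = z[j] + eps * (1.0 if z[j] >= 0 else -1.0)
        for i in range(n_in):
            R_prev[i] += x[i] * W[i, j] / denom * R[j]
    return R_prev


class TestLRP:
    def test_conservation_bias_free(self, small_encoder64, rng):
        x = rng.normal(size=(2, 12, 28))
        small_encoder64.forward(x)
        R0 = rng.normal(size=(2, 128))
        R = small_encoder64.lrp(R0, eps=0.0)
        np.testing.assert_allclose(R.sum(axis=(1, 2)), R0.sum(axis=1), atol=1e-6)

    def test_equal_contributions_split_evenly(self, rng):
        layer = nn.Dense(2, 1, rng, bias=False)
        layer.W[...] = 1.0
        layer.forward(np.array([[1.0, 1.0]]))
        R = layer.lrp(np.array([[1.0]]), eps=0.0)
        np.testing.assert_allclose(R, [[0.5, 0.5]], atol=1e-12)

    def test_matches_naive_double_loop(self, rng):
        """Independent per-neuron loop over the equivalent dense connections."""
        from gaitproto.layout import BLOCKS

        config = EncoderConfig(T=8, dtype="float64", use_bias=False)
        enc = Encoder(config, np.random.default_rng(9))
        step = rng.normal(size=(8, 28))
        eps = 1e-7
        c = 3
        got = lrp_map(enc, step, c, LRPConfig(eps)).data
        v = enc.forward(step[None])

        # capture each conv's input activations and pre-activations, and the
        # dense caches, before any probing clobbers them
        dense_caches = [(enc.dense2.x[0].copy(), enc.dense2.z[0].copy(),
                         enc.dense2.W.copy()),
                        (enc.dense1.x[0].copy(), enc.dense1.z[0].copy(),
                         enc.dense1.W.copy())]
        conv_caches = []  # per block: list of (x_input, z)
        for (_, sl, _), layers in zip(BLOCKS, enc.subs):
            h = np.ascontiguousarray(step[:, sl])[None]
            block = []
            for layer in layers:
                if isinstance(layer, nn.Conv1d):
                    block.append((h[0].copy(), None))
                h = layer.forward(h)
                if isinstance(layer, nn.Conv1d):
                    block[-1] = (block[-1][0], h[0].copy())
            conv_caches.append(block)

        def dense_equiv(layer, in_shape):
            """Column i of the equivalent dense matrix is layer(e_i)."""
            n_in = int(np.prod(in_shape))
            basis = np.eye(n_in).reshape((n_in,) + tuple(in_shape))
            return layer.forward(basis).reshape(n_in, -1)

        R = np.zeros(128)
        R[c] = v[0, c]
        for x, z, W in dense_caches:
            R = naive_lrp_dense(x, W, z, R, eps)
        out = np.zeros((8, 28))
        fw = enc.flat_width
        for bi, ((_, sl, width), layers) in enumerate(zip(BLOCKS, enc.subs)):
            Rb = R[bi * fw : (bi + 1) * fw]
            convs = [l for l in layers if isinstance(l, nn.Conv1d)]
            for conv, (x_input, z) in zip(reversed(convs),
                                          reversed(conv_caches[bi])):
                W_eq = dense_equiv(conv, x_input.shape)
                Rb = naive_lrp_dense(x_input.ravel(), W_eq, z.ravel(), Rb, eps)
            out[:, sl] = Rb.reshape(8, width)
        np.testing.assert_allclose(got, out, atol=1e-6)

    def test_zero_epsilon_zero_denominator_raises(self, rng):
        layer = nn.Dense(2, 1, rng, bias=False)
        layer.W[...] = np.array([[1.0], [-1.0]])
        layer.forward(np.array([[1.0, 1.0]]))  # z = 0 exactly
        with pytest.raises(ZeroDivisionError):
            layer.lrp(np.array([[1.0]]), eps=0.0)


class TestAveraging:
    def test_identical_maps(self, rng):
        m = rng.normal(size=(6, 28))
        maps = [AttributionMap(m.copy(), "sa", c) for c in range(128)]
        np.testing.assert_allclose(average_components(maps).data, m, atol=1e-12)

    def test_arithmetic_mean_of_constants(self):
        maps = [AttributionMap(np.full((4, 28), float(c)), "sa", c - 1)
                for c in range(1, 129)]
        np.testing.assert_allclose(average_components(maps).data, 64.5)

    def test_loop_oracle(self, rng):
        stack = rng.normal(size=(128, 5, 28))
        oracle = sum(stack[c] for c in range(128)) / 128
        got = average_components([AttributionMap(stack[c], "lrp", c)
                                  for c in range(128)])
        np.testing.assert_allclose(got.data, oracle, atol=1e-12)

    def test_wrong_count_rejected(self, rng):
        with pytest.raises(ValueError):
            average_components([AttributionMap(np.zeros((4, 28)), "sa", 0)] * 100)


class TestCommonMap:
    def test_single_step_degenerate(self, small_encoder64, rng):
        step = rng.normal(size=(12, 28))
        cm = common_map(small_encoder64, step[None], "sa")
        a = attribution_map(small_encoder64, step, "sa")
        np.testing.assert_allclose(cm.data, a.data, atol=1e-10)
        assert cm.n_steps == 1

    def test_duplication_invariant(self, small_encoder64, rng):
        steps = rng.normal(size=(2, 12, 28))
        cm1 = common_map(small_encoder64, steps, "sa")
        cm2 = common_map(small_encoder64, np.concatenate([steps, steps]), "sa")
        np.testing.assert_allclose(cm1.data, cm2.data, atol=1e-10)

    def test_grand_mean_oracle(self, small_encoder64, rng):
        groups = {a: rng.normal(size=(2, 12, 28)) for a in range(3)}
        cm = common_map(small_encoder64, groups, "lrp")
        acc = np.zeros((12, 28))
        for g in groups.values():
            for row in g:
                acc += attribution_map(small_encoder64, row, "lrp").data
        np.testing.assert_allclose(cm.data, acc / 6, atol=1e-10)
        assert cm.n_subjects == 3 and cm.n_steps == 6

    def test_empty_rejected(self, small_encoder64):
        with pytest.raises(ValueError):
            common_map(small_encoder64, np.empty((0, 12, 28)), "sa")


class TestOcclusionPlan:
    def test_quintiles_are_top_percent_blocks(self, rng):
        data = rng.normal(size=(25, 4))  # L = 100
        plan = make_occlusion_plan(data)
        assert plan.L == 100
        o1 = plan.quintile(1)
        assert len(o1) == 20
        top20 = np.argsort(-np.abs(data).ravel())[:20]
        assert set(o1) == set(top20)

    def test_all_equal_relevance_is_row_major(self):
        plan = make_occlusion_plan(np.ones((3, 4)))
        np.testing.assert_array_equal(plan.order, np.arange(12))

    def test_unique_maximum_first(self, rng):
        data = rng.uniform(0.1, 0.5, size=(6, 28))
        data[4, 9] = 7.0
        plan = make_occlusion_plan(data)
        assert plan.positions(1)[0].tolist() == [4, 9]

    def test_remainder_goes_to_last_quintile(self):
        plan = make_occlusion_plan(np.ones((3, 28)))  # L = 84 = 5*16 + 4
        sizes = [len(plan.quintile(k)) for k in range(1, 6)]
        assert sizes == [16, 16, 16, 16, 20]


class TestOcclusion:
    def test_empty_identity_full_zero_idempotent(self, rng):
        step = rng.normal(size=(6, 28))
        np.testing.assert_array_equal(occlude(step, np.empty((0, 2), int)), step)
        assert np.all(occlude(step, np.argwhere(np.ones((6, 28)))) == 0)
        pos = np.array([[0, 0], [5, 27]])
        once = occlude(step, pos)
        np.testing.assert_array_equal(occlude(once, pos), once)

    def test_out_of_bounds(self, rng):
        with pytest.raises(IndexError):
            occlude(rng.normal(size=(6, 28)), np.array([[6, 0]]))

    def test_batch_matches_single(self, rng):
        steps = rng.normal(size=(3, 6, 28))
        flat = np.array([0, 10, 167])
        out = occlude_batch(steps, flat)
        for i in range(3):
            np.testing.assert_array_equal(out[i], occlude(steps[i], flat))


class TestPerturbation:
    def test_no_occlusion_reproduces_baseline_metrics(self, tiny_model,
                                                      tiny_dataset):
        from gaitproto.experiment import fit_pipeline
        from gaitproto.recognizer import SplitSpec, split_dataset

        spec = SplitSpec(n_train=2, n_known=1, n_unknown=1, n_shots=3,
                         repetitions=1, seed=0)
        split = split_dataset(tiny_dataset, spec, 0)
        pipe = fit_pipeline(tiny_model, split.shots, 2.2, 0.3, -0.1, split)
        known_emb = {a: pipe.embed(v) for a, v in split.known_test.items()}
        unknown = np.concatenate(list(split.unknown_test.values()))
        base = pipe.evaluate(known_emb, pipe.embed(unknown))
        # occluding zero positions changes nothing
        known_occl = {a: pipe.embed(occlude_batch(v, np.array([], dtype=int)))
                      for a, v in split.known_test.items()}
        again = pipe.evaluate(known_occl, pipe.embed(unknown))
        assert base.as_dict() == again.as_dict()
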