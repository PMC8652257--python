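import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modcaps import SourceSpec, coupling_from_logits, routing, squash
from modcaps.core import CapsuleConfig, CapsuleModel
from modcaps.train import TrainConfig, _margin_loss_grad, margin_loss

from oracles import encode_oracle, routing_oracle, softmax_oracle, squash_oracle


def tiny_model(l=2, k=3, n=3, m=4, seed=1, **cfg_kwargs):
    specs = [SourceSpec(f"s{i}", "numeric", tuple(f"s{i}_f{j}" for j in range(3 + i)))
             for i in range(l)]
    cfg = CapsuleConfig(n=n, m=m, **cfg_kwargs)
    return CapsuleModel.initialize(specs, [f"c{j}" for j in range(k)], cfg, seed=seed)


# ---------------------------------------------------------------------------
# squash
# ---------------------------------------------------------------------------

class TestSquash:
    def test_zero_maps_to_zero(self):
        np.testing.assert_array_equal(squash(np.zeros(4)), np.zeros(4))

    def test_half_norm_squared_point(self):
        s = np.array([math.sqrt(0.5), 0.0])
        np.testing.assert_allclose(squash(s), [0.5, 0.0], atol=1e-12)

    def test_norm_law_on_grid(self):
        norms = np.linspace(0.0, 100.0, 401)[1:]
        for rho in norms:
            s = np.array([rho, 0.0, 0.0])
            out = np.linalg.norm(squash(s))
            assert abs(out - rho**2 / (0.5 + rho**2)) < 1e-6

    def test_monotone_and_bounded(self):
        norms = np.linspace(0.0, 100.0, 500)
        outs = [np.linalg.norm(squash(np.array([r, 0.0]))) for r in norms]
        assert all(b > a for a, b in zip(outs, outs[1:]))
        assert all(o < 1.0 for o in outs)

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=6))
    @settings(max_examples=100, deadline=None)
    def test_matches_scalar_oracle(self, vec):
        got = squash(np.array(vec, dtype=float))
        want = squash_oracle(vec)
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_custom_constant(self):
        s = np.array([2.0, 0.0])
        out = squash(s, const=1.0)
        assert abs(np.linalg.norm(out) - 4.0 / 5.0) < 1e-12


# ---------------------------------------------------------------------------
# couplings
# ---------------------------------------------------------------------------

class TestCouplingFromLogits:
    def test_uniform_at_zero(self):
        c = coupling_from_logits(np.zeros((2, 3)))
        np.testing.assert_allclose(c, np.full((2, 3), 1.0 / 3.0))

    def test_saturation_without_overflow(self):
        c = coupling_from_logits(np.array([[1000.0, 0.0]]))
        assert np.isfinite(c).all()
        np.testing.assert_allclose(c[0], [1.0, 0.0], atol=1e-12)

    def test_ln2_closed_form(self):
        c = coupling_from_logits(np.array([math.log(2.0), 0.0]))
        np.testing.assert_allclose(c, [2.0 / 3.0, 1.0 / 3.0], atol=1e-9)

    def test_matches_oracle(self, rng):
        b = rng.normal(size=(5, 4))
        got = coupling_from_logits(b)
        for i in range(5):
            np.testing.assert_allclose(got[i], softmax_oracle(list(b[i])),
                                       atol=1e-12)

    def test_rows_sum_to_one(self, rng):
        c = coupling_from_logits(rng.normal(size=(7, 3, 5)))
        np.testing.assert_allclose(c.sum(axis=-1), 1.0, atol=1e-12)
        assert (c > 0).all()


# ---------------------------------------------------------------------------
# encoders and prediction vectors
# ---------------------------------------------------------------------------

class TestEncode:
    def test_zero_input_zero_capsule(self):
        model = tiny_model()
        blocks = [np.zeros((2, s.length)) for s in model.sources]
        u = model.encode(blocks)
        np.testing.assert_array_equal(u, np.zeros_like(u))

    def test_tanh_saturation_with_identity_weights(self):
        spec = SourceSpec("a", "numeric", ("f1", "f2", "f3"))
        model = CapsuleModel.initialize([spec], ["x", "y"],
                                        CapsuleConfig(n=3, m=2), seed=0)
        model.Wp[0] = np.eye(3)
        u = model.encode([np.array([[10.0, -10.0, 0.0]])])
        np.testing.assert_allclose(u[0, 0], [1.0, -1.0, 0.0], atol=1e-4)

    def test_matches_double_loop_oracle(self, rng):
        model = tiny_model(seed=3)
        blocks = [rng.normal(size=(4, s.length)) for s in model.sources]
        u = model.encode(blocks)
        for b in range(4):
            for i, block in enumerate(blocks):
                want = encode_oracle(model.Wp[i].tolist(), block[b].tolist())
                np.testing.assert_allclose(u[b, i], want, atol=1e-6)

    def test_tanh_range(self, rng):
        model = tiny_model(seed=2)
        blocks = [rng.normal(size=(8, s.length)) for s in model.sources]
        u = model.encode(blocks)
        assert (u > -1).all() and (u < 1).all()
        # extreme inputs may saturate to exactly +-1 in float64, never beyond
        big = [b * 1e3 for b in blocks]
        u = model.encode(big)
        assert (np.abs(u) <= 1.0).all()

    def test_shape_mismatch_names_source(self):
        model = tiny_model()
        blocks = [np.zeros((2, model.sources[0].length)),
                  np.zeros((2, 99))]
        with pytest.raises(ValueError, match="'s1'"):
            model.encode(blocks)


class TestPredictVectors:
    def test_zero_capsules_zero_predictions(self):
        model = tiny_model()
        u = np.zeros((2, model.n_sources, model.config.n))
        np.testing.assert_array_equal(model.predict_vectors(u), 0.0)

    def test_identity_weights_copy_capsule(self, rng):
        model = tiny_model(n=4, m=4)
        model.W = np.broadcast_to(
            np.eye(4), (model.n_sources, model.n_classes, 4, 4)).copy()
        u = rng.normal(size=(3, model.n_sources, 4))
        u_hat = model.predict_vectors(u)
        for j in range(model.n_classes):
            np.testing.assert_allclose(u_hat[:, :, j, :], u, atol=1e-12)

    def test_matches_nested_loop_oracle(self, rng):
        model = tiny_model(seed=5)
        u = rng.normal(size=(2, model.n_sources, model.config.n))
        u_hat = model.predict_vectors(u)
        for b in range(2):
            for i in range(model.n_sources):
                for j in range(model.n_classes):
                    want = np.array(model.W[i, j]) @ u[b, i]
                    np.testing.assert_allclose(u_hat[b, i, j], want, atol=1e-6)


# ---------------------------------------------------------------------------
# routing
# ---------------------------------------------------------------------------

class TestRouting:
    def test_r_below_one_errors(self, rng):
        with pytest.raises(ValueError, match="r"):
            routing(rng.normal(size=(1, 2, 2, 2)), r=0)

    def test_single_iteration_uniform_couplings(self, rng):
        u_hat = rng.normal(size=(1, 3, 4, 2))
        v, c = routing(u_hat, r=1)
        np.testing.assert_allclose(c, 0.25)
        s = u_hat.sum(axis=1) * 0.25
        np.testing.assert_allclose(v, squash(s), atol=1e-12)

    def test_identical_predictions_symmetry(self, rng):
        # all primary capsules agree -> every capsule's coupling row is the
        # same (the dot products are equal across i), and with r=1 the
        # couplings are exactly uniform
        one = rng.normal(size=(1, 1, 3, 4))
        u_hat = np.repeat(one, 5, axis=1)
        _, c1 = routing(u_hat, r=1)
        np.testing.assert_allclose(c1, 1.0 / 3.0, atol=1e-12)
        _, c = routing(u_hat, r=3)
        for i in range(1, 5):
            np.testing.assert_allclose(c[:, i], c[:, 0], atol=1e-9)

    @pytest.mark.parametrize("l", [1, 2, 3])
    @pytest.mark.parametrize("k", [1, 2, 3])
    @pytest.mark.parametrize("m", [1, 2, 3])
    @pytest.mark.parametrize("r", [1, 2, 3])
    def test_matches_scalar_loop_oracle(self, l, k, m, r):
        rng = np.random.default_rng(l * 1000 + k * 100 + m * 10 + r)
        u_hat = rng.normal(size=(2, l, k, m))
        v, c = routing(u_hat, r=r)
        for b in range(2):
            v_o, c_o = routing_oracle(u_hat[b].tolist(), r)
            np.testing.assert_allclose(v[b], v_o, atol=1e-6)
            np.testing.assert_allclose(c[b], c_o, atol=1e-6)

    @pytest.mark.parametrize("variant", ["normalize_every_iter", "accumulate_logits"])
    def test_variants_match_oracle(self, variant, rng):
        u_hat = rng.normal(size=(2, 3, 2, 4))
        kwargs = {variant: True}
        v, c = routing(u_hat, r=3, **kwargs)
        for b in range(2):
            v_o, c_o = routing_oracle(u_hat[b].tolist(), 3, **kwargs)
            np.testing.assert_allclose(v[b], v_o, atol=1e-6)
            np.testing.assert_allclose(c[b], c_o, atol=1e-6)

    def test_hand_stepped_small_integers(self):
        # l=2, k=2, m=2, r=2 with small integer predictions.
        u_hat = np.array([[[[1.0, 0.0], [0.0, 2.0]],
                           [[1.0, 1.0], [-1.0, 0.0]]]])
        v, c = routing(u_hat, r=2)
        v_o, c_o = routing_oracle(u_hat[0].tolist(), 2)
        np.testing.assert_allclose(v[0], v_o, atol=1e-6)
        np.testing.assert_allclose(c[0], c_o, atol=1e-6)

    def test_coupling_normalization_property(self, rng):
        u_hat = rng.normal(size=(6, 5, 4, 3))
        _, c = routing(u_hat, r=3)
        np.testing.assert_allclose(c.sum(axis=-1), 1.0, atol=1e-6)
        assert (c > 0).all()

    def test_capsule_lengths_below_one(self, rng):
        u_hat = rng.normal(size=(6, 5, 4, 3)) * 50
        v, _ = routing(u_hat, r=3)
        lengths = np.linalg.norm(v, axis=-1)
        assert (lengths < 1.0).all()

    def test_permutation_equivariance(self, rng):
        u_hat = rng.normal(size=(3, 5, 4, 3))
        perm = rng.permutation(5)
        v1, c1 = routing(u_hat, r=3)
        v2, c2 = routing(u_hat[:, perm], r=3)
        np.testing.assert_allclose(v2, v1, atol=1e-6)
        np.testing.assert_allclose(c2, c1[:, perm], atol=1e-6)

    def test_determinism(self, rng):
        u_hat = rng.normal(size=(4, 3, 3, 3))
        v1, c1 = routing(u_hat.copy(), r=3)
        v2, c2 = routing(u_hat.copy(), r=3)
        assert np.array_equal(v1, v2) and np.array_equal(c1, c2)


# ---------------------------------------------------------------------------
# full forward
# ---------------------------------------------------------------------------

class TestForward:
    def test_zero_encoders_symmetric_argmax(self):
        model = tiny_model()
        model.Wp = [np.zeros_like(w) for w in model.Wp]
        blocks = [np.zeros((2, s.length)) for s in model.sources]
        scores, _ = model.forward(blocks)
        assert np.ptp(scores) == 0
        assert (model.predict(blocks) == 0).all()

    def test_scores_in_unit_interval(self, rng):
        model = tiny_model(seed=7)
        blocks = [rng.normal(size=(10, s.length)) * 5 for s in model.sources]
        scores, _ = model.forward(blocks)
        assert (scores >= 0).all() and (scores < 1).all()

    def test_end_to_end_oracle_composition(self, rng):
        model = tiny_model(seed=11)
        blocks = [rng.normal(size=(3, s.length)) for s in model.sources]
        scores, c = model.forward(blocks)
        for b in range(3):
            u = [encode_oracle(model.Wp[i].tolist(), blocks[i][b].tolist())
                 for i in range(model.n_sources)]
            u_hat = [[(np.array(model.W[i, j]) @ np.array(u[i])).tolist()
                      for j in range(model.n_classes)]
                     for i in range(model.n_sources)]
            v_o, c_o = routing_oracle(u_hat, model.config.r)
            want = [math.sqrt(sum(z * z for z in vj)) for vj in v_o]
            np.testing.assert_allclose(scores[b], want, atol=1e-5)
            np.testing.assert_allclose(c[b], c_o, atol=1e-5)

    def test_wrong_block_count(self):
        model = tiny_model()
        with pytest.raises(ValueError, match="source blocks"):
            model.forward([np.zeros((1, 3))])


# ---------------------------------------------------------------------------
# gradients
# ---------------------------------------------------------------------------

class TestBackward:
    @pytest.mark.parametrize("variant", [{}, {"accumulate_logits": True},
                                         {"r": 1}, {"r": 2}])
    def test_matches_central_differences(self, variant):
        rng = np.random.default_rng(42)
        model = tiny_model(n=3, m=4, seed=1, **({} if "r" not in variant else {}))
        if variant:
            for key, val in variant.items():
                setattr(model.config, key, val)
        blocks = [rng.normal(size=(5, s.length)) for s in model.sources]
        y = rng.integers(0, model.n_classes, 5)
        tcfg = TrainConfig()

        def loss():
            scores, _, cache = model.forward(blocks, return_cache=True)
            return margin_loss(scores, y, tcfg), cache, scores

        base, cache, scores = loss()
        dWp, dW = model.backward(cache, _margin_loss_grad(scores, y, tcfg))
        eps = 1e-6
        for p, g in zip(model.Wp + [model.W], dWp + [dW]):
            for _ in range(8):
                idx = tuple(rng.integers(0, d) for d in p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                lp = loss()[0]
                p[idx] = orig - eps
                lm = loss()[0]
                p[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert abs(num - g[idx]) < 1e-5 * max(1.0, abs(num))


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, rng):
        model = tiny_model(seed=9)
        path = tmp_path / "model.npz"
        model.save(path)
        back = CapsuleModel.load(path)
        assert back.class_names == model.class_names
        assert [s.name for s in back.sources] == [s.name for s in model.sources]
        assert back.config == model.config
        blocks = [rng.normal(size=(4, s.length)) for s in model.sources]
        np.testing.assert_array_equal(model.predict_scores(blocks),
                                      back.predict_scores(blocks))

    def test_version_field_checked(self, tmp_path):
        model = tiny_model()
        path = tmp_path / "model.npz"
        model.save(path)
        import json as _json
        import numpy as _np
        with _np.load(path) as npz:
            arrays = {k: npz[k] for k in npz.files}
        meta = _json.loads(bytes(arrays["meta_json"].tobytes()))
        meta["format_version"] = 999
        arrays["meta_json"] = _np.frombuffer(
            _json.dumps(meta).encode(), dtype=_np.uint8)
        _np.savez(path, **arrays)
        with pytest.raises(ValueError, match="format version"):
            CapsuleModel.load(path)
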