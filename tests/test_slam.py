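import numpy as np
import pytest

import vsaslam as vs
from vsaslam.nef import LIFParams
from vsaslam.slam import (
    AssocMemory,
    LoopClosureState,
    OVCPopulation,
    loop_closure,
    observe,
    ol_bind,
    ovc_encode,
    reverse_recall,
    vector_to_landmark,
)
from vsaslam.vsa import bind, bundle, inverse


@pytest.fixture(scope="module")
def demo_env(vocab):
    return vs.worked_example_environment(vocab)


class TestObserve:
    def test_empty_when_far(self, demo_env):
        assert observe(demo_env, [-1.0, 1.0], 0.1) == []

    def test_closed_ball_boundary(self, demo_env):
        # landmark exactly at the view radius is included
        lm = demo_env.landmarks[0]
        x = lm.position + np.array([0.3, 0.0])
        obs = observe(demo_env, x, 0.3)
        assert any(o.index == 0 for o in obs)

    def test_exact_displacements(self, demo_env):
        x = np.array([0.1, 0.1])
        for o in observe(demo_env, x, 1.0):
            lm = demo_env.landmarks[o.index]
            assert np.allclose(o.displacement, lm.position - x)

    def test_brute_force_subset(self, vocab):
        env = vs.make_environment(3, n_landmarks=10, m=2, vocab=vocab)
        x = np.zeros(2)
        radius = 0.45
        expected = {
            i
            for i, lm in enumerate(env.landmarks)
            if np.linalg.norm(lm.position - x) <= radius
        }
        got = {o.index for o in observe(env, x, radius)}
        assert got == expected and 0 < len(got) < 10


class TestOVC:
    def test_landmark_at_agent_gives_identity(self, full_encoder, demo_env):
        lm = demo_env.landmarks[0]
        obs = observe(demo_env, lm.position, 0.3)
        vecs, _ = ovc_encode(full_encoder, obs)
        target = [o for o in obs if o.index == 0]
        assert target
        idx = obs.index(target[0])
        ident = np.zeros(full_encoder.d)
        ident[0] = 1.0
        assert np.allclose(vecs[idx], ident, atol=1e-9)

    def test_preferred_offset_neuron_fires_maximally(self, full_encoder):
        ovc = OVCPopulation.build(full_encoder, view_radius=0.3, n=100, seed=0)
        # a neuron's encoder is the encoding of its preferred offset; probing
        # with exactly that offset drives it at its maximum rate
        i = 13
        probe = ovc.pop.encoders[i]
        rates = ovc.pop.rates(probe)
        from vsaslam.nef import lif_rate

        assert rates[i] == pytest.approx(
            lif_rate(ovc.pop.lif, ovc.pop.gain[i] + ovc.pop.bias[i])
        )


class TestOLBind:
    def test_clean_inputs_give_landmark_location(
        self, full_encoder, full_readout
    ):
        x = np.array([0.2, -0.1])
        xi = np.array([0.45, 0.15])
        out = ol_bind(
            full_encoder.encode_vec(x), full_encoder.encode_vec(xi - x)
        )
        assert np.linalg.norm(full_readout.map_decode(out) - xi) < 0.02

    def test_identity_ego_returns_self_estimate(self, full_encoder):
        est = full_encoder.encode_vec([0.3, 0.3])
        ident = np.zeros(full_encoder.d)
        ident[0] = 1.0
        assert np.allclose(ol_bind(est, ident), est, atol=1e-9)

    def test_noisy_estimate_error_bounded(self, full_encoder, full_readout):
        # Monte-Carlo: landmark decode error tracks the self-estimate error
        rng = np.random.default_rng(1)
        x = np.array([-0.3, 0.2])
        xi = np.array([0.0, 0.45])
        for _ in range(10):
            offset = rng.normal(0, 0.03, 2)
            est = full_encoder.encode_vec(x + offset)  # biased self-estimate
            out = ol_bind(est, full_encoder.encode_vec(xi - x))
            err = np.linalg.norm(full_readout.map_decode(out) - xi)
            assert err <= np.linalg.norm(offset) + 0.03


@pytest.fixture()
def memory(full_encoder):
    return AssocMemory(
        full_encoder.d, full_encoder.d, n=1000,
        lif=LIFParams(), seed=0,
    )


class TestAssocMemory:
    def test_gate_off_bit_identical(self, memory, vocab, full_encoder):
        enc0 = memory.pop.encoders.copy()
        dec0 = memory.decoders.copy()
        memory.learning_gate = False
        memory.train_step(
            np.asarray(vocab["BLUE"]), full_encoder.encode_vec([0.1, 0.1]),
            1e-3, 10,
        )
        assert np.array_equal(memory.pop.encoders, enc0)
        assert np.array_equal(memory.decoders, dec0)

    def test_untrained_recall_uninformative(self, memory, full_encoder):
        # Monte-Carlo baseline: recalls of an untrained memory carry no
        # similarity to values stored later
        rng = np.random.default_rng(2)
        for seed in range(5):
            v = vs.Vocabulary(full_encoder.d, seed=100 + seed)
            key = v.random_pointer("K")
            value = full_encoder.encode_vec(rng.uniform(-0.8, 0.8, 2))
            r = memory.recall(np.asarray(key))
            denom = np.linalg.norm(r) * np.linalg.norm(value)
            sim = (r @ value) / denom if denom > 0 else 0.0
            assert abs(sim) < 0.3

    def test_single_association_one_second(self, memory, vocab, full_encoder):
        key = np.asarray(bind(vocab["BLUE"], vocab["SQUARE"]))
        value = full_encoder.encode_vec([0.5, -0.2])
        memory.learning_gate = True
        for _ in range(200):  # 1 simulated second at 5 steps per 25 ms
            memory.train_step(key, value, 1e-3, 5)
        r = memory.recall(key)
        sim = r @ value / (np.linalg.norm(r) * np.linalg.norm(value))
        assert sim > 0.9

    def test_worked_mapping_three_associations(
        self, vocab, full_encoder, full_readout
    ):
        # the published worked mapping: three feature->location pairs decode
        # back to their stored coordinates within 0.05 units
        mem = AssocMemory(full_encoder.d, full_encoder.d, n=1000, seed=1)
        pairs = [
            (bind(vocab["BLUE"], vocab["SQUARE"]), [0.6, 0.2]),
            (bind(vocab["BLUE"], vocab["TRIANGLE"]), [0.0, -0.6]),
            (bind(vocab["ORANGE"], vocab["TRIANGLE"]), [-0.2, 0.2]),
        ]
        mem.learning_gate = True
        for _ in range(150):
            for key, loc in pairs:
                mem.train_step(
                    np.asarray(key), full_encoder.encode_vec(loc), 1e-3, 5
                )
        for key, loc in pairs:
            dec = full_readout.map_decode(mem.recall(np.asarray(key)))
            assert np.linalg.norm(dec - np.asarray(loc)) < 0.05

    def test_compositional_query(self, vocab, full_encoder, full_readout):
        mem = AssocMemory(full_encoder.d, full_encoder.d, n=1000, seed=2)
        k1 = np.asarray(bind(vocab["BLUE"], vocab["SQUARE"]))
        k2 = np.asarray(bind(vocab["BLUE"], vocab["TRIANGLE"]))
        v1 = full_encoder.encode_vec([0.6, 0.2])
        v2 = full_encoder.encode_vec([0.0, -0.6])
        mem.learning_gate = True
        for _ in range(150):
            mem.train_step(k1, v1, 1e-3, 5)
            mem.train_step(k2, v2, 1e-3, 5)
        combo = (k1 + k2) / np.sqrt(2)
        r = mem.recall(combo)
        individual = mem.recall(k1) + mem.recall(k2)
        cos = r @ individual / (
            np.linalg.norm(r) * np.linalg.norm(individual)
        )
        assert cos > 0.9
        # similarity map shows modes at both stored locations
        field = full_readout.field(r)
        pts = full_readout.points
        near1 = field[np.linalg.norm(pts - [0.6, 0.2], axis=1) < 0.05].max()
        near2 = field[np.linalg.norm(pts - [0.0, -0.6], axis=1) < 0.05].max()
        far = field[
            (np.linalg.norm(pts - [0.6, 0.2], axis=1) > 0.3)
            & (np.linalg.norm(pts - [0.0, -0.6], axis=1) > 0.3)
        ].max()
        assert near1 > far and near2 > far

    def test_voja_captures_encoders_toward_keys(self, vocab, full_encoder):
        # sustained presentation pulls the responding neurons' encoders onto
        # the presented key (the specialization the memory relies on)
        mem = AssocMemory(full_encoder.d, full_encoder.d, n=1000, seed=3,
                          voja_rate=2e-2)
        key = np.asarray(bind(vocab["BLUE"], vocab["SQUARE"]))
        winners_before = np.argsort(-mem.activities(key))[:10]
        align_before = (mem.pop.encoders[winners_before] @ key).mean()
        mem.learning_gate = True
        value = full_encoder.encode_vec([0.0, 0.0])
        for _ in range(400):
            mem.train_step(key, value, 1e-3, 5)
        align_after = (mem.pop.encoders[winners_before] @ key).mean()
        assert align_after > align_before + 0.3
        assert align_after > 0.9

    def test_hdf5_round_trip(self, memory, vocab, full_encoder, tmp_path):
        key = np.asarray(vocab["BLUE"])
        memory.learning_gate = True
        memory.train_step(key, full_encoder.encode_vec([0.2, 0.2]), 1e-3, 20)
        path = tmp_path / "mem.h5"
        memory.save(path)
        loaded = AssocMemory.load(path)
        assert np.allclose(loaded.recall(key), memory.recall(key))


class TestReverseRecall:
    @pytest.fixture(scope="class")
    def reverse_memory(self, vocab):
        # region queries need a kernel wide enough that its integral over an
        # area dominates the encoder's ripple noise
        enc = vs.make_encoder(181, 2, length_scale=0.3, seed=2)
        mem = AssocMemory(enc.d, enc.d, n=1000, seed=4)
        env = vs.worked_example_environment(vocab)
        rng = np.random.default_rng(0)
        mem.learning_gate = True
        for _ in range(150):
            for lm in env.landmarks:
                mem.train_step(
                    enc.encode_vec(lm.position + rng.normal(0, 0.03, 2)),
                    np.asarray(env.feature_pointer(lm)),
                    1e-3,
                    5,
                )
        feats = {
            lm.name: np.asarray(env.feature_pointer(lm))
            for lm in env.landmarks
        }
        return mem, env, enc, feats

    def test_point_query_ranks_own_feature_first(self, reverse_memory):
        mem, env, enc, feats = reverse_memory
        for lm in env.landmarks:
            ranked = reverse_recall(mem, enc.encode_vec(lm.position), feats)
            assert ranked[0][0] == lm.name

    def test_area_query_finds_contained_landmarks(self, reverse_memory):
        mem, env, enc, feats = reverse_memory
        # area containing the orange triangle and blue square only
        region = enc.encode_region(
            lambda p: (p[:, 0] > -0.5) & (p[:, 0] < 0.9)
            & (p[:, 1] > -0.1) & (p[:, 1] < 0.5),
            101,
        )
        region = region / np.linalg.norm(region)
        ranked = reverse_recall(mem, region, feats)
        top_two = {ranked[0][0], ranked[1][0]}
        assert top_two == {"ORANGE*TRIANGLE", "BLUE*SQUARE"}
        assert ranked[1][1] > 2 * max(ranked[2][1], 0.01)

    def test_empty_area_low_similarity(self, reverse_memory):
        mem, env, enc, feats = reverse_memory
        region = enc.encode_region(
            lambda p: (p[:, 0] < -0.7) & (p[:, 1] < -0.7), 101
        )
        region = region / np.linalg.norm(region)
        ranked = reverse_recall(mem, region, feats)
        assert ranked[0][1] < 0.3


class TestVectorToLandmark:
    def test_clean_inputs_exact(self, full_encoder, full_readout):
        x = np.array([0.1, 0.4])
        xi = np.array([-0.3, -0.2])
        out = vector_to_landmark(
            full_encoder.encode_vec(x), full_encoder.encode_vec(xi)
        )
        dec = full_readout.map_decode(out)
        assert np.linalg.norm(dec - (xi - x)) < 0.02

    def test_agent_at_landmark_decodes_origin(
        self, full_encoder, full_readout
    ):
        x = np.array([0.25, 0.25])
        out = vector_to_landmark(
            full_encoder.encode_vec(x), full_encoder.encode_vec(x)
        )
        cell = full_readout.axes[0][1] - full_readout.axes[0][0]
        assert np.linalg.norm(full_readout.map_decode(out)) <= cell


class TestLoopClosure:
    def test_nothing_in_view(self, memory, full_encoder, full_readout):
        state = LoopClosureState()
        out = loop_closure(
            state, None, memory, None,
            full_encoder.encode_vec([0.0, 0.0]), full_readout,
        )
        assert not out.valid
        assert np.allclose(out.correction, 0.0)

    def test_untrained_memory_invalid(
        self, memory, full_encoder, full_readout, demo_env
    ):
        obs = observe(demo_env, demo_env.landmarks[0].position, 0.3)[0]
        ego = full_encoder.encode_vec(obs.displacement)
        out = loop_closure(
            LoopClosureState(), obs, memory, ego,
            full_encoder.encode_vec([0.0, 0.0]), full_readout,
        )
        assert not out.valid

    def test_correction_points_toward_truth(
        self, vocab, full_encoder, full_readout, demo_env
    ):
        # algebraic oracle: with an exact map entry, the corrected estimate
        # is closer to the true encoding than the uncorrected one
        mem = AssocMemory(full_encoder.d, full_encoder.d, n=1000, seed=5)
        lm = demo_env.landmarks[0]
        key = np.asarray(demo_env.feature_pointer(lm))
        mem.learning_gate = True
        for _ in range(200):
            mem.train_step(
                key, full_encoder.encode_vec(lm.position), 1e-3, 5
            )
        x_true = lm.position + np.array([-0.15, 0.1])
        obs = [o for o in observe(demo_env, x_true, 0.4) if o.index == 0][0]
        ego = full_encoder.encode_vec(obs.displacement)
        truth = full_encoder.encode_vec(x_true)
        pi_est = full_encoder.encode_vec(x_true + [0.1, -0.08])  # offset
        out = loop_closure(
            LoopClosureState(), obs, mem, ego, pi_est, full_readout
        )
        assert out.valid
        corrected = pi_est + out.correction
        assert float(corrected @ truth) > float(pi_est @ truth)

    def test_exact_map_corrections_never_hurt(
        self, full_encoder, full_readout
    ):
        # with exact entries, corrected decode error <= uncorrected, 5 seeds
        for seed in range(5):
            rng = np.random.default_rng(seed)
            vv = vs.Vocabulary(full_encoder.d, seed=seed)
            env = vs.make_environment(seed, n_landmarks=3, m=2, vocab=vv)
            mem = AssocMemory(full_encoder.d, full_encoder.d, n=1000,
                              seed=seed)
            mem.learning_gate = True
            for lm in env.landmarks:
                key = np.asarray(env.feature_pointer(lm))
                for _ in range(150):
                    mem.train_step(
                        key, full_encoder.encode_vec(lm.position), 1e-3, 5
                    )
            lm = env.landmarks[0]
            x_true = lm.position + rng.normal(0, 0.1, 2)
            obs_all = observe(env, x_true, 1.0)
            obs = [o for o in obs_all if o.index == 0][0]
            ego = full_encoder.encode_vec(obs.displacement)
            pi_est = full_encoder.encode_vec(x_true + rng.normal(0, 0.1, 2))
            out = loop_closure(
                LoopClosureState(), obs, mem, ego, pi_est, full_readout
            )
            if not out.valid:
                continue
            err_before = np.linalg.norm(
                full_readout.map_decode(pi_est) - x_true
            )
            corrected = pi_est + out.correction
            err_after = np.linalg.norm(
                full_readout.map_decode(corrected) - x_true
            )
            assert err_after <= err_before + 1e-9
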