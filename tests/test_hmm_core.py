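"""HMM initialization, Baum-Welch, Viterbi and alignment filtering."""

import itertools

import numpy as np
import pytest

from apiscan.hmm_core import (GaussianMixtureState, baum_welch, build_network,
                              dumps_models, flat_start_init,
                              forced_align_filter, forward_loglik,
                              loads_models, local_init, make_left_right,
                              network_log_emissions, split_mixtures,
                              total_loglik, viterbi)


def brute_force_loglik(net, X):
    """Sum over every monotone-legal path by explicit enumeration."""
    logB = network_log_emissions(net, X)
    S, T = net.n_states, X.shape[0]
    total = -np.inf
    for path in itertools.product(range(S), repeat=T):
        lp = net.log_entry[path[0]] + logB[0, path[0]]
        for t in range(1, T):
            lp += net.log_trans[path[t - 1], path[t]] + logB[t, path[t]]
        lp += net.log_exit[path[-1]]
        total = np.logaddexp(total, lp)
    return total


def brute_force_viterbi(net, X):
    logB = network_log_emissions(net, X)
    S, T = net.n_states, X.shape[0]
    best = -np.inf
    for path in itertools.product(range(S), repeat=T):
        lp = net.log_entry[path[0]] + logB[0, path[0]]
        for t in range(1, T):
            lp += net.log_trans[path[t - 1], path[t]] + logB[t, path[t]]
        lp += net.log_exit[path[-1]]
        best = max(best, lp)
    return best


def random_model(rng, label, n_states, dim=2, n_comp=1):
    m = make_left_right(label, n_states, dim)
    for st in m.states:
        st.weights = rng.dirichlet(np.ones(n_comp))
        st.means = rng.normal(size=(n_comp, dim))
        st.variances = rng.uniform(0.3, 1.5, size=(n_comp, dim))
    return m


class TestInitialization:
    def test_flat_start_identical_models_with_global_stats(self, rng):
        clips = [rng.normal(2.0, 1.5, size=(30, 4)) for _ in range(5)]
        models = flat_start_init(clips, {"normal": 3, "swarm": 3})
        frames = np.concatenate(clips)
        for m in models.values():
            for st in m.states:
                assert np.allclose(st.means[0], frames.mean(axis=0))
                assert np.allclose(st.variances[0], frames.var(axis=0))
        a, b = models["normal"], models["swarm"]
        assert np.allclose(a.states[0].means, b.states[0].means)
        assert np.array_equal(a.trans, b.trans)

    def test_flat_start_floors_zero_variance(self):
        with pytest.warns(UserWarning):
            models = flat_start_init([np.zeros((1, 3))], {"normal": 1})
        assert np.all(models["normal"].states[0].variances > 0)

    def test_local_init_per_class_stats(self):
        feats = {"normal": [np.zeros((10, 2))], "swarm": [np.ones((10, 2))]}
        with pytest.warns(UserWarning):  # zero within-class variance
            models = local_init(feats, {"normal": 2, "swarm": 2})
        assert np.allclose(models["normal"].states[0].means[0], 0.0)
        assert np.allclose(models["swarm"].states[0].means[0], 1.0)

    def test_local_init_identical_data_symmetric(self, rng):
        X = rng.normal(size=(40, 3))
        models = local_init({"normal": [X], "swarm": [X.copy()]},
                            {"normal": 2, "swarm": 2})
        assert np.allclose(models["normal"].states[1].means,
                           models["swarm"].states[1].means)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="no training clips"):
            local_init({"normal": [np.ones((5, 2))], "swarm": []},
                       {"normal": 1, "swarm": 1})


class TestOracleEquivalence:
    @pytest.mark.parametrize("n_states,T", [(1, 4), (2, 5), (3, 8)])
    def test_forward_matches_enumeration(self, rng, n_states, T):
        m = random_model(rng, "normal", n_states)
        net = build_network([(m, False)])
        X = rng.normal(size=(T, 2))
        assert forward_loglik(net, X) == pytest.approx(
            brute_force_loglik(net, X), abs=1e-8)

    def test_forward_matches_enumeration_composite(self, rng):
        sil = random_model(rng, "silence", 1)
        act = random_model(rng, "normal", 2)
        net = build_network([(sil, True), (act, False), (sil, True)])
        X = rng.normal(size=(6, 2))
        assert forward_loglik(net, X) == pytest.approx(
            brute_force_loglik(net, X), abs=1e-8)

    @pytest.mark.parametrize("n_states,T", [(2, 4), (3, 7)])
    def test_viterbi_matches_enumeration(self, rng, n_states, T):
        m = random_model(rng, "normal", n_states)
        net = build_network([(m, False)])
        X = rng.normal(size=(T, 2))
        res = viterbi(net, X)
        assert res.alignable
        assert res.log_likelihood == pytest.approx(
            brute_force_viterbi(net, X), abs=1e-8)
        # the reported path itself scores its reported likelihood
        logB = network_log_emissions(net, X)
        p = res.state_path
        lp = net.log_entry[p[0]] + logB[0, p[0]]
        for t in range(1, T):
            lp += net.log_trans[p[t - 1], p[t]] + logB[t, p[t]]
        lp += net.log_exit[p[-1]]
        assert lp == pytest.approx(res.log_likelihood, abs=1e-8)

    def test_viterbi_path_monotone_left_right(self, rng):
        m = random_model(rng, "normal", 3)
        net = build_network([(m, False)])
        res = viterbi(net, rng.normal(size=(10, 2)))
        assert np.all(np.diff(res.state_path) >= 0)

    def test_viterbi_at_most_forward(self, rng):
        for _ in range(10):
            m = random_model(rng, "normal", 3)
            net = build_network([(m, False)])
            X = rng.normal(size=(12, 2))
            assert viterbi(net, X).log_likelihood <= forward_loglik(net, X) + 1e-10

    def test_unalignable_when_too_short(self, rng):
        m = random_model(rng, "normal", 3)
        net = build_network([(m, False)])
        res = viterbi(net, rng.normal(size=(2, 2)))  # T < mandatory states
        assert not res.alignable
        assert res.log_likelihood == -np.inf


class TestBaumWelch:
    def test_single_state_converges_to_sample_stats(self, rng):
        X = rng.normal(1.5, 2.0, size=(400, 3))
        models = flat_start_init([X], {"normal": 1})
        # perturb so EM has work to do
        models["normal"].states[0].means += 1.0
        baum_welch(models, [(X, "normal")], n_iter=3, with_silence=False)
        st = models["normal"].states[0]
        assert np.allclose(st.means[0], X.mean(axis=0), atol=1e-6)
        assert np.allclose(st.variances[0], X.var(axis=0), atol=1e-5)

    def test_zero_iterations_no_change(self, rng):
        X = rng.normal(size=(50, 2))
        models = flat_start_init([X], {"normal": 2})
        before = dumps_models(models)
        hist = baum_welch(models, [(X, "normal")], n_iter=0,
                          with_silence=False)
        assert hist == []
        assert dumps_models(models) == before

    def test_loglik_monotone_over_iterations(self, rng):
        clips = [(rng.normal(size=(30, 2)) + (0 if i % 2 else 2),
                  "normal" if i % 2 else "swarm") for i in range(8)]
        models = flat_start_init([X for X, _ in clips],
                                 {"normal": 2, "swarm": 2})
        hist = baum_welch(models, clips, n_iter=5, with_silence=False)
        diffs = np.diff(hist)
        assert np.all(diffs >= -1e-6 * np.abs(np.array(hist[:-1])))
        # recorded history is the pre-update likelihood; after the last
        # update the total can only improve further
        assert total_loglik(models, clips, with_silence=False) >= hist[-1] - 1e-6

    def test_too_short_clips_skipped_with_warning(self, rng):
        models = flat_start_init([rng.normal(size=(30, 2))], {"normal": 5})
        data = [(rng.normal(size=(30, 2)), "normal"),
                (rng.normal(size=(3, 2)), "normal")]
        with pytest.warns(UserWarning, match="skipped"):
            baum_welch(models, data, n_iter=1, with_silence=False)

    def test_reestimated_parameters_valid(self, rng):
        clips = [(rng.normal(size=(40, 3)), "normal") for _ in range(4)]
        models = flat_start_init([X for X, _ in clips], {"normal": 3})
        models = split_mixtures(models)
        baum_welch(models, clips, n_iter=3, with_silence=False)
        m = models["normal"]
        m.validate()
        for st in m.states:
            assert np.all(np.isfinite(st.means))
            assert abs(st.weights.sum() - 1.0) < 1e-9
            assert np.all(st.variances >= m.var_floor[None, :] - 1e-15)


class TestMixtureSplitting:
    def test_doubling_ladder_reaches_32(self, rng):
        models = flat_start_init([rng.normal(size=(20, 2))], {"normal": 1})
        sizes = [models["normal"].states[0].n_components]
        for _ in range(5):
            models = split_mixtures(models)
            sizes.append(models["normal"].states[0].n_components)
        assert sizes == [1, 2, 4, 8, 16, 32]

    def test_weights_halved(self, rng):
        models = flat_start_init([rng.normal(size=(20, 2))], {"normal": 1})
        models = split_mixtures(models)
        assert np.allclose(models["normal"].states[0].weights, [0.5, 0.5])

    def test_state_mean_preserved_by_split(self, rng):
        models = flat_start_init([rng.normal(size=(50, 3))], {"normal": 1})
        st0 = models["normal"].states[0]
        before = (st0.weights[:, None] * st0.means).sum(axis=0)
        models = split_mixtures(models)
        st1 = models["normal"].states[0]
        after = (st1.weights[:, None] * st1.means).sum(axis=0)
        assert np.allclose(before, after, atol=1e-12)


class TestForcedAlignFilter:
    def test_white_noise_clip_flagged_in_tonal_set(self, rng):
        # tight cluster + one far-off clip
        clips = [(rng.normal(0, 0.3, size=(20, 2)), "normal")
                 for _ in range(30)]
        clips.append((rng.normal(30.0, 0.3, size=(20, 2)), "normal"))
        models = flat_start_init([X for X, _ in clips], {"normal": 1})
        baum_welch(models, clips, n_iter=2, with_silence=False)
        kept, frac = forced_align_filter(models, clips, with_silence=False)
        assert len(kept) == 30
        assert frac == pytest.approx(1 / 31)

    def test_homogeneous_set_kept(self, rng):
        clips = [(rng.normal(size=(20, 2)), "normal") for _ in range(20)]
        models = flat_start_init([X for X, _ in clips], {"normal": 1})
        baum_welch(models, clips, n_iter=2, with_silence=False)
        kept, frac = forced_align_filter(models, clips, with_silence=False)
        assert frac <= 0.02 or len(kept) == len(clips)


class TestSerialization:
    def test_roundtrip_exact(self, rng):
        models = {"normal": random_model(rng, "normal", 3, dim=4, n_comp=2),
                  "swarm": random_model(rng, "swarm", 2, dim=4, n_comp=4)}
        for m in models.values():
            # renormalize weights exactly as training would
            for st in m.states:
                st.weights = st.weights / st.weights.sum()
        text = dumps_models(models)
        back = loads_models(text)
        for lab, m in models.items():
            b = back[lab]
            assert b.n_states == m.n_states
            assert np.array_equal(b.trans, m.trans)
            for sa, sb in zip(m.states, b.states):
                assert np.array_equal(sa.means, sb.means)
                assert np.array_equal(sa.variances, sb.variances)
                assert np.array_equal(sa.weights, sb.weights)
        # byte-stable: re-serialization identical
        assert dumps_models(back) == text

    def test_version_checked(self):
        with pytest.raises(ValueError, match="version"):
            loads_models("apiscan-models v99\nnmodels 0\n")

    def test_garbage_rejected(self):
        with pytest.raises(ValueError, match="model file"):
            loads_models("hello world")


class TestCrossCheckEmissions:
    def test_state_density_matches_sklearn(self, rng):
        """Mixture log-density agrees with an independent implementation."""
        from sklearn.mixture import GaussianMixture
        X = rng.normal(size=(50, 3))
        gms = GaussianMixtureState(
            weights=np.array([0.3, 0.7]),
            means=rng.normal(size=(2, 3)),
            variances=rng.uniform(0.5, 1.5, size=(2, 3)))
        sk = GaussianMixture(n_components=2, covariance_type="diag")
        sk.weights_ = gms.weights
        sk.means_ = gms.means
        sk.covariances_ = gms.variances
        sk.precisions_cholesky_ = 1.0 / np.sqrt(gms.variances)
        assert np.allclose(gms.log_pdf(X), sk.score_samples(X), atol=1e-8)
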