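import numpy as np
import pytest

from envsca import (
    EnvScaModel,
    classify,
    dist_env,
    dist_envsca,
    dist_sca,
    group_features,
    select_frequencies,
    simulate_series,
    tune_kappa,
    varying_m_params,
)
from envsca.classify import DEFAULT_KAPPA_GRID, GroupModel
from envsca.spectral import EnvelopeScalings, features_for_series


def make_feature(lam, gam):
    lam = np.asarray(lam, dtype=float)
    gam = np.asarray(gam, dtype=float)
    K = lam.shape[0]
    return EnvelopeScalings(lam=lam, gam=gam, freqs=np.arange(1, K + 1) / (2 * K + 2))


def unit_cols(p, K, rng):
    g = rng.standard_normal((p, K))
    return g / np.linalg.norm(g, axis=0, keepdims=True)


@pytest.fixture
def random_features(rng):
    feats = [
        make_feature(np.abs(rng.standard_normal(6)) + 0.1, unit_cols(3, 6, rng))
        for _ in range(8)
    ]
    labels = ["g1"] * 4 + ["g2"] * 4
    return feats, labels


class TestGroupFeatures:
    def test_single_member_group_equals_member(self, rng):
        f = make_feature([1.0, 2.0], unit_cols(2, 2, rng))
        gm = group_features([f], ["a"])
        np.testing.assert_array_equal(gm.Lambda[0], f.lam)
        np.testing.assert_array_equal(gm.Gamma[0], f.gam)
        assert gm.n_per_group == (1,)

    def test_identical_members_mean_equals_either(self, rng):
        f = make_feature([1.0, 2.0], unit_cols(2, 2, rng))
        gm = group_features([f, f], ["a", "a"])
        np.testing.assert_array_equal(gm.Lambda[0], f.lam)

    def test_averaging_shrinks_scaling_norm(self):
        f1 = make_feature([1.0], [[1.0], [0.0]])
        f2 = make_feature([1.0], [[0.0], [1.0]])
        gm = group_features([f1, f2], ["a", "a"])
        np.testing.assert_allclose(gm.Gamma[0][:, 0], [0.5, 0.5])
        assert np.linalg.norm(gm.Gamma[0][:, 0]) < 1.0

    def test_mismatched_grids_rejected(self, rng):
        f1 = make_feature([1.0, 2.0], unit_cols(2, 2, rng))
        f2 = make_feature([1.0, 2.0, 3.0], unit_cols(2, 3, rng))
        with pytest.raises(ValueError, match="interpolate"):
            group_features([f1, f2], ["a", "b"])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no training features"):
            group_features([], [])


class TestDistances:
    @pytest.fixture
    def two_group_model(self):
        return GroupModel(
            group_labels=("a", "b"),
            Lambda=np.array([[0.0, 0.0], [1.0, 2.0]]),
            Gamma=np.zeros((2, 2, 2)),
            n_per_group=(1, 1),
            freqs=np.array([0.25, 0.5]),
        )

    def test_env_distance_examples(self, two_group_model):
        f = make_feature([1.0, 2.0], np.eye(2))
        assert dist_env(f, two_group_model, 1) == 0.0
        assert dist_env(f, two_group_model, 0) == 5.0

    def test_sca_distance_examples(self, two_group_model, rng):
        g = unit_cols(2, 2, rng)
        f = make_feature([1.0, 2.0], g)
        # zero group mean: distance is the number of unit columns
        assert np.isclose(dist_sca(f, two_group_model, 0), 2.0)
        swapped = GroupModel(
            group_labels=("a",),
            Lambda=np.zeros((1, 2)),
            Gamma=np.array([[[0.0, 1.0], [1.0, 0.0]]]),
            n_per_group=(1,),
            freqs=two_group_model.freqs,
        )
        f_eye = make_feature([1.0, 1.0], np.eye(2))
        assert np.isclose(dist_sca(f_eye, swapped, 0), 4.0)

    def test_envsca_hand_computed_example(self):
        model = GroupModel(
            group_labels=("a",),
            Lambda=np.zeros((1, 2)),
            Gamma=np.zeros((1, 2, 2)),
            n_per_group=(1,),
            freqs=np.array([0.25, 0.5]),
        )
        f = make_feature([1.0, 0.0], np.eye(2))
        # 0.5 * (1/1) + 0.5 * (2/2) = 1
        assert np.isclose(dist_envsca(f, model, 0, kappa=0.5), 1.0)

    def test_envsca_endpoints_reduce_to_normalized_components(
        self, two_group_model, rng
    ):
        f = make_feature([1.0, 2.0], unit_cols(2, 2, rng))
        env_norm = f.lam @ f.lam
        assert np.isclose(
            dist_envsca(f, two_group_model, 0, 1.0),
            dist_env(f, two_group_model, 0) / env_norm,
        )
        assert np.isclose(
            dist_envsca(f, two_group_model, 0, 0.0),
            dist_sca(f, two_group_model, 0) / 2.0,
        )

    def test_zero_distance_for_matching_feature_any_kappa(self, rng):
        g = unit_cols(2, 3, rng)
        f = make_feature([1.0, 2.0, 3.0], g)
        model = group_features([f], ["a"])
        for kappa in (0.0, 0.3, 1.0):
            assert dist_envsca(f, model, 0, kappa) == 0.0

    def test_degenerate_zero_norm_feature_rejected(self, two_group_model):
        f = make_feature([0.0, 0.0], np.zeros((2, 2)))
        with pytest.raises(ValueError, match="degenerate"):
            dist_envsca(f, two_group_model, 0, 0.5)

    def test_grid_mismatch_rejected(self, two_group_model, rng):
        f = make_feature([1.0, 2.0, 3.0], unit_cols(2, 3, rng))
        with pytest.raises(ValueError, match="K"):
            dist_env(f, two_group_model, 0)


class TestClassify:
    def test_minimum_distance_wins(self, random_features):
        feats, labels = random_features
        gm = group_features(feats, labels)
        res = classify(feats[:1], gm, method="env")
        d = [dist_env(feats[0], gm, j) for j in range(2)]
        assert res.predicted[0] == gm.group_labels[int(np.argmin(d))]

    def test_exact_tie_goes_to_lowest_group_index(self, rng, caplog):
        f = make_feature([1.0, 1.0], unit_cols(2, 2, rng))
        gm = group_features([f, f], ["a", "b"])  # both groups identical
        import logging

        with caplog.at_level(logging.WARNING, logger="envsca.classify"):
            res = classify([f], gm, method="env")
        assert res.predicted[0] == "a"
        assert any("tie" in r.message for r in caplog.records)

    def test_unknown_method_rejected(self, random_features):
        feats, labels = random_features
        gm = group_features(feats, labels)
        with pytest.raises(ValueError, match="unknown method"):
            classify(feats, gm, method="bogus")

    def test_kappa_endpoints_reproduce_env_and_sca_rankings(
        self, random_features
    ):
        feats, labels = random_features
        gm = group_features(feats, labels)
        env_pred = classify(feats, gm, method="env").predicted
        sca_pred = classify(feats, gm, method="sca").predicted
        assert classify(feats, gm, "envsca", kappa=1.0).predicted == env_pred
        assert classify(feats, gm, "envsca", kappa=0.0).predicted == sca_pred

    def test_group_label_permutation_equivariance(self, random_features):
        feats, labels = random_features
        swapped = ["x2" if l == "g1" else "x1" for l in labels]
        p1 = classify(feats, group_features(feats, labels), "env").predicted
        p2 = classify(feats, group_features(feats, swapped), "env").predicted
        mapping = {"g1": "x2", "g2": "x1"}
        assert tuple(mapping[p] for p in p1) == p2


class TestTuneKappa:
    def test_grid_of_one_returns_that_value(self, random_features):
        feats, labels = random_features
        kappa, rate = tune_kappa(feats, labels, grid=np.array([0.3]))
        assert kappa == 0.3
        assert 0.0 <= rate <= 1.0

    def test_identical_groups_near_chance(self, rng):
        f = [
            make_feature(np.abs(rng.standard_normal(5)) + 0.1, unit_cols(2, 5, rng))
            for _ in range(6)
        ]
        feats = f + f  # group 2 duplicates group 1 exactly
        labels = ["a"] * 6 + ["b"] * 6
        _, rate = tune_kappa(feats, labels)
        assert rate <= 0.75  # exchangeable groups carry no signal

    def test_singleton_group_rejected(self, rng):
        feats = [
            make_feature([1.0, 2.0], unit_cols(2, 2, rng)) for _ in range(3)
        ]
        with pytest.raises(ValueError, match="single member"):
            tune_kappa(feats, ["a", "a", "b"])

    def test_deterministic_bit_for_bit(self, random_features):
        feats, labels = random_features
        assert tune_kappa(feats, labels) == tune_kappa(feats, labels)

    def test_ties_break_to_largest_kappa(self, rng):
        # two well-separated groups in both features: every kappa achieves a
        # perfect LOO rate, so the tie must resolve to 1.0
        g1 = [make_feature([5.0, 5.0], np.eye(2)) for _ in range(3)]
        g2 = [make_feature([1.0, 1.0], np.eye(2)[::-1]) for _ in range(3)]
        for f in g1 + g2:
            f.lam[:] += rng.normal(scale=1e-3, size=2)
        kappa, rate = tune_kappa(g1 + g2, ["a"] * 3 + ["b"] * 3)
        assert rate == 1.0
        assert kappa == 1.0

    def test_default_grid_is_eleven_points(self):
        np.testing.assert_allclose(DEFAULT_KAPPA_GRID, np.arange(11) / 10)


class TestSelectFrequencies:
    def test_full_proportion_keeps_everything(self, random_features):
        feats, labels = random_features
        gm = group_features(feats, labels)
        se, ss = select_frequencies(gm, 1.0)
        np.testing.assert_array_equal(se, np.arange(gm.K))
        np.testing.assert_array_equal(ss, np.arange(gm.K))

    def test_single_discriminative_frequency_found(self):
        K = 5
        Lambda = np.ones((2, K))
        Lambda[1, 3] = 2.0  # groups differ only at index 3
        gm = GroupModel(
            group_labels=("a", "b"),
            Lambda=Lambda,
            Gamma=np.zeros((2, 2, K)),
            n_per_group=(1, 1),
            freqs=np.arange(1, K + 1) / 12,
        )
        se, _ = select_frequencies(gm, 1 / K)
        np.testing.assert_array_equal(se, [3])

    def test_three_group_scores_match_pairwise_enumeration(self, rng):
        feats = [
            make_feature(np.abs(rng.standard_normal(4)) + 0.1, unit_cols(2, 4, rng))
            for _ in range(6)
        ]
        labels = ["a", "a", "b", "b", "c", "c"]
        gm = group_features(feats, labels)
        # oracle: explicit loop over the three unordered pairs
        d_env = np.zeros(4)
        d_sca = np.zeros(4)
        for j, h in ((0, 1), (0, 2), (1, 2)):
            d_env += (gm.Lambda[j] - gm.Lambda[h]) ** 2
            d_sca += ((gm.Gamma[j] - gm.Gamma[h]) ** 2).sum(axis=0)
        se, ss = select_frequencies(gm, 2 / 4)
        np.testing.assert_array_equal(
            se, np.sort(np.argsort(-d_env, kind="stable")[:2])
        )
        np.testing.assert_array_equal(
            ss, np.sort(np.argsort(-d_sca, kind="stable")[:2])
        )

    def test_invalid_proportion_rejected(self, random_features):
        feats, labels = random_features
        gm = group_features(feats, labels)
        with pytest.raises(ValueError, match="proportion"):
            select_frequencies(gm, 0.0)


class TestModelResultsSurface:
    def test_fit_predict_score_roundtrip(self, rng):
        train, labels = [], []
        for group in (1, 2):
            params = varying_m_params(4, group)
            for k in range(4):
                train.append(simulate_series(params, 200, rng))
                labels.append(f"g{group}")
        model = EnvScaModel.from_series(train, labels)
        res = model.fit(method="envsca", kappa="auto")
        assert res.kappa in DEFAULT_KAPPA_GRID
        assert 0.0 <= res.loo_rate <= 1.0
        test = [simulate_series(varying_m_params(4, 1), 200, rng) for _ in range(5)]
        score = res.score(
            [features_for_series(s) for s in test], ["g1"] * 5
        )
        assert 0.0 <= score <= 1.0
        out = res.summary()
        assert "ENVSCA" in out and "kappa" in out

    def test_from_series_interpolates_unequal_lengths(self, rng):
        train, labels = [], []
        for group in (1, 2):
            params = varying_m_params(4, group)
            for T in (150, 200, 250):
                train.append(simulate_series(params, T, rng))
                labels.append(f"g{group}")
        res = EnvScaModel.from_series(train, labels).fit(method="env")
        assert res.group_model.K == (150 - 1) // 2

    def test_fixed_kappa_respected(self, random_features):
        feats, labels = random_features
        res = EnvScaModel(feats, labels).fit(method="envsca", kappa=0.7)
        assert res.kappa == 0.7
        assert res.loo_rate is None

    def test_select_prop_restricts_distances(self, random_features):
        feats, labels = random_features
        res = EnvScaModel(feats, labels).fit(method="env", select_prop=0.5)
        assert len(res.group_model.selected_env) == int(np.ceil(0.5 * 6))
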