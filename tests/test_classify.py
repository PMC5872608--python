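import numpy as np
import pytest

import semgkit as sk
from semgkit.classify import (
    TrialSet,
    assemble_trials,
    cross_session_evaluate,
    evaluate,
    repeated_split_accuracy,
    select_configuration,
    split_trials,
    train_lda,
)
from semgkit.config import RunConfig
from semgkit.records import FeatureTrial


def gaussian_trials(rng, mean, n, label, feature_names):
    return [
        FeatureTrial(
            values=rng.normal(loc=mean, scale=1.0),
            label=label,
            feature_names=feature_names,
        )
        for _ in range(n)
    ]


def two_cloud_set(rng, sep=10.0, n=50, p=4, seed=0):
    names = [f"CH{i + 1}:MAV" for i in range(p)]
    mu1 = np.zeros(p)
    mu2 = np.zeros(p)
    mu2[0] = sep
    trials = [
        gaussian_trials(rng, mu1, n, 1, names),
        gaussian_trials(rng, mu2, n, 2, names),
    ]
    return assemble_trials(trials, seed=seed)


class TestAssembleTrials:
    def test_counts_preserved(self, rng):
        names = ["CH1:MAV"]
        ts = assemble_trials(
            [
                gaussian_trials(rng, [0.0], 26, 1, names),
                gaussian_trials(rng, [1.0], 30, 2, names),
            ],
            seed=1,
        )
        assert ts.n_trials == 56
        assert (ts.y == 1).sum() == 26 and (ts.y == 2).sum() == 30

    def test_same_seed_same_permutation(self, rng):
        names = ["CH1:MAV"]
        lists = [
            gaussian_trials(rng, [0.0], 10, 1, names),
            gaussian_trials(rng, [1.0], 10, 2, names),
        ]
        a = assemble_trials(lists, seed=5)
        b = assemble_trials(lists, seed=5)
        np.testing.assert_array_equal(a.X, b.X)
        np.testing.assert_array_equal(a.y, b.y)

    def test_label_collision_rejected(self, rng):
        names = ["CH1:MAV"]
        with pytest.raises(sk.ParameterError, match="label"):
            assemble_trials(
                [
                    gaussian_trials(rng, [0.0], 5, 1, names),
                    gaussian_trials(rng, [1.0], 5, 1, names),
                ],
                seed=0,
            )

    def test_empty_movement_rejected(self, rng):
        with pytest.raises(sk.ParameterError):
            assemble_trials([gaussian_trials(rng, [0.0], 5, 1, ["CH1:MAV"]), []], 0)


class TestSplitTrials:
    def test_stratified_counts(self, rng):
        ts = two_cloud_set(rng, n=50)
        train, test = split_trials(ts, 0.7, seed=0)
        assert train.n_trials == 70 and test.n_trials == 30
        for label in (1, 2):
            assert (train.y == label).sum() == 35
            assert (test.y == label).sum() == 15

    def test_union_is_original(self, rng):
        ts = two_cloud_set(rng, n=20)
        train, test = split_trials(ts, 0.7, seed=3)
        combined = np.vstack([train.X, test.X])
        assert combined.shape == ts.X.shape
        # every original row appears exactly once
        original = {tuple(row) for row in ts.X}
        assert {tuple(row) for row in combined} == original

    def test_same_seed_same_split(self, rng):
        ts = two_cloud_set(rng, n=20)
        a = split_trials(ts, 0.7, seed=9)
        b = split_trials(ts, 0.7, seed=9)
        np.testing.assert_array_equal(a[0].X, b[0].X)
        np.testing.assert_array_equal(a[1].X, b[1].X)

    def test_tiny_class_rejected(self, rng):
        names = ["CH1:MAV"]
        ts = assemble_trials(
            [
                gaussian_trials(rng, [0.0], 1, 1, names),
                gaussian_trials(rng, [1.0], 10, 2, names),
            ],
            seed=0,
        )
        with pytest.raises(sk.ParameterError):
            split_trials(ts, 0.7, seed=0)


class TestTrainLda:
    def test_separable_clouds_perfect_accuracy(self, rng):
        ts = two_cloud_set(rng, sep=10.0, n=100)
        train, test = split_trials(ts, 0.7, seed=0)
        assert evaluate(train_lda(train), test) == 1.0

    def test_identical_distributions_chance_level(self, rng):
        names = ["CH1:MAV", "CH1:WL"]
        train = assemble_trials(
            [
                gaussian_trials(rng, [0.0, 0.0], 100, 1, names),
                gaussian_trials(rng, [0.0, 0.0], 100, 2, names),
            ],
            seed=0,
        )
        test = assemble_trials(
            [
                gaussian_trials(rng, [0.0, 0.0], 100, 1, names),
                gaussian_trials(rng, [0.0, 0.0], 100, 2, names),
            ],
            seed=1,
        )
        acc = evaluate(train_lda(train), test)
        assert acc == pytest.approx(0.5, abs=0.15)

    def test_weights_match_closed_form(self):
        # classes with diagonal within-class scatter, worked by hand
        X1 = np.array([[1, 0], [-1, 0], [0, 2], [0, -2]], dtype=float)
        X2 = X1 + np.array([3.0, 1.0])
        ts = TrialSet(
            np.vstack([X1, X2]), np.array([1] * 4 + [2] * 4), ["CH1:MAV", "CH2:MAV"]
        )
        model = train_lda(ts)
        # pooled covariance: scatter diag(2+2, 8+8)/(8-2) = diag(2/3, 8/3)
        gamma = 1e-3
        S = np.diag([2 / 3, 8 / 3])
        S = (1 - gamma) * S + gamma * (np.trace(S) / 2) * np.eye(2)
        expected_w = np.linalg.solve(S, np.array([3.0, 1.0]))
        np.testing.assert_allclose(model.w, expected_w, rtol=1e-12)
        np.testing.assert_allclose(model.pooled_covariance, S, rtol=1e-12)

    def test_decision_matches_discriminant_comparison(self, rng):
        ts = two_cloud_set(rng, sep=2.0, n=60)
        model = train_lda(ts)
        scores = model.discriminant_scores(ts.X)
        via_scores = np.where(scores[:, 1] > scores[:, 0], 2, 1)
        np.testing.assert_array_equal(model.predict(ts.X), via_scores)

    def test_matches_sklearn_direction(self, rng):
        pytest.importorskip("sklearn")
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        ts = two_cloud_set(rng, sep=3.0, n=80, p=6)
        model = train_lda(ts, shrinkage=1e-9)
        ref = LinearDiscriminantAnalysis(solver="lsqr").fit(ts.X, ts.y)
        cos = np.dot(model.w, ref.coef_[0]) / (
            np.linalg.norm(model.w) * np.linalg.norm(ref.coef_[0])
        )
        assert cos == pytest.approx(1.0, abs=1e-6)
        assert np.mean(model.predict(ts.X) == ref.predict(ts.X)) == 1.0

    def test_single_class_rejected(self, rng):
        names = ["CH1:MAV"]
        trials = gaussian_trials(rng, [0.0], 10, 1, names)
        X = np.vstack([t.values for t in trials])
        ts = TrialSet(X, np.ones(10, dtype=int), names)
        with pytest.raises(sk.ParameterError):
            train_lda(ts)

    def test_empty_test_set_rejected(self, rng):
        ts = two_cloud_set(rng)
        model = train_lda(ts)
        empty = TrialSet(np.zeros((0, ts.X.shape[1])), np.zeros(0), ts.feature_names)
        with pytest.raises(sk.ParameterError):
            evaluate(model, empty)

    def test_inverted_model_complements_accuracy(self, rng):
        ts = two_cloud_set(rng, sep=4.0, n=40)
        train, test = split_trials(ts, 0.7, seed=0)
        model = train_lda(train)
        acc = evaluate(model, test)
        model.w = -model.w
        model.b = -model.b
        assert evaluate(model, test) == pytest.approx(1.0 - acc)

    def test_accuracy_invariant_under_affine_transform(self, rng):
        ts = two_cloud_set(rng, sep=1.5, n=60, p=3)
        train, test = split_trials(ts, 0.7, seed=2)
        base = evaluate(train_lda(train), test)
        scale, shift = 37.5, np.array([-4.0, 2.0, 100.0])
        t2 = TrialSet(scale * train.X + shift, train.y, train.feature_names)
        s2 = TrialSet(scale * test.X + shift, test.y, test.feature_names)
        assert evaluate(train_lda(t2), s2) == pytest.approx(base)


class TestSelection:
    def _session(self, rng, sep):
        names = [f"CH{i + 1}:{f}" for i in range(4) for f in ("MAV", "WL")]
        mu1 = np.zeros(8)
        mu2 = np.full(8, sep)
        return [
            gaussian_trials(rng, mu1, 40, 1, names),
            gaussian_trials(rng, mu2, 40, 2, names),
        ]

    def test_separable_profiles_selected(self, rng):
        cfg = RunConfig(
            window_lengths_s=[0.5], feature_set=["MAV", "WL"], n_repetitions=10
        )
        results = select_configuration({0.5: self._session(rng, sep=5.0)}, cfg)
        assert results
        assert results[0].mean_accuracy >= 0.95
        assert all(len(r.per_repetition) == 10 for r in results)

    def test_impossible_threshold_empty(self, rng):
        cfg = RunConfig(
            window_lengths_s=[0.5], feature_set=["MAV", "WL"], accuracy_threshold=1.01
        )
        assert select_configuration({0.5: self._session(rng, sep=5.0)}, cfg) == []

    def test_results_sorted_by_accuracy_then_parsimony(self, rng):
        cfg = RunConfig(window_lengths_s=[0.5], feature_set=["MAV", "WL"])
        results = select_configuration({0.5: self._session(rng, sep=3.0)}, cfg)
        keys = [
            (-r.mean_accuracy, len(r.channel_subset), len(r.feature_subset))
            for r in results
        ]
        assert keys == sorted(keys)

    def test_cross_session_resubstitution_identity(self, rng):
        ts = two_cloud_set(rng, sep=1.0, n=40)
        chosen = sk.SelectionResult(
            window_length_s=0.5,
            channel_subset=("CH1",),
            feature_subset=("MAV",),
            mean_accuracy=1.0,
            per_repetition=[1.0],
        )
        acc = cross_session_evaluate(ts, ts, chosen)
        model = train_lda(ts.select_columns(["CH1:MAV"]))
        assert acc == evaluate(model, ts.select_columns(["CH1:MAV"]))

    def test_absent_channel_rejected(self, rng):
        ts = two_cloud_set(rng, n=20)
        chosen = sk.SelectionResult(0.5, ("CH9",), ("MAV",), 1.0, [1.0])
        with pytest.raises(sk.ParameterError):
            cross_session_evaluate(ts, ts, chosen)

    def test_repetition_seeds_are_distinct_and_derived(self, rng):
        ts = two_cloud_set(rng, sep=0.5, n=40)
        cfg = RunConfig(window_lengths_s=[0.5], n_repetitions=5, seed=11)
        a = repeated_split_accuracy(ts, cfg)
        b = repeated_split_accuracy(ts, cfg)
        assert a == b  # deterministic in the master seed
        assert len(a) == 5


def test_accuracy_monotone_in_gain_separation():
    """Wider inter-class gain gaps must not make classification worse."""
    from semgkit.pipeline import record_to_trials

    cfg = RunConfig(
        window_lengths_s=[0.5], feature_set=["MAV", "WL", "SD"],
        channel_subset=[0, 1, 2, 6],
    )
    base = np.full(8, 0.4)
    means = []
    for sep in (0.02, 0.15, 0.5):
        accs = []
        for seed in range(10):
            gains2 = base.copy()
            gains2[[0, 1, 2, 6]] += sep
            p1 = sk.MovementProfile("m1", 1, tuple(base))
            p2 = sk.MovementProfile("m2", 2, tuple(gains2))
            trials = []
            for label, prof in ((1, p1), (2, p2)):
                rec, _ = sk.generate_session(
                    prof, n_reps=1, seed=1000 + 7 * seed + label
                )
                trials.append(record_to_trials(rec, cfg, label, 0.5))
            ts = sk.assemble_trials(trials, seed=seed)
            train, test = sk.split_trials(ts, 0.7, seed=seed)
            accs.append(sk.evaluate(sk.train_lda(train), test))
        means.append(float(np.mean(accs)))
    assert means[1] >= means[0] - 0.02
    assert means[2] >= means[1] - 0.02
    assert means[2] >= means[0]
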