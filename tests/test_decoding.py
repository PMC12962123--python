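"""Shrinkage-LDA engine, cross-validation schemes, fold hygiene."""

import numpy as np
import pytest

import facedecode as fd
from facedecode import decoding
from facedecode.behavior import ClassSplit
from facedecode.decoding import (
    SchedulingError,
    class_decoding,
    cv_accuracy,
    group_average,
    lda_fit,
    lda_predict,
    oas_shrinkage,
    pairwise_image_decoding,
)


class TestLDA:
    def test_shrinkage_matches_sklearn_oas(self):
        from sklearn.covariance import OAS

        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 6))
        S = (X - X.mean(0)).T @ (X - X.mean(0)) / 40
        ours = oas_shrinkage(S[None], n=40)[0]
        ref = OAS(assume_centered=True).fit(X - X.mean(0)).covariance_
        assert np.allclose(ours, ref, rtol=1e-8)

    def test_separated_clouds_perfect_training_accuracy(self):
        rng = np.random.default_rng(1)
        X0 = rng.standard_normal((20, 4)) - 10
        X1 = rng.standard_normal((20, 4)) + 10
        X = np.vstack([X0, X1])
        y = np.repeat([0, 1], 20)
        w, b = lda_fit(X, y)
        assert (lda_predict(w, b, X) == y).all()

    def test_known_gaussian_matches_closed_form_direction(self):
        # identity covariance: the discriminant direction is mu1 - mu0
        rng = np.random.default_rng(2)
        mu = np.array([1.0, -2.0, 0.5])
        X = np.vstack([rng.standard_normal((2000, 3)), rng.standard_normal((2000, 3)) + mu])
        y = np.repeat([0, 1], 2000)
        w, _ = lda_fit(X, y)
        cos = w @ mu / (np.linalg.norm(w) * np.linalg.norm(mu))
        assert cos > 0.99

    def test_predictions_match_sklearn_lda(self):
        from sklearn.covariance import OAS
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(3)
        X = np.vstack([rng.standard_normal((30, 8)), rng.standard_normal((30, 8)) + 0.8])
        y = np.repeat([0, 1], 30)
        Xtest = rng.standard_normal((50, 8)) + 0.4
        w, b = lda_fit(X, y)
        ref = LinearDiscriminantAnalysis(solver="lsqr", covariance_estimator=OAS()).fit(X, y)
        agree = (lda_predict(w, b, Xtest) == ref.predict(Xtest)).mean()
        assert agree > 0.95

    def test_shuffled_labels_chance_accuracy(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((400, 6))
        y = rng.permutation(np.repeat([0, 1], 200))
        groups = np.arange(400) % 4
        acc = cv_accuracy(X[:, :, None], y, groups)
        assert abs(acc[0] - 0.5) < 0.08  # binomial noise at n=400

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            lda_fit(np.zeros((10, 3)), np.ones(10))


class TestPairwise:
    def test_pair_enumeration_count(self, tiny_pairwise, tiny_cfg):
        n = tiny_cfg.n_stimuli
        assert tiny_pairwise.pair_accuracy.shape[0] == n * (n - 1) // 2

    def test_symmetric_in_pair_order(self, tiny_world):
        epochs = tiny_world["epochs"]
        ev = epochs.events
        idx = np.flatnonzero(ev["stimulus_id"].isin([0, 1]))
        X = epochs.data[idx].astype(float)
        acc_01 = cv_accuracy(X, ev["stimulus_id"].to_numpy()[idx] == 1, ev["block"].to_numpy()[idx])
        acc_10 = cv_accuracy(X, ev["stimulus_id"].to_numpy()[idx] == 0, ev["block"].to_numpy()[idx])
        assert np.allclose(acc_01, acc_10)

    def test_signal_raises_poststimulus_accuracy(self, tiny_world, tiny_pairwise):
        times = tiny_world["epochs"].times
        pre = tiny_pairwise.accuracy[times < 0].mean()
        post = tiny_pairwise.accuracy[(times > 60) & (times < 140)].mean()
        assert post > pre + 0.15
        assert abs(pre - 0.5) < 0.05

    def test_missing_stimulus_in_block_rejected(self, tiny_world):
        epochs = tiny_world["epochs"]
        broken = fd.EpochSet(
            data=epochs.data[1:],
            times=epochs.times,
            sample_rate=epochs.sample_rate,
            channels=epochs.channels,
            events=epochs.events.iloc[1:].reset_index(drop=True),
        )
        with pytest.raises(SchedulingError):
            pairwise_image_decoding(broken)


@pytest.fixture(scope="module")
def split(tiny_world):
    cat = tiny_world["catalog"]
    order = np.argsort(cat["latent_valence"].to_numpy())
    ids = cat["stimulus_id"].to_numpy()
    return ClassSplit(low_ids=ids[order[:3]], high_ids=ids[order[-3:]])


class TestClassDecoding:

    def test_fold_count_is_k_times_blocks(self, tiny_world, split):
        tc = class_decoding(tiny_world["epochs"], split, pairing_seed=0)
        assert tc.n_folds == split.k * tiny_world["cfg"].n_blocks

    def test_folds_exclude_test_exemplars_and_block(self, tiny_world, split, monkeypatch):
        epochs = tiny_world["epochs"]
        stim = epochs.events["stimulus_id"].to_numpy()
        block = epochs.events["block"].to_numpy()
        calls = []
        orig = decoding._fold_accuracy

        def spy(X, y, train_idx, test_idx):
            calls.append((train_idx.copy(), test_idx.copy()))
            return orig(X, y, train_idx, test_idx)

        monkeypatch.setattr(decoding, "_fold_accuracy", spy)
        class_decoding(epochs, split, pairing_seed=0)
        assert calls
        k = split.k
        for train_idx, test_idx in calls:
            assert not set(train_idx) & set(test_idx)
            # the tested exemplars never occur in training, in any block
            assert not set(stim[test_idx]) & set(stim[train_idx])
            # the tested block never occurs in training
            assert not set(block[test_idx]) & set(block[train_idx])
            # training uses k-1 exemplars per class across the other blocks
            n_blocks = len(np.unique(block))
            assert len(train_idx) == 2 * (k - 1) * (n_blocks - 1)
            assert len(test_idx) == 2

    def test_class_signal_recovered_after_onset(self, tiny_world, split):
        tc = class_decoding(tiny_world["epochs"], split, pairing_seed=0)
        times = tiny_world["epochs"].times
        onset = tiny_world["truth"].onset_ms["valence"]
        pre = tc.accuracy[times < 0].mean()
        post = tc.accuracy[(times > onset + 20) & (times < onset + 60)].mean()
        assert post > pre + 0.1

    def test_unknown_split_ids_rejected(self, tiny_world):
        split = ClassSplit(low_ids=np.array([100]), high_ids=np.array([101]))
        with pytest.raises(SchedulingError):
            class_decoding(tiny_world["epochs"], split)


class TestGroupAverage:
    def test_identity_and_mean(self, tiny_pairwise):
        g1 = group_average([tiny_pairwise])
        assert np.allclose(g1.accuracy, tiny_pairwise.accuracy)
        a = decoding.DecodingTimecourse(tiny_pairwise.times, np.full_like(tiny_pairwise.accuracy, 0.4), "pairwise_image")
        b = decoding.DecodingTimecourse(tiny_pairwise.times, np.full_like(tiny_pairwise.accuracy, 0.6), "pairwise_image")
        g = group_average([a, b])
        assert np.allclose(g.accuracy, 0.5)
        assert g.subject_stack.shape == (2, len(tiny_pairwise.times))

    def test_grid_mismatch_rejected(self, tiny_pairwise):
        other = decoding.DecodingTimecourse(tiny_pairwise.times + 1.0, tiny_pairwise.accuracy, "pairwise_image")
        with pytest.raises(ValueError):
            group_average([tiny_pairwise, other])

    def test_sem_shrinks_with_subjects(self, tiny_null_epochs):
        tc = pairwise_image_decoding(tiny_null_epochs, store_pairs=True)
        # split pairs into pseudo-subjects: SEM of means over m samples ~ 1/sqrt(m)
        pair_acc = tc.pair_accuracy
        rng = np.random.default_rng(0)
        sems = []
        for m in (2, 8):
            means = [pair_acc[rng.choice(len(pair_acc), m)].mean() for _ in range(200)]
            sems.append(np.std(means))
        assert sems[1] < sems[0]
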