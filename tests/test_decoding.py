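import numpy as np
import pytest

import tapkin as tk
from tapkin.decoding import (
    DecoderParams,
    FeatureMatrix,
    N_PAIRS,
    build_feature_matrix,
    make_windows,
    pairwise_wtc_features,
    reduce_dimensions,
    split_datasets,
    train_eval,
)
from tapkin.keypoints import CONDITIONS, TAPPING_KEYPOINTS
from tapkin.wavelet import WaveletParams


@pytest.fixture(scope="module")
def small_wp():
    return WaveletParams()


def _roi_14(seed=0, n=344):
    rng = np.random.default_rng(seed)
    t = np.arange(n) / 60.0
    base = np.sin(2 * np.pi * 5 * t)
    return np.column_stack(
        [10 * base + rng.normal(0, 1, n) for _ in range(len(TAPPING_KEYPOINTS))]
    )


class TestPairwiseFeatures:
    def test_combinatorics(self, small_wp):
        assert N_PAIRS == 91
        F = pairwise_wtc_features(_roi_14(), small_wp)
        assert F.shape == (344, 40 * 91)
        assert np.isfinite(F).all()
        assert F.min() >= 0.0 and F.max() <= 1.0

    def test_duplicate_keypoint_pair_is_self_coherent(self, small_wp):
        roi = _roi_14(seed=1)
        roi[:, 1] = roi[:, 0]  # duplicate one keypoint as another
        F = pairwise_wtc_features(roi, small_wp)
        # pair (0, 1) is the first lexicographic pair -> channel 0 of each
        # frequency block; check the tapping-band frequencies
        fi = np.argmin(np.abs(small_wp.freqs - 5.0))
        assert F[:, fi * N_PAIRS + 0].min() >= 0.999

    def test_wrong_keypoint_count_rejected(self, small_wp):
        with pytest.raises(ValueError, match="14"):
            pairwise_wtc_features(np.zeros((344, 13)), small_wp)


class TestBuildAndReduce:
    def test_rows_grouped_by_condition_in_order(self):
        blocks = [
            (np.full((5, 3), i, dtype=np.float32), c, f"t{i}")
            for i, c in enumerate(["index_focused", "reference", "middle_focused", "sequence_focused"])
        ]
        fm = build_feature_matrix(blocks)
        assert list(fm.labels[:5]) == ["reference"] * 5
        assert fm.X.shape == (20, 3)

    def test_missing_condition_rejected(self):
        blocks = [(np.zeros((5, 3), np.float32), "reference", "t0")]
        with pytest.raises(ValueError, match="absent"):
            build_feature_matrix(blocks)

    def test_low_rank_data_fully_explained(self):
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(5, 50))
        X = (rng.normal(size=(300, 5)) @ basis).astype(np.float32)
        fm = FeatureMatrix(
            X=X,
            labels=np.array(["reference"] * 300, object),
            trial_ids=np.array(["t"] * 300, object),
        )
        out = reduce_dimensions(fm, DecoderParams(n_components=30))
        assert out.explained_variance == pytest.approx(1.0, abs=1e-5)
        assert out.X.shape == (300, 30)
        # components beyond the true rank carry ~no variance
        assert out.X[:, 6:].var(axis=0).max() < 1e-6 * out.X[:, 0].var()

    def test_reconstruction_error_decreases_with_components(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 40)).astype(np.float32)
        X[:, :10] *= 5
        errs = []
        for k in (2, 8, 20):
            from sklearn.decomposition import PCA

            pca = PCA(n_components=k, svd_solver="full").fit(X)
            rec = pca.inverse_transform(pca.transform(X))
            errs.append(np.mean((X - rec) ** 2))
        assert errs[0] > errs[1] > errs[2]

    def test_constant_features_rejected(self):
        fm = FeatureMatrix(
            X=np.zeros((200, 10), np.float32),
            labels=np.array(["reference"] * 200, object),
            trial_ids=np.array(["t"] * 200, object),
        )
        with pytest.raises(ValueError, match="zero variance"):
            reduce_dimensions(fm, DecoderParams(n_components=5))


def _labeled_fm(points_per_trial, trials_per_cond, n_feat=6, seed=0):
    rng = np.random.default_rng(seed)
    X, labels, tids = [], [], []
    for c in CONDITIONS:
        for t in range(trials_per_cond):
            X.append(rng.normal(size=(points_per_trial, n_feat)))
            labels += [c] * points_per_trial
            tids += [f"{c}_t{t}"] * points_per_trial
    return FeatureMatrix(
        X=np.vstack(X).astype(np.float32),
        labels=np.array(labels, object),
        trial_ids=np.array(tids, object),
    )


class TestSplitDatasets:
    def test_trial_disjoint_blocks(self):
        fm = _labeled_fm(100, 12)
        p = DecoderParams(n_datasets=6, window_len=60)
        ds = split_datasets(fm, p)
        assert len(ds) == 6
        for cond in CONDITIONS:
            seen = set()
            for d in ds:
                tids = set(fm.trial_ids[d[cond]])
                assert not (tids & seen)  # no trial appears in two datasets
                seen |= tids
            assert len(seen) == 12
        sizes = [len(d["reference"]) for d in ds]
        assert sum(sizes) == 1200
        assert max(sizes) - min(sizes) <= 100  # balanced to trial graining

    def test_rows_disjoint_and_complete(self):
        fm = _labeled_fm(80, 6)
        ds = split_datasets(fm, DecoderParams(window_len=60))
        all_rows = np.concatenate([d[c] for d in ds for c in CONDITIONS])
        assert len(all_rows) == len(set(all_rows.tolist())) == len(fm.labels)

    def test_insufficient_points_named(self):
        fm = _labeled_fm(10, 6)
        with pytest.raises(ValueError, match="reference"):
            split_datasets(fm, DecoderParams(window_len=60))

    def test_fewer_trials_than_datasets(self):
        fm = _labeled_fm(400, 3)
        with pytest.raises(ValueError, match="trials"):
            split_datasets(fm, DecoderParams(n_datasets=6))


class TestMakeWindows:
    @pytest.mark.parametrize(
        "n,expected", [(344, 72), (60, 1), (59, 0), (64, 2), (63, 1)]
    )
    def test_window_arithmetic(self, n, expected):
        fm = FeatureMatrix(
            X=np.random.default_rng(0).normal(size=(n, 4)).astype(np.float32),
            labels=np.array(["reference"] * n, object),
            trial_ids=np.array(["t"] * n, object),
        )
        p = DecoderParams(window_len=60, window_step=4)
        if expected == 0:
            with pytest.warns(UserWarning, match="shorter"):
                Xw, yw = make_windows(fm, {"reference": np.arange(n)}, p)
        else:
            Xw, yw = make_windows(fm, {"reference": np.arange(n)}, p)
        assert len(Xw) == expected
        if expected:
            assert Xw.shape[1] == 60 * 4
            assert set(yw) == {"reference"}

    def test_window_content_matches_rows(self):
        fm = FeatureMatrix(
            X=np.arange(70 * 2, dtype=np.float32).reshape(70, 2),
            labels=np.array(["reference"] * 70, object),
            trial_ids=np.array(["t"] * 70, object),
        )
        p = DecoderParams(window_len=60, window_step=4)
        Xw, _ = make_windows(fm, {"reference": np.arange(70)}, p)
        assert np.array_equal(Xw[0], fm.X[:60].ravel())
        assert np.array_equal(Xw[1], fm.X[4:64].ravel())


class TestTrainEval:
    def _sample_sets(self, seed=0, n_per=40, n_feat=30, signal=0.0):
        rng = np.random.default_rng(seed)
        sets = []
        for _ in range(6):
            X, y = [], []
            for i, c in enumerate(CONDITIONS):
                xc = rng.normal(size=(n_per, n_feat))
                xc[:, i] += signal
                X.append(xc)
                y += [c] * n_per
            sets.append((np.vstack(X).astype(np.float32), np.array(y, object)))
        return sets

    def test_confusion_rows_sum_to_one(self):
        res = train_eval(self._sample_sets(signal=1.0), DecoderParams())
        assert np.allclose(res.confusion.sum(axis=1), 1.0, atol=1e-9)
        assert res.mean_accuracy == pytest.approx(np.diag(res.confusion).mean())
        assert res.chance_level == 0.25

    def test_separable_signal_decoded(self):
        res = train_eval(self._sample_sets(signal=3.0), DecoderParams())
        assert res.mean_accuracy > 0.9

    def test_pure_noise_near_chance(self):
        accs = [
            train_eval(self._sample_sets(seed=s), DecoderParams()).mean_accuracy
            for s in range(4)
        ]
        assert abs(np.mean(accs) - 0.25) < 0.08

    def test_label_shuffle_destroys_signal(self):
        """Shuffling sample labels within datasets drives accuracy to
        chance — no leakage pathway survives the label permutation."""
        rng = np.random.default_rng(7)
        sets = self._sample_sets(signal=3.0)
        shuffled = [(X, rng.permutation(y)) for X, y in sets]
        res = train_eval(shuffled, DecoderParams())
        assert abs(res.mean_accuracy - 0.25) < 0.1

    def test_deterministic(self):
        a = train_eval(self._sample_sets(signal=0.5), DecoderParams(seed=3))
        b = train_eval(self._sample_sets(signal=0.5), DecoderParams(seed=3))
        assert np.array_equal(a.confusion, b.confusion)

    def test_missing_condition_rejected(self):
        sets = self._sample_sets()
        X, y = sets[2]
        sets[2] = (X[y != "reference"], y[y != "reference"])
        with pytest.raises(ValueError, match="reference"):
            train_eval(sets, DecoderParams())

    def test_fewer_than_two_datasets_rejected(self):
        with pytest.raises(ValueError):
            train_eval(self._sample_sets()[:1], DecoderParams())
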