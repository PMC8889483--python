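"""Encoding, windowing, child-grouped splits, metrics, and training."""

import numpy as np
import pytest

from gazescan import (GazeTrack, SequenceClassifier, WindowConfig,
                      encode_track, evaluate, label_to_code, sliding_windows,
                      split_by_child)
from gazescan.classifier import decode_sequence


def track(codes, video_id="v", child_id="c", label=1):
    return GazeTrack(video_id, child_id, label, np.asarray(codes, dtype=int))


class TestEncoding:
    def test_alphabetical_codes(self):
        t = track([label_to_code(x) for x in ("AA", "AB", "DD")])
        assert encode_track(t).v.tolist() == [0, 1, 15]

    def test_bb_is_sixth_label(self):
        t = track([label_to_code("BB")])
        assert encode_track(t).v.tolist() == [5]

    def test_roundtrip(self, rng):
        codes = rng.integers(0, 16, 30)
        seq = encode_track(track(codes))
        assert [label_to_code(lab) for lab in decode_sequence(seq.v)] == \
            codes.tolist()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            encode_track(GazeTrack("v", "c", 1, np.array([], dtype=int)))


class TestWindows:
    @pytest.mark.parametrize("length, w, s, expected", [
        (9, 4, 2, 3),     # worked example: 3 windows at starts 0, 2, 4
        (5, 5, 1, 1),     # exact fit
        (100, 50, 10, 6),  # starts 0, 10, ..., 50
        (49, 50, 10, 0),   # too short
    ])
    def test_window_counts(self, length, w, s, expected, rng):
        seq = encode_track(track(rng.integers(0, 16, length)))
        assert len(sliding_windows(seq, WindowConfig(w, s))) == expected

    def test_count_formula_matches_enumeration(self):
        # brute-force enumeration of valid starts over a parameter grid
        for length in range(1, 51, 7):
            for w in range(1, 11):
                for s in range(1, 11):
                    brute = len([b for b in range(0, length, s)
                                 if b + w <= length and b % s == 0])
                    assert WindowConfig(w, s).n_windows(length) == brute

    def test_one_hot_structure_and_label_inheritance(self, rng):
        codes = rng.integers(0, 16, 23)
        seq = encode_track(track(codes, label=1))
        for k, win in enumerate(sliding_windows(seq, WindowConfig(4, 3))):
            assert win.feature.shape == (4, 16)
            assert set(np.unique(win.feature)) <= {0, 1}
            assert win.feature.sum(axis=1).tolist() == [1, 1, 1, 1]
            assert win.label == 1
            np.testing.assert_array_equal(win.feature.argmax(axis=1),
                                          codes[3 * k:3 * k + 4])

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            WindowConfig(0, 1)


class TestSplit:
    @staticmethod
    def _toy_tracks():
        tracks = []
        for i in range(10):
            label = int(i < 6)
            for v in range(3):
                tracks.append(track(np.zeros(5, dtype=int), f"c{i}_v{v}",
                                    f"c{i}", label))
        return tracks

    def test_children_never_straddle_splits(self):
        train, val, test = split_by_child(self._toy_tracks(), seed=0)
        sets = [set(t.child_id for t in part) for part in (train, val, test)]
        assert not (sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2])
        assert len(train) + len(val) + len(test) == 30
        # videos travel with their child (3 each)
        assert all(len(part) % 3 == 0 for part in (train, val, test))

    def test_same_seed_same_split(self):
        parts1 = split_by_child(self._toy_tracks(), seed=5)
        parts2 = split_by_child(self._toy_tracks(), seed=5)
        for p1, p2 in zip(parts1, parts2):
            assert [t.video_id for t in p1] == [t.video_id for t in p2]

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError):
            split_by_child(self._toy_tracks(), ratios=(0.5, 0.2, 0.2))

    def test_missing_class_warns(self):
        tracks = [track(np.zeros(5, dtype=int), f"v{i}", f"c{i}", 1)
                  for i in range(3)]
        with pytest.warns(UserWarning, match="missing a diagnosis class"):
            split_by_child(tracks, seed=0)


class TestEvaluate:
    def test_perfect_predictions(self):
        m = evaluate([1, 0, 1, 0], [1, 0, 1, 0])
        assert m.macro_recall == m.macro_precision == 1.0
        assert m.weighted_recall == m.weighted_precision == 1.0

    def test_hand_computed_confusion_matrix(self):
        # TP=3, FN=2, TN=2, FP=1: unequal supports (5 vs 3), so weighted
        # averages differ from macro ones
        y_true = [1, 1, 1, 1, 1, 0, 0, 0]
        y_pred = [1, 1, 1, 0, 0, 1, 0, 0]
        m = evaluate(y_true, y_pred)
        assert (m.tp, m.fn, m.tn, m.fp) == (3, 2, 2, 1)
        assert m.macro_recall == pytest.approx((3 / 5 + 2 / 3) / 2)
        assert m.weighted_recall == pytest.approx((5 * 3 / 5 + 3 * 2 / 3) / 8)
        assert m.macro_precision == pytest.approx((3 / 4 + 2 / 4) / 2)
        assert m.weighted_precision == pytest.approx((5 * 3 / 4 + 3 * 2 / 4) / 8)

    def test_degenerate_all_positive_on_balanced(self):
        m = evaluate([1, 1, 0, 0], [1, 1, 1, 1])
        assert m.macro_recall == 0.5

    def test_weighted_equals_macro_at_equal_support(self, rng):
        y_true = np.array([1] * 20 + [0] * 20)
        y_pred = rng.integers(0, 2, 40)
        m = evaluate(y_true, y_pred)
        assert m.weighted_recall == pytest.approx(m.macro_recall)
        assert m.weighted_precision == pytest.approx(m.macro_precision)

    def test_absent_class_recall_zero_with_warning(self):
        with pytest.warns(UserWarning, match="recall of class 0"):
            m = evaluate([1, 1], [1, 0])
        assert m.macro_recall == pytest.approx(0.25)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import precision_score, recall_score
        y_true = rng.integers(0, 2, 60)
        y_pred = rng.integers(0, 2, 60)
        m = evaluate(y_true, y_pred)
        for avg, mine_r, mine_p in (("macro", m.macro_recall, m.macro_precision),
                                    ("weighted", m.weighted_recall,
                                     m.weighted_precision)):
            assert mine_r == pytest.approx(recall_score(y_true, y_pred,
                                                        average=avg))
            assert mine_p == pytest.approx(precision_score(y_true, y_pred,
                                                           average=avg))


class TestTraining:
    @staticmethod
    def _separable_tracks(n_per_class=6, frames=40):
        # ASD tracks dwell on AOI 5, NT on AOI 6: linearly separable
        tracks = []
        for i in range(n_per_class):
            tracks.append(track(np.full(frames, 5), f"a{i}", f"ca{i}", 1))
            tracks.append(track(np.full(frames, 6), f"n{i}", f"cn{i}", 0))
        return tracks

    def test_separable_data_reaches_perfect_recall(self):
        tracks = self._separable_tracks()
        train = [t for t in tracks if t.child_id[-1] in "01234"][:16]
        val = [t for t in tracks if t.child_id not in
               {x.child_id for x in train}]
        clf = SequenceClassifier(window=10, shift=5, hidden_size=8,
                                 max_epochs=15, patience=15, seed=0)
        res = clf.fit(train, val)
        assert res.val_metrics.macro_recall == 1.0

    def test_fixed_seed_identical_training_trajectory(self):
        tracks = self._separable_tracks(4)
        clf = SequenceClassifier(window=10, shift=10, hidden_size=6,
                                 max_epochs=3, seed=42)
        h1 = clf.fit(tracks, tracks).history
        h2 = clf.fit(tracks, tracks).history
        assert h1 == h2

    def test_single_class_training_rejected(self):
        tracks = [track(np.full(20, 5), f"a{i}", f"c{i}", 1) for i in range(4)]
        clf = SequenceClassifier(window=10, shift=10, seed=0)
        with pytest.raises(ValueError, match="both classes"):
            clf.fit(tracks, tracks)

    def test_probability_threshold_rule(self):
        tracks = self._separable_tracks(3)
        clf = SequenceClassifier(window=10, shift=10, hidden_size=6,
                                 max_epochs=2, seed=1)
        res = clf.fit(tracks, tracks)
        p, y_hat, _, _ = res.predict_windows(tracks)
        np.testing.assert_array_equal(y_hat, (p >= 0.5).astype(int))

    def test_grid_search_tabulates_and_ranks(self):
        from gazescan import grid_search
        tracks = self._separable_tracks(4, frames=30)
        table = grid_search(tracks, tracks, windows=(10,), shifts=(5, 10),
                            seed=0, hidden_size=6, max_epochs=4, patience=4)
        assert list(table.columns) == ["window", "shift", "macro_recall",
                                       "macro_precision", "weighted_recall",
                                       "weighted_precision"]
        assert len(table) == 2
        assert table["macro_recall"].is_monotonic_decreasing

    def test_per_video_majority_vote_runs(self):
        tracks = self._separable_tracks(4)
        clf = SequenceClassifier(window=10, shift=5, hidden_size=6,
                                 max_epochs=8, patience=8, seed=2)
        res = clf.fit(tracks, tracks)
        m = res.evaluate(tracks, unit="video")
        assert 0.0 <= m.macro_recall <= 1.0
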