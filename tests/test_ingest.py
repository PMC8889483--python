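"""Loading, validation, quality filtering, and track construction."""

import numpy as np
import pandas as pd
import pytest

from gazescan import (build_tracks, filter_frames, load_annotations,
                      load_tracks, read_tracks, save_tracks)
from gazescan.ingest import load_openface_csv

META = pd.DataFrame({
    "child_id": ["c1", "c2"],
    "diagnosis": ["ASD", "NT"],
    "age": [5, 7],
    "sex": ["M", "F"],
})


def ann_frame(rows):
    return pd.DataFrame(rows, columns=["video_id", "child_id", "frame_index",
                                       "n_faces", "confidence", "gaze_x",
                                       "gaze_y"])


def write_pair(tmp_path, ann, meta=META):
    a, m = tmp_path / "ann.csv", tmp_path / "meta.csv"
    ann.to_csv(a, index=False)
    meta.to_csv(m, index=False)
    return a, m


class TestLoadAnnotations:
    def test_well_formed_two_rows(self, tmp_path):
        ann = ann_frame([("v1", "c1", 0, 1, 0.9, 0.0, 0.0),
                         ("v1", "c1", 1, 1, 0.8, 0.5, -0.5)])
        a, m = write_pair(tmp_path, ann)
        loaded, meta = load_annotations(a, m)
        assert len(loaded) == 2
        assert (loaded["diagnosis"] == "ASD").all()

    def test_out_of_range_coordinate_cites_row(self, tmp_path):
        ann = ann_frame([("v1", "c1", 0, 1, 0.9, 0.0, 0.0),
                         ("v1", "c1", 1, 1, 0.9, 1.5, 0.0)])
        a, m = write_pair(tmp_path, ann)
        with pytest.raises(ValueError, match=r"gaze_x.*\[2\]"):
            load_annotations(a, m)

    def test_unknown_child_named(self, tmp_path):
        ann = ann_frame([("v1", "ghost", 0, 1, 0.9, 0.0, 0.0)])
        a, m = write_pair(tmp_path, ann)
        with pytest.raises(ValueError, match="ghost"):
            load_annotations(a, m)

    def test_missing_column_named(self, tmp_path):
        ann = ann_frame([("v1", "c1", 0, 1, 0.9, 0.0, 0.0)])
        ann = ann.drop(columns=["confidence"])
        a, m = write_pair(tmp_path, ann)
        with pytest.raises(ValueError, match="confidence"):
            load_annotations(a, m)

    def test_non_numeric_coordinate_rejected(self, tmp_path):
        ann = ann_frame([("v1", "c1", 0, 1, 0.9, "oops", 0.0)])
        a, m = write_pair(tmp_path, ann)
        with pytest.raises(ValueError, match="gaze_x"):
            load_annotations(a, m)


class TestFilterFrames:
    @pytest.mark.parametrize("n_faces, confidence, kept", [
        (1, 0.80, True),
        (2, 0.80, True),    # two faces retained
        (0, 0.99, False),   # zero faces removed
        (3, 0.99, False),   # more than two faces removed
        (1, 0.74, False),   # below-threshold confidence removed
        (1, 0.75, True),    # exactly at threshold retained
    ])
    def test_filter_rules(self, n_faces, confidence, kept):
        ann = ann_frame([("v1", "c1", 0, n_faces, confidence, 0.0, 0.0)])
        assert (len(filter_frames(ann)) == 1) is kept

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        ann = ann_frame([("v1", "c1", i, int(f), c, 0.0, 0.0)
                         for i, (f, c) in enumerate(
                             zip(rng.integers(0, 4, 50), rng.random(50)))])
        once = filter_frames(ann)
        twice = filter_frames(once)
        assert once.equals(twice)

    def test_order_preserved(self):
        ann = ann_frame([("v1", "c1", i, 1, 0.9, 0.0, 0.0) for i in range(5)])
        assert filter_frames(ann)["frame_index"].tolist() == [0, 1, 2, 3, 4]


class TestBuildTracks:
    def test_aoi_sequence_from_coordinates(self, tmp_path):
        ann = ann_frame([("v1", "c1", 0, 1, 0.9, 0.0, 0.0),
                         ("v1", "c1", 1, 1, 0.9, 0.0, 0.0),
                         ("v1", "c1", 2, 1, 0.9, -0.9, 0.9)])
        a, m = write_pair(tmp_path, ann)
        tracks = load_tracks(a, m)
        assert len(tracks) == 1
        assert tracks[0].aoi_labels == ["CC", "CC", "AA"]
        assert tracks[0].label == 1

    def test_fully_filtered_video_excluded(self, tmp_path, caplog):
        ann = ann_frame([("v1", "c1", 0, 0, 0.9, 0.0, 0.0),
                         ("v2", "c2", 0, 1, 0.9, 0.0, 0.0)])
        a, m = write_pair(tmp_path, ann)
        import logging
        with caplog.at_level(logging.WARNING, logger="gazescan.ingest"):
            tracks = load_tracks(a, m)
        assert [t.video_id for t in tracks] == ["v2"]
        assert "v1" in caplog.text

    def test_two_videos_two_tracks_with_retention(self, tmp_path):
        ann = ann_frame(
            [("v1", "c1", i, 1, 0.9, 0.0, 0.0) for i in range(4)]
            + [("v2", "c2", 0, 1, 0.9, 0.1, 0.1),
               ("v2", "c2", 1, 0, 0.9, 0.1, 0.1)])
        a, m = write_pair(tmp_path, ann)
        tracks = {t.video_id: t for t in load_tracks(a, m)}
        assert len(tracks) == 2
        assert tracks["v1"].retained_fraction == 1.0
        assert tracks["v2"].retained_fraction == 0.5
        assert tracks["v2"].diagnosis == "NT"

    def test_gap_break_splits_track(self):
        ann = ann_frame([("v1", "c1", i, 1, 0.9, 0.0, 0.0)
                         for i in (0, 1, 2, 100, 101)])
        ann["diagnosis"] = "ASD"
        tracks = build_tracks(ann, gap_break=10)
        assert [t.video_id for t in tracks] == ["v1#1", "v1#2"]
        assert [len(t) for t in tracks] == [3, 2]


class TestOpenFaceImporter:
    def test_angle_rescale_and_axis_flip(self, tmp_path):
        raw = pd.DataFrame({
            "frame": [1, 2, 3],
            "confidence": [0.9, 0.9, 0.5],
            "gaze_angle_x": [-0.8, 0.0, 0.8],   # full left, center, full right
            "gaze_angle_y": [0.8, 0.0, -0.8],   # down, center, up (OpenFace)
        })
        path = tmp_path / "of.csv"
        raw.to_csv(path, index=False)
        ann = load_openface_csv(path, "v1", "c1")
        assert list(ann.columns) == ["video_id", "child_id", "frame_index",
                                     "n_faces", "confidence", "gaze_x",
                                     "gaze_y"]
        assert ann["gaze_x"].tolist() == [-1.0, 0.0, 1.0]
        assert ann["gaze_y"].tolist() == [-1.0, 0.0, 1.0]  # down -> -1
        assert (ann["n_faces"] == 1).all()

    def test_out_of_range_angles_clipped(self, tmp_path):
        raw = pd.DataFrame({"confidence": [1.0], "gaze_angle_x": [2.5],
                            "gaze_angle_y": [-2.5]})
        path = tmp_path / "of.csv"
        raw.to_csv(path, index=False)
        ann = load_openface_csv(path, "v", "c")
        assert ann["gaze_x"].iloc[0] == 1.0 and ann["gaze_y"].iloc[0] == 1.0

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "of.csv"
        pd.DataFrame({"confidence": [1.0]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="gaze_angle_x"):
            load_openface_csv(path, "v", "c")


class TestTrackIO:
    def test_save_read_roundtrip(self, tmp_path, planted_tracks):
        path = save_tracks(planted_tracks[:5], tmp_path / "tracks.jsonl")
        back = read_tracks(path)
        assert len(back) == 5
        for t0, t1 in zip(planted_tracks[:5], back):
            assert t0.video_id == t1.video_id
            assert t0.label == t1.label
            assert np.array_equal(t0.aoi, t1.aoi)
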