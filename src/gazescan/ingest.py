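"""Reading gaze-annotation tables, quality filtering, AOI discretization.

Input is the canonical pair of CSVs (one annotation row per video frame, one
metadata row per child).  The quality filter mirrors the upstream labelling
pipeline being emulated: frames whose face detector found 0 or more than 2
faces are removed, as are frames whose gaze-estimation confidence is below
75% (a confidence of exactly 0.75 is kept).  Surviving frames are
discretized onto the 16-AOI grid, yielding one ordered AOI label sequence
per video (a :class:`GazeTrack`).

Frames removed by the filter do NOT split a track: the retained sequence is
treated as contiguous.  An optional ``gap_break`` parameter splits a video
into separate tracks wherever the retained frame indices jump by more than
the given number of frames, for sensitivity analysis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .aoi import AOI_LABELS, assign_aoi_codes

logger = logging.getLogger(__name__)

__all__ = [
    "GazeTrack",
    "load_annotations",
    "filter_frames",
    "build_tracks",
    "load_tracks",
    "save_tracks",
    "read_tracks",
    "DEFAULT_CONFIDENCE_THRESHOLD",
]

DEFAULT_CONFIDENCE_THRESHOLD = 0.75

_REQUIRED_ANN = ["video_id", "child_id", "frame_index", "n_faces",
                 "confidence", "gaze_x", "gaze_y"]
_REQUIRED_META = ["child_id", "diagnosis"]


@dataclass
class GazeTrack:
    """One video's retained, AOI-discretized gaze sequence.

    ``aoi`` holds integer AOI codes (AA=0 ... DD=15, alphabetical) in frame
    order; ``label`` is 1 for ASD, 0 for NT; ``retained_fraction`` is the
    share of the video's raw frames that survived the quality filter.
    """

    video_id: str
    child_id: str
    label: int
    aoi: np.ndarray
    retained_fraction: float = 1.0

    def __len__(self) -> int:
        return len(self.aoi)

    @property
    def diagnosis(self) -> str:
        return "ASD" if self.label == 1 else "NT"

    @property
    def aoi_labels(self) -> list[str]:
        """The sequence as two-letter AOI labels."""
        return [AOI_LABELS[c] for c in self.aoi]


def _fail(msg: str) -> None:
    raise ValueError(msg)


def load_annotations(annotation_path, metadata_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load and validate the annotation and metadata CSVs.

    Returns (annotations, metadata) where annotations carry a ``diagnosis``
    column joined from the metadata.  Malformed input raises ``ValueError``
    naming the offending column and the first offending CSV row numbers
    (1-based, excluding the header).
    """
    annotation_path, metadata_path = Path(annotation_path), Path(metadata_path)
    ann = pd.read_csv(annotation_path)
    meta = pd.read_csv(metadata_path)

    missing = [c for c in _REQUIRED_ANN if c not in ann.columns]
    if missing:
        _fail(f"{annotation_path}: missing columns {missing}")
    missing = [c for c in _REQUIRED_META if c not in meta.columns]
    if missing:
        _fail(f"{metadata_path}: missing columns {missing}")

    for col in ("frame_index", "n_faces", "confidence", "gaze_x", "gaze_y"):
        vals = pd.to_numeric(ann[col], errors="coerce")
        bad = vals.isna() & ann[col].notna()
        if ann[col].isna().any() or bad.any():
            rows = (ann.index[vals.isna()] + 1).tolist()[:5]
            _fail(f"non-numeric or missing values in column '{col}' at rows {rows}")
        ann[col] = vals
    for col, lo, hi in (("gaze_x", -1.0, 1.0), ("gaze_y", -1.0, 1.0),
                        ("confidence", 0.0, 1.0)):
        bad = (ann[col] < lo) | (ann[col] > hi)
        if bad.any():
            rows = (ann.index[bad] + 1).tolist()[:5]
            _fail(f"column '{col}' out of range [{lo}, {hi}] at rows {rows}")
    if (ann["n_faces"] < 0).any() or (ann["frame_index"] < 0).any():
        _fail("columns 'n_faces' and 'frame_index' must be non-negative")

    if meta["child_id"].duplicated().any():
        dup = meta.loc[meta["child_id"].duplicated(), "child_id"].iloc[0]
        _fail(f"duplicate child_id in metadata: {dup!r}")
    bad_dx = ~meta["diagnosis"].isin(["ASD", "NT"])
    if bad_dx.any():
        _fail(f"diagnosis must be 'ASD' or 'NT', got "
              f"{meta.loc[bad_dx, 'diagnosis'].unique().tolist()}")
    unknown = set(ann["child_id"]) - set(meta["child_id"])
    if unknown:
        _fail(f"annotation child_id(s) absent from metadata: {sorted(unknown)}")

    ann = ann.merge(meta[["child_id", "diagnosis"]], on="child_id", how="left")
    ann = ann.sort_values(["video_id", "frame_index"], kind="stable")
    if ann.duplicated(["video_id", "frame_index"]).any():
        _fail("duplicate frame_index within a video")
    return ann.reset_index(drop=True), meta


def filter_frames(frames: pd.DataFrame,
                  confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD
                  ) -> pd.DataFrame:
    """Apply the frame-quality filter; order is preserved.

    Retains exactly the frames with ``n_faces`` in {1, 2} and
    ``confidence >= confidence_threshold`` (retention inclusive at the
    threshold: "below 75%" is removed).  Idempotent.
    """
    keep = (frames["n_faces"].isin([1, 2])
            & (frames["confidence"] >= confidence_threshold))
    return frames.loc[keep]


def build_tracks(retained: pd.DataFrame,
                 raw_counts: pd.Series | dict | None = None,
                 gap_break: int | None = None) -> list[GazeTrack]:
    """Discretize retained frames into one :class:`GazeTrack` per video.

    ``raw_counts`` maps video_id to the pre-filter frame count (used for
    ``retained_fraction``; defaults to the retained count, i.e. fraction 1).
    Videos with zero retained frames are excluded and logged.  With
    ``gap_break`` set, a video splits into ``<video_id>#<k>`` segments
    wherever consecutive retained frame indices differ by more than
    ``gap_break``.
    """
    tracks: list[GazeTrack] = []
    if raw_counts is None:
        raw_counts = {}
    n_empty = 0
    for video_id, grp in retained.groupby("video_id", sort=True):
        if len(grp) == 0:  # pragma: no cover - groupby drops empty groups
            continue
        codes = assign_aoi_codes(grp["gaze_x"].to_numpy(),
                                 grp["gaze_y"].to_numpy())
        child_id = str(grp["child_id"].iloc[0])
        label = 1 if grp["diagnosis"].iloc[0] == "ASD" else 0
        raw_n = int(raw_counts.get(video_id, len(grp)))
        frac = len(grp) / raw_n if raw_n else 0.0
        if gap_break is None:
            tracks.append(GazeTrack(str(video_id), child_id, label, codes, frac))
        else:
            idx = grp["frame_index"].to_numpy()
            cuts = np.flatnonzero(np.diff(idx) > gap_break) + 1
            for k, seg in enumerate(np.split(codes, cuts)):
                tracks.append(GazeTrack(f"{video_id}#{k + 1}", child_id,
                                        label, seg, frac))
    all_videos = retained["video_id"].unique() if len(retained) else []
    if raw_counts:
        empty = set(raw_counts) - set(map(str, all_videos))
        for vid in sorted(empty):
            n_empty += 1
            logger.warning("video %s: all frames removed by quality filter", vid)
    if n_empty:
        logger.warning("%d video(s) excluded (no retained frames)", n_empty)
    return tracks


def load_tracks(annotation_path, metadata_path,
                confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
                gap_break: int | None = None) -> list[GazeTrack]:
    """Full ingest: load + validate, filter, discretize.  Returns tracks."""
    ann, _meta = load_annotations(annotation_path, metadata_path)
    raw_counts = ann.groupby("video_id").size().to_dict()
    retained = filter_frames(ann, confidence_threshold)
    return build_tracks(retained, raw_counts, gap_break)


def load_openface_csv(path, video_id: str, child_id: str,
                      angle_range: tuple[float, float] = (-0.8, 0.8),
                      angle_cols: tuple[str, str] = ("gaze_angle_x",
                                                     "gaze_angle_y"),
                      confidence_col: str = "confidence") -> pd.DataFrame:
    """Experimental importer for OpenFace-style per-frame CSVs (one video).

    Maps the gaze-angle pair (radians; positive y is downward gaze in the
    OpenFace convention) to the canonical [-1, 1] coordinates by a linear
    rescale over ``angle_range``, clipping outside it, and assumes a single
    tracked face per frame.  The angle-to-coordinate normalization is an
    assumption of this importer, not a property of the canonical format.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in (*angle_cols, confidence_col) if c not in df.columns]
    if missing:
        _fail(f"{path}: missing OpenFace columns {missing}")
    lo, hi = angle_range
    if not hi > lo:
        raise ValueError("angle_range must be increasing")

    def rescale(angles):
        return np.clip(2.0 * (angles - lo) / (hi - lo) - 1.0, -1.0, 1.0)

    frame_index = (df["frame"].to_numpy()
                   if "frame" in df.columns else np.arange(len(df)))
    return pd.DataFrame({
        "video_id": video_id,
        "child_id": child_id,
        "frame_index": frame_index,
        "n_faces": 1,
        "confidence": np.clip(df[confidence_col].to_numpy(float), 0.0, 1.0),
        "gaze_x": rescale(df[angle_cols[0]].to_numpy(float)),
        # OpenFace's positive vertical angle is downward; canonical +y is up
        "gaze_y": -rescale(df[angle_cols[1]].to_numpy(float)),
    })


def tracks_from_dataframes(annotations: pd.DataFrame, metadata: pd.DataFrame,
                           confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
                           gap_break: int | None = None) -> list[GazeTrack]:
    """Ingest in-memory tables (already well-formed): filter + discretize.

    Same semantics as :func:`load_tracks` minus the CSV round-trip and the
    heavyweight validation; intended for simulated cohorts.
    """
    ann = annotations.merge(metadata[["child_id", "diagnosis"]],
                            on="child_id", how="left")
    raw_counts = ann.groupby("video_id").size().to_dict()
    retained = filter_frames(ann, confidence_threshold)
    return build_tracks(retained, raw_counts, gap_break)


def save_tracks(tracks: list[GazeTrack], path) -> Path:
    """Write tracks as JSON lines (video_id, child_id, label, aoi codes)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for t in tracks:
            fh.write(json.dumps({
                "video_id": t.video_id,
                "child_id": t.child_id,
                "label": int(t.label),
                "retained_fraction": round(float(t.retained_fraction), 10),
                "aoi": [int(c) for c in t.aoi],
            }) + "\n")
    return path


def read_tracks(path) -> list[GazeTrack]:
    """Read tracks written by :func:`save_tracks`."""
    tracks = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            tracks.append(GazeTrack(d["video_id"], d["child_id"],
                                    int(d["label"]),
                                    np.asarray(d["aoi"], dtype=np.int64),
                                    float(d.get("retained_fraction", 1.0))))
    return tracks
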