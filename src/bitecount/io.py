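"""Landmark, ratio and annotation I/O.

A :class:`LandmarkSeries` holds the per-frame 468-point 3D face mesh for one
meal video, in the mesh's normalised image coordinates (x, y in [0, 1]
relative to frame width/height, z a unitless relative depth).  Frames where
the face detector found no face are kept as gaps (``face_detected=False``)
rather than dropped or zero-filled, so downstream signal code can mark them
missing.

Two CSV dialects are supported:

* ``long`` (canonical): one row per landmark point,
  ``video_id,frame,time_s,point_index,x,y,z``.  A frame with no detected
  face is stored as a single row with ``point_index = -1`` and empty
  coordinates.
* ``wide``: one row per frame,
  ``video_id,frame,time_s,face_detected`` plus 1404 coordinate columns
  ``x0,y0,z0,...,x467,y467,z467``.

Both dialects carry series metadata (participant id, fps) in leading
``# key=value`` comment lines.  UTF-8, comma-delimited, ``.`` decimal.
"""
from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import BackendContractError, DataError, SchemaError

N_MESH_POINTS = 468

MEAL_TYPES = ("breakfast", "lunch", "dinner", "dessert")
TEXTURE_CONDITIONS = ("fast_soft", "slow_hard")
PROCESSING_CONDITIONS = ("unprocessed", "processed")

ANNOTATION_COLUMNS = (
    "video_id",
    "participant_id",
    "meal_type",
    "texture_condition",
    "processing_condition",
    "annotated_bites",
)

#: Signature of a pluggable video-to-landmarks backend: given one image
#: frame, return a (468, 3) float array or None when no face is found.
LandmarkBackend = Callable[[np.ndarray], Optional[np.ndarray]]


@dataclass(frozen=True)
class LandmarkFrame:
    """One video frame's face-mesh detection result."""

    frame_index: int
    time_s: float
    points: Optional[np.ndarray]  # (468, 3) when a face was detected
    face_detected: bool

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        if self.time_s < 0:
            raise ValueError("time_s must be >= 0")
        if self.face_detected:
            if self.points is None or np.asarray(self.points).shape != (N_MESH_POINTS, 3):
                raise ValueError(
                    f"a detected face must carry exactly {N_MESH_POINTS} (x, y, z) points"
                )
        elif self.points is not None:
            raise ValueError("points must be absent when face_detected is False")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LandmarkFrame):
            return NotImplemented
        if (self.frame_index, self.time_s, self.face_detected) != (
            other.frame_index,
            other.time_s,
            other.face_detected,
        ):
            return False
        if self.points is None:
            return other.points is None
        return other.points is not None and np.array_equal(self.points, other.points)


@dataclass
class LandmarkSeries:
    """Ordered face-mesh frames for one video.

    ``points`` is an ``(n_frames, 468, 3)`` float array with NaN rows at
    frames where no face was detected; ``face_detected`` is the matching
    boolean mask.  Frame indices are implicitly consecutive from 0.
    """

    video_id: str
    participant_id: str
    fps: float
    points: np.ndarray
    face_detected: np.ndarray
    time_s: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        self.points = np.asarray(self.points, dtype=float).reshape(-1, N_MESH_POINTS, 3)
        self.face_detected = np.asarray(self.face_detected, dtype=bool).reshape(-1)
        n = len(self.face_detected)
        if self.points.shape[0] != n:
            raise ValueError("points and face_detected lengths differ")
        if self.time_s is None:
            self.time_s = np.arange(n, dtype=float) / self.fps
        self.time_s = np.asarray(self.time_s, dtype=float).reshape(-1)
        if len(self.time_s) != n:
            raise ValueError("time_s length differs from frame count")
        if n > 1 and not np.all(np.diff(self.time_s) > 0):
            raise DataError("time_s must strictly increase with frame index")

    @property
    def n_frames(self) -> int:
        return len(self.face_detected)

    @property
    def frames(self) -> Iterator[LandmarkFrame]:
        for i in range(self.n_frames):
            yield self[i]

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, i: int) -> LandmarkFrame:
        detected = bool(self.face_detected[i])
        return LandmarkFrame(
            frame_index=i,
            time_s=float(self.time_s[i]),
            points=self.points[i].copy() if detected else None,
            face_detected=detected,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LandmarkSeries):
            return NotImplemented
        return (
            self.video_id == other.video_id
            and self.participant_id == other.participant_id
            and self.fps == other.fps
            and np.array_equal(self.face_detected, other.face_detected)
            and np.array_equal(self.time_s, other.time_s)
            and np.array_equal(self.points, other.points, equal_nan=True)
        )

    @classmethod
    def from_frames(
        cls,
        video_id: str,
        participant_id: str,
        fps: float,
        frames: Sequence[LandmarkFrame],
    ) -> "LandmarkSeries":
        n = len(frames)
        for i, f in enumerate(frames):
            if f.frame_index != i:
                raise DataError(
                    f"frame indices must be consecutive from 0; got {f.frame_index} at position {i}"
                )
        points = np.full((n, N_MESH_POINTS, 3), np.nan)
        detected = np.zeros(n, dtype=bool)
        times = np.empty(n)
        for i, f in enumerate(frames):
            times[i] = f.time_s
            detected[i] = f.face_detected
            if f.face_detected:
                points[i] = f.points
        return cls(video_id, participant_id, fps, points, detected, times)


@dataclass(frozen=True)
class AnnotationRecord:
    """Ground-truth bite count plus condition labels for one video."""

    video_id: str
    participant_id: str
    meal_type: str
    texture_condition: str
    processing_condition: str
    annotated_bites: int

    def __post_init__(self) -> None:
        if self.meal_type not in MEAL_TYPES:
            raise DataError(f"unknown meal_type {self.meal_type!r}; expected one of {MEAL_TYPES}")
        if self.texture_condition not in TEXTURE_CONDITIONS:
            raise DataError(
                f"unknown texture_condition {self.texture_condition!r}; "
                f"expected one of {TEXTURE_CONDITIONS}"
            )
        if self.processing_condition not in PROCESSING_CONDITIONS:
            raise DataError(
                f"unknown processing_condition {self.processing_condition!r}; "
                f"expected one of {PROCESSING_CONDITIONS}"
            )
        if self.annotated_bites < 0:
            raise DataError("annotated_bites must be >= 0")


# ---------------------------------------------------------------------------
# landmark CSV


def _coord_columns() -> list:
    cols = []
    for i in range(N_MESH_POINTS):
        cols.extend([f"x{i}", f"y{i}", f"z{i}"])
    return cols


def _read_meta(path: Path) -> tuple[dict, str]:
    meta = {}
    body_lines = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line[1:].strip()
                if "=" in stripped:
                    key, _, value = stripped.partition("=")
                    meta[key.strip()] = value.strip()
            else:
                body_lines.append(line)
    return meta, "".join(body_lines)


def write_landmark_series(
    series: LandmarkSeries, path: Union[str, Path], dialect: str = "long"
) -> Path:
    """Write a landmark series to CSV; returns the path written.

    The file round-trips: :func:`read_landmark_series` on the output yields
    an object equal to ``series``.
    """
    path = Path(path)
    if dialect not in ("long", "wide"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("# bitecount-landmarks v1\n")
        fh.write(f"# dialect={dialect}\n")
        fh.write(f"# video_id={series.video_id}\n")
        fh.write(f"# participant_id={series.participant_id}\n")
        fh.write(f"# fps={series.fps!r}\n")
        if dialect == "long":
            fh.write("video_id,frame,time_s,point_index,x,y,z\n")
            for i in range(series.n_frames):
                t = repr(float(series.time_s[i]))
                if series.face_detected[i]:
                    for j in range(N_MESH_POINTS):
                        x, y, z = (repr(float(v)) for v in series.points[i, j])
                        fh.write(f"{series.video_id},{i},{t},{j},{x},{y},{z}\n")
                else:
                    fh.write(f"{series.video_id},{i},{t},-1,,,\n")
        else:
            fh.write("video_id,frame,time_s,face_detected," + ",".join(_coord_columns()) + "\n")
            for i in range(series.n_frames):
                t = repr(float(series.time_s[i]))
                if series.face_detected[i]:
                    coords = ",".join(repr(float(v)) for v in series.points[i].ravel())
                else:
                    coords = "," * (3 * N_MESH_POINTS - 1)
                fh.write(f"{series.video_id},{i},{t},{int(series.face_detected[i])},{coords}\n")
    return path


def read_landmark_series(path: Union[str, Path], dialect: str = "auto") -> LandmarkSeries:
    """Read a landmark series written in the long or wide CSV dialect."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta, body = _read_meta(path)
    if dialect == "auto":
        dialect = meta.get("dialect", "long")
    if dialect not in ("long", "wide"):
        raise ValueError(f"unknown dialect {dialect!r}")
    fps = float(meta.get("fps", 0) or 0)
    if fps <= 0:
        raise SchemaError("missing or invalid 'fps' metadata line")
    participant_id = meta.get("participant_id", "")
    df = pd.read_csv(_io.StringIO(body), float_precision="round_trip")
    if dialect == "long":
        required = {"video_id", "frame", "time_s", "point_index", "x", "y", "z"}
        missing = required - set(df.columns)
        extra = set(df.columns) - required
        if missing:
            raise SchemaError(f"missing column(s): {sorted(missing)}")
        if extra:
            raise SchemaError(f"unexpected column(s): {sorted(extra)}")
        return _series_from_long(df, participant_id, fps, meta.get("video_id", ""))
    required = {"video_id", "frame", "time_s", "face_detected", *(_coord_columns())}
    missing = sorted(required - set(df.columns))
    extra = sorted(set(df.columns) - required)
    if missing:
        raise SchemaError(f"missing column(s): {missing[:5]}{'...' if len(missing) > 5 else ''}")
    if extra:
        raise SchemaError(f"unexpected column(s): {extra[:5]}{'...' if len(extra) > 5 else ''}")
    return _series_from_wide(df, participant_id, fps, meta.get("video_id", ""))


def _check_frames_consecutive(frame_ids: np.ndarray) -> None:
    if len(frame_ids) and not np.array_equal(frame_ids, np.arange(len(frame_ids))):
        raise DataError("frame indices must be consecutive from 0 and monotone")


def _series_from_long(
    df: pd.DataFrame, participant_id: str, fps: float, video_id: str
) -> LandmarkSeries:
    if len(df):
        video_id = str(df["video_id"].iloc[0])
    frame_ids = df["frame"].drop_duplicates().to_numpy()
    _check_frames_consecutive(frame_ids)
    n = len(frame_ids)
    points = np.full((n, N_MESH_POINTS, 3), np.nan)
    detected = np.zeros(n, dtype=bool)
    times = np.empty(n)
    for frame, grp in df.groupby("frame", sort=True):
        times[frame] = grp["time_s"].iloc[0]
        idx = grp["point_index"].to_numpy()
        if len(idx) == 1 and idx[0] == -1:
            continue  # no-face gap frame
        if not np.array_equal(np.sort(idx), np.arange(N_MESH_POINTS)):
            raise SchemaError(
                f"frame {frame}: expected point_index 0..{N_MESH_POINTS - 1}, got {len(idx)} rows"
            )
        detected[frame] = True
        order = np.argsort(idx)
        points[frame] = grp[["x", "y", "z"]].to_numpy()[order]
    if n and not np.all(np.diff(times) > 0):
        raise DataError("time_s must strictly increase with frame index")
    return LandmarkSeries(video_id, participant_id, fps, points, detected, times)


def _series_from_wide(
    df: pd.DataFrame, participant_id: str, fps: float, video_id: str
) -> LandmarkSeries:
    if len(df):
        video_id = str(df["video_id"].iloc[0])
    _check_frames_consecutive(df["frame"].to_numpy())
    n = len(df)
    detected = df["face_detected"].to_numpy().astype(bool)
    coords = df[_coord_columns()].to_numpy(dtype=float).reshape(n, N_MESH_POINTS, 3)
    coords[~detected] = np.nan
    return LandmarkSeries(
        video_id, participant_id, fps, coords, detected, df["time_s"].to_numpy(dtype=float)
    )


# ---------------------------------------------------------------------------
# annotation CSV


def annotations_to_frame(records: Sequence[AnnotationRecord]) -> pd.DataFrame:
    """Tabulate annotation records as a DataFrame (one row per video)."""
    return pd.DataFrame([vars(r) for r in records], columns=list(ANNOTATION_COLUMNS))


def write_annotations(records: Sequence[AnnotationRecord], path: Union[str, Path]) -> Path:
    path = Path(path)
    annotations_to_frame(records).to_csv(path, index=False)
    return path


def read_annotations(path: Union[str, Path]) -> list:
    """Read the annotation table; one :class:`AnnotationRecord` per row.

    Condition labels are validated against the documented enumerations and
    duplicate video ids rejected.
    """
    df = pd.read_csv(path, dtype={"video_id": str, "participant_id": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"missing column(s): {sorted(missing)}")
    dupes = df["video_id"][df["video_id"].duplicated()]
    if len(dupes):
        raise DataError(f"duplicate video_id(s): {sorted(set(dupes))}")
    return [
        AnnotationRecord(
            video_id=row.video_id,
            participant_id=row.participant_id,
            meal_type=row.meal_type,
            texture_condition=row.texture_condition,
            processing_condition=row.processing_condition,
            annotated_bites=int(row.annotated_bites),
        )
        for row in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# video -> landmarks via a pluggable backend


def extract_landmarks(
    video_source: Union[str, Path, Iterable[np.ndarray]],
    backend: LandmarkBackend,
    *,
    fps: Optional[float] = None,
    video_id: str = "video",
    participant_id: str = "",
) -> LandmarkSeries:
    """Run a landmark backend over a stream of video frames.

    ``video_source`` may be any iterable of image arrays (fps must then be
    given) or a video file path, which is decoded with OpenCV if installed —
    the face-mesh engine and the decoder are optional extras, never imported
    by the core.  The backend contract: ``backend(image)`` returns a
    (468, 3) array, or None when no face is found.
    """
    if isinstance(video_source, (str, Path)):
        frames_iter, fps = _decode_video(Path(video_source), fps)
    else:
        if fps is None or fps <= 0:
            raise ValueError("fps must be given (and > 0) for an in-memory frame stream")
        frames_iter = iter(video_source)

    frames = []
    for i, image in enumerate(frames_iter):
        result = backend(image)
        if result is None:
            frames.append(LandmarkFrame(i, i / fps, None, False))
            continue
        pts = np.asarray(result, dtype=float)
        if pts.shape != (N_MESH_POINTS, 3):
            raise BackendContractError(
                f"backend returned shape {pts.shape}; expected ({N_MESH_POINTS}, 3) or None"
            )
        frames.append(LandmarkFrame(i, i / fps, pts, True))
    return LandmarkSeries.from_frames(video_id, participant_id, fps, frames)


def _decode_video(path: Path, fps_override: Optional[float]):
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        import cv2  # optional extra
    except ImportError as exc:  # pragma: no cover - decoder not installed here
        raise ImportError(
            "decoding video files requires opencv-python; "
            "pass an iterable of frames plus fps instead"
        ) from exc

    cap = cv2.VideoCapture(str(path))  # pragma: no cover
    if not cap.isOpened():  # pragma: no cover
        raise IOError(f"cannot open video {path}")

    def frames():  # pragma: no cover
        while True:
            ok, frame = cap.read()
            if not ok:
                break
            yield frame
        cap.release()

    fps = fps_override or float(cap.get(cv2.CAP_PROP_FPS))  # pragma: no cover
    return frames(), fps  # pragma: no cover
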