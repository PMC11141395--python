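"""Mouth-ratio signal: per-frame ratio, smoothing, outlier removal.

The mouth ratio is the Euclidean distance between the upper- and lower-lip
key points divided by the distance between the left and right mouth corners
(mesh indices 0, 17, 61 and 291).  It is near 0 for a closed mouth and
rises sharply when the mouth opens to receive a bite; being a ratio of
distances it is invariant to where the face sits in the frame, to head
rotation, and to how close the participant is to the camera.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import DataError, DegenerateGeometryError, SchemaError
from .io import LandmarkFrame, LandmarkSeries, N_MESH_POINTS


@dataclass(frozen=True)
class MouthKeypointMap:
    """Mesh indices of the four mouth key points.

    Defaults are the face-mesh upper lip (0), lower lip (17), left mouth
    corner (61) and right mouth corner (291).
    """

    upper_lip_index: int = 0
    lower_lip_index: int = 17
    left_corner_index: int = 61
    right_corner_index: int = 291

    def __post_init__(self) -> None:
        idx = (
            self.upper_lip_index,
            self.lower_lip_index,
            self.left_corner_index,
            self.right_corner_index,
        )
        if len(set(idx)) != 4:
            raise ValueError("the four mouth key-point indices must be distinct")
        if not all(0 <= i < N_MESH_POINTS for i in idx):
            raise ValueError(f"key-point indices must lie in [0, {N_MESH_POINTS - 1}]")

    @property
    def indices(self) -> tuple:
        return (
            self.upper_lip_index,
            self.lower_lip_index,
            self.left_corner_index,
            self.right_corner_index,
        )


DEFAULT_KEYMAP = MouthKeypointMap()


@dataclass
class RatioSeries:
    """Per-frame mouth ratio for one video; NaN marks a missing value."""

    video_id: str
    participant_id: str
    fps: float
    ratio: np.ndarray
    time_s: Optional[np.ndarray] = None
    smoothed: bool = False
    window: Optional[int] = None

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        self.ratio = np.asarray(self.ratio, dtype=float).reshape(-1)
        if self.time_s is None:
            self.time_s = np.arange(len(self.ratio), dtype=float) / self.fps
        self.time_s = np.asarray(self.time_s, dtype=float).reshape(-1)
        if len(self.time_s) != len(self.ratio):
            raise ValueError("time_s and ratio lengths differ")
        if len(self.time_s) > 1 and not np.all(np.diff(self.time_s) > 0):
            raise DataError("time_s must strictly increase")
        with np.errstate(invalid="ignore"):
            if np.any(self.ratio < 0):
                raise DataError("mouth ratios must be >= 0 where present")
        if self.smoothed and (self.window is None or self.window < 1):
            raise ValueError("a smoothed series must record its window length")

    @property
    def frame_index(self) -> np.ndarray:
        return np.arange(len(self.ratio))

    def __len__(self) -> int:
        return len(self.ratio)


def _distance(a: np.ndarray, b: np.ndarray, use_z: bool = True) -> np.ndarray:
    d = a - b
    if not use_z:
        d = d[..., :2]
    return np.sqrt(np.sum(d * d, axis=-1))


def mouth_ratio(
    frame: LandmarkFrame,
    keymap: MouthKeypointMap = DEFAULT_KEYMAP,
    use_z: bool = True,
) -> float:
    """Mouth ratio for a single frame: lip separation over mouth width.

    Full 3D Euclidean distances by default; ``use_z=False`` falls back to a
    2D image-plane ratio for comparison against 68-point-style pipelines.
    Returns NaN (a missing value, not an error) when no face was detected.
    """
    if not frame.face_detected:
        return float("nan")
    pts = frame.points
    num = _distance(pts[keymap.upper_lip_index], pts[keymap.lower_lip_index], use_z)
    den = _distance(pts[keymap.left_corner_index], pts[keymap.right_corner_index], use_z)
    if den == 0:
        raise DegenerateGeometryError(
            f"mouth corners coincide at frame {frame.frame_index}; ratio undefined"
        )
    return float(num / den)


def ratio_series(
    series: LandmarkSeries,
    keymap: MouthKeypointMap = DEFAULT_KEYMAP,
    use_z: bool = True,
) -> RatioSeries:
    """Mouth ratio at every frame of a landmark series (vectorised).

    Frames with no detected face yield missing values; frames with
    degenerate geometry (coincident mouth corners) are likewise marked
    missing, with a warning rather than an exception, so one corrupt frame
    cannot sink a whole meal video.
    """
    pts = series.points  # (n, 468, 3)
    num = _distance(pts[:, keymap.upper_lip_index], pts[:, keymap.lower_lip_index], use_z)
    den = _distance(pts[:, keymap.left_corner_index], pts[:, keymap.right_corner_index], use_z)
    degenerate = series.face_detected & (den == 0)
    if np.any(degenerate):
        warnings.warn(
            f"{series.video_id}: {int(degenerate.sum())} frame(s) with coincident "
            "mouth corners marked missing",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(series.face_detected & ~degenerate, num / den, np.nan)
    return RatioSeries(
        video_id=series.video_id,
        participant_id=series.participant_id,
        fps=series.fps,
        ratio=r,
        time_s=series.time_s.copy(),
        smoothed=False,
    )


def smooth(series: RatioSeries, window: int = 5) -> RatioSeries:
    """Trailing moving average over ``window`` frames.

    The value at frame t is the mean of the available (non-missing) raw
    values in frames [t - window + 1, t]; partial windows at the start of
    the series average whatever frames exist.  The window is causal
    (trailing) so the counter can run on a live stream.  Length is
    unchanged; a frame whose whole window is missing stays missing.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    values = pd.Series(series.ratio).rolling(window, min_periods=1).mean().to_numpy()
    return replace(series, ratio=values, smoothed=True, window=window)


def remove_outliers(
    collection: Sequence[RatioSeries], z_max: float = 3.0
) -> list:
    """Per-participant z-score outlier removal, pooled across videos.

    Mean and standard deviation (population, ddof=0) are computed over all
    non-missing frames of all the participant's videos together; frames
    with \\|r - mean\\| / sd > ``z_max`` become missing.  Frame counts are
    unchanged.  If the pooled sd is 0 nothing can be an outlier: the input
    is returned unchanged with a warning.
    """
    if z_max <= 0:
        raise ValueError("z_max must be > 0")
    participants = {s.participant_id for s in collection}
    if len(participants) > 1:
        raise ValueError(
            f"remove_outliers pools statistics per participant; got {sorted(participants)}"
        )
    pooled = np.concatenate([s.ratio for s in collection]) if collection else np.array([])
    pooled = pooled[~np.isnan(pooled)]
    if len(pooled) < 2:
        raise DataError("need at least 2 non-missing values to compute z-scores")
    mu = float(pooled.mean())
    sigma = float(pooled.std(ddof=0))
    if sigma == 0:
        warnings.warn("pooled standard deviation is 0; no outliers removed", stacklevel=2)
        return [replace(s, ratio=s.ratio.copy()) for s in collection]
    out = []
    for s in collection:
        z = np.abs(s.ratio - mu) / sigma
        cleaned = np.where(z > z_max, np.nan, s.ratio)
        out.append(replace(s, ratio=cleaned))
    return out


# ---------------------------------------------------------------------------
# ratio CSV (video_id,participant_id,frame,time_s,ratio,smoothed[,window])

RATIO_COLUMNS = ("video_id", "participant_id", "frame", "time_s", "ratio", "smoothed", "window")


def write_ratio_series(series: RatioSeries, path: Union[str, Path]) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "video_id": series.video_id,
            "participant_id": series.participant_id,
            "frame": series.frame_index,
            "time_s": series.time_s,
            "ratio": series.ratio,
            "smoothed": int(series.smoothed),
            "window": series.window if series.window is not None else "",
        }
    )
    df.to_csv(path, index=False)
    return path


def read_ratio_series(path: Union[str, Path], fps: float) -> RatioSeries:
    """Read a ratio CSV back; missing ratios are empty fields."""
    df = pd.read_csv(
        path, dtype={"video_id": str, "participant_id": str}, float_precision="round_trip"
    )
    missing = set(RATIO_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"missing column(s): {sorted(missing)}")
    smoothed = bool(df["smoothed"].iloc[0]) if len(df) else False
    window = None
    if smoothed:
        window = int(df["window"].iloc[0])
    return RatioSeries(
        video_id=str(df["video_id"].iloc[0]) if len(df) else "",
        participant_id=str(df["participant_id"].iloc[0]) if len(df) else "",
        fps=fps,
        ratio=df["ratio"].to_numpy(dtype=float),
        time_s=df["time_s"].to_numpy(dtype=float),
        smoothed=smoothed,
        window=window,
    )
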