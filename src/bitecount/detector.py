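"""Threshold bite detection.

A bite shows up in the mouth-ratio signal as a brief excursion above a
per-participant threshold θ: the mouth opens to receive food and closes
again.  The detector smooths the ratio, marks every frame strictly above θ,
and debounces by collapsing each maximal run of consecutive above-threshold
frames into a single timestamped bite event.

:class:`ThresholdBiteCounter` packages the rule as a scikit-learn estimator
(one hyperparameter, no training) so that threshold search can run through
standard model-selection machinery.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .ratio import RatioSeries, smooth as _smooth

DEFAULT_WINDOW = 5


@dataclass(frozen=True)
class BiteEvent:
    """One detected bite: a maximal run of frames above threshold."""

    onset_frame: int
    onset_time_s: float
    peak_ratio: float
    duration_frames: int

    def __post_init__(self) -> None:
        if self.duration_frames < 1:
            raise ValueError("duration_frames must be >= 1")


@dataclass
class BiteResult:
    """Detection output for one video."""

    video_id: str
    predicted_bites: int
    events: Sequence[BiteEvent]

    def __post_init__(self) -> None:
        if self.predicted_bites != len(self.events):
            raise ValueError("predicted_bites must equal the number of events")


def _runs_above(above: np.ndarray) -> list:
    """Start/stop (half-open) index pairs of maximal True runs."""
    if not above.any():
        return []
    padded = np.concatenate([[False], above, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


class ThresholdBiteCounter(BaseEstimator):
    """Rule-based bite counter: count threshold crossings of the mouth ratio.

    Parameters
    ----------
    threshold : float, default 0.5
        Mouth-ratio value θ strictly above which a frame is part of a bite.
    window : int, default 5
        Trailing moving-average window (frames) applied to raw input series.
        Series already smoothed upstream are used as-is.
    min_gap : int, default 0
        Merge above-threshold runs separated by at most ``min_gap``
        below-threshold frames.  0 keeps the plain debouncing rule: two
        runs separated by a single below-threshold frame are two bites.
    bridge_missing : int, default 0
        Treat gaps of at most this many missing frames inside a run as part
        of the run.  0 (default) lets a missing frame terminate the run.

    The estimator has no trainable state: ``fit`` only validates parameters
    and records the input size, so cross-validated scores measure the
    stability of a candidate θ across subsets of a participant's meals.
    """

    def __init__(
        self,
        threshold: float = 0.5,
        window: int = DEFAULT_WINDOW,
        min_gap: int = 0,
        bridge_missing: int = 0,
    ):
        self.threshold = threshold
        self.window = window
        self.min_gap = min_gap
        self.bridge_missing = bridge_missing

    # -- core rule ---------------------------------------------------------

    def _validate_params(self) -> None:
        if self.threshold is not None and self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.min_gap < 0 or self.bridge_missing < 0:
            raise ValueError("min_gap and bridge_missing must be >= 0")

    def detect(self, series: RatioSeries) -> BiteResult:
        """Detect bite events in one ratio series."""
        self._validate_params()
        if not series.smoothed:
            series = _smooth(series, self.window)
        values = series.ratio
        missing = np.isnan(values)
        if self.bridge_missing > 0:
            values = values.copy()
            for start, stop in _runs_above(missing):
                if stop - start <= self.bridge_missing:
                    left = values[start - 1] if start > 0 else np.nan
                    right = values[stop] if stop < len(values) else np.nan
                    fill = np.nanmin([left, right])
                    if not np.isnan(fill):
                        values[start:stop] = fill
        with np.errstate(invalid="ignore"):
            above = values > self.threshold  # NaN compares False: missing ends a run
        runs = _runs_above(above)
        if self.min_gap > 0 and len(runs) > 1:
            merged = [runs[0]]
            for start, stop in runs[1:]:
                prev_start, prev_stop = merged[-1]
                gap = slice(prev_stop, start)
                if start - prev_stop <= self.min_gap and not missing[gap].any():
                    merged[-1] = (prev_start, stop)
                else:
                    merged.append((start, stop))
            runs = merged
        events = [
            BiteEvent(
                onset_frame=int(start),
                onset_time_s=float(series.time_s[start]),
                peak_ratio=float(np.nanmax(values[start:stop])),
                duration_frames=int(stop - start),
            )
            for start, stop in runs
        ]
        return BiteResult(series.video_id, len(events), events)

    # -- scikit-learn surface ---------------------------------------------

    def fit(self, X: Sequence[RatioSeries], y=None) -> "ThresholdBiteCounter":
        """No-op fit: validates parameters and records the input size."""
        self._validate_params()
        self.n_videos_ = len(X)
        return self

    def predict(self, X: Sequence[RatioSeries]) -> np.ndarray:
        """Predicted bite count per video."""
        check_is_fitted(self, "n_videos_")
        return np.array([self.detect(series).predicted_bites for series in X])

    def score(self, X: Sequence[RatioSeries], y: Sequence[int]) -> float:
        """Negative mean absolute difference between predicted and annotated
        bite counts; 0 is perfect, more negative is worse."""
        y = np.asarray(y, dtype=float)
        if len(y) != len(X):
            raise ValueError("X and y lengths differ")
        return float(-np.mean(np.abs(self.predict(X) - y)))


def detect_events(
    series: RatioSeries,
    threshold: float,
    window: int = DEFAULT_WINDOW,
    min_gap: int = 0,
    bridge_missing: int = 0,
) -> BiteResult:
    """Detect bite events: one event per maximal run of frames with
    (smoothed) ratio strictly above ``threshold``."""
    counter = ThresholdBiteCounter(threshold, window, min_gap, bridge_missing)
    return counter.detect(series)


def count_bites(series: RatioSeries, threshold: float, window: int = DEFAULT_WINDOW) -> int:
    """Number of bites detected in one series at threshold θ."""
    return detect_events(series, threshold, window).predicted_bites


def events_to_frame(results: Sequence[BiteResult]):
    """Tabulate events from one or more videos as a DataFrame."""
    import pandas as pd

    rows = [
        {
            "video_id": res.video_id,
            "onset_frame": ev.onset_frame,
            "onset_time_s": ev.onset_time_s,
            "peak_ratio": ev.peak_ratio,
            "duration_frames": ev.duration_frames,
        }
        for res in results
        for ev in res.events
    ]
    return pd.DataFrame(
        rows, columns=["video_id", "onset_frame", "onset_time_s", "peak_ratio", "duration_frames"]
    )
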