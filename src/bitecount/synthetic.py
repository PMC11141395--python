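"""Synthetic mouth-ratio traces, landmark streams and annotated cohorts.

Every other module can be exercised without any video data: the generator
plants bites with known onsets into a mouth-ratio trace and reports, per
trace, the band of thresholds that separates them from the baseline, so
detector and search behaviour can be checked against exact ground truth.

A trace is ``baseline + chewing oscillation + bite bumps + noise``:

* baseline — the closed-mouth ratio level (about 0.1 in practice);
* chewing — a sub-threshold sinusoid; chewing moves the lips only
  slightly, which is why chew counting is out of reach for a threshold
  rule, and is gated off inside bite bumps (one does not chew while the
  mouth is open to receive food);
* bites — smooth raised-cosine excursions of a configured amplitude and
  width at randomised onsets separated by a refractory gap;
* noise — i.i.d. Gaussian detector jitter.

The separability invariant ``3·noise_sd + chew_amplitude < bite_amplitude``
guarantees planted bites clear the noise floor.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import ConfigError
from .io import (
    MEAL_TYPES,
    PROCESSING_CONDITIONS,
    TEXTURE_CONDITIONS,
    AnnotationRecord,
    LandmarkSeries,
    N_MESH_POINTS,
)
from .ratio import DEFAULT_KEYMAP, MouthKeypointMap, RatioSeries, smooth as _smooth

#: Videos per participant in the validation study (15 participants, 164 videos).
STUDY_VIDEO_COUNTS = (10, 14, 14, 13, 11, 6, 14, 14, 13, 13, 7, 12, 8, 9, 6)


@dataclass
class TraceConfig:
    """Parameters of one simulated meal's mouth-ratio trace.

    Defaults emulate a realistic meal signal: closed-mouth baseline ratio
    0.12, chewing oscillation of amplitude 0.06 at 1.5 Hz, bites opening
    the mouth by 0.55 over 0.6 s, at least 2 s apart, 30 frames/s video.
    """

    fps: float = 30.0
    duration_s: Optional[float] = None  # None: just long enough for the bites
    baseline: float = 0.12
    noise_sd: float = 0.01
    chew_amplitude: float = 0.06
    chew_freq_hz: float = 1.5
    n_bites: int = 20
    bite_amplitude: float = 0.55
    bite_width_s: float = 0.6
    bite_gap_s: float = 2.0
    seed: int = 0

    lead_s: float = 1.0  # quiet margin before the first and after the last bite

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.baseline < 0 or self.noise_sd < 0:
            raise ConfigError("fps must be > 0 and baseline/noise_sd >= 0")
        if self.n_bites < 0:
            raise ConfigError("n_bites must be >= 0")
        if self.bite_amplitude <= 0 or self.bite_width_s <= 0 or self.bite_gap_s <= 0:
            raise ConfigError("bite amplitude, width and gap must be > 0")
        if not 3 * self.noise_sd + self.chew_amplitude < self.bite_amplitude:
            raise ConfigError(
                "planted bites must be separable: need "
                "3*noise_sd + chew_amplitude < bite_amplitude"
            )
        needed = self._needed_duration()
        if self.duration_s is None:
            self.duration_s = needed
        elif self.duration_s < needed:
            raise ConfigError(
                f"{self.n_bites} bites with gap {self.bite_gap_s}s and width "
                f"{self.bite_width_s}s need at least {needed:.1f}s; got {self.duration_s}s"
            )

    def _needed_duration(self) -> float:
        spacing = self.bite_width_s + self.bite_gap_s
        return 2 * self.lead_s + max(self.n_bites, 1) * spacing


@dataclass
class GroundTruth:
    """What the generator actually planted in one trace."""

    onset_times: np.ndarray  # bite-bump start times, seconds
    onset_frames: np.ndarray
    band: Tuple[float, float]  # thresholds that recover the count exactly (noise-free)
    annotated_bites: int

    def __post_init__(self) -> None:
        self.onset_times = np.asarray(self.onset_times, dtype=float)
        self.onset_frames = np.asarray(self.onset_frames, dtype=int)
        if self.annotated_bites != len(self.onset_times):
            raise ValueError("annotated_bites must match the planted onsets")


def _bump_profile(t: np.ndarray, onset: float, width: float) -> np.ndarray:
    """Raised-cosine bump on [onset, onset + width], peak 1 at the centre."""
    phase = (t - onset) / width
    inside = (phase >= 0) & (phase <= 1)
    out = np.zeros_like(t)
    out[inside] = 0.5 * (1 - np.cos(2 * np.pi * phase[inside]))
    return out


def _plant_onsets(config: TraceConfig, rng: np.random.Generator) -> np.ndarray:
    spacing = config.bite_width_s + config.bite_gap_s
    jitter = rng.random(config.n_bites) * 0.5 * config.bite_width_s
    onsets = config.lead_s + spacing * np.arange(config.n_bites) + jitter
    if config.n_bites and onsets[-1] + config.bite_width_s + config.lead_s > config.duration_s:
        raise ConfigError("bites do not fit in the requested duration")
    return onsets


def simulate_ratio_trace(
    config: TraceConfig,
    video_id: str = "sim",
    participant_id: str = "simP",
    smooth_window: int = 5,
) -> Tuple[RatioSeries, GroundTruth]:
    """Simulate one raw (unsmoothed) mouth-ratio trace with ground truth.

    The reported threshold band is computed from the noise-free rendering
    of the same trace after the detector's ``smooth_window``-frame trailing
    average: its lower edge is just above anything the baseline and chewing
    can reach, its upper edge just below the weakest smoothed bite peak, so
    in the noise-free limit any threshold inside the band recovers exactly
    the planted count.  Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fps))
    t = np.arange(n) / config.fps
    onsets = _plant_onsets(config, rng)

    bumps = np.zeros(n)
    support = np.zeros(n, dtype=bool)
    for onset in onsets:
        profile = _bump_profile(t, onset, config.bite_width_s)
        bumps += config.bite_amplitude * profile
        support |= profile > 0

    # chewing pauses around each bite: gate off within half a bump width
    pad = int(np.ceil(0.5 * config.bite_width_s * config.fps))
    gated = support.copy()
    if pad and support.any():
        kernel = np.ones(2 * pad + 1)
        gated = np.convolve(support.astype(float), kernel, mode="same") > 0
    chew = config.chew_amplitude * np.sin(2 * np.pi * config.chew_freq_hz * t)
    chew[gated] = 0.0

    clean = config.baseline + chew + bumps
    noisy = clean + config.noise_sd * rng.standard_normal(n)
    values = np.clip(noisy, 0.0, None)

    band = _threshold_band(clean, support, onsets, config, smooth_window)
    truth = GroundTruth(
        onset_times=onsets,
        onset_frames=np.floor(onsets * config.fps).astype(int),
        band=band,
        annotated_bites=config.n_bites,
    )
    series = RatioSeries(
        video_id=video_id,
        participant_id=participant_id,
        fps=config.fps,
        ratio=values,
        smoothed=False,
    )
    return series, truth


def _threshold_band(
    clean: np.ndarray,
    support: np.ndarray,
    onsets: np.ndarray,
    config: TraceConfig,
    smooth_window: int,
) -> Tuple[float, float]:
    import pandas as pd

    smoothed = pd.Series(clean).rolling(smooth_window, min_periods=1).mean().to_numpy()
    # the trailing window smears each bump smooth_window frames to the right
    tail = support.copy()
    for k in range(1, smooth_window + 1):
        tail[k:] |= support[:-k]
    outside = ~tail
    lo = float(smoothed[outside].max()) if outside.any() else config.baseline
    if len(onsets) == 0:
        return (lo + 1e-9 * config.bite_amplitude, float("inf"))
    fps, width = config.fps, config.bite_width_s
    peaks = []
    for onset in onsets:
        start = int(np.floor(onset * fps))
        stop = min(int(np.ceil((onset + width) * fps)) + smooth_window, len(smoothed))
        peaks.append(smoothed[start:stop].max())
    hi = float(min(peaks))
    if not lo < hi:
        raise ConfigError("no separating threshold band exists for this configuration")
    # the exact open separating interval, pulled in only by a float-safety sliver:
    # in the noise-free limit every threshold inside recovers the planted count
    eps = 1e-9 * (hi - lo)
    return (lo + eps, hi - eps)


def simulate_landmark_series(
    config: TraceConfig,
    video_id: str = "sim",
    participant_id: str = "simP",
    keymap: MouthKeypointMap = DEFAULT_KEYMAP,
) -> Tuple[LandmarkSeries, GroundTruth]:
    """Render a full 468-point landmark stream encoding a simulated trace.

    The mouth corners sit a fixed width apart and the lip key points are
    separated vertically by (trace value x mouth width), so the mouth
    ratio of each frame reproduces the simulated trace exactly; the other
    464 mesh points are arbitrary but fixed valid coordinates.
    """
    trace, truth = simulate_ratio_trace(config, video_id, participant_id)
    n = len(trace)
    face_rng = np.random.default_rng(config.seed + 1)
    base = np.empty((N_MESH_POINTS, 3))
    base[:, 0] = face_rng.random(N_MESH_POINTS)
    base[:, 1] = face_rng.random(N_MESH_POINTS)
    base[:, 2] = face_rng.random(N_MESH_POINTS) * 0.1 - 0.05

    points = np.repeat(base[None, :, :], n, axis=0)
    width = 0.2
    left = np.array([0.4, 0.5, 0.0])
    right = np.array([0.6, 0.5, 0.0])
    points[:, keymap.left_corner_index] = left
    points[:, keymap.right_corner_index] = right
    half_sep = 0.5 * width * trace.ratio
    points[:, keymap.upper_lip_index, 0] = 0.5
    points[:, keymap.upper_lip_index, 1] = 0.5 - half_sep
    points[:, keymap.upper_lip_index, 2] = 0.0
    points[:, keymap.lower_lip_index, 0] = 0.5
    points[:, keymap.lower_lip_index, 1] = 0.5 + half_sep
    points[:, keymap.lower_lip_index, 2] = 0.0

    series = LandmarkSeries(
        video_id=video_id,
        participant_id=participant_id,
        fps=config.fps,
        points=points,
        face_detected=np.ones(n, dtype=bool),
        time_s=trace.time_s.copy(),
    )
    return series, truth


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class Cohort:
    """A simulated annotated cohort with full ground truth."""

    series: list  # RatioSeries per video
    annotations: list  # AnnotationRecord per video
    ground_truth: Dict[str, GroundTruth]  # by video_id

    def participant_bands(self) -> Dict[str, Tuple[float, float]]:
        """Per-participant separating band: the intersection of the
        participant's per-video bands (valid for every one of their meals)."""
        bands: Dict[str, Tuple[float, float]] = {}
        for record in self.annotations:
            lo, hi = self.ground_truth[record.video_id].band
            if record.participant_id in bands:
                cur_lo, cur_hi = bands[record.participant_id]
                bands[record.participant_id] = (max(cur_lo, lo), min(cur_hi, hi))
            else:
                bands[record.participant_id] = (lo, hi)
        for pid, (lo, hi) in bands.items():
            if not lo < hi:
                raise ConfigError(f"participant {pid}: per-video bands do not intersect")
        return bands


def simulate_cohort(
    n_participants: int = 15,
    videos_per_participant: Union[None, int, Tuple[int, int], Sequence[int]] = None,
    template: Optional[TraceConfig] = None,
    seed: int = 0,
    mean_bites: float = 41.0,
    sd_bites: float = 15.0,
    jitter: bool = True,
) -> Cohort:
    """Simulate a whole annotated cohort with per-participant signal jitter.

    Defaults mirror the validation study's shape: 15 participants with
    6-14 meal videos each (164 in total) and per-video annotated counts
    around 41 +/- 15 bites (clipped to [5, 90], so a few sub-10-bite meals
    exercise the meal filter).  Each participant gets jittered baseline,
    chew and bite amplitudes — hence a distinct true threshold band — and
    each video a texture condition: soft-texture meals get wider bite
    bumps spaced further apart (large bites, fewer per minute), hard ones
    narrower bumps closer together.  ``jitter=False`` keeps the template's
    signal parameters for everyone (a homogeneous cohort, where one shared
    threshold is perfect for all participants).
    """
    if n_participants < 1:
        raise ConfigError("need at least one participant")
    template = template or TraceConfig()
    rng = np.random.default_rng(seed)

    if videos_per_participant is None:
        counts = [STUDY_VIDEO_COUNTS[i % len(STUDY_VIDEO_COUNTS)] for i in range(n_participants)]
    elif isinstance(videos_per_participant, int):
        counts = [videos_per_participant] * n_participants
    elif isinstance(videos_per_participant, tuple) and len(videos_per_participant) == 2:
        lo, hi = videos_per_participant
        counts = list(rng.integers(lo, hi + 1, n_participants))
    else:
        counts = list(videos_per_participant)
        if len(counts) != n_participants:
            raise ConfigError("per-participant video counts must match n_participants")

    series: list = []
    annotations: list = []
    truths: Dict[str, GroundTruth] = {}
    for p in range(n_participants):
        pid = f"P{p + 1:02d}"
        if not jitter:
            jittered = replace(template, duration_s=None)
        else:
            for _ in range(100):  # reject jitter that breaks separability
                jittered = replace(
                    template,
                    baseline=float(rng.uniform(0.08, 0.16)),
                    bite_amplitude=float(rng.uniform(0.45, 0.70)),
                    chew_amplitude=float(rng.uniform(0.04, 0.08)),
                    chew_freq_hz=float(rng.uniform(1.0, 2.0)),
                    duration_s=None,
                )
                if 3 * jittered.noise_sd + jittered.chew_amplitude < jittered.bite_amplitude:
                    break
            else:  # pragma: no cover - unreachable with sane templates
                raise ConfigError("could not draw a separable participant configuration")

        for v in range(counts[p]):
            vid = f"{pid}-v{v + 1:02d}"
            texture = TEXTURE_CONDITIONS[(p + v) % 2]
            if texture == "fast_soft":  # large bites, fewer per minute
                width, gap = template.bite_width_s * 1.4, template.bite_gap_s * 1.3
            else:  # small bites, more per minute
                width, gap = template.bite_width_s * 0.8, template.bite_gap_s * 0.85
            n_bites = int(np.clip(np.round(rng.normal(mean_bites, sd_bites)), 5, 90))
            config = replace(
                jittered,
                n_bites=n_bites,
                bite_width_s=width,
                bite_gap_s=gap,
                duration_s=None,
                seed=int(rng.integers(2**31)),
            )
            trace, truth = simulate_ratio_trace(config, video_id=vid, participant_id=pid)
            series.append(trace)
            truths[vid] = truth
            annotations.append(
                AnnotationRecord(
                    video_id=vid,
                    participant_id=pid,
                    meal_type=MEAL_TYPES[v % len(MEAL_TYPES)],
                    texture_condition=texture,
                    processing_condition=PROCESSING_CONDITIONS[v % 2],
                    annotated_bites=truth.annotated_bites,
                )
            )
    return Cohort(series=series, annotations=annotations, ground_truth=truths)
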