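"""Per-participant threshold tuning and leave-one-out transfer.

The bite counter has a single hyperparameter, the mouth-ratio threshold θ,
tuned separately for every participant against their manually annotated
bite counts.  Three search strategies are offered over the same
1-D objective — grid search, random search, and Bayesian (sequential
model-based) optimisation — each scored by k-fold cross-validation with
the negative mean absolute count error.  For a participant without any
annotation, a threshold is transferred by leave-one-out averaging of the
thresholds tuned on everyone else.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import scipy.stats
import yaml
from sklearn.model_selection import GridSearchCV, KFold, RandomizedSearchCV

from .detector import DEFAULT_WINDOW, ThresholdBiteCounter, count_bites
from .errors import ConfigError, PairingError, TuningError
from .io import AnnotationRecord
from .ratio import RatioSeries, smooth as _smooth

SEARCH_METHODS = ("grid", "random", "bayesian")


@dataclass
class SearchConfig:
    """Search space and evaluation settings for threshold tuning.

    θ bounds default to [0.05, 1.5]: closed-mouth ratios sit well below 1,
    bite openings near or above it, so the band safely brackets any
    plausible per-participant threshold.
    """

    method: str = "random"
    theta_lo: float = 0.05
    theta_hi: float = 1.5
    grid_step: float = 0.01
    n_iterations: Optional[int] = None  # default 60 random / 30 bayesian
    k_min: int = 2
    k_max: int = 5
    min_bites: int = 10
    window: int = DEFAULT_WINDOW
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in SEARCH_METHODS:
            raise ConfigError(f"unknown method {self.method!r}; expected one of {SEARCH_METHODS}")
        if not self.theta_lo < self.theta_hi:
            raise ConfigError("degenerate bounds: need theta_lo < theta_hi")
        if self.theta_lo <= 0:
            raise ConfigError("theta_lo must be > 0")
        if self.grid_step <= 0:
            raise ConfigError("grid_step must be > 0")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ConfigError("need 2 <= k_min <= k_max")
        if self.n_iterations is None:
            self.n_iterations = 60 if self.method == "random" else 30
        if self.n_iterations < 1:
            raise ConfigError("n_iterations must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "SearchConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump({k: v for k, v in vars(self).items()}, fh, sort_keys=False)


@dataclass
class SearchResult:
    """Tuned threshold for one participant under one search method."""

    participant_id: str
    method: str
    best_theta: float
    cv_score: float  # negative mean |predicted - annotated| bites; 0 is perfect
    fold_scores: np.ndarray
    candidates: np.ndarray
    candidate_scores: np.ndarray
    n_videos: int
    cv_k: int
    seed: int

    def __post_init__(self) -> None:
        if self.cv_score > 1e-12:
            raise ValueError("cv_score is a negative-error score; it cannot exceed 0")


def _pair(
    videos: Sequence[RatioSeries], annotations: Sequence[AnnotationRecord]
) -> list:
    by_id = {a.video_id: a for a in annotations}
    pairs = []
    for v in videos:
        if v.video_id not in by_id:
            raise PairingError(f"video {v.video_id!r} has no annotation record")
        pairs.append((v, by_id[v.video_id]))
    return pairs


def score(
    theta: float,
    videos: Sequence[RatioSeries],
    annotations: Sequence[AnnotationRecord],
    window: int = DEFAULT_WINDOW,
) -> float:
    """Negative mean absolute difference between predicted and annotated
    counts over the given videos; 0 is perfect."""
    pairs = _pair(videos, annotations)
    if not pairs:
        raise ValueError("need at least one video to score")
    errors = [abs(count_bites(v, theta, window) - a.annotated_bites) for v, a in pairs]
    return -float(np.mean(errors))


def filter_meals(
    videos: Sequence[RatioSeries],
    annotations: Sequence[AnnotationRecord],
    min_bites: int = 10,
) -> tuple:
    """Drop meals with fewer than ``min_bites`` annotated bites (strictly
    less than; a 10-bite meal at the default is kept).  Small meals such as
    desserts carry too few events to inform the threshold."""
    pairs = _pair(videos, annotations)
    kept = [(v, a) for v, a in pairs if a.annotated_bites >= min_bites]
    if not kept:
        raise TuningError(f"no meals with >= {min_bites} annotated bites; cannot tune")
    videos_out = [v for v, _ in kept]
    annos_out = [a for _, a in kept]
    return videos_out, annos_out


def cv_folds(n_videos: int, k_min: int = 2, k_max: int = 5) -> int:
    """Number of CV folds for a participant: clamp the video count into
    [k_min, k_max] (so k never exceeds the number of samples)."""
    if n_videos < 2:
        warnings.warn(
            f"only {n_videos} video(s); falling back to scoring without cross-validation",
            stacklevel=2,
        )
        return 1
    return min(k_max, max(k_min, n_videos), n_videos)


def _cv_splits(n: int, k: int, seed: int) -> list:
    if k <= 1:
        return [(np.arange(n), np.arange(n))]  # no-CV fallback: score on everything
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return list(kf.split(np.arange(n)))


def _best_by_smallest_theta(candidates: np.ndarray, mean_scores: np.ndarray) -> int:
    """Index of the best score; exact ties broken toward the smaller θ."""
    best = np.max(mean_scores)
    tied = np.flatnonzero(mean_scores == best)
    return int(tied[np.argmin(candidates[tied])])


def tune(
    videos: Sequence[RatioSeries],
    annotations: Sequence[AnnotationRecord],
    config: SearchConfig,
) -> SearchResult:
    """Tune θ for one participant's videos against annotated counts.

    Meals below the bite filter are dropped first; candidate thresholds are
    proposed by the configured method and each is scored by k-fold CV (mean
    over folds of the validation-fold score).  Grid and random search run
    through scikit-learn's searchers; ties are broken toward the smaller θ.
    """
    participant_ids = {v.participant_id for v in videos}
    if len(participant_ids) != 1:
        raise TuningError(f"tune expects one participant's videos; got {sorted(participant_ids)}")
    participant_id = participant_ids.pop()

    videos, annotations = filter_meals(videos, annotations, config.min_bites)
    if len(videos) < 2:
        raise TuningError("need at least 2 videos after meal filtering to tune")
    # smooth once up front so each candidate evaluation skips the rolling mean
    pairs = _pair(videos, annotations)
    X = [v if v.smoothed else _smooth(v, config.window) for v, _ in pairs]
    y = np.array([a.annotated_bites for _, a in pairs])
    k = cv_folds(len(X), config.k_min, config.k_max)
    estimator = ThresholdBiteCounter(window=config.window)

    if config.method == "grid":
        candidates = _grid_candidates(config)
        cv_results = _sklearn_search(
            GridSearchCV(estimator, {"threshold": list(candidates)}, cv=_cv_splits(len(X), k, config.seed)),
            X, y,
        )
    elif config.method == "random":
        cv_results = _sklearn_search(
            RandomizedSearchCV(
                estimator,
                {"threshold": scipy.stats.uniform(config.theta_lo, config.theta_hi - config.theta_lo)},
                n_iter=config.n_iterations,
                cv=_cv_splits(len(X), k, config.seed),
                random_state=config.seed,
            ),
            X, y,
        )
    else:
        cv_results = _bayesian_search(X, y, k, config)

    candidates, mean_scores, fold_scores = cv_results
    best = _best_by_smallest_theta(candidates, mean_scores)
    return SearchResult(
        participant_id=participant_id,
        method=config.method,
        best_theta=float(candidates[best]),
        cv_score=float(mean_scores[best]),
        fold_scores=fold_scores[best],
        candidates=candidates,
        candidate_scores=mean_scores,
        n_videos=len(X),
        cv_k=k,
        seed=config.seed,
    )


def _grid_candidates(config: SearchConfig) -> np.ndarray:
    n_steps = int(np.floor((config.theta_hi - config.theta_lo) / config.grid_step + 1e-9))
    return config.theta_lo + config.grid_step * np.arange(n_steps + 1)


def _sklearn_search(searcher, X, y) -> tuple:
    searcher.fit(X, y)
    res = searcher.cv_results_
    candidates = np.array([p["threshold"] for p in res["params"]], dtype=float)
    mean_scores = np.asarray(res["mean_test_score"], dtype=float)
    n_splits = searcher.n_splits_
    fold_scores = np.column_stack(
        [res[f"split{i}_test_score"] for i in range(n_splits)]
    )
    return candidates, mean_scores, fold_scores


def _cv_objective(theta, X, y, splits, window):
    est = ThresholdBiteCounter(threshold=float(theta), window=window)
    est.fit(X, y)
    return np.array(
        [est.score([X[i] for i in test], y[test]) for _, test in splits], dtype=float
    )


def _bayesian_search(X, y, k: int, config: SearchConfig) -> tuple:
    """1-D sequential model-based optimisation of the CV score.

    A Gaussian-process surrogate (Matern 5/2 + white noise) is fitted to
    the evaluated (θ, score) pairs and the next candidate maximises
    expected improvement over a dense random candidate set.  The first
    third of the budget (at least 5 points) is uniform exploration.
    """
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import Matern, WhiteKernel

    rng = np.random.default_rng(config.seed)
    splits = _cv_splits(len(X), k, config.seed)
    lo, hi = config.theta_lo, config.theta_hi
    n_init = min(max(5, config.n_iterations // 3), config.n_iterations)

    thetas: list = list(lo + (hi - lo) * rng.random(n_init))
    fold_scores = [_cv_objective(t, X, y, splits, config.window) for t in thetas]
    scores = [fs.mean() for fs in fold_scores]

    span = hi - lo
    kernel = Matern(length_scale=span / 5, nu=2.5) + WhiteKernel(
        noise_level=1e-2, noise_level_bounds=(1e-8, 1e2)
    )
    while len(thetas) < config.n_iterations:
        gp = GaussianProcessRegressor(
            kernel=kernel, normalize_y=True, random_state=config.seed, alpha=1e-10
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # GP convergence chatter on flat objectives
            gp.fit(np.asarray(thetas).reshape(-1, 1), np.asarray(scores))
        pool = lo + span * rng.random(512)
        mu, sd = gp.predict(pool.reshape(-1, 1), return_std=True)
        best_so_far = max(scores)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (mu - best_so_far) / sd
            ei = (mu - best_so_far) * scipy.stats.norm.cdf(z) + sd * scipy.stats.norm.pdf(z)
        ei[sd == 0] = 0.0
        nxt = float(pool[np.argmax(ei)])
        thetas.append(nxt)
        fs = _cv_objective(nxt, X, y, splits, config.window)
        fold_scores.append(fs)
        scores.append(fs.mean())

    return (
        np.asarray(thetas, dtype=float),
        np.asarray(scores, dtype=float),
        np.vstack(fold_scores),
    )


def tune_cohort(
    videos: Sequence[RatioSeries],
    annotations: Sequence[AnnotationRecord],
    config: SearchConfig,
) -> Dict[str, SearchResult]:
    """Tune every annotated participant in a cohort; returns results keyed
    by participant id.  Participants whose meals all fall below the bite
    filter are skipped with a warning."""
    by_participant: Dict[str, list] = {}
    for v in videos:
        by_participant.setdefault(v.participant_id, []).append(v)
    results: Dict[str, SearchResult] = {}
    for pid in sorted(by_participant):
        try:
            results[pid] = tune(by_participant[pid], annotations, config)
        except TuningError as exc:
            warnings.warn(f"participant {pid}: {exc}", stacklevel=2)
    return results


def loocv_transfer(
    results: Mapping[str, SearchResult] | Sequence[SearchResult],
    target_participant: str,
) -> float:
    """Threshold for a participant with no annotation: the unweighted mean
    of every *other* participant's tuned threshold (leave-one-out).

    The target's own result, if present, is always excluded, so the
    transferred threshold never depends on the target's data.
    """
    if isinstance(results, Mapping):
        results = list(results.values())
    others = [r.best_theta for r in results if r.participant_id != target_participant]
    if len(others) < 1 or len(results) < 2:
        raise TuningError("leave-one-out transfer needs results from at least 2 participants")
    return float(np.mean(others))


def loocv_transfer_all(
    results: Mapping[str, SearchResult] | Sequence[SearchResult]
) -> Dict[str, float]:
    """Transferred threshold for every participant in the cohort: n
    participants yield n leave-one-out averages, each excluding exactly its
    own participant."""
    if isinstance(results, Mapping):
        results = list(results.values())
    return {r.participant_id: loocv_transfer(results, r.participant_id) for r in results}


def results_to_frame(results: Mapping[str, SearchResult] | Sequence[SearchResult]):
    """Thresholds table: participant_id,method,best_theta,cv_score,seed."""
    import pandas as pd

    if isinstance(results, Mapping):
        results = list(results.values())
    return pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "method": r.method,
                "best_theta": r.best_theta,
                "cv_score": r.cv_score,
                "seed": r.seed,
            }
            for r in results
        ]
    )
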