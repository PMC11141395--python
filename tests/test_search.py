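"""Threshold tuning (grid/random/Bayesian) and leave-one-out transfer."""
import numpy as np
import pytest
from sklearn.model_selection import KFold

import bitecount as bc
from bitecount.errors import ConfigError, PairingError, TuningError
from bitecount.io import AnnotationRecord
from bitecount.search import (
    SearchConfig,
    SearchResult,
    _grid_candidates,
    cv_folds,
    filter_meals,
    loocv_transfer,
    loocv_transfer_all,
    score,
    tune,
    tune_cohort,
)

from conftest import make_ratio


def annotate(video_id, bites, participant="p"):
    return AnnotationRecord(video_id, participant, "lunch", "fast_soft", "processed", bites)


def pulses(n, video_id="v"):
    """A series with exactly n well-separated unit pulses (count n at any
    threshold in (0, 1))."""
    values = np.zeros(3 * n + 1)
    values[1::3] = 1.0
    return make_ratio(values, video_id=video_id)


def test_score_examples():
    videos = [pulses(10, "a"), pulses(20, "b")]
    exact = [annotate("a", 10), annotate("b", 20)]
    assert score(0.5, videos, exact) == 0.0
    off = [annotate("a", 12), annotate("b", 18)]
    assert score(0.5, videos, off) == pytest.approx(-2.0)
    with pytest.raises(PairingError):
        score(0.5, videos, [annotate("a", 10)])


def test_filter_meals_boundary():
    videos = [pulses(9, "a"), pulses(10, "b"), pulses(25, "c")]
    annos = [annotate("a", 9), annotate("b", 10), annotate("c", 25)]
    kept_videos, kept_annos = filter_meals(videos, annos, min_bites=10)
    assert [v.video_id for v in kept_videos] == ["b", "c"]  # 10-bite meal is kept
    with pytest.raises(TuningError):
        filter_meals(videos[:1], annos[:1], min_bites=10)


@pytest.mark.parametrize("n,k", [(14, 5), (5, 5), (3, 3), (2, 2)])
def test_cv_folds_clamp(n, k):
    assert cv_folds(n) == k


def test_cv_folds_single_video_falls_back():
    with pytest.warns(UserWarning, match="without cross-validation"):
        assert cv_folds(1) == 1


def test_search_config_validation():
    with pytest.raises(ConfigError):
        SearchConfig(theta_lo=0.5, theta_hi=0.5)
    with pytest.raises(ConfigError):
        SearchConfig(method="annealing")
    assert SearchConfig(method="random").n_iterations == 60
    assert SearchConfig(method="bayesian").n_iterations == 30


def test_search_config_yaml_round_trip(tmp_path):
    cfg = SearchConfig(method="grid", theta_lo=0.1, theta_hi=0.9, grid_step=0.05, seed=3)
    cfg.to_yaml(tmp_path / "c.yaml")
    assert SearchConfig.from_yaml(tmp_path / "c.yaml") == cfg


def participant_videos(cohort, pid):
    return [s for s in cohort.series if s.participant_id == pid]


def test_grid_search_equals_exhaustive_argmax(noise_free_cohort):
    """Grid search through the CV machinery must agree with a brute-force
    evaluation of every grid candidate (smallest θ wins ties)."""
    cohort = noise_free_cohort
    config = SearchConfig(method="grid", theta_lo=0.1, theta_hi=0.9, grid_step=0.02, seed=11)
    videos = participant_videos(cohort, "P01")
    result = tune(videos, cohort.annotations, config)

    videos_f, annos_f = filter_meals(videos, cohort.annotations, config.min_bites)
    k = cv_folds(len(videos_f))
    splits = list(KFold(k, shuffle=True, random_state=config.seed).split(videos_f))
    candidates = _grid_candidates(config)
    means = []
    for theta in candidates:
        fold_scores = [
            score(theta, [videos_f[i] for i in test], annos_f) for _, test in splits
        ]
        means.append(np.mean(fold_scores))
    means = np.asarray(means)
    best = means.max()
    expected_theta = candidates[means == best].min()
    assert result.best_theta == pytest.approx(expected_theta, abs=1e-12)
    assert result.cv_score == pytest.approx(best, abs=1e-12)


@pytest.mark.parametrize("method", ["grid", "random", "bayesian"])
def test_all_methods_recover_true_band(noise_free_cohort, method):
    cohort = noise_free_cohort
    bands = cohort.participant_bands()
    for pid, (lo, hi) in bands.items():
        result = tune(
            participant_videos(cohort, pid),
            cohort.annotations,
            SearchConfig(method=method, seed=1),
        )
        assert lo <= result.best_theta <= hi
        assert result.cv_score == 0.0
        assert result.method == method and result.participant_id == pid


@pytest.mark.parametrize("method", ["random", "bayesian"])
def test_seeded_search_is_deterministic(noise_free_cohort, method):
    videos = participant_videos(noise_free_cohort, "P02")
    config = SearchConfig(method=method, seed=5, n_iterations=15)
    first = tune(videos, noise_free_cohort.annotations, config)
    second = tune(videos, noise_free_cohort.annotations, config)
    assert first.best_theta == second.best_theta
    np.testing.assert_array_equal(first.candidates, second.candidates)


def test_tune_requires_single_participant(noise_free_cohort):
    with pytest.raises(TuningError):
        tune(noise_free_cohort.series, noise_free_cohort.annotations, SearchConfig())


def test_tie_break_prefers_smaller_theta():
    """Every candidate scores 0 on these pulse traces, so the reported
    best must be the smallest candidate."""
    videos = [pulses(12, "a"), pulses(15, "b")]
    annos = [annotate("a", 12), annotate("b", 15)]
    config = SearchConfig(method="grid", theta_lo=0.1, theta_hi=0.9, grid_step=0.1, seed=0)
    result = tune(videos, annos, config)
    assert result.best_theta == pytest.approx(0.1)
    assert result.cv_score == 0.0


# --- leave-one-out transfer ----------------------------------------------


def _result(pid, theta):
    return SearchResult(
        participant_id=pid, method="random", best_theta=theta, cv_score=0.0,
        fold_scores=np.zeros(2), candidates=np.array([theta]),
        candidate_scores=np.zeros(1), n_videos=2, cv_k=2, seed=0,
    )


def test_loocv_transfer_arithmetic():
    same = {f"p{i}": _result(f"p{i}", 0.4) for i in range(14)}
    assert loocv_transfer(same, "p0") == pytest.approx(0.4)
    spread = {f"p{i}": _result(f"p{i}", float(i)) for i in range(1, 16)}
    assert loocv_transfer(spread, "p15") == pytest.approx(7.5)  # mean of 1..14
    with pytest.raises(TuningError):
        loocv_transfer({"p1": _result("p1", 0.4)}, "p1")


def test_loocv_transfer_excludes_target_only():
    results = {f"p{i}": _result(f"p{i}", float(i)) for i in range(1, 16)}
    transferred = loocv_transfer_all(results)
    assert len(transferred) == 15
    assert len(set(transferred.values())) == 15  # 15 distinct averages
    # independence from the target's own threshold
    perturbed = dict(results)
    perturbed["p3"] = _result("p3", 99.0)
    assert loocv_transfer(perturbed, "p3") == transferred["p3"]


def test_cohort_tune_and_transfer_exact_on_homogeneous_cohort():
    """Identical signal parameters across participants: the transferred
    (averaged) threshold stays inside everyone's band, so per-video counts
    are exact."""
    template = bc.TraceConfig(noise_sd=0.0)
    cohort = bc.simulate_cohort(
        n_participants=3, videos_per_participant=3, template=template, seed=3,
        mean_bites=13, sd_bites=2, jitter=False,
    )
    results = tune_cohort(
        cohort.series, cohort.annotations, SearchConfig(method="random", seed=2, n_iterations=25)
    )
    transferred = loocv_transfer_all(results)
    annos = {a.video_id: a for a in cohort.annotations}
    for series in cohort.series:
        theta = transferred[series.participant_id]
        assert bc.count_bites(series, theta) == annos[series.video_id].annotated_bites
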