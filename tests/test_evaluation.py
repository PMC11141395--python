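"""Accuracy metric, report tables and descriptive statistics."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import bitecount as bc
from bitecount.errors import UndefinedAccuracyError
from bitecount.evaluation import round_half_up


def test_round_half_up():
    assert round_half_up(76.45) == 76.5  # not banker's rounding
    assert round_half_up(2.25) == 2.3
    assert round_half_up(-2.25) == -2.3
    assert round_half_up(94.58483) == 94.6


def test_accuracy_basic_values():
    assert bc.accuracy(554, 524) == pytest.approx(94.5848, abs=1e-4)
    assert bc.accuracy(100, 100) == 100.0
    assert bc.accuracy(100, 0) == 0.0
    with pytest.raises(UndefinedAccuracyError):
        bc.accuracy(0, 10)


def test_accuracy_fold_back_warns_and_clamps():
    with pytest.warns(UserWarning, match="folded-back"):
        assert bc.accuracy(502, 1334) == pytest.approx(65.7371, abs=1e-4)
    with pytest.warns(UserWarning):
        assert bc.accuracy(502, 1334, clamp_at_zero=True) == 0.0


@given(st.integers(1, 2000), st.integers(0, 2000))
def test_accuracy_matches_formula(t, p):
    expected = abs(100 - 100 * abs(p - t) / t)
    assert bc.accuracy(t, p, warn_foldback=False) == pytest.approx(expected)


@given(st.integers(1, 1000), st.integers(0, 1000))
def test_accuracy_symmetric_and_monotone(t, d):
    """accuracy(T, T)=100; symmetric in |P-T|; decreasing until P=2T."""
    assert bc.accuracy(t, t) == 100.0
    d = min(d, t)
    assert bc.accuracy(t, t + d, warn_foldback=False) == pytest.approx(
        bc.accuracy(t, t - d, warn_foldback=False)
    )
    if d >= 1:
        assert bc.accuracy(t, t + d, warn_foldback=False) < bc.accuracy(
            t, t + d - 1, warn_foldback=False
        )


def _tables(counts):
    annotations = pd.DataFrame(
        {
            "video_id": [f"v{i}" for i in range(len(counts))],
            "participant_id": [pid for pid, _, _ in counts],
            "annotated_bites": [t for _, t, _ in counts],
        }
    )
    predictions = pd.DataFrame(
        {
            "video_id": [f"v{i}" for i in range(len(counts))],
            "method": "grid",
            "predicted_bites": [p for _, _, p in counts],
        }
    )
    return annotations, predictions


def test_participant_report_pools_counts():
    annotations, predictions = _tables(
        [("a", 30, 25), ("a", 20, 25), ("b", 40, 50)]
    )
    report = bc.participant_report(annotations, predictions)
    rows = report.rows.set_index("participant_id")
    assert rows.loc["a", "annotated"] == 50 and rows.loc["a", "predicted"] == 50
    assert rows.loc["a", "accuracy"] == 100.0  # pooled, not mean of per-video
    assert rows.loc["b", "accuracy"] == 75.0
    summary = report.summary.iloc[0]
    assert summary["total_annotated"] == 90 and summary["total_predicted"] == 100
    assert summary["mean_accuracy"] == round_half_up((100.0 + 75.0) / 2)


def test_participant_report_per_video_variant():
    annotations, predictions = _tables([("a", 30, 25), ("a", 20, 25)])
    report = bc.participant_report(annotations, predictions, per_video=True)
    expected = (bc.accuracy(30, 25) + bc.accuracy(20, 25)) / 2
    assert report.rows["accuracy"].iloc[0] == round_half_up(expected)


def test_participant_report_single_group_std():
    annotations, predictions = _tables([("a", 30, 30)])
    with pytest.warns(UserWarning, match="single group"):
        report = bc.participant_report(annotations, predictions)
    assert report.summary["std_accuracy"].iloc[0] == 0.0
    assert report.rows["accuracy"].iloc[0] == 100.0


@given(st.integers(0, 2**16))
def test_participant_report_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    counts = [
        (f"p{i % 4}", int(rng.integers(20, 80)), int(rng.integers(0, 120)))
        for i in range(12)
    ]
    annotations, predictions = _tables(counts)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", UserWarning)  # fold-back rows expected
        report = bc.participant_report(annotations, predictions, round_to=None)
    for pid, grp in report.rows.groupby("participant_id"):
        t = sum(c[1] for c in counts if c[0] == pid)
        p = sum(c[2] for c in counts if c[0] == pid)
        assert grp["accuracy"].iloc[0] == pytest.approx(
            bc.accuracy(t, p, warn_foldback=False)
        )


def test_pooled_accuracy_by_condition():
    annotations = pd.DataFrame(
        {
            "video_id": ["a", "b", "c"],
            "texture_condition": ["fast_soft", "fast_soft", "slow_hard"],
            "annotated_bites": [30, 20, 40],
        }
    )
    predictions = pd.DataFrame(
        {"video_id": ["a", "b", "c"], "method": "m", "predicted_bites": [25, 25, 40]}
    )
    table = bc.pooled_accuracy(annotations, predictions).set_index("group")
    assert table.loc["fast_soft", "accuracy"] == 100.0  # pooled 50 vs 50
    assert table.loc["slow_hard", "accuracy"] == 100.0
    with pytest.raises(ValueError):
        bc.pooled_accuracy(annotations, predictions, group_by="missing_column")


def test_pooled_accuracy_warns_on_empty_group():
    annotations = pd.DataFrame(
        {
            "video_id": ["a", "b"],
            "texture_condition": ["fast_soft", "slow_hard"],
            "annotated_bites": [30, 20],
        }
    )
    predictions = pd.DataFrame({"video_id": ["a"], "method": "m", "predicted_bites": [30]})
    with pytest.warns(UserWarning, match="empty group"):
        table = bc.pooled_accuracy(annotations, predictions)
    assert table["group"].tolist() == ["fast_soft"]


def test_summary_stats_small_and_study_scale():
    stats = bc.summary_stats([1, 2, 3])
    assert stats["mean"] == 2 and stats["median"] == 2 and stats["range"] == 2
    # a 164-video cohort totalling 6,719 bites averages 40.97 bites/meal
    counts = np.full(164, 6719 // 164)
    counts[: 6719 % 164] += 1
    assert bc.summary_stats(counts)["mean"] == pytest.approx(40.97, abs=0.005)
    with pytest.raises(ValueError):
        bc.summary_stats([])


@given(st.integers(0, 2**16))
def test_summary_stats_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 100, size=30)
    stats = bc.summary_stats(counts)
    assert stats["mean"] == pytest.approx(counts.mean())
    assert stats["variance"] == pytest.approx(counts.var(ddof=1))
    assert stats["q1"] == pytest.approx(np.percentile(counts, 25))
    values, freq = np.unique(counts, return_counts=True)
    assert stats["mode"] == values[freq == freq.max()].min()


def spearman_oracle(x, y):
    """Average-rank Spearman: Pearson correlation of the rank vectors."""
    import scipy.stats

    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def test_rank_correlation():
    x = [3, 1, 4, 1, 5, 9, 2, 6]
    assert bc.rank_correlation(x, x) == pytest.approx(1.0)
    assert bc.rank_correlation(x, [-v for v in x]) == pytest.approx(-1.0)
    tied = [1, 2, 2, 3, 4, 4, 4, 5]
    assert bc.rank_correlation(x, tied) == pytest.approx(spearman_oracle(x, tied))
    with pytest.raises(ValueError):
        bc.rank_correlation([1, 1, 1], [1, 2, 3])
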