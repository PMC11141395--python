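"""Accuracy metric and report tables.

Accuracy is computed on pooled bite totals, not per-event matching: with
annotated total T and predicted total P,

    A = | 100 - 100 * |P - T| / T |   (percent)

i.e. 100 x (1 - relative absolute count error), with the absolute value of
the result reported when over-prediction exceeds twice the annotation (the
"fold-back").  A fold-back figure flatters a gross over-count — 65.7% for a
2.7x over-prediction — so such rows are flagged with a warning, and
``clamp_at_zero=True`` offers max(0, .) as an alternative convention.

Report values are rounded to one decimal place, half-up.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .errors import UndefinedAccuracyError


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (as report tables print), not
    banker's rounding."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def accuracy(
    annotated: float,
    predicted: float,
    clamp_at_zero: bool = False,
    warn_foldback: bool = True,
) -> float:
    """Bite-count accuracy (percent, unrounded) from pooled totals."""
    if annotated <= 0:
        raise UndefinedAccuracyError("accuracy undefined for a zero annotated total")
    if predicted < 0:
        raise ValueError("predicted total must be >= 0")
    raw = 100.0 - 100.0 * abs(predicted - annotated) / annotated
    if raw < 0:
        if warn_foldback:
            warnings.warn(
                f"prediction {predicted} exceeds twice the annotation {annotated}; "
                f"reported accuracy {abs(raw):.1f}% is a folded-back value",
                stacklevel=2,
            )
        return 0.0 if clamp_at_zero else abs(raw)
    return raw


@dataclass
class AccuracyReport:
    """Per-group accuracy table plus its summary footer.

    ``rows``: one row per group (participant, condition, ...) with pooled
    annotated/predicted totals and the accuracy percent.
    ``summary``: per method — totals over groups, unweighted mean and
    standard deviation (sample, ddof=1) of the group accuracies.
    """

    rows: pd.DataFrame
    summary: pd.DataFrame

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"AccuracyReport\n{self.rows}\n\nSummary\n{self.summary}"


def _pooled(df: pd.DataFrame, by: list, round_to: Optional[int], clamp: bool) -> pd.DataFrame:
    grouped = (
        df.groupby(by, sort=True)[["annotated", "predicted"]].sum().reset_index()
    )
    acc = [
        accuracy(t, p, clamp_at_zero=clamp) for t, p in zip(grouped["annotated"], grouped["predicted"])
    ]
    if round_to is not None:
        acc = [round_half_up(a, round_to) for a in acc]
    grouped["accuracy"] = acc
    return grouped


def participant_report(
    annotations: pd.DataFrame,
    predictions: pd.DataFrame,
    round_to: Optional[int] = 1,
    clamp_at_zero: bool = False,
    per_video: bool = False,
) -> AccuracyReport:
    """Per-participant accuracy per search method.

    Parameters
    ----------
    annotations : DataFrame with columns video_id, participant_id,
        annotated_bites (one row per video).
    predictions : DataFrame with columns video_id, method, predicted_bites.
    round_to : decimal places for reported accuracies (half-up); None keeps
        unrounded values.
    per_video : by default accuracy is computed on each participant's
        *pooled* totals; True averages per-video accuracies instead
        (a stricter, non-standard variant kept behind this flag).

    Participants contributing no videos are excluded with a warning.
    """
    needed = {"video_id", "participant_id", "annotated_bites"}
    if not needed <= set(annotations.columns):
        raise ValueError(f"annotations must have columns {sorted(needed)}")
    df = predictions.merge(
        annotations[["video_id", "participant_id", "annotated_bites"]], on="video_id", how="left"
    )
    if df["annotated_bites"].isna().any():
        missing = df.loc[df["annotated_bites"].isna(), "video_id"].tolist()
        raise ValueError(f"predictions for unannotated video(s): {missing[:5]}")
    empty = set(annotations["participant_id"]) - set(df["participant_id"])
    if empty:
        warnings.warn(f"participant(s) with no predictions excluded: {sorted(empty)}", stacklevel=2)
    df = df.rename(columns={"annotated_bites": "annotated", "predicted_bites": "predicted"})

    if per_video:
        df["accuracy"] = [
            accuracy(t, p, clamp_at_zero=clamp_at_zero)
            for t, p in zip(df["annotated"], df["predicted"])
        ]
        rows = (
            df.groupby(["participant_id", "method"], sort=True)
            .agg(annotated=("annotated", "sum"), predicted=("predicted", "sum"),
                 accuracy=("accuracy", "mean"))
            .reset_index()
        )
        if round_to is not None:
            rows["accuracy"] = [round_half_up(a, round_to) for a in rows["accuracy"]]
    else:
        rows = _pooled(df, ["participant_id", "method"], round_to, clamp_at_zero)

    summaries = []
    for method, grp in rows.groupby("method", sort=True):
        accs = grp["accuracy"].to_numpy(dtype=float)
        std = float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0
        if len(accs) == 1:
            warnings.warn(
                f"method {method!r}: single group, standard deviation reported as 0",
                stacklevel=2,
            )
        summaries.append(
            {
                "method": method,
                "n_groups": len(grp),
                "total_annotated": int(grp["annotated"].sum()),
                "total_predicted": int(grp["predicted"].sum()),
                "mean_accuracy": round_half_up(float(np.mean(accs)), round_to)
                if round_to is not None
                else float(np.mean(accs)),
                "std_accuracy": round_half_up(std, round_to) if round_to is not None else std,
            }
        )
    return AccuracyReport(rows=rows, summary=pd.DataFrame(summaries))


def pooled_accuracy(
    annotations: pd.DataFrame,
    predictions: pd.DataFrame,
    group_by: str = "texture_condition",
    round_to: Optional[int] = 1,
    clamp_at_zero: bool = False,
) -> pd.DataFrame:
    """Accuracy per condition group from pooled counts.

    Counts are summed across all videos in each group *before* the accuracy
    formula is applied (never a mean of per-video accuracies).  Empty
    groups are excluded with a warning.
    """
    if group_by not in annotations.columns:
        raise ValueError(f"annotations lack the grouping column {group_by!r}")
    df = predictions.merge(
        annotations[["video_id", group_by, "annotated_bites"]], on="video_id", how="inner"
    ).rename(columns={"annotated_bites": "annotated", "predicted_bites": "predicted"})
    present = set(df[group_by])
    empty = set(annotations[group_by]) - present
    if empty:
        warnings.warn(f"empty group(s) excluded: {sorted(empty)}", stacklevel=2)
    out = _pooled(df, [group_by], round_to, clamp_at_zero)
    return out.rename(columns={group_by: "group"})


def summary_stats(counts: Sequence[float], ddof: int = 1) -> pd.Series:
    """Descriptive statistics of per-video bite counts.

    Mode is the smallest most-frequent value; quartiles use linear
    interpolation between closest ranks; variance/sd are sample (ddof=1)
    by default.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("need at least one count")
    q1, q2, q3 = np.percentile(counts, [25, 50, 75])
    return pd.Series(
        {
            "mean": float(np.mean(counts)),
            "median": float(np.median(counts)),
            "mode": float(scipy.stats.mode(counts, keepdims=False).mode),
            "range": float(np.ptp(counts)),
            "variance": float(np.var(counts, ddof=ddof)) if counts.size > ddof else float("nan"),
            "std": float(np.std(counts, ddof=ddof)) if counts.size > ddof else float("nan"),
            "q1": float(q1),
            "q2": float(q2),
            "q3": float(q3),
        }
    )


def rank_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman's rank correlation (average ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    return float(scipy.stats.spearmanr(x, y).statistic)
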