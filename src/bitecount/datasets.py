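"""Bundled evaluation dataset: published bite-count totals.

The validation study behind this package tuned per-participant thresholds
on 164 annotated meal videos from 15 participants (labelled A-Q) and
reported pooled bite totals per participant and per search method, the
per-participant leave-one-out (transferred-threshold) accuracies, and
pooled totals per food-texture condition.  Those printed totals are bundled
here so the accuracy arithmetic can be reproduced without any video data.
"""
from __future__ import annotations

import pandas as pd

# participant, n videos, annotated total, predicted totals per search method
_PER_PARTICIPANT = [
    # pid, videos, annotated, grid, random, bayesian
    ("A", 10, 554, 524, 532, 369),
    ("B", 14, 502, 662, 647, 1334),
    ("C", 14, 552, 917, 597, 947),
    ("D", 13, 450, 521, 516, 519),
    ("E", 11, 657, 490, 572, 490),
    ("F", 6, 241, 214, 193, 618),
    ("G", 14, 478, 520, 516, 525),
    ("H", 14, 607, 594, 559, 620),
    ("I", 13, 443, 327, 328, 327),
    ("L", 13, 668, 1031, 1019, 958),
    ("M", 7, 349, 254, 220, 252),
    ("N", 12, 389, 354, 353, 412),
    ("O", 8, 179, 256, 264, 256),
    ("P", 9, 406, 513, 504, 507),
    ("Q", 6, 244, 246, 240, 243),
]

# Transferred-threshold (leave-one-out) accuracy per participant, percent.
# Participant G is printed as 94.8 in the study's per-participant table but
# as 94.6 in its summary statistics (reported max); 94.6 is carried here as
# it is the value consistent with the reported mean (71.4) and maximum.
_LOOCV_ACCURACY = [
    ("A", 46.6),
    ("B", 83.9),
    ("C", 94.6),
    ("D", 83.1),
    ("E", 40.5),
    ("F", 74.3),
    ("G", 94.6),
    ("H", 36.6),
    ("I", 89.2),
    ("L", 71.0),
    ("M", 62.8),
    ("N", 82.5),
    ("O", 73.2),
    ("P", 49.8),
    ("Q", 88.9),
]

# pooled totals per food-texture condition (transferred thresholds)
_TEXTURE = [
    ("fast_soft", 2871, 2684),
    ("slow_hard", 3848, 4120),
]


def load_validation_counts() -> dict:
    """Published count tables as tidy DataFrames.

    Returns a dict with keys:

    ``per_participant``
        video_id-free totals: participant_id, n_videos, annotated, and
        predicted totals under each tuning method (grid/random/bayesian).
    ``loocv_accuracy``
        participant_id, accuracy (percent) with transferred thresholds.
    ``texture``
        condition, annotated, predicted pooled totals.
    """
    per_participant = pd.DataFrame(
        _PER_PARTICIPANT,
        columns=["participant_id", "n_videos", "annotated", "grid", "random", "bayesian"],
    )
    loocv = pd.DataFrame(_LOOCV_ACCURACY, columns=["participant_id", "accuracy"])
    texture = pd.DataFrame(_TEXTURE, columns=["condition", "annotated", "predicted"])
    return {"per_participant": per_participant, "loocv_accuracy": loocv, "texture": texture}


def validation_counts_long() -> dict:
    """The same totals reshaped for the report builders.

    Returns ``annotations`` (video_id, participant_id, annotated_bites,
    texture_condition where applicable) and ``predictions`` (video_id,
    method, predicted_bites), with one synthetic "video" per participant
    (or per condition group) carrying that group's pooled total — accuracy
    on pooled counts is unchanged by this collapsing.
    """
    tables = load_validation_counts()
    pp = tables["per_participant"]
    annotations = pd.DataFrame(
        {
            "video_id": "pooled-" + pp["participant_id"],
            "participant_id": pp["participant_id"],
            "annotated_bites": pp["annotated"],
        }
    )
    predictions = pp.melt(
        id_vars=["participant_id"],
        value_vars=["grid", "random", "bayesian"],
        var_name="method",
        value_name="predicted_bites",
    )
    predictions.insert(0, "video_id", "pooled-" + predictions["participant_id"])
    predictions = predictions[["video_id", "method", "predicted_bites"]]

    tex = tables["texture"]
    texture_annotations = pd.DataFrame(
        {
            "video_id": "pooled-" + tex["condition"],
            "texture_condition": tex["condition"],
            "annotated_bites": tex["annotated"],
        }
    )
    texture_predictions = pd.DataFrame(
        {
            "video_id": "pooled-" + tex["condition"],
            "method": "loocv",
            "predicted_bites": tex["predicted"],
        }
    )
    return {
        "annotations": annotations,
        "predictions": predictions,
        "texture_annotations": texture_annotations,
        "texture_predictions": texture_predictions,
    }
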