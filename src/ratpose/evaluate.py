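"""Nose-eye-normalised accuracy: the package's evaluation criterion.

Raw pixel error is not comparable across images: the animal's apparent size
varies with body size and camera distance.  Each landmark's error is
therefore normalised by the labelled nose-eye distance of the same image
(in the spirit of the head-normalised PCKh criterion for human pose):

    error_i = dist(pred_i, label_i) / dist(nose_label, eye_label) - p

with evaluation margin ``p`` (default 0.1).  A prediction is correct iff
``error_i <= 0``, i.e. it lies within ``p`` nose-eye distances of its
label.  Per-landmark accuracy is the percentage of correct predictions;
the Total is the arithmetic mean of the nine per-landmark accuracies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import AnnotatedDataset
from .errors import ConfigurationError, EvaluationError
from .landmarks import LANDMARK_NAMES, N_LANDMARKS, LandmarkSet


@dataclass
class EvalConfig:
    """Evaluation margin ``p`` (unitless fraction of the nose-eye distance)."""

    p: float = 0.1

    def __post_init__(self) -> None:
        if self.p < 0:
            raise ConfigurationError("evaluation margin p must be >= 0")


@dataclass
class PointError:
    """Normalised error of one landmark prediction."""

    landmark: str
    error: float
    correct: bool

    def __post_init__(self) -> None:
        if self.correct != (self.error <= 0):
            raise EvaluationError("correct flag must equal (error <= 0)")


def normalized_error(
    pred: tuple[float, float],
    label: tuple[float, float],
    nose_label: tuple[float, float],
    eye_label: tuple[float, float],
    cfg: EvalConfig | None = None,
) -> float:
    """Euclidean prediction error over the nose-eye distance, minus ``p``.

    Scale-invariant: multiplying every coordinate by the same positive
    factor leaves the value unchanged.
    """
    cfg = cfg or EvalConfig()
    denom = math.dist(nose_label, eye_label)
    if denom <= 0:
        raise EvaluationError("nose-eye distance must be positive")
    return math.dist(pred, label) / denom - cfg.p


def is_correct(error: float) -> bool:
    """A prediction is correct iff its normalised error is <= 0."""
    if not math.isfinite(error):
        raise EvaluationError("error must be finite")
    return error <= 0.0


@dataclass
class EvaluationReport:
    """Per-landmark and total accuracies over one test set (percent)."""

    per_landmark: dict[str, float]
    total: float
    n_images: int
    p: float
    n_excluded: int = 0
    per_landmark_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, acc in self.per_landmark.items():
            if not 0.0 <= acc <= 100.0:
                raise EvaluationError(f"accuracy for {name!r} outside [0, 100]")

    @classmethod
    def from_per_landmark(
        cls, per_landmark: dict[str, float], n_images: int = 0, p: float = 0.1
    ) -> "EvaluationReport":
        """Aggregate a report from per-landmark accuracies; the Total is
        their arithmetic mean."""
        if set(per_landmark) != set(LANDMARK_NAMES):
            raise EvaluationError("per-landmark accuracies must cover all 9 names")
        total = float(np.mean([per_landmark[n] for n in LANDMARK_NAMES]))
        return cls(dict(per_landmark), total, n_images, p)

    @property
    def total_rounded(self) -> float:
        """Total rounded to one decimal, the reporting precision."""
        return round(self.total, 1)

    def as_row(self) -> dict[str, float]:
        row = {name: round(self.per_landmark[name], 1) for name in LANDMARK_NAMES}
        row["total"] = self.total_rounded
        return row


def evaluate(
    predictions: list[LandmarkSet],
    labels: AnnotatedDataset,
    cfg: EvalConfig | None = None,
) -> EvaluationReport:
    """Score aligned predictions against labelled images.

    Landmarks whose label is flagged invisible are excluded from the
    counts; images with a non-positive nose-eye label distance are excluded
    entirely and reported via ``n_excluded``.
    """
    cfg = cfg or EvalConfig()
    if len(predictions) != len(labels):
        raise EvaluationError(
            f"{len(predictions)} predictions for {len(labels)} labelled images"
        )
    correct = np.zeros(N_LANDMARKS, dtype=int)
    count = np.zeros(N_LANDMARKS, dtype=int)
    excluded = 0
    for pred, rec in zip(predictions, labels.records):
        lab = rec.landmarks
        denom = lab.nose_eye_distance()
        if denom <= 0:
            excluded += 1
            continue
        d = np.linalg.norm(pred.xy - lab.xy, axis=1)
        err = d / denom - cfg.p
        vis = lab.visible
        count += vis
        correct += vis & (err <= 0)
    if count.sum() == 0:
        raise EvaluationError("no evaluable landmarks (all excluded or invisible)")
    acc = np.where(count > 0, 100.0 * correct / np.maximum(count, 1), 0.0)
    per_landmark = {name: float(acc[i]) for i, name in enumerate(LANDMARK_NAMES)}
    total = float(np.mean(acc))
    return EvaluationReport(
        per_landmark=per_landmark,
        total=total,
        n_images=len(labels) - excluded,
        p=cfg.p,
        n_excluded=excluded,
        per_landmark_counts={n: int(count[i]) for i, n in enumerate(LANDMARK_NAMES)},
    )


def write_report_table(rows: list[tuple[str, str, EvaluationReport]], path: str) -> None:
    """Write an accuracy comparison table (structure, decoder, per-landmark
    %, total %) as CSV."""
    out = []
    for structure, decoder, report in rows:
        row = {"structure": structure, "decoder": decoder}
        row.update(report.as_row())
        out.append(row)
    pd.DataFrame(out).to_csv(path, index=False)
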