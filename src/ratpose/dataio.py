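"""Annotated-dataset and trajectory I/O plus the train/test split.

Annotation files are a single JSON document per dataset::

    {
      "metadata": {...provenance...},
      "records": [
        {"image": "img_00000.png", "width": 256, "height": 128,
         "frame_index": 0,
         "landmarks": [{"name": "nose_tip", "x": 180.1, "y": 55.2,
                        "visible": true}, ...x9]},
        ...
      ]
    }

Trajectories are long-format CSV with columns ``frame, landmark, x, y``
(coordinates written with six decimals).  All coordinates are 0-based,
sub-pixel, top-left origin.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

from .errors import FormatError, SchemaError, SplitError
from .landmarks import LANDMARK_NAMES, LandmarkSet


@dataclass
class AnnotatedImage:
    """One labelled frame: an image reference plus its nine landmarks."""

    image_path: str
    width: int
    height: int
    landmarks: LandmarkSet
    frame_index: int | None = None

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise SchemaError(f"record {self.image_path!r}: non-positive image size")
        xy = self.landmarks.xy
        vis = self.landmarks.visible
        inside = (
            (xy[:, 0] >= 0) & (xy[:, 0] < self.width)
            & (xy[:, 1] >= 0) & (xy[:, 1] < self.height)
        )
        if np.any(vis & ~inside):
            bad = [LANDMARK_NAMES[i] for i in np.nonzero(vis & ~inside)[0]]
            raise SchemaError(
                f"record {self.image_path!r}: visible landmarks outside image: {bad}"
            )


@dataclass
class AnnotatedDataset:
    """A list of annotated frames plus generator provenance.

    ``root`` is the directory image paths are relative to (set on read/
    generation) so images can be loaded lazily via :meth:`load_image`.
    """

    records: list[AnnotatedImage]
    metadata: dict = field(default_factory=dict)
    root: str | None = None

    def __post_init__(self) -> None:
        if not self.records:
            raise SchemaError("dataset must contain at least one record")
        paths = [r.image_path for r in self.records]
        if len(set(paths)) != len(paths):
            raise SchemaError("dataset image paths must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def load_image(self, record: AnnotatedImage) -> np.ndarray:
        path = record.image_path
        if self.root is not None and not os.path.isabs(path):
            path = os.path.join(self.root, path)
        with Image.open(path) as im:
            return np.asarray(im.convert("RGB"))

    def subset(self, indices) -> "AnnotatedDataset":
        return AnnotatedDataset(
            records=[self.records[i] for i in indices],
            metadata=dict(self.metadata),
            root=self.root,
        )


# ---------------------------------------------------------------------------
# annotation JSON
# ---------------------------------------------------------------------------

def write_annotations(dataset: AnnotatedDataset, path: str) -> None:
    doc = {
        "metadata": dataset.metadata,
        "records": [
            {
                "image": r.image_path,
                "width": r.width,
                "height": r.height,
                **({"frame_index": r.frame_index} if r.frame_index is not None else {}),
                "landmarks": r.landmarks.to_records(),
            }
            for r in dataset.records
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_annotations(path: str) -> AnnotatedDataset:
    """Read a dataset JSON; schema violations raise SchemaError naming the record."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"malformed JSON in {path!r}: {exc}") from exc
    if not isinstance(doc, dict) or "records" not in doc:
        raise SchemaError(f"{path!r}: missing top-level 'records' key")
    records = []
    for rec in doc["records"]:
        name = rec.get("image", "<unnamed>")
        try:
            lm = LandmarkSet.from_records(rec["landmarks"])
        except (KeyError, SchemaError) as exc:
            raise SchemaError(f"record {name!r}: {exc}") from exc
        records.append(
            AnnotatedImage(
                image_path=rec["image"],
                width=int(rec["width"]),
                height=int(rec["height"]),
                landmarks=lm,
                frame_index=rec.get("frame_index"),
            )
        )
    return AnnotatedDataset(
        records=records,
        metadata=doc.get("metadata", {}),
        root=os.path.dirname(os.path.abspath(path)),
    )


# ---------------------------------------------------------------------------
# train/test split
# ---------------------------------------------------------------------------

def split_dataset(
    dataset: AnnotatedDataset,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[AnnotatedDataset, AnnotatedDataset]:
    """Random disjoint/exhaustive partition with ``floor(n * fraction)``
    training records (80/20 by default).

    The permutation is drawn from ``seed`` only, so the same seed always
    yields the same membership.
    """
    if not 0.0 < train_fraction < 1.0:
        raise SplitError("train_fraction must lie strictly between 0 and 1")
    n = len(dataset)
    if n < 2:
        raise SplitError("need at least 2 records to split")
    n_train = math.floor(n * train_fraction)
    if n_train == 0 or n_train == n:
        raise SplitError(
            f"fraction {train_fraction} leaves an empty side for n={n}"
        )
    perm = np.random.default_rng(seed).permutation(n)
    return dataset.subset(np.sort(perm[:n_train])), dataset.subset(np.sort(perm[n_train:]))


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryRecord:
    """Per-frame landmark coordinates over a video.

    ``image_height`` is retained so joint heights (``image_height - y``) can
    be derived without the frames at hand; ``frame_rate`` is nominal
    100 frames/s.
    """

    frames: list[int]
    landmark_sets: list[LandmarkSet]
    frame_rate: float = 100.0
    image_height: int | None = None

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.landmark_sets):
            raise FormatError("frames and landmark sets must align 1:1")
        if any(b <= a for a, b in zip(self.frames, self.frames[1:])):
            raise FormatError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def coords(self, landmark: str) -> np.ndarray:
        """(n_frames, 2) array of one landmark's positions."""
        from .landmarks import landmark_index

        i = landmark_index(landmark)
        return np.array([ls.xy[i] for ls in self.landmark_sets])


def write_trajectory(traj: TrajectoryRecord, path: str) -> None:
    rows = []
    for f, ls in zip(traj.frames, traj.landmark_sets):
        for i, name in enumerate(LANDMARK_NAMES):
            rows.append((f, name, round(float(ls.xy[i, 0]), 6), round(float(ls.xy[i, 1]), 6)))
    df = pd.DataFrame(rows, columns=["frame", "landmark", "x", "y"])
    df.to_csv(path, index=False, float_format="%.6f")


def read_trajectory(path: str, frame_rate: float = 100.0,
                    image_height: int | None = None) -> TrajectoryRecord:
    df = pd.read_csv(path)
    expected = ["frame", "landmark", "x", "y"]
    if list(df.columns) != expected:
        raise FormatError(f"{path!r}: expected columns {expected}, got {list(df.columns)}")
    if df.empty:
        return TrajectoryRecord([], [], frame_rate, image_height)
    frames = sorted(df["frame"].unique().tolist())
    if any(b <= a for a, b in zip(frames, frames[1:])):
        raise FormatError("frame indices must be strictly increasing")
    sets = []
    for f in frames:
        sub = df[df["frame"] == f]
        recs = [
            {"name": r.landmark, "x": r.x, "y": r.y, "visible": True}
            for r in sub.itertuples()
        ]
        try:
            sets.append(LandmarkSet.from_records(recs))
        except SchemaError as exc:
            raise FormatError(f"frame {f}: {exc}") from exc
    return TrajectoryRecord(list(map(int, frames)), sets, frame_rate, image_height)
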