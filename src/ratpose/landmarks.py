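"""The nine named rodent landmarks and the :class:`LandmarkSet` container.

Every annotation, prediction and trajectory in the package is expressed as a
:class:`LandmarkSet`: an ordered mapping of the nine canonical landmark names
to sub-pixel image coordinates.  The coordinate convention is fixed
throughout: origin at the top-left corner, ``x`` rightward, ``y`` downward,
continuous (sub-pixel) values.  "Height" in gait analysis is
``image_height - y``.

The nine landmarks cover the visible side of a rat in side view.  Knee and
hip are deliberately absent: under fur they cannot be labelled reliably.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SchemaError

#: Canonical landmark order. All arrays with a landmark axis follow it.
LANDMARK_NAMES: tuple[str, ...] = (
    "nose_tip",
    "eye",
    "ear",
    "front_claw_wrist",
    "front_claw_tip",
    "back_claw_ankle",
    "back_claw_palm",
    "back_claw_tip",
    "tail",
)

N_LANDMARKS = len(LANDMARK_NAMES)

_INDEX = {name: i for i, name in enumerate(LANDMARK_NAMES)}


def landmark_index(name: str) -> int:
    """Index of ``name`` in the canonical order; SchemaError if unknown."""
    try:
        return _INDEX[name]
    except KeyError:
        raise SchemaError(
            f"unknown landmark name {name!r}; valid names are {list(LANDMARK_NAMES)}"
        ) from None


@dataclass
class LandmarkSet:
    """Ordered coordinates of the nine landmarks for one image.

    Parameters
    ----------
    xy:
        ``(9, 2)`` float array of ``(x, y)`` pixel coordinates in canonical
        landmark order.
    visible:
        ``(9,)`` boolean array; invisible landmarks keep their coordinates
        but are excluded from losses and evaluation.
    """

    xy: np.ndarray
    visible: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.shape != (N_LANDMARKS, 2):
            raise SchemaError(
                f"LandmarkSet needs exactly {N_LANDMARKS} (x, y) rows, got shape "
                f"{self.xy.shape}"
            )
        if not np.all(np.isfinite(self.xy)):
            raise SchemaError("landmark coordinates must be finite")
        if self.visible is None:
            self.visible = np.ones(N_LANDMARKS, dtype=bool)
        else:
            self.visible = np.asarray(self.visible, dtype=bool)
            if self.visible.shape != (N_LANDMARKS,):
                raise SchemaError("visibility flags must have shape (9,)")

    # -- accessors ---------------------------------------------------------
    def __getitem__(self, name: str) -> tuple[float, float]:
        i = landmark_index(name)
        return float(self.xy[i, 0]), float(self.xy[i, 1])

    def get(self, name: str) -> np.ndarray:
        return self.xy[landmark_index(name)]

    @property
    def names(self) -> tuple[str, ...]:
        return LANDMARK_NAMES

    def nose_eye_distance(self) -> float:
        """Euclidean distance between nose tip and eye (the metric denominator)."""
        return float(np.linalg.norm(self.get("nose_tip") - self.get("eye")))

    # -- (de)serialisation -------------------------------------------------
    def to_records(self) -> list[dict]:
        return [
            {
                "name": name,
                "x": float(self.xy[i, 0]),
                "y": float(self.xy[i, 1]),
                "visible": bool(self.visible[i]),
            }
            for i, name in enumerate(LANDMARK_NAMES)
        ]

    @classmethod
    def from_records(cls, records: list[dict]) -> "LandmarkSet":
        if len(records) != N_LANDMARKS:
            raise SchemaError(
                f"expected {N_LANDMARKS} landmarks, got {len(records)}"
            )
        xy = np.zeros((N_LANDMARKS, 2))
        vis = np.ones(N_LANDMARKS, dtype=bool)
        seen = set()
        for rec in records:
            i = landmark_index(rec["name"])
            if i in seen:
                raise SchemaError(f"duplicate landmark {rec['name']!r}")
            seen.add(i)
            xy[i] = (rec["x"], rec["y"])
            vis[i] = bool(rec.get("visible", True))
        return cls(xy, vis)

    def copy(self) -> "LandmarkSet":
        return LandmarkSet(self.xy.copy(), self.visible.copy())

    def scaled(self, sx: float, sy: float) -> "LandmarkSet":
        """New set with x scaled by ``sx`` and y by ``sy`` (resize bookkeeping)."""
        out = self.xy.copy()
        out[:, 0] *= sx
        out[:, 1] *= sy
        return LandmarkSet(out, self.visible.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LandmarkSet):
            return NotImplemented
        return bool(
            np.array_equal(self.xy, other.xy)
            and np.array_equal(self.visible, other.visible)
        )
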