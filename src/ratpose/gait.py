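"""Joint-motion quantification from tracked landmark trajectories.

Given a video, the trained landmark estimator yields per-frame coordinates
(:func:`track_video`).  From the resulting trajectory this module derives
joint-height time series (height = image_height - y, in pixels; no camera
calibration is assumed), splits the gait cycle into *falling* and *lifting*
hind-limb phases from the sign of the smoothed height derivative, detects
stride peaks to estimate the stride period, and measures per-phase
horizontal travel of the fore versus hind limb.

The phase-segmentation and peak-detection procedures are the package's own
(simple, documented defaults); the biological observable they quantify is
the alternating stance/swing pattern of treadmill locomotion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .dataio import TrajectoryRecord
from .errors import ConfigurationError, EvaluationError
from .landmarks import LANDMARK_NAMES, landmark_index
from .models import CascadeModel
from .training import predict_landmarks

FALLING = "falling"
LIFTING = "lifting"

#: joint -> overlay colour, fixed: fore claw wrist yellow, hind claw ankle
#: green, hind claw palm blue, hind claw tip red
OVERLAY_COLORS: dict[str, tuple[int, int, int]] = {
    "front_claw_wrist": (255, 255, 0),
    "back_claw_ankle": (0, 200, 0),
    "back_claw_palm": (0, 80, 255),
    "back_claw_tip": (255, 40, 40),
}


@dataclass
class GaitSummary:
    """Derived gait quantities for one tracked video."""

    heights: dict[str, np.ndarray]
    phase_labels: list[str]
    stride_peaks: np.ndarray
    period_frames: float | None
    displacement_by_phase: dict[str, dict[str, float]]
    reference_joint: str = "back_claw_ankle"

    def to_json(self, path: str) -> None:
        doc = {
            "reference_joint": self.reference_joint,
            "period_frames": self.period_frames,
            "stride_peaks": [int(i) for i in self.stride_peaks],
            "displacement_by_phase": self.displacement_by_phase,
            "phase_counts": {
                ph: int(sum(1 for q in self.phase_labels if q == ph))
                for ph in (FALLING, LIFTING)
            },
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


# ---------------------------------------------------------------------------
# tracking
# ---------------------------------------------------------------------------

def track_video(
    model: CascadeModel,
    frames: list[np.ndarray],
    frame_rate: float = 100.0,
    batch_size: int = 8,
) -> TrajectoryRecord:
    """Run the estimator on ordered frames; final-stage decoded coordinates
    per frame, no temporal smoothing."""
    if not frames:
        raise ConfigurationError("no frames to track")
    sets = predict_landmarks(model, frames, batch_size=batch_size)
    return TrajectoryRecord(
        frames=list(range(len(frames))),
        landmark_sets=sets,
        frame_rate=frame_rate,
        image_height=frames[0].shape[0],
    )


# ---------------------------------------------------------------------------
# height series and phase segmentation
# ---------------------------------------------------------------------------

def height_series(traj: TrajectoryRecord, joint: str) -> np.ndarray:
    """Per-frame joint height in pixels above the image bottom
    (``image_height - y``)."""
    landmark_index(joint)  # raises on unknown joints
    if traj.image_height is None:
        raise EvaluationError("trajectory lacks image_height; cannot form heights")
    return traj.image_height - traj.coords(joint)[:, 1]


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    pad = w // 2
    xp = np.pad(x, pad, mode="edge")
    kernel = np.ones(w) / w
    out = np.convolve(xp, kernel, mode="valid")
    return out[: len(x)]


def _merge_short_runs(labels: list[str], min_run: int = 2) -> list[str]:
    labels = list(labels)
    changed = True
    while changed:
        changed = False
        runs = []
        start = 0
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] != labels[start]:
                runs.append((start, i))
                start = i
        for a, b in runs:
            if b - a < min_run and len(runs) > 1:
                neighbor = labels[a - 1] if a > 0 else labels[b]
                if labels[a] != neighbor:
                    labels[a:b] = [neighbor] * (b - a)
                    changed = True
                    break
    return labels


def segment_phases(
    traj: TrajectoryRecord,
    reference_joint: str = "back_claw_ankle",
    smooth_window: int = 5,
) -> list[str]:
    """Label every frame ``lifting`` or ``falling``.

    The reference joint's height series is smoothed with a moving average of
    ``smooth_window`` frames; a frame is *lifting* where the smoothed height
    is rising (first difference > 0) and *falling* otherwise (stance frames,
    where the height is flat, count as falling).  Runs shorter than two
    frames are merged into their neighbours.
    """
    if len(traj) < smooth_window:
        raise ConfigurationError(
            f"trajectory ({len(traj)} frames) shorter than smoothing window "
            f"({smooth_window})"
        )
    h = _moving_average(height_series(traj, reference_joint), smooth_window)
    d = np.diff(h)
    labels = [LIFTING if di > 0 else FALLING for di in d]
    labels.insert(0, labels[0])
    return _merge_short_runs(labels, min_run=2)


# ---------------------------------------------------------------------------
# stride peaks
# ---------------------------------------------------------------------------

def detect_strides(
    series: np.ndarray,
    min_prominence: float | None = None,
    min_separation: int | None = None,
) -> tuple[np.ndarray, float | None]:
    """Local maxima of a height series and the median inter-peak gap.

    Defaults: prominence 0.2x the series range; separation from the first
    autocorrelation peak (a half-period guess), falling back to 3 frames.
    Returns ``(peak_indices, period)`` with ``period = None`` when fewer
    than two peaks are found.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 3:
        raise ConfigurationError("series must have at least 3 samples")
    rng_span = float(series.max() - series.min())
    if min_prominence is None:
        min_prominence = 0.2 * rng_span if rng_span > 0 else 1e-9
    if min_separation is None:
        min_separation = max(_autocorr_period_guess(series) // 2, 3)
    peaks, _ = find_peaks(
        series, prominence=min_prominence, distance=max(int(min_separation), 1)
    )
    if len(peaks) < 2:
        return peaks, None
    return peaks, float(np.median(np.diff(peaks)))


def _autocorr_period_guess(series: np.ndarray) -> int:
    x = series - series.mean()
    if np.allclose(x, 0):
        return 6
    ac = np.correlate(x, x, mode="full")[len(x) - 1 :]
    # first local maximum after the zero-lag peak
    for lag in range(1, len(ac) - 1):
        if ac[lag] >= ac[lag - 1] and ac[lag] >= ac[lag + 1] and ac[lag] > 0:
            return lag
    return 6


def estimate_period_autocorr(series: np.ndarray) -> int | None:
    """Period estimate as the first positive autocorrelation maximum
    (exact on noiseless periodic ground truth)."""
    lag = _autocorr_period_guess(series)
    return lag if lag > 1 else None


# ---------------------------------------------------------------------------
# per-phase limb displacement
# ---------------------------------------------------------------------------

def limb_displacement_by_phase(
    traj: TrajectoryRecord,
    phase_labels: list[str] | None = None,
    fore_joint: str = "front_claw_wrist",
    hind_joint: str = "back_claw_ankle",
) -> dict[str, dict[str, float]]:
    """Horizontal path length of the fore vs hind limb in each gait phase.

    Each frame-to-frame step |dx| is attributed to the phase of its later
    frame; the per-joint phase sums add up to that joint's total path
    length.
    """
    if phase_labels is None:
        phase_labels = segment_phases(traj)
    out = {ph: {"fore": 0.0, "hind": 0.0} for ph in (FALLING, LIFTING)}
    for key, joint in (("fore", fore_joint), ("hind", hind_joint)):
        x = traj.coords(joint)[:, 0]
        dx = np.abs(np.diff(x))
        for t, step in enumerate(dx):
            out[phase_labels[t + 1]][key] += float(step)
    return out


def summarize_gait(
    traj: TrajectoryRecord,
    reference_joint: str = "back_claw_ankle",
    smooth_window: int = 5,
) -> GaitSummary:
    """Full quantification: heights, phases, stride peaks, displacements."""
    joints = list(OVERLAY_COLORS)
    heights = {j: height_series(traj, j) for j in joints}
    labels = segment_phases(traj, reference_joint, smooth_window)
    peaks, period = detect_strides(heights[reference_joint])
    disp = limb_displacement_by_phase(traj, labels)
    return GaitSummary(
        heights=heights,
        phase_labels=labels,
        stride_peaks=peaks,
        period_frames=period,
        displacement_by_phase=disp,
        reference_joint=reference_joint,
    )


def write_gait_csv(traj: TrajectoryRecord, labels: list[str], path: str) -> None:
    """Long-format per-frame CSV: frame, joint, x, y, height, phase."""
    if traj.image_height is None:
        raise EvaluationError("trajectory lacks image_height")
    rows = []
    for t, (f, ls) in enumerate(zip(traj.frames, traj.landmark_sets)):
        for i, name in enumerate(LANDMARK_NAMES):
            rows.append(
                (
                    f,
                    name,
                    float(ls.xy[i, 0]),
                    float(ls.xy[i, 1]),
                    float(traj.image_height - ls.xy[i, 1]),
                    labels[t],
                )
            )
    pd.DataFrame(
        rows, columns=["frame", "joint", "x", "y", "height", "phase"]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# overlays
# ---------------------------------------------------------------------------

def render_overlay(
    frames: list[np.ndarray],
    traj: TrajectoryRecord,
    trail_length: int = 8,
    colors: dict[str, tuple[int, int, int]] | None = None,
    dot_radius: int = 2,
) -> list[np.ndarray]:
    """Draw each tracked joint's recent positions onto the frames.

    At frame ``t`` the positions from frames ``max(0, t - trail_length + 1)
    .. t`` are drawn as filled dots in the fixed joint colours, so motion
    leaves a short trail.
    """
    if trail_length < 1:
        raise ConfigurationError("trail_length must be >= 1")
    colors = colors or OVERLAY_COLORS
    out = []
    coords = {j: traj.coords(j) for j in colors}
    for t, frame in enumerate(frames):
        img = frame.copy()
        lo = max(0, t - trail_length + 1)
        for joint, col in colors.items():
            for s in range(lo, t + 1):
                _draw_dot(img, coords[joint][s], dot_radius, col)
        out.append(img)
    return out


def _draw_dot(img: np.ndarray, center, radius: int, color) -> None:
    h, w = img.shape[:2]
    cx, cy = float(center[0]), float(center[1])
    x0, x1 = max(int(cx - radius), 0), min(int(cx + radius) + 1, w)
    y0, y1 = max(int(cy - radius), 0), min(int(cy + radius) + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    ys, xs = np.mgrid[y0:y1, x0:x1]
    mask = (xs - cx) ** 2 + (ys - cy) ** 2 <= radius**2
    img[y0:y1, x0:x1][mask] = color
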