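"""Synthetic rodent-gait scene generator.

Real annotated rat-locomotion footage cannot be redistributed, so this module
is the package's data source: a side-view articulated rat silhouette walking
on a treadmill-style belt, rendered with known sub-pixel landmark positions
and known gait parameters.  Every downstream stage (codec, networks,
training, evaluation, gait quantification) is exercised against it, and
parameter-recovery tests compare against the closed-form kinematics defined
here.

The kinematic model is deliberately simple but realistic in its proportions
and rates: at the nominal 100 frames/s a default stride period of 24 frames
is ~4 strides/s, a typical treadmill rate for a young rat; the duty factor
(stance fraction) defaults to 0.6 as in walking gaits; hind-limb stride
length exceeds fore-limb stride length.  Each body segment is drawn as a
filled capsule or ellipse with a distinct tone so that a small network can
learn localisation from modest data.

Coordinates follow the package convention (origin top-left, x right, y down,
sub-pixel floats).  ``gait_pose`` works in a body-local frame whose origin is
the hip's ground projection with the ground line at ``y = 0`` (body points
have negative y); generators place that frame into the scene.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np
from PIL import Image

from .errors import ConfigurationError, GenerationError
from .landmarks import LANDMARK_NAMES, LandmarkSet

TWO_PI = 2.0 * math.pi


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def _default_segment_lengths() -> dict[str, float]:
    # px at body_scale 1 in the desk-scale 256x128 scene
    return {
        "head": 30.0,
        "torso": 60.0,
        "forelimb_upper": 18.0,
        "forelimb_lower": 16.0,
        "hind_thigh": 20.0,
        "hind_shank": 20.0,
        "hind_foot": 14.0,
        "tail": 35.0,
    }


def _default_landmark_offsets() -> dict[str, tuple[float, float]]:
    """Displacement of each landmark from its parent joint (px, scale 1).

    Parents: head landmarks hang off the shoulder, fore-claw landmarks off
    the shoulder's ground column, hind-claw landmarks off the hip's ground
    column, tail off the hip.
    """
    return {
        "eye": (20.0, -10.0),           # from shoulder
        "nose_tip": (21.0, 8.0),        # from eye; |offset| = 22.5 px
        "ear": (-13.0, -5.0),           # from eye
        "front_claw_wrist": (-2.0, -8.0),
        "front_claw_tip": (6.0, 0.0),
        "back_claw_ankle": (-8.0, -14.0),
        "back_claw_palm": (-4.0, -5.0),
        "back_claw_tip": (2.0, 0.0),
        "tail": (-35.0, -6.0),          # from hip
    }


@dataclass
class SkeletonConfig:
    """Per-bone lengths and landmark placement of the synthetic rat."""

    segment_lengths: dict[str, float] = field(default_factory=_default_segment_lengths)
    body_scale: float = 1.0
    landmark_offsets: dict[str, tuple[float, float]] = field(
        default_factory=_default_landmark_offsets
    )
    hip_height: float = 38.0      # resting hip height above ground, px
    shoulder_height: float = 36.0
    shoulder_advance: float = 60.0  # horizontal hip->shoulder distance, px

    def __post_init__(self) -> None:
        for name, ln in self.segment_lengths.items():
            if not ln > 0:
                raise ConfigurationError(f"segment length {name!r} must be > 0, got {ln}")
        if not self.body_scale > 0:
            raise ConfigurationError("body_scale must be > 0")
        missing = set(LANDMARK_NAMES) - set(self.landmark_offsets)
        if missing:
            raise ConfigurationError(f"landmark_offsets missing {sorted(missing)}")


@dataclass
class GaitConfig:
    """Periodic treadmill gait parameters.

    ``phase_offsets`` holds per-limb phase leads in radians (keys ``fore``
    and ``hind``); the default half-cycle offset alternates the two visible
    limbs.  ``forward_speed_px_per_frame`` is 0 on a treadmill (the body is
    stationary in the camera frame while limbs cycle).
    """

    period_frames: int = 24
    amplitude_px: float = 14.0
    duty_factor: float = 0.6
    phase_offsets: dict[str, float] = field(
        default_factory=lambda: {"hind": 0.0, "fore": math.pi}
    )
    forward_speed_px_per_frame: float = 0.0
    stride_px_hind: float = 36.0
    stride_px_fore: float = 22.0

    def __post_init__(self) -> None:
        if int(self.period_frames) != self.period_frames or self.period_frames < 4:
            raise ConfigurationError("period_frames must be an integer >= 4")
        self.period_frames = int(self.period_frames)
        if not 0.0 < self.duty_factor < 1.0:
            raise ConfigurationError("duty_factor must lie in (0, 1)")
        if self.amplitude_px < 0:
            raise ConfigurationError("amplitude_px must be >= 0")
        if self.forward_speed_px_per_frame < 0:
            raise ConfigurationError("forward_speed_px_per_frame must be >= 0")


@dataclass
class SceneConfig:
    """Image geometry, background style and pixel noise.

    Default desk scale is 256x128 (W x H); the full acquisition scale
    1056x720 at 100 frames/s is available by configuration.
    """

    image_width: int = 256
    image_height: int = 128
    background_style: str = "textured-belt"  # or "flat"
    noise_sigma: float = 2.0
    rng_seed: int = 0
    frame_rate: float = 100.0

    def __post_init__(self) -> None:
        if self.image_width < 64 or self.image_height < 64:
            raise ConfigurationError("scene must be at least 64x64 pixels")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        if self.background_style not in ("flat", "textured-belt"):
            raise ConfigurationError(
                f"unknown background_style {self.background_style!r}"
            )


# ---------------------------------------------------------------------------
# closed-form gait kinematics
# ---------------------------------------------------------------------------

def _cycle_fraction(phase: float, offset: float) -> float:
    return ((phase + offset) / TWO_PI) % 1.0


def swing_bump(frac: float, duty: float) -> float:
    """Vertical lift profile over one cycle: 0 during stance ``[0, duty)``,
    a half-sine over the swing fraction."""
    if frac < duty:
        return 0.0
    return math.sin(math.pi * (frac - duty) / (1.0 - duty))


def stride_x(frac: float, duty: float, stride: float) -> float:
    """Horizontal claw excursion about its neutral point.

    During stance the claw is carried backwards by the belt from +S/2 to
    -S/2; during swing it is swung forwards again.  Continuous and periodic.
    """
    half = 0.5 * stride
    if frac < duty:
        return half - stride * (frac / duty)
    return -half + stride * ((frac - duty) / (1.0 - duty))


# small per-landmark phase leads: the ankle lifts first, then palm, then tip
_ANKLE_LEAD = 0.04
_PALM_LEAD = 0.02
_WRIST_LEAD = 0.03


def gait_pose(
    phase: float,
    skeleton: SkeletonConfig | None = None,
    gait: GaitConfig | None = None,
    origin: tuple[float, float] = (0.0, 0.0),
) -> LandmarkSet:
    """Closed-form landmark positions at gait phase ``phase`` (radians).

    Returns coordinates in a frame whose origin is ``origin`` (the hip's
    ground projection); with the default origin, ground contact is ``y = 0``
    and body points have negative ``y``.  The mapping is deterministic and
    2*pi-periodic; during the stance fraction the claw tips sit exactly on
    the ground line.
    """
    skeleton = skeleton or SkeletonConfig()
    gait = gait or GaitConfig()
    if not math.isfinite(phase):
        raise ConfigurationError("phase must be finite")
    s = skeleton.body_scale
    off = skeleton.landmark_offsets
    duty = gait.duty_factor
    ox, oy = origin

    f_h = _cycle_fraction(phase, gait.phase_offsets.get("hind", 0.0))
    f_f = _cycle_fraction(phase, gait.phase_offsets.get("fore", math.pi))

    # torso anchors with a small double-frequency bob (two steps per cycle)
    bob = 1.5 * s * math.sin(2.0 * phase)
    hip = np.array([0.0, -(skeleton.hip_height * s + bob)])
    shoulder = np.array(
        [
            skeleton.shoulder_advance * s,
            -(skeleton.shoulder_height * s + 1.5 * s * math.sin(2.0 * phase + 0.5)),
        ]
    )

    # head chain
    eye = shoulder + np.array(off["eye"]) * s
    nose = eye + np.array(off["nose_tip"]) * s
    ear = eye + np.array(off["ear"]) * s

    # hind limb: closed-form height/excursion per landmark
    A = gait.amplitude_px * s
    S_h = gait.stride_px_hind * s
    hx = 0.0  # hip ground column
    tip_x = hx + off["back_claw_tip"][0] * s + stride_x(f_h, duty, S_h)
    tip_y = -A * swing_bump(f_h, duty)
    palm_x = hx + off["back_claw_palm"][0] * s + 0.9 * stride_x(f_h, duty, S_h)
    palm_y = (
        off["back_claw_palm"][1] * s
        - 0.35 * A * swing_bump(_cycle_fraction(phase, gait.phase_offsets.get("hind", 0.0) + TWO_PI * _PALM_LEAD), duty)
    )
    ankle_x = hx + off["back_claw_ankle"][0] * s + 0.6 * stride_x(f_h, duty, S_h)
    ankle_y = (
        off["back_claw_ankle"][1] * s
        - 0.6 * A * swing_bump(_cycle_fraction(phase, gait.phase_offsets.get("hind", 0.0) + TWO_PI * _ANKLE_LEAD), duty)
    )

    # fore limb
    A_f = 0.6 * A
    S_f = gait.stride_px_fore * s
    sx_col = shoulder[0]
    ftip_x = sx_col + off["front_claw_tip"][0] * s + stride_x(f_f, duty, S_f)
    ftip_y = -A_f * swing_bump(f_f, duty)
    wrist_x = sx_col + off["front_claw_wrist"][0] * s + 0.8 * stride_x(f_f, duty, S_f)
    wrist_y = (
        off["front_claw_wrist"][1] * s
        - 0.5 * A_f * swing_bump(_cycle_fraction(phase, gait.phase_offsets.get("fore", math.pi) + TWO_PI * _WRIST_LEAD), duty)
    )

    tail = hip + np.array(off["tail"]) * s + np.array([0.0, 2.0 * s * math.sin(phase)])

    xy = np.zeros((9, 2))
    pts = {
        "nose_tip": nose,
        "eye": eye,
        "ear": ear,
        "front_claw_wrist": np.array([wrist_x, wrist_y]),
        "front_claw_tip": np.array([ftip_x, ftip_y]),
        "back_claw_ankle": np.array([ankle_x, ankle_y]),
        "back_claw_palm": np.array([palm_x, palm_y]),
        "back_claw_tip": np.array([tip_x, tip_y]),
        "tail": tail,
    }
    for i, name in enumerate(LANDMARK_NAMES):
        xy[i] = pts[name] + np.array([ox, oy])
    return LandmarkSet(xy)


def _pose_joints(phase, skeleton, gait, origin):
    """Internal joints (hip, shoulder) needed for rendering, same frame."""
    s = skeleton.body_scale
    bob = 1.5 * s * math.sin(2.0 * phase)
    hip = np.array([0.0, -(skeleton.hip_height * s + bob)]) + origin
    shoulder = np.array(
        [
            skeleton.shoulder_advance * s,
            -(skeleton.shoulder_height * s + 1.5 * s * math.sin(2.0 * phase + 0.5)),
        ]
    ) + origin
    return hip, shoulder


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

# distinct tone per segment so landmarks are visually separable
_TONES = {
    "tail": (105, 85, 75),
    "hind_upper": (150, 110, 80),
    "hind_foot": (200, 150, 60),
    "hind_toe": (225, 110, 60),
    "torso": (165, 135, 105),
    "fore_upper": (120, 160, 90),
    "fore_paw": (90, 190, 160),
    "head": (190, 160, 125),
    "snout": (215, 180, 140),
    "ear": (130, 95, 110),
    "eye": (30, 25, 25),
}


def _draw_capsule(img: np.ndarray, p0, p1, radius: float, color) -> None:
    """Fill all pixels within ``radius`` of segment p0-p1 with ``color``."""
    h, w, _ = img.shape
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    x0 = max(int(math.floor(min(p0[0], p1[0]) - radius)) , 0)
    x1 = min(int(math.ceil(max(p0[0], p1[0]) + radius)) + 1, w)
    y0 = max(int(math.floor(min(p0[1], p1[1]) - radius)), 0)
    y1 = min(int(math.ceil(max(p0[1], p1[1]) + radius)) + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    ys, xs = np.mgrid[y0:y1, x0:x1]
    d = p1 - p0
    denom = float(d @ d)
    if denom == 0.0:
        t = np.zeros_like(xs, dtype=float)
    else:
        t = ((xs - p0[0]) * d[0] + (ys - p0[1]) * d[1]) / denom
        t = np.clip(t, 0.0, 1.0)
    cx = p0[0] + t * d[0]
    cy = p0[1] + t * d[1]
    mask = (xs - cx) ** 2 + (ys - cy) ** 2 <= radius**2
    img[y0:y1, x0:x1][mask] = color


def _draw_ellipse(img: np.ndarray, center, a: float, b: float, angle: float, color) -> None:
    h, w, _ = img.shape
    cx, cy = center
    r = max(a, b)
    x0 = max(int(cx - r) - 1, 0)
    x1 = min(int(cx + r) + 2, w)
    y0 = max(int(cy - r) - 1, 0)
    y1 = min(int(cy + r) + 2, h)
    if x0 >= x1 or y0 >= y1:
        return
    ys, xs = np.mgrid[y0:y1, x0:x1]
    ca, sa = math.cos(angle), math.sin(angle)
    u = (xs - cx) * ca + (ys - cy) * sa
    v = -(xs - cx) * sa + (ys - cy) * ca
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    img[y0:y1, x0:x1][mask] = color


def _background(scene: SceneConfig, ground_y: float) -> np.ndarray:
    img = np.empty((scene.image_height, scene.image_width, 3), dtype=float)
    img[:] = (92.0, 92.0, 97.0)
    if scene.background_style == "textured-belt":
        # belt below the ground line with mild vertical slats
        gy = int(round(ground_y)) + 2
        gy = min(max(gy, 0), scene.image_height)
        img[gy:] = (70.0, 68.0, 66.0)
        xs = np.arange(scene.image_width)
        stripe = ((xs // 12) % 2) * 10.0
        img[gy:] += stripe[None, :, None]
        # back wall line
        img[: max(gy - 90, 0)] = (105.0, 105.0, 110.0)
    return img


def render_frame(
    landmarks: LandmarkSet,
    scene: SceneConfig,
    rng: np.random.Generator | None = None,
    joints: tuple[np.ndarray, np.ndarray] | None = None,
    ground_y: float | None = None,
) -> tuple[np.ndarray, LandmarkSet]:
    """Rasterise one annotated frame.

    Parameters
    ----------
    landmarks:
        Scene-frame landmark positions (as produced by :func:`gait_pose`
        with a scene origin).
    scene:
        Geometry/noise configuration.
    rng:
        Source for pixel noise; with ``noise_sigma == 0`` the render is a
        pure function of pose and scene.
    joints:
        Optional (hip, shoulder) scene positions; estimated from landmarks
        when absent.
    ground_y:
        Scene y of the belt surface; defaults to the lowest claw landmark.

    Returns the uint8 RGB image and the landmarks with visibility flags
    cleared for any point outside the image bounds.
    """
    h, w = scene.image_height, scene.image_width
    xy = landmarks.xy
    if ground_y is None:
        ground_y = float(
            max(xy[LANDMARK_NAMES.index("back_claw_tip"), 1],
                xy[LANDMARK_NAMES.index("front_claw_tip"), 1])
        )
    span_x = xy[:, 0].max() - xy[:, 0].min()
    span_y = xy[:, 1].max() - xy[:, 1].min()
    if span_x > w or span_y > h:
        raise GenerationError(
            f"scene {w}x{h} too small for skeleton span {span_x:.0f}x{span_y:.0f}"
        )

    img = _background(scene, ground_y)

    p = {name: xy[i] for i, name in enumerate(LANDMARK_NAMES)}
    if joints is not None:
        hip, shoulder = joints
    else:
        hip = p["tail"] - np.array([-35.0, -6.0])
        shoulder = p["eye"] - np.array([20.0, -10.0])

    scale = abs(shoulder[0] - hip[0]) / 60.0 if shoulder[0] != hip[0] else 1.0
    r = lambda base: max(base * scale, 1.5)

    # back-to-front draw order
    _draw_capsule(img, hip, p["tail"], r(3.0), _TONES["tail"])
    _draw_capsule(img, hip, p["back_claw_ankle"], r(5.0), _TONES["hind_upper"])
    _draw_capsule(img, p["back_claw_ankle"], p["back_claw_palm"], r(3.0), _TONES["hind_foot"])
    _draw_capsule(img, p["back_claw_palm"], p["back_claw_tip"], r(2.5), _TONES["hind_toe"])
    body_c = 0.5 * (hip + shoulder)
    body_len = np.linalg.norm(shoulder - hip)
    ang = math.atan2(shoulder[1] - hip[1], shoulder[0] - hip[0])
    _draw_ellipse(img, body_c, 0.62 * body_len + 6 * scale, r(16.0), ang, _TONES["torso"])
    _draw_capsule(img, shoulder, p["front_claw_wrist"], r(4.0), _TONES["fore_upper"])
    _draw_capsule(img, p["front_claw_wrist"], p["front_claw_tip"], r(2.5), _TONES["fore_paw"])
    head_c = 0.45 * shoulder + 0.55 * p["eye"]
    _draw_ellipse(img, head_c, r(16.0), r(11.0), math.atan2(
        p["nose_tip"][1] - shoulder[1], p["nose_tip"][0] - shoulder[0]), _TONES["head"])
    _draw_capsule(img, p["eye"], p["nose_tip"], r(3.5), _TONES["snout"])
    _draw_ellipse(img, p["ear"], r(4.5), r(3.5), 0.0, _TONES["ear"])
    _draw_capsule(img, p["eye"], p["eye"], r(2.0), _TONES["eye"])

    if scene.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(scene.rng_seed)
        img += rng.normal(0.0, scene.noise_sigma, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    vis = (
        (xy[:, 0] >= 0) & (xy[:, 0] < w) & (xy[:, 1] >= 0) & (xy[:, 1] < h)
    )
    out = LandmarkSet(xy.copy(), landmarks.visible & vis)
    return img, out


# ---------------------------------------------------------------------------
# dataset / video generation
# ---------------------------------------------------------------------------

_DEFAULT_ANCHOR_X = 96.0
_DEFAULT_GROUND_Y = 112.0


def _scene_anchor(scene: SceneConfig) -> tuple[float, float]:
    """Default hip-ground anchor, scaled from the desk-scale reference."""
    return (
        _DEFAULT_ANCHOR_X * scene.image_width / 256.0,
        _DEFAULT_GROUND_Y * scene.image_height / 128.0,
    )


def _configs_dict(skeleton, gait, scene) -> dict:
    d = {
        "skeleton": asdict(skeleton),
        "gait": asdict(gait),
        "scene": asdict(scene),
        "coordinates": "origin top-left, x right, y down, sub-pixel",
    }
    return d


def generate_dataset(
    n_images: int,
    out_dir: str,
    skeleton: SkeletonConfig | None = None,
    gait: GaitConfig | None = None,
    scene: SceneConfig | None = None,
    seed: int = 0,
):
    """Render ``n_images`` annotated stills at random gait phases/positions.

    Writes PNG images, one ``annotations.json`` and one
    ``ground_truth.json`` (per-image phase, anchor and scale, plus the gait
    parameters) to ``out_dir``.  Identical seeds give byte-identical
    datasets.  Returns the :class:`~ratpose.dataio.AnnotatedDataset`.
    """
    from .dataio import AnnotatedDataset, AnnotatedImage, write_annotations

    if n_images < 1:
        raise ConfigurationError("n_images must be >= 1")
    skeleton = skeleton or SkeletonConfig()
    gait = gait or GaitConfig()
    scene = scene or SceneConfig()
    rng = np.random.default_rng(seed)
    try:
        os.makedirs(out_dir, exist_ok=True)
    except OSError as exc:  # pragma: no cover - filesystem dependent
        raise GenerationError(f"cannot create output directory {out_dir!r}: {exc}")

    ax0, gy0 = _scene_anchor(scene)
    sx_scale = scene.image_width / 256.0
    records = []
    truth = []
    for i in range(n_images):
        phase = float(rng.uniform(0.0, TWO_PI))
        anchor_x = ax0 + float(rng.uniform(-12.0, 12.0)) * sx_scale
        ground_y = gy0 + float(rng.uniform(-4.0, 2.0)) * scene.image_height / 128.0
        scale = float(rng.uniform(0.95, 1.05)) * skeleton.body_scale * min(
            scene.image_width / 256.0, scene.image_height / 128.0
        )
        skel_i = SkeletonConfig(
            segment_lengths=skeleton.segment_lengths,
            body_scale=scale,
            landmark_offsets=skeleton.landmark_offsets,
            hip_height=skeleton.hip_height,
            shoulder_height=skeleton.shoulder_height,
            shoulder_advance=skeleton.shoulder_advance,
        )
        lm = gait_pose(phase, skel_i, gait, origin=(anchor_x, ground_y))
        joints = _pose_joints(phase, skel_i, gait, np.array([anchor_x, ground_y]))
        img, lm = render_frame(lm, scene, rng=rng, joints=joints, ground_y=ground_y)
        fname = f"img_{i:05d}.png"
        path = os.path.join(out_dir, fname)
        try:
            Image.fromarray(img).save(path)
        except OSError as exc:  # pragma: no cover
            raise GenerationError(f"failed writing image {path!r}: {exc}")
        records.append(
            AnnotatedImage(
                image_path=fname,
                width=scene.image_width,
                height=scene.image_height,
                landmarks=lm,
                frame_index=i,
            )
        )
        truth.append(
            {"image": fname, "phase": phase, "anchor_x": anchor_x,
             "ground_y": ground_y, "body_scale": scale}
        )

    dataset = AnnotatedDataset(records=records, metadata=_configs_dict(skeleton, gait, scene) | {"seed": seed}, root=out_dir)
    write_annotations(dataset, os.path.join(out_dir, "annotations.json"))
    with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
        json.dump({"gait": asdict(gait), "frames": truth}, fh, indent=1)
    return dataset


def generate_video(
    n_frames: int,
    out_dir: str | None,
    skeleton: SkeletonConfig | None = None,
    gait: GaitConfig | None = None,
    scene: SceneConfig | None = None,
    seed: int = 0,
):
    """Render an ordered gait sequence with per-frame ground truth.

    Consecutive frames advance the gait phase by ``2*pi / period_frames``;
    the body anchor advances by ``forward_speed_px_per_frame``.  Returns
    ``(frames, trajectory)`` where ``frames`` is a list of uint8 images and
    ``trajectory`` a :class:`~ratpose.dataio.TrajectoryRecord` of the true
    landmark positions.  When ``out_dir`` is given, numbered PNGs and the
    ground-truth trajectory CSV are written there as well.
    """
    from .dataio import TrajectoryRecord, write_trajectory

    skeleton = skeleton or SkeletonConfig()
    gait = gait or GaitConfig()
    scene = scene or SceneConfig()
    if n_frames < gait.period_frames:
        raise ConfigurationError("n_frames must cover at least one gait period")
    rng = np.random.default_rng(seed)
    ax0, gy0 = _scene_anchor(scene)
    scale = skeleton.body_scale * min(scene.image_width / 256.0, scene.image_height / 128.0)
    skel = SkeletonConfig(
        segment_lengths=skeleton.segment_lengths,
        body_scale=scale,
        landmark_offsets=skeleton.landmark_offsets,
        hip_height=skeleton.hip_height,
        shoulder_height=skeleton.shoulder_height,
        shoulder_advance=skeleton.shoulder_advance,
    )

    frames = []
    sets = []
    for t in range(n_frames):
        phase = TWO_PI * t / gait.period_frames
        anchor = (ax0 + gait.forward_speed_px_per_frame * t, gy0)
        lm = gait_pose(phase, skel, gait, origin=anchor)
        joints = _pose_joints(phase, skel, gait, np.array(anchor))
        img, lm = render_frame(lm, scene, rng=rng, joints=joints, ground_y=gy0)
        frames.append(img)
        sets.append(lm)

    traj = TrajectoryRecord(
        frames=list(range(n_frames)),
        landmark_sets=sets,
        frame_rate=scene.frame_rate,
        image_height=scene.image_height,
    )
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for t, img in enumerate(frames):
            Image.fromarray(img).save(os.path.join(out_dir, f"frame_{t:05d}.png"))
        write_trajectory(traj, os.path.join(out_dir, "trajectory_truth.csv"))
        with open(os.path.join(out_dir, "video_config.json"), "w") as fh:
            json.dump(_configs_dict(skeleton, gait, scene) | {"seed": seed, "n_frames": n_frames}, fh, indent=1)
    return frames, traj
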