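"""Losses, augmentation, input resizing and the training driver.

Every cascade stage carries its own loss term (intermediate supervision):
gradient reaches the early stages directly, which keeps deep cascades
trainable.  The loss depends on the decoder:

* FCR - smooth L1 between regressed and label coordinates;
* HMP - mean squared error between predicted and Gaussian label heatmaps;
* HIR - each stage's heatmap is decoded with the differentiable integral
  regression and smooth L1 is applied to the decoded coordinates.

Coordinate losses (FCR, HIR) are computed in input-pixel units for both
decoders so their magnitudes are comparable.  Images keep their natural
unequal width/height: they are resized anisotropically (no padding) to the
model's input size, and landmark coordinates are scaled per axis by the same
factors.  Colour augmentation perturbs hue/saturation/value; geometry and
landmarks are untouched.

Optimiser defaults (Adam, lr 1e-3, batch 8) are chosen for fast CPU
convergence on desk-scale synthetic data; all are configurable.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image
from skimage import color as skcolor

from . import autodiff as ad
from .autodiff.tensor import Tensor
from .dataio import AnnotatedDataset
from .errors import ConfigurationError, TrainingError
from .evaluate import EvalConfig, EvaluationReport, evaluate
from .heatcodec import GaussianLabelConfig, encode_gaussian
from .landmarks import LANDMARK_NAMES, N_LANDMARKS, LandmarkSet
from .models import (
    CascadeModel,
    StagePredictions,
    decode_stage_output,
    hir_coordinates,
)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def smooth_l1(x):
    """Elementwise smooth L1: ``0.5 x^2`` for ``|x| < 1``, ``|x| - 0.5``
    otherwise.  Continuous at the branch point and nonnegative."""
    x = np.asarray(x, dtype=float)
    out = np.where(np.abs(x) < 1.0, 0.5 * x**2, np.abs(x) - 0.5)
    return float(out) if out.ndim == 0 else out


def heatmap_mse(pred, label) -> float:
    """Mean squared difference over all cells and channels of two stacks."""
    pv = pred.values if hasattr(pred, "values") else np.asarray(pred)
    lv = label.values if hasattr(label, "values") else np.asarray(label)
    if pv.shape != lv.shape:
        raise ConfigurationError(
            f"heatmap shape mismatch: {pv.shape} vs {lv.shape}"
        )
    return float(np.mean((pv - lv) ** 2))


def _coord_stage_loss(coords: Tensor, target: np.ndarray, visible: np.ndarray) -> Tensor:
    """Mean smooth-L1 over the visible coordinates (Tensor-valued)."""
    diff = coords - target
    sl = ad.smooth_l1_tensor(diff)
    mask = visible[..., None].astype(coords.dtype)
    n_terms = max(float(mask.sum() * 2), 1.0)
    return (sl * mask).sum() * (1.0 / n_terms)


def multi_stage_loss(
    preds: StagePredictions,
    target,
    decoder: str | None = None,
    visible: np.ndarray | None = None,
) -> Tensor:
    """Sum of per-stage losses (intermediate supervision).

    ``target`` is an ``(N, 9, 2)`` input-pixel coordinate array for FCR/HIR
    or an ``(N, 9, H_map, W_map)`` label-heatmap array for HMP.
    """
    decoder = decoder or preds.config.decoder
    cfg = preds.config
    target = np.asarray(target)
    if decoder in ("FCR", "HIR"):
        if target.ndim != 3 or target.shape[1:] != (N_LANDMARKS, 2):
            raise ConfigurationError(
                f"{decoder} needs (N, 9, 2) coordinate targets, got {target.shape}"
            )
    elif target.ndim != 4:
        raise ConfigurationError(
            f"HMP needs (N, 9, H_map, W_map) heatmap targets, got {target.shape}"
        )
    if visible is None:
        visible = np.ones(target.shape[:2] if target.ndim >= 2 else (1,), dtype=bool)

    total: Tensor | None = None
    for out in preds.outputs:
        if decoder == "FCR":
            n = out.shape[0]
            h, w = cfg.input_size
            coords = out.reshape(n, N_LANDMARKS, 2) * np.array(
                [w, h], dtype=out.dtype
            )
            stage = _coord_stage_loss(coords, target, visible)
        elif decoder == "HIR":
            coords = hir_coordinates(out, cfg.stride)
            stage = _coord_stage_loss(coords, target, visible)
        elif decoder == "HMP":
            diff = out - target.astype(out.dtype)
            stage = (diff * diff).mean()
        else:
            raise ConfigurationError(f"unknown decoder {decoder!r}")
        total = stage if total is None else total + stage
    return total


# ---------------------------------------------------------------------------
# augmentation and resizing
# ---------------------------------------------------------------------------

def hsv_shift(image: np.ndarray, dh: float, ds: float, dv: float) -> np.ndarray:
    """Shift an RGB image in HSV space: hue by ``dh`` turns (wrapping),
    saturation/value by ``ds``/``dv`` (clamped to [0, 1])."""
    was_uint8 = image.dtype == np.uint8
    rgb = image.astype(float) / (255.0 if was_uint8 else 1.0)
    hsv = skcolor.rgb2hsv(rgb)
    hsv[..., 0] = (hsv[..., 0] + dh) % 1.0
    hsv[..., 1] = np.clip(hsv[..., 1] + ds, 0.0, 1.0)
    hsv[..., 2] = np.clip(hsv[..., 2] + dv, 0.0, 1.0)
    out = skcolor.hsv2rgb(hsv)
    if was_uint8:
        return np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)
    return out


def hsv_jitter(
    image: np.ndarray,
    ranges: tuple[float, float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Random HSV perturbation within symmetric ``ranges`` = (dh, ds, dv).

    Landmark coordinates are unaffected (colour-only augmentation)."""
    dh, ds, dv = ranges
    if dh == ds == dv == 0:
        return image
    return hsv_shift(
        image,
        float(rng.uniform(-dh, dh)),
        float(rng.uniform(-ds, ds)),
        float(rng.uniform(-dv, dv)),
    )


def resize_for_input(
    image: np.ndarray,
    landmarks: LandmarkSet | None,
    input_size: tuple[int, int],
) -> tuple[np.ndarray, LandmarkSet | None]:
    """Direct anisotropic resize (no padding) to ``input_size`` = (H, W);
    landmark x/y are scaled by the same per-axis factors."""
    h_in, w_in = input_size
    if h_in <= 0 or w_in <= 0:
        raise ConfigurationError("input size must be positive")
    if image.size == 0:
        raise ConfigurationError("empty image")
    h0, w0 = image.shape[:2]
    if (h0, w0) == (h_in, w_in):
        return image, landmarks.copy() if landmarks is not None else None
    resized = np.asarray(
        Image.fromarray(image).resize((w_in, h_in), Image.BILINEAR)
    )
    lm = landmarks.scaled(w_in / w0, h_in / h0) if landmarks is not None else None
    return resized, lm


# ---------------------------------------------------------------------------
# training driver
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    epochs: int = 10
    batch_size: int = 4
    learning_rate: float = 2e-3
    optimizer: str = "adam"
    eval_every_epochs: int = 2
    seed: int = 0
    hsv_ranges: tuple[float, float, float] = (0.05, 0.2, 0.2)
    eval_margin: float = 0.1

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.eval_every_epochs < 1:
            raise ConfigurationError("epochs and eval_every_epochs must be >= 1")
        if not all(0.0 <= r <= 1.0 for r in self.hsv_ranges):
            raise ConfigurationError("HSV jitter fractions must lie in [0, 1]")
        if self.optimizer.lower() not in ("adam", "sgd"):
            raise ConfigurationError("optimizer must be 'adam' or 'sgd'")


@dataclass
class TrainHistory:
    """Evaluation points (epoch, per-stage reports) plus the loss trace."""

    eval_epochs: list[int] = field(default_factory=list)
    stage_reports: list[list[EvaluationReport]] = field(default_factory=list)
    epoch_losses: list[float] = field(default_factory=list)
    wall_time_s: float = 0.0

    def final_report(self, stage: int = -1) -> EvaluationReport:
        return self.stage_reports[-1][stage]


def _prepare_split(dataset: AnnotatedDataset, model: CascadeModel):
    """Load, resize and normalise a split once; returns images (N,3,H,W)
    float32, input-pixel targets, visibility and the original records."""
    h_in, w_in = model.cfg.input_size
    images = []
    targets = np.zeros((len(dataset), N_LANDMARKS, 2), dtype=np.float32)
    visible = np.zeros((len(dataset), N_LANDMARKS), dtype=bool)
    scales = np.zeros((len(dataset), 2))
    for i, rec in enumerate(dataset.records):
        img = dataset.load_image(rec)
        img, lm = resize_for_input(img, rec.landmarks, (h_in, w_in))
        images.append(img)
        targets[i] = lm.xy
        visible[i] = lm.visible
        scales[i] = (rec.width / w_in, rec.height / h_in)
    return images, targets, visible, scales


def _to_batch(images: list[np.ndarray]) -> np.ndarray:
    arr = np.stack(images).astype(np.float32) / 255.0
    return np.ascontiguousarray(arr.transpose(0, 3, 1, 2))


def predict_landmarks(
    model: CascadeModel,
    images: list[np.ndarray],
    original_sizes: list[tuple[int, int]] | None = None,
    batch_size: int = 8,
    stage: int = -1,
) -> list[LandmarkSet]:
    """Decode one stage's predictions for a list of RGB images, mapped back
    to each image's original resolution."""
    h_in, w_in = model.cfg.input_size
    prepared = []
    scales = []
    for i, img in enumerate(images):
        orig = original_sizes[i] if original_sizes else (img.shape[1], img.shape[0])
        resized, _ = resize_for_input(img, None, (h_in, w_in))
        prepared.append(resized)
        scales.append((orig[0] / w_in, orig[1] / h_in))
    out: list[LandmarkSet] = []
    was_training = model.training
    model.eval()
    with ad.no_grad():
        for lo in range(0, len(prepared), batch_size):
            batch = _to_batch(prepared[lo : lo + batch_size])
            preds = model.forward(batch)
            coords = decode_stage_output(preds.outputs[stage].data, model.cfg)
            for j in range(coords.shape[0]):
                sx, sy = scales[lo + j]
                xy = coords[j] * np.array([sx, sy])
                out.append(LandmarkSet(xy))
    if was_training:
        model.train()
    return out


def _evaluate_stages(
    model: CascadeModel,
    images: list[np.ndarray],
    scales: np.ndarray,
    test_set: AnnotatedDataset,
    p: float,
    batch_size: int,
) -> list[EvaluationReport]:
    """Evaluate every cascade stage's decoded predictions on the test set."""
    n_stages = model.cfg.stages
    per_stage_preds: list[list[LandmarkSet]] = [[] for _ in range(n_stages)]
    was_training = model.training
    model.eval()
    with ad.no_grad():
        for lo in range(0, len(images), batch_size):
            batch = _to_batch(images[lo : lo + batch_size])
            preds = model.forward(batch)
            for s in range(n_stages):
                coords = decode_stage_output(preds.outputs[s].data, model.cfg)
                for j in range(coords.shape[0]):
                    xy = coords[j] * scales[lo + j]
                    per_stage_preds[s].append(LandmarkSet(xy))
    if was_training:
        model.train()
    cfg = EvalConfig(p=p)
    return [evaluate(per_stage_preds[s], test_set, cfg) for s in range(n_stages)]


def train(
    model: CascadeModel,
    train_set: AnnotatedDataset,
    test_set: AnnotatedDataset,
    cfg: TrainConfig,
) -> tuple[CascadeModel, TrainHistory]:
    """Train the cascade with intermediate supervision.

    Shuffling and colour augmentation are driven by ``cfg.seed`` only, so a
    fixed seed reproduces the run exactly on CPU.  Every
    ``eval_every_epochs`` epochs, every stage's decoded predictions are
    scored on ``test_set`` with the nose-eye-normalised criterion.
    """
    t0 = time.time()
    overlap = {r.image_path for r in train_set.records} & {
        r.image_path for r in test_set.records
    }
    if overlap:
        raise TrainingError(f"train/test overlap: {sorted(overlap)[:3]}...")
    rng = np.random.default_rng(cfg.seed)
    images, targets, visible, _ = _prepare_split(train_set, model)
    test_images, _, _, test_scales = _prepare_split(test_set, model)

    decoder = model.cfg.decoder
    heat_targets = None
    if decoder == "HMP":
        h_in, w_in = model.cfg.input_size
        gauss = GaussianLabelConfig()
        heat_targets = np.stack(
            [
                encode_gaussian(
                    LandmarkSet(targets[i], visible[i]),
                    model.cfg.stride,
                    (h_in, w_in),
                    gauss,
                ).values
                for i in range(len(images))
            ]
        ).astype(np.float32)

    params = model.parameters()
    if cfg.optimizer.lower() == "adam":
        opt = ad.Adam(params, lr=cfg.learning_rate)
    else:
        opt = ad.SGD(params, lr=cfg.learning_rate)

    history = TrainHistory()
    n = len(images)
    model.train()
    for epoch in range(1, cfg.epochs + 1):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for lo in range(0, n, cfg.batch_size):
            idx = perm[lo : lo + cfg.batch_size]
            batch_imgs = [
                hsv_jitter(images[i], cfg.hsv_ranges, rng) for i in idx
            ]
            x = _to_batch(batch_imgs)
            preds = model.forward(x)
            if decoder == "HMP":
                loss = multi_stage_loss(preds, heat_targets[idx], decoder)
            else:
                loss = multi_stage_loss(
                    preds, targets[idx], decoder, visible=visible[idx]
                )
            lval = float(loss.data)
            if not np.isfinite(lval):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += lval
            n_batches += 1
        history.epoch_losses.append(epoch_loss / max(n_batches, 1))
        if epoch % cfg.eval_every_epochs == 0 or epoch == cfg.epochs:
            if epoch in history.eval_epochs:
                continue
            reports = _evaluate_stages(
                model, test_images, test_scales, test_set, cfg.eval_margin,
                cfg.batch_size,
            )
            history.eval_epochs.append(epoch)
            history.stage_reports.append(reports)
    history.wall_time_s = time.time() - t0
    return model, history


def write_history(history: TrainHistory, path: str) -> None:
    """Training-history CSV: one row per (evaluation epoch, stage) with
    per-landmark accuracies and the total."""
    rows = []
    for epoch, reports in zip(history.eval_epochs, history.stage_reports):
        for s, rep in enumerate(reports):
            row = {"epoch": epoch, "stage": s + 1}
            row.update({name: rep.per_landmark[name] for name in LANDMARK_NAMES})
            row["total"] = rep.total
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
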