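"""Cascade landmark-estimation networks (CCN and CHN).

Both structures share a basic feature-extraction backbone: repeated
[conv, conv, downsample] blocks followed by five same-size convolutions.
At stride 8 the backbone has three downsampling layers and 11 convolution
layers (feature map = input/8); the stride-4 variant drops one
[conv, conv, downsample] block (9 convolutions, two downsamplings,
feature map = input/4).  Channels double at each downsampling from
``base_channels``, capped at ``max_channels``.

CCN ("cascade convolution network"): four refinement stages of nine 3x3
convolutions each.  Stage 1 consumes the backbone features; later stages
consume the channel-concatenation of backbone features and the previous
stage's prediction, merged by a 1x1 feature-fusion convolution.

CHN ("cascade hourglass network"): two stages, each an hourglass with two
max-pool downsamplings, two nearest-neighbour upsamplings and residual skip
connections at every resolution; stage 2 fuses backbone features with the
stage-1 output.

Heads: a 1x1 convolution to 9 heatmap channels (HMP/HIR decoding) or a
fully connected layer regressing 18 values = 9 (x, y) pairs normalised by
input size (FCR).  Every stage has its own head (intermediate supervision);
inference reads the final stage only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff.layers import count_macs
from .autodiff.tensor import Tensor
from .errors import BuildError, ConfigurationError, ShapeError
from .heatcodec import HeatmapStack, decode_hmp, decode_hir
from .landmarks import N_LANDMARKS

_STRUCTURES = ("CCN", "CHN")
_DECODERS = ("FCR", "HMP", "HIR")


@dataclass
class ModelConfig:
    """Architecture description embedded in every checkpoint."""

    structure: str = "CCN"
    decoder: str = "HIR"
    stride: int = 8
    stages: int | None = None        # default: 4 for CCN, 2 for CHN
    base_channels: int = 32
    max_channels: int | None = None  # default: 4 * base_channels
    stage_channels: int | None = None  # default: backbone output channels
    input_size: tuple[int, int] = (256, 512)  # (H, W)
    init_seed: int = 0

    def __post_init__(self) -> None:
        if self.structure not in _STRUCTURES:
            raise ConfigurationError(f"structure must be one of {_STRUCTURES}")
        if self.decoder not in _DECODERS:
            raise ConfigurationError(f"decoder must be one of {_DECODERS}")
        if self.stride not in (8, 4):
            raise ConfigurationError("stride must be 8 or 4")
        if self.stages is None:
            self.stages = 4 if self.structure == "CCN" else 2
        if self.stages < 1:
            raise ConfigurationError("stages must be >= 1")
        if self.max_channels is None:
            self.max_channels = 4 * self.base_channels
        self.input_size = (int(self.input_size[0]), int(self.input_size[1]))
        h, w = self.input_size
        if h % self.stride or w % self.stride:
            raise BuildError(
                f"input size {self.input_size} not divisible by stride {self.stride}"
            )
        if self.structure == "CHN" and ((h // self.stride) % 4 or (w // self.stride) % 4):
            raise BuildError(
                "CHN hourglass needs the feature map divisible by 4 "
                f"(got {h // self.stride}x{w // self.stride})"
            )

    @property
    def n_downsamples(self) -> int:
        return 3 if self.stride == 8 else 2

    @property
    def backbone_channels(self) -> int:
        return min(self.base_channels * 2**self.n_downsamples, self.max_channels)

    @property
    def map_size(self) -> tuple[int, int]:
        return self.input_size[0] // self.stride, self.input_size[1] // self.stride


@dataclass
class StagePredictions:
    """All per-stage outputs of one forward pass.

    ``outputs`` holds one tensor per stage: ``(N, 9, H_map, W_map)`` heatmaps
    for HMP/HIR, ``(N, 18)`` normalised coordinates for FCR.  Training uses
    all of them (intermediate supervision); inference reads :attr:`final`.
    """

    outputs: list[Tensor]
    kind: str  # "heatmap" or "coords"
    config: ModelConfig = field(repr=False, default=None)  # type: ignore[assignment]

    def __len__(self) -> int:
        return len(self.outputs)

    @property
    def final(self) -> Tensor:
        return self.outputs[-1]

    def stage_heatmaps(self, stage: int, sample: int) -> HeatmapStack:
        if self.kind != "heatmap":
            raise ConfigurationError("FCR predictions carry no heatmaps")
        return HeatmapStack(
            np.asarray(self.outputs[stage].data[sample], dtype=float),
            self.config.stride,
            self.config.input_size,
        )


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _conv_bn_relu(cin, cout, rng, stride=1):
    return ad.Sequential(
        ad.Conv2d(cin, cout, 3, stride=stride, padding=1, rng=rng),
        ad.BatchNorm2d(cout),
        ad.ReLU(),
    )


class _Residual(ad.Module):
    def __init__(self, channels, rng):
        super().__init__()
        self.conv1 = ad.Conv2d(channels, channels, 3, padding=1, rng=rng)
        self.bn1 = ad.BatchNorm2d(channels)
        self.conv2 = ad.Conv2d(channels, channels, 3, padding=1, rng=rng)
        self.bn2 = ad.BatchNorm2d(channels)

    def forward(self, x):
        y = self.bn1(self.conv1(x)).relu()
        y = self.bn2(self.conv2(y))
        return (y + x).relu()


class FeatureExtractor(ad.Module):
    """The shared basic feature-extraction backbone.

    Operates channels-last: input ``(N, H_in, W_in, 3)``, output
    ``(N, H_in/stride, W_in/stride, C)``.  A ``(N, 3, H, W)`` array is
    transposed automatically for convenience.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        mods: list[ad.Module] = []
        self.conv_layer_count = 0
        self.downsample_count = 0
        cin = 3
        c = cfg.base_channels
        for _ in range(cfg.n_downsamples):
            mods.append(_conv_bn_relu(cin, c, rng))
            mods.append(_conv_bn_relu(c, c, rng))
            self.conv_layer_count += 2
            cnext = min(c * 2, cfg.max_channels)
            mods.append(_conv_bn_relu(c, cnext, rng, stride=2))
            self.downsample_count += 1
            cin = c = cnext
        for _ in range(5):
            mods.append(_conv_bn_relu(c, c, rng))
            self.conv_layer_count += 1
        self.body = ad.Sequential(*mods)
        self.out_channels = c

    def forward(self, x):
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x))
        if x.ndim == 4 and x.shape[1] == 3 and x.shape[3] != 3:
            x = x.transpose((0, 2, 3, 1))
        return self.body(x)


class _CCNStage(ad.Module):
    """1x1 feature-fusion entry + nine 3x3 convolutions + head."""

    def __init__(self, cin, width, cfg, rng):
        super().__init__()
        self.fuse = _conv_bn_relu_1x1(cin, width, rng)
        self.body = ad.Sequential(*[_conv_bn_relu(width, width, rng) for _ in range(9)])
        self.head = _make_head(width, cfg, rng)
        self.decoder = cfg.decoder

    def forward(self, x):
        feat = self.body(self.fuse(x))
        return _apply_head(self.head, feat, self.decoder)


class _Hourglass(ad.Module):
    """Two-level encoder-decoder with residual skips; max-pool down,
    nearest-neighbour up."""

    def __init__(self, channels, rng):
        super().__init__()
        self.skip1 = _Residual(channels, rng)
        self.pool1 = ad.MaxPool2d()
        self.res1 = _Residual(channels, rng)
        self.skip2 = _Residual(channels, rng)
        self.pool2 = ad.MaxPool2d()
        self.bottom1 = _Residual(channels, rng)
        self.bottom2 = _Residual(channels, rng)
        self.up1 = ad.UpsampleNearest2d(2)
        self.res2 = _Residual(channels, rng)
        self.up2 = ad.UpsampleNearest2d(2)
        self.res3 = _Residual(channels, rng)

    def forward(self, x):
        s1 = self.skip1(x)
        d1 = self.res1(self.pool1(x))
        s2 = self.skip2(d1)
        d2 = self.bottom2(self.bottom1(self.pool2(d1)))
        u1 = self.res2(self.up1(d2) + s2)
        u2 = self.res3(self.up2(u1) + s1)
        return u2


class _CHNStage(ad.Module):
    def __init__(self, cin, width, cfg, rng):
        super().__init__()
        self.fuse = _conv_bn_relu_1x1(cin, width, rng)
        self.hourglass = _Hourglass(width, rng)
        self.head = _make_head(width, cfg, rng)
        self.decoder = cfg.decoder

    def forward(self, x):
        feat = self.hourglass(self.fuse(x))
        return _apply_head(self.head, feat, self.decoder)


def _conv_bn_relu_1x1(cin, cout, rng):
    return ad.Sequential(
        ad.Conv2d(cin, cout, 1, stride=1, padding=0, rng=rng),
        ad.BatchNorm2d(cout),
        ad.ReLU(),
    )


def _make_head(width, cfg, rng):
    if cfg.decoder == "FCR":
        h_map, w_map = cfg.map_size
        return ad.Linear(width * h_map * w_map, 2 * N_LANDMARKS, rng=rng)
    return ad.Conv2d(width, N_LANDMARKS, 1, stride=1, padding=0, rng=rng)


def _apply_head(head, feat, decoder):
    """Returns (public stage output, fusion map for the next stage).

    Feature maps are channels-last internally; heatmap outputs are exposed
    as ``(N, 9, H_map, W_map)``.
    """
    if decoder == "FCR":
        n = feat.shape[0]
        return head(feat.reshape(n, -1)), feat
    out_cl = head(feat)  # (N, H, W, 9)
    return out_cl.transpose((0, 3, 1, 2)), out_cl


# ---------------------------------------------------------------------------
# the cascade model
# ---------------------------------------------------------------------------

class CascadeModel(ad.Module):
    def __init__(self, cfg: ModelConfig):
        super().__init__()
        rng = np.random.default_rng(cfg.init_seed)
        self.cfg = cfg
        self.backbone = FeatureExtractor(cfg, rng)
        cb = self.backbone.out_channels
        width = cfg.stage_channels or cb
        stage_cls = _CCNStage if cfg.structure == "CCN" else _CHNStage
        # under FCR the previous stage's prediction is a coordinate vector,
        # which cannot be concatenated spatially; the stage's pre-head
        # feature map is fused instead
        prev_ch = width if cfg.decoder == "FCR" else N_LANDMARKS
        self.stage_modules = []
        for s in range(cfg.stages):
            cin = cb if s == 0 else cb + prev_ch
            stage = stage_cls(cin, width, cfg, rng)
            self.stage_modules.append(stage)
            self._children[f"stage{s}"] = stage
        self.stage_width = width

    def forward(self, images) -> StagePredictions:
        """Run all cascade stages on a batch.

        ``images``: ``(N, 3, H_in, W_in)`` float array (or Tensor), values
        roughly in [0, 1].
        """
        x = images if isinstance(images, Tensor) else Tensor(np.asarray(images))
        h, w = self.cfg.input_size
        if x.ndim != 4 or x.shape[1] != 3 or x.shape[2] != h or x.shape[3] != w:
            raise ShapeError(
                f"expected input of shape (N, 3, {h}, {w}), got {tuple(x.shape)}"
            )
        feats = self.backbone(x.transpose((0, 2, 3, 1)))  # channels-last inside
        outputs = []
        prev_fuse = None
        for s, stage in enumerate(self.stage_modules):
            inp = feats if s == 0 else ad.concat([feats, prev_fuse], axis=3)
            out, fuse = stage(inp)
            outputs.append(out)
            prev_fuse = fuse
        kind = "coords" if self.cfg.decoder == "FCR" else "heatmap"
        return StagePredictions(outputs=outputs, kind=kind, config=self.cfg)

    # -- decoding ----------------------------------------------------------
    def decode_stage(self, preds: StagePredictions, stage: int = -1) -> np.ndarray:
        """Decode one stage's raw output to input-pixel coordinates
        ``(N, 9, 2)`` using the configured decoder."""
        out = preds.outputs[stage].data
        return decode_stage_output(out, self.cfg)

    def predict(self, images) -> np.ndarray:
        """Inference: final-stage decoded coordinates, ``(N, 9, 2)`` px."""
        with ad.no_grad():
            was_training = self.training
            self.eval()
            preds = self.forward(images)
            if was_training:
                self.train()
        return self.decode_stage(preds, -1)

    # -- accounting --------------------------------------------------------
    def count_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def count_multiply_adds(self, input_size: tuple[int, int] | None = None) -> int:
        """Analytic multiply-add count of one single-image forward pass."""
        h, w = input_size or self.cfg.input_size
        if (h, w) != tuple(self.cfg.input_size):
            raise ConfigurationError("model is built for a fixed input size")
        x = np.zeros((1, 3, h, w), dtype=np.float32)
        was_training = self.training
        self.eval()
        with ad.no_grad(), count_macs() as counter:
            self.forward(x)
        if was_training:
            self.train()
        return int(counter[0])


def decode_stage_output(out: np.ndarray, cfg: ModelConfig) -> np.ndarray:
    """Decode raw stage output (numpy) to input-pixel coordinates."""
    h, w = cfg.input_size
    if cfg.decoder == "FCR":
        coords = np.asarray(out, dtype=float).reshape(-1, N_LANDMARKS, 2).copy()
        coords[:, :, 0] *= w
        coords[:, :, 1] *= h
        return coords
    decode = decode_hmp if cfg.decoder == "HMP" else decode_hir
    n = out.shape[0]
    coords = np.zeros((n, N_LANDMARKS, 2))
    for i in range(n):
        stack = HeatmapStack(np.asarray(out[i], dtype=float), cfg.stride, cfg.input_size)
        coords[i] = decode(stack).xy
    return coords


def hir_coordinates(maps: Tensor, stride: int) -> Tensor:
    """Differentiable integral-regression decode of a heatmap tensor.

    ``maps``: ``(N, 9, H_map, W_map)``; returns ``(N, 9, 2)`` input-pixel
    coordinates.  Softmax is taken jointly over each channel's map;
    marginal column/row sums weighted by their indices give the expected
    coordinate, scaled by the stride.
    """
    n, k, h_map, w_map = maps.shape
    flat = maps.reshape(n * k, h_map * w_map)
    p = flat.softmax(axis=-1).reshape(n * k, h_map, w_map)
    col_w = p.sum(axis=1)  # (n*k, W_map)
    row_w = p.sum(axis=2)  # (n*k, H_map)
    xs = (col_w * np.arange(w_map, dtype=maps.dtype)).sum(axis=1) * float(stride)
    ys = (row_w * np.arange(h_map, dtype=maps.dtype)).sum(axis=1) * float(stride)
    out = ad.concat([xs.reshape(n * k, 1), ys.reshape(n * k, 1)], axis=1)
    return out.reshape(n, k, 2)


def build_backbone(cfg: ModelConfig) -> FeatureExtractor:
    """The basic feature extractor on its own (stride-8 or stride-4)."""
    return FeatureExtractor(cfg, np.random.default_rng(cfg.init_seed))


def build_model(cfg: ModelConfig) -> CascadeModel:
    return CascadeModel(cfg)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: CascadeModel, path: str) -> None:
    """Save weights with the ModelConfig embedded, so loading needs no
    out-of-band shape knowledge."""
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(asdict(model.cfg)).encode(), dtype=np.uint8
    )
    np.savez(path, **state)


def load_checkpoint(path: str) -> CascadeModel:
    with np.load(path if path.endswith(".npz") else path + ".npz") as data:
        cfg_json = bytes(data["__config__"]).decode()
        cfg_dict = json.loads(cfg_json)
        cfg_dict["input_size"] = tuple(cfg_dict["input_size"])
        cfg = ModelConfig(**cfg_dict)
        model = CascadeModel(cfg)
        state = {k: data[k] for k in data.files if k != "__config__"}
    model.load_state_dict(state)
    return model
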