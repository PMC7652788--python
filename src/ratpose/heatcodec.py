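"""Gaussian heatmap encoding and the HMP / HIR coordinate decoders.

A landmark label can be represented either as coordinates or as a
per-landmark probability heatmap on a grid ``stride`` times coarser than the
input image.  This module converts between the two representations:

``encode_gaussian``
    writes a separable Gaussian bump of amplitude ``A`` centred on the
    landmark.  The exponent divides each squared offset by ``2*sigma`` (the
    bump's width parameters are used directly as printed variances rather
    than being squared again); with the default ``sigma = 3`` the value three
    map cells from the centre along x is ``exp(-9/6) ~= 0.223``.

``decode_hmp``
    "heatmap maximum position": bicubic-upsample the map back to input
    resolution (Catmull-Rom kernel, ``a = -0.5``) and take the integer
    argmax.  Not differentiable; accuracy is limited by quantisation.

``decode_hir``
    "heatmap integral regression": softmax the whole map jointly, marginalise
    over rows/columns, and take the probability-weighted expected index
    (soft-argmax), scaled by the stride to input resolution.  Differentiable
    and sub-pixel.

Map/input coordinate mapping is ``x_map = x_in / stride`` on encode and
``x_in = x_map * stride`` on decode, with no half-pixel offset, so an
encode/decode round trip is exactly invertible for interior landmarks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DecodeError, EncodeError
from .landmarks import N_LANDMARKS, LandmarkSet


@dataclass
class GaussianLabelConfig:
    """Amplitude and per-axis width of the encoded Gaussian bump."""

    amplitude: float = 1.0
    sigma_x: float = 3.0
    sigma_y: float = 3.0

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ConfigurationError("amplitude and sigmas must be > 0")


@dataclass
class HeatmapStack:
    """Nine per-landmark score maps at a known stride.

    ``values`` has shape ``(9, H_map, W_map)`` with
    ``H_map = H_in / stride`` (exact division enforced).
    """

    values: np.ndarray
    stride: int
    input_size: tuple[int, int]  # (H_in, W_in)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        h_in, w_in = self.input_size
        if h_in % self.stride or w_in % self.stride:
            raise ConfigurationError(
                f"input size {self.input_size} not divisible by stride {self.stride}"
            )
        expected = (N_LANDMARKS, h_in // self.stride, w_in // self.stride)
        if self.values.shape != expected:
            raise ConfigurationError(
                f"heatmap stack shape {self.values.shape} != expected {expected}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("heatmap values must be finite")

    @property
    def map_size(self) -> tuple[int, int]:
        return self.values.shape[1], self.values.shape[2]


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

def encode_gaussian(
    landmarks: LandmarkSet,
    stride: int,
    input_size: tuple[int, int],
    cfg: GaussianLabelConfig | None = None,
) -> HeatmapStack:
    """Encode landmark coordinates as Gaussian label heatmaps.

    Invisible landmarks yield an all-zero channel; a visible landmark whose
    map-space centre falls outside the grid raises :class:`EncodeError`.
    """
    cfg = cfg or GaussianLabelConfig()
    h_in, w_in = input_size
    if h_in % stride or w_in % stride:
        raise EncodeError(f"input size {input_size} not divisible by stride {stride}")
    h_map, w_map = h_in // stride, w_in // stride
    gx = np.arange(w_map, dtype=float)
    gy = np.arange(h_map, dtype=float)
    maps = np.zeros((N_LANDMARKS, h_map, w_map))
    for k in range(N_LANDMARKS):
        if not landmarks.visible[k]:
            continue
        xc = landmarks.xy[k, 0] / stride
        yc = landmarks.xy[k, 1] / stride
        if not (0.0 <= xc < w_map and 0.0 <= yc < h_map):
            raise EncodeError(
                f"landmark {landmarks.names[k]!r} centre ({xc:.2f}, {yc:.2f}) "
                f"off the {w_map}x{h_map} map grid"
            )
        ex = np.exp(-((gx - xc) ** 2) / (2.0 * cfg.sigma_x))
        ey = np.exp(-((gy - yc) ** 2) / (2.0 * cfg.sigma_y))
        maps[k] = cfg.amplitude * ey[:, None] * ex[None, :]
    return HeatmapStack(maps, stride, (h_in, w_in))


# ---------------------------------------------------------------------------
# bicubic upsampling (Catmull-Rom, a = -0.5)
# ---------------------------------------------------------------------------

def _keys_kernel(t: np.ndarray, a: float = -0.5) -> np.ndarray:
    """Keys cubic convolution kernel."""
    t = np.abs(t)
    out = np.zeros_like(t)
    m1 = t <= 1
    m2 = (t > 1) & (t < 2)
    out[m1] = (a + 2) * t[m1] ** 3 - (a + 3) * t[m1] ** 2 + 1
    out[m2] = a * t[m2] ** 3 - 5 * a * t[m2] ** 2 + 8 * a * t[m2] - 4 * a
    return out


def _bicubic_matrix(n_out: int, n_src: int, stride: int) -> np.ndarray:
    """(n_out, n_src) interpolation weights for sample positions p/stride.

    Edge handling replicates the border sample (tap indices clipped).
    """
    s = np.arange(n_out, dtype=float) / stride
    base = np.floor(s).astype(int)
    mat = np.zeros((n_out, n_src))
    for tap in (-1, 0, 1, 2):
        idx = np.clip(base + tap, 0, n_src - 1)
        w = _keys_kernel(s - (base + tap))
        np.add.at(mat, (np.arange(n_out), idx), w)
    return mat


def bicubic_upsample(channel: np.ndarray, stride: int) -> np.ndarray:
    """Upsample one 2D map by ``stride`` with the Catmull-Rom bicubic kernel,
    sampling output pixel ``p`` at map coordinate ``p / stride``."""
    h_map, w_map = channel.shape
    wy = _bicubic_matrix(h_map * stride, h_map, stride)
    wx = _bicubic_matrix(w_map * stride, w_map, stride)
    return wy @ channel @ wx.T


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def decode_hmp(stack: HeatmapStack) -> LandmarkSet:
    """Heatmap-maximum-position decode: bicubic upsample to input resolution
    and take the integer argmax (ties: first in row-major order)."""
    h_in, w_in = stack.input_size
    xy = np.zeros((N_LANDMARKS, 2))
    for k in range(N_LANDMARKS):
        ch = stack.values[k]
        if np.isnan(ch).all():
            raise DecodeError(f"channel {k} is all-NaN")
        up = bicubic_upsample(ch, stack.stride) if stack.stride > 1 else ch
        flat = int(np.argmax(up))
        r, c = divmod(flat, w_in)
        xy[k] = (c, r)
    return LandmarkSet(xy)


def stable_softmax(z: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the flattened array."""
    z = np.asarray(z, dtype=float)
    e = np.exp(z - z.max())
    return e / e.sum()


def soft_argmax_1d(z: np.ndarray) -> float:
    """Probability-weighted expected index of a 1-D score vector.

    ``sum_i i * softmax(z)_i`` with 0-based indices; smooth in ``z``.
    """
    z = np.asarray(z, dtype=float).ravel()
    if z.size == 0:
        raise ValueError("soft_argmax_1d needs a non-empty vector")
    if not np.all(np.isfinite(z)):
        raise ValueError("soft_argmax_1d needs finite values")
    p = stable_softmax(z)
    return float(np.arange(z.size) @ p)


def decode_hir(stack: HeatmapStack) -> LandmarkSet:
    """Integral-regression decode.

    Per channel: joint softmax over all map cells, marginal sums per column
    (x weights) and per row (y weights), expected index times stride.
    Returns sub-pixel input-resolution coordinates.
    """
    h_map, w_map = stack.map_size
    xy = np.zeros((N_LANDMARKS, 2))
    cols = np.arange(w_map, dtype=float)
    rows = np.arange(h_map, dtype=float)
    for k in range(N_LANDMARKS):
        ch = stack.values[k]
        if np.isnan(ch).any():
            raise DecodeError(f"channel {k} contains NaN")
        p = stable_softmax(ch).reshape(h_map, w_map)
        xy[k, 0] = (p.sum(axis=0) @ cols) * stack.stride
        xy[k, 1] = (p.sum(axis=1) @ rows) * stack.stride
    return LandmarkSet(xy)
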