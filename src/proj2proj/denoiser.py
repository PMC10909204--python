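"""The trainable image-to-image denoiser f_theta: a multi-scale encoder–decoder.

A U-Net-style network: per scale two 3x3 convolutions with ReLU, 2x average
pooling between encoder scales, nearest-neighbour upsampling and skip
concatenation in the decoder, and a final 1x1 convolution.  Channel counts
double per scale.  The reference configuration is five scales with 64 base
channels (64, 128, 256, 512, 1024); a compact three-scale preset is used for
desk-scale experiments.

The network is implemented directly on numpy (im2col convolutions driving
BLAS matmuls, float32 throughout) with hand-written backward passes, so the
whole training graph — FBP input, network, re-projection — stays inside one
numerical stack and gradients are exact.  ``n_scales=0`` degenerates to a
single 1x1 convolution initialised to the exact identity, which is the
ablation network used to show that reconstruction without a trained denoiser
reduces to plain FBP.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, InvalidInputError

__all__ = [
    "DenoiserConfig",
    "Denoiser",
    "build_denoiser",
    "denoise",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]

_CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class DenoiserConfig:
    """Architecture hyperparameters.

    ``n_scales=0`` is the degenerate identity-initialised 1x1 network.
    """

    n_scales: int = 5
    base_channels: int = 64
    in_channels: int = 1
    out_channels: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_scales < 0:
            raise ConfigurationError(f"n_scales must be >= 0, got {self.n_scales}")
        if self.n_scales > 0 and self.base_channels < 1:
            raise ConfigurationError("base_channels must be >= 1")
        if self.in_channels < 1 or self.out_channels < 1:
            raise ConfigurationError("channel counts must be >= 1")

    @classmethod
    def full_scale(cls, seed: int = 0) -> "DenoiserConfig":
        """Five scales, 64 base channels (64..1024)."""
        return cls(n_scales=5, base_channels=64, seed=seed)

    @classmethod
    def desk(cls, seed: int = 0) -> "DenoiserConfig":
        """Four scales, 16 base channels."""
        return cls(n_scales=4, base_channels=16, seed=seed)

    @classmethod
    def compact(cls, seed: int = 0) -> "DenoiserConfig":
        """Four scales, 8 base channels — the default for desk-scale training.

        Depth is kept (receptive field is what streak removal needs) while
        channel counts are cut, which is where the compute lives.
        """
        return cls(n_scales=4, base_channels=8, seed=seed)

    @classmethod
    def identity(cls) -> "DenoiserConfig":
        return cls(n_scales=0, base_channels=1)


def _conv_layout(cfg: DenoiserConfig) -> list[tuple[str, int, int, int]]:
    """(name, in_channels, out_channels, kernel) for every convolution, in order."""
    if cfg.n_scales == 0:
        return [("final", cfg.in_channels, cfg.out_channels, 1)]
    ch = [cfg.base_channels * 2**i for i in range(cfg.n_scales)]
    layout: list[tuple[str, int, int, int]] = []
    prev = cfg.in_channels
    for i in range(cfg.n_scales):
        layout.append((f"enc{i}a", prev, ch[i], 3))
        layout.append((f"enc{i}b", ch[i], ch[i], 3))
        prev = ch[i]
    for i in range(cfg.n_scales - 2, -1, -1):
        layout.append((f"dec{i}a", ch[i] + ch[i + 1], ch[i], 3))
        layout.append((f"dec{i}b", ch[i], ch[i], 3))
    layout.append(("final", ch[0], cfg.out_channels, 1))
    return layout


# ---------------------------------------------------------------------------
# Primitives (float32, NHWC; kernels stored (k, k, Cin, Cout))
# ---------------------------------------------------------------------------
# 3x3 convolutions are computed as nine shifted GEMMs on the zero-padded
# input, which keeps every matmul operand a cheap strided slice instead of a
# gathered im2col buffer — the dominant cost on a single CPU core.

def _conv_forward(x, w, b, cache=None):
    n, h, wd, ci = x.shape
    co = w.shape[-1]
    if w.shape[0] == 1:
        y_mat = x.reshape(-1, ci) @ w[0, 0]
        y_mat += b
        if cache is not None:
            cache.append(x)
        return y_mat.reshape(n, h, wd, co)
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    y_mat = np.tile(b, (n * h * wd, 1))
    for i in range(3):
        for j in range(3):
            y_mat += xp[:, i : i + h, j : j + wd, :].reshape(-1, ci) @ w[i, j]
    if cache is not None:
        cache.append(xp)
    return y_mat.reshape(n, h, wd, co)


def _conv_backward(dy, w, cached):
    ci, co = w.shape[-2:]
    n, h, wd = dy.shape[:3]
    dy_mat = dy.reshape(-1, co)
    if w.shape[0] == 1:
        x = cached
        dw = (x.reshape(-1, ci).T @ dy_mat)[None, None]
        db = dy_mat.sum(axis=0)
        dx = (dy_mat @ w[0, 0].T).reshape(n, h, wd, ci)
        return dx, dw, db
    xp = cached
    dw = np.empty_like(w)
    for i in range(3):
        for j in range(3):
            dw[i, j] = xp[:, i : i + h, j : j + wd, :].reshape(-1, ci).T @ dy_mat
    db = dy_mat.sum(axis=0)
    # gradient wrt input: convolution of dy with the flipped, io-transposed kernel
    w_flip = np.ascontiguousarray(w[::-1, ::-1].transpose(0, 1, 3, 2))
    dx = _conv_forward(dy, w_flip, np.zeros(ci, dtype=w.dtype))
    return dx, dw, db


def _avgpool2(x):
    n, h, w, c = x.shape
    return x.reshape(n, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4))


def _avgpool2_backward(dy):
    return np.repeat(np.repeat(dy, 2, axis=1), 2, axis=2) * np.float32(0.25)


def _upsample2(x):
    return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)


def _upsample2_backward(dy):
    n, h, w, c = dy.shape
    return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


# ---------------------------------------------------------------------------
# The network
# ---------------------------------------------------------------------------

class Denoiser:
    """f_theta with explicit parameter storage and hand-written gradients."""

    def __init__(self, config: DenoiserConfig, params: dict[str, np.ndarray] | None = None):
        self.config = config
        self.layout = _conv_layout(config)
        if params is None:
            params = self._init_params()
        self.params = params

    def _init_params(self) -> dict[str, np.ndarray]:
        rng = np.random.default_rng(self.config.seed)
        params: dict[str, np.ndarray] = {}
        for name, ci, co, k in self.layout:
            if self.config.n_scales == 0 and ci == co:
                # identity start for the degenerate 1x1 network
                w = np.eye(ci, co, dtype=np.float32).reshape(1, 1, ci, co)
            else:
                std = np.sqrt(2.0 / (ci * k * k))
                w = (rng.standard_normal((k, k, ci, co)) * std).astype(np.float32)
            params[f"{name}.w"] = w
            params[f"{name}.b"] = np.zeros(co, dtype=np.float32)
        return params

    def copy(self) -> "Denoiser":
        return Denoiser(self.config, {k: v.copy() for k, v in self.params.items()})

    # -- forward / backward ------------------------------------------------
    @property
    def dtype(self) -> np.dtype:
        return self.params[f"{self.layout[0][0]}.w"].dtype

    def _stride(self) -> int:
        return 2 ** max(self.config.n_scales - 1, 0)

    def forward_batch(self, x: np.ndarray, train: bool = False):
        """x: (N, H, W, C) float32, H and W divisible by 2**(n_scales-1).

        Returns (y, cache); cache is None unless ``train``.
        """
        cfg = self.config
        if x.ndim != 4 or x.shape[-1] != cfg.in_channels:
            raise InvalidInputError(f"expected (N, H, W, {cfg.in_channels}), got {x.shape}")
        s = self._stride()
        if x.shape[1] % s or x.shape[2] % s:
            raise InvalidInputError(
                f"spatial size {x.shape[1:3]} not divisible by {s}; pad the input"
            )
        # computation dtype follows the parameters (float32 by default;
        # promote the params to float64 for high-precision gradient checks)
        x = np.ascontiguousarray(x, dtype=self.dtype)
        p = self.params
        cache: dict | None = {"convs": {}, "relus": {}} if train else None

        def conv_relu(name, h, relu=True):
            cc = cache["convs"].setdefault(name, []) if train else None
            y = _conv_forward(h, p[f"{name}.w"], p[f"{name}.b"], cc)
            if relu:
                np.maximum(y, 0.0, out=y)
                if train:
                    cache["relus"][name] = y > 0
            return y

        if cfg.n_scales == 0:
            return conv_relu("final", x, relu=False), cache

        skips = []
        h = x
        for i in range(cfg.n_scales):
            h = conv_relu(f"enc{i}a", h)
            h = conv_relu(f"enc{i}b", h)
            if i < cfg.n_scales - 1:
                skips.append(h)
                h = _avgpool2(h)
        for i in range(cfg.n_scales - 2, -1, -1):
            h = _upsample2(h)
            h = np.concatenate([skips[i], h], axis=-1)
            h = conv_relu(f"dec{i}a", h)
            h = conv_relu(f"dec{i}b", h)
        y = conv_relu("final", h, relu=False)
        return y, cache

    def backward_batch(self, cache: dict, dy: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss wrt every parameter, given d(loss)/d(output)."""
        cfg = self.config
        p = self.params
        grads: dict[str, np.ndarray] = {}

        def conv_back(name, dh, relu=True):
            if relu:
                dh = dh * cache["relus"][name]
            dx, dw, db = _conv_backward(dh, p[f"{name}.w"], cache["convs"][name][0])
            grads[f"{name}.w"] = dw
            grads[f"{name}.b"] = db
            return dx

        dh = np.ascontiguousarray(dy, dtype=self.dtype)
        dh = conv_back("final", dh, relu=False)
        if cfg.n_scales == 0:
            return grads

        ch = [cfg.base_channels * 2**i for i in range(cfg.n_scales)]
        dskips: dict[int, np.ndarray] = {}
        for i in range(cfg.n_scales - 1):
            dh = conv_back(f"dec{i}b", dh)
            dh = conv_back(f"dec{i}a", dh)
            dskips[i] = dh[..., : ch[i]]
            dh = _upsample2_backward(np.ascontiguousarray(dh[..., ch[i] :]))
        for i in range(cfg.n_scales - 1, -1, -1):
            if i < cfg.n_scales - 1:
                dh = _avgpool2_backward(dh) + dskips[i]
            dh = conv_back(f"enc{i}b", dh)
            dh = conv_back(f"enc{i}a", dh)
        # dh would be d(loss)/d(input); nothing upstream needs it
        return grads


def build_denoiser(config: DenoiserConfig) -> Denoiser:
    """Instantiate a denoiser with deterministic (seeded) He initialisation."""
    return Denoiser(config)


def denoise(d: Denoiser, image: np.ndarray) -> np.ndarray:
    """Apply f_theta to one 2D image, reflect-padding to the scale stride."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise InvalidInputError(f"expected a 2D image, got shape {image.shape}")
    s = d._stride()
    h, w = image.shape
    ph = (-h) % s
    pw = (-w) % s
    x = image
    if ph or pw:
        if h < 2 or w < 2:
            raise InvalidInputError(f"image {image.shape} too small to pad to stride {s}")
        x = np.pad(image, ((0, ph), (0, pw)), mode="reflect")
    y, _ = d.forward_batch(x[None, :, :, None].astype(d.dtype))
    return y[0, :h, :w, 0].astype(np.float64)


def count_parameters(d: Denoiser) -> int:
    """Exact count of trainable scalars."""
    return int(sum(v.size for v in d.params.values()))


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(d: Denoiser, path: str | pathlib.Path) -> None:
    """Single-file .npz checkpoint with the config embedded (format v1)."""
    meta = {"version": _CHECKPOINT_VERSION, "config": d.config.__dict__}
    np.savez(path, __meta__=np.array(json.dumps(meta)), **d.params)


def load_checkpoint(path: str | pathlib.Path) -> Denoiser:
    with np.load(path) as data:
        meta = json.loads(str(data["__meta__"]))
        if meta.get("version") != _CHECKPOINT_VERSION:
            raise ConfigurationError(
                f"unsupported checkpoint version {meta.get('version')}"
            )
        cfg = DenoiserConfig(**meta["config"])
        params = {k: data[k] for k in data.files if k != "__meta__"}
    return Denoiser(cfg, params)
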