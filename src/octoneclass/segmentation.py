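"""4-class U-Net segmentation of skin OCT patches.

The network labels every pixel of a 256 (depth) x 32 (A-scan) patch as air,
stratum corneum, epidermis or dermis.  It has five encoder and five decoder
stages with base width 16 and x2 channel growth; each encoder stage is
[3x3 conv, ReLU, 3x3 conv, ReLU, max-pool].  On a 32-pixel-wide input five
poolings are geometrically impossible, so the fifth encoder stage omits its
pool and acts as the bridge, giving four down/up-samplings (256x32 ->
16x2 at the bottleneck); the first decoder stage correspondingly operates at
bottleneck resolution without upsampling.  The last decoder stage emits 16
channels per pixel — the activations after its final ReLU are the per-pixel
feature vectors reused for one-class classification — followed by a 1x1
convolution producing the 4 class scores.

Training uses pixelwise cross-entropy with Adam (mini-batch 40, initial
learning rate 1e-3, 10 epochs by default) and is fully deterministic for a
fixed seed.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, asdict

import numpy as np

from . import _nn
from ._nn import Param, DTYPE
from .exceptions import ParameterError, InputError, DataError
from .phantom import OCTImage, SegmentationMask, AIR, DERMIS


@dataclass(frozen=True)
class UNetConfig:
    """Architecture parameters. Defaults follow the study's description."""

    input_height: int = 256
    input_width: int = 32
    n_classes: int = 4
    n_stages: int = 5          # encoder stages; decoder mirrors them
    base_features: int = 16    # channels of 1st encoder and last decoder stage
    in_channels: int = 1
    # OCT magnitude images are conventionally log-compressed before display
    # and CNN processing; "log" applies log10(x + input_floor) to the linear
    # magnitudes at the network input (phantoms and anomaly operators stay
    # in the linear domain).  "linear" feeds raw magnitudes.
    input_transform: str = "log"
    input_floor: float = 1e-3

    @property
    def n_pools(self) -> int:
        # the last encoder stage is the bridge and does not pool
        return self.n_stages - 1

    @property
    def channel_widths(self) -> tuple[int, ...]:
        """Encoder channel widths, x2 growth per stage: (16, 32, 64, 128, 256)."""
        return tuple(self.base_features * 2 ** s for s in range(self.n_stages))

    def validate(self) -> None:
        if self.n_stages < 2:
            raise ParameterError("n_stages must be >= 2")
        if self.base_features < 1 or self.n_classes < 2:
            raise ParameterError("base_features >= 1 and n_classes >= 2 required")
        if self.input_transform not in ("log", "linear"):
            raise ParameterError("input_transform must be 'log' or 'linear'")
        if self.input_floor <= 0:
            raise ParameterError("input_floor must be > 0")
        factor = 2 ** self.n_pools
        if self.input_height % factor or self.input_width % factor:
            raise ParameterError(
                f"input spatial size {self.input_height}x{self.input_width} "
                f"must be divisible by the total downsampling factor {factor}")


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation recipe: Adam, batch 40, lr 1e-3, 10 epochs, cross-entropy."""

    mini_batch: int = 40
    initial_lr: float = 1e-3
    epochs: int = 10
    seed: int = 0
    validation_fraction: float = 0.0
    class_weights: tuple[float, ...] | None = None  # optional, defaults off

    def validate(self) -> None:
        if self.epochs < 1:
            raise ParameterError("epochs must be >= 1")
        if not (0 <= self.validation_fraction < 1):
            raise ParameterError("validation_fraction must be in [0, 1)")
        if self.mini_batch < 1:
            raise ParameterError("mini_batch must be >= 1")


def split_into_patches(image: OCTImage, patch_width: int = 32) -> list[OCTImage]:
    """Split a B-scan into non-overlapping, left-aligned patches.

    A trailing remainder narrower than ``patch_width`` is discarded.  Each
    patch records its lateral offset in the parent image.
    """
    if patch_width < 1:
        raise ParameterError("patch_width must be >= 1")
    if image.width < patch_width:
        raise InputError(
            f"image width {image.width} < patch width {patch_width}")
    n = image.width // patch_width
    return [
        OCTImage(pixels=image.pixels[:, k * patch_width:(k + 1) * patch_width],
                 axial_spacing=image.axial_spacing,
                 lateral_spacing=image.lateral_spacing,
                 lateral_offset=image.lateral_offset + k * patch_width)
        for k in range(n)
    ]


class SegmenterModel:
    """Trained (or initialised) U-Net with its config and provenance.

    Parameters live in ``self.params`` (name -> (weight Param, bias Param));
    ``self.provenance`` records the init seed, training seed and a checksum
    of the training data so checkpoints are traceable.
    """

    def __init__(self, config: UNetConfig, seed: int = 0):
        config.validate()
        self.config = config
        self.provenance: dict = {"init_seed": int(seed)}
        self.train_log: list[float] = []
        rng = np.random.default_rng(seed)
        widths = config.channel_widths
        p: dict[str, tuple[Param, Param]] = {}

        def conv(name, cout, cin, k=3):
            p[name] = (_nn.he_conv(rng, cout, cin, k),
                       Param(np.zeros(cout, dtype=DTYPE)))

        cin = config.in_channels
        for s, w in enumerate(widths):
            conv(f"enc{s}a", w, cin)
            conv(f"enc{s}b", w, w)
            cin = w
        bw = widths[-1]
        conv("dec0a", bw, bw)
        conv("dec0b", bw, bw)
        for j in range(1, config.n_stages):
            w = widths[-1 - j]          # 128, 64, 32, 16
            conv(f"dec{j}up", w, 2 * w)
            conv(f"dec{j}a", w, 2 * w)  # after skip concatenation
            conv(f"dec{j}b", w, w)
        conv("head", config.n_classes, widths[0], k=1)
        self.params = p

    # -- forward / backward -------------------------------------------------

    def parameters(self) -> list[Param]:
        out = []
        for wp, bp in self.params.values():
            out.extend([wp, bp])
        return out

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        c = self.config
        if x.ndim == 2:
            x = x[None, :, :, None]
        elif x.ndim == 3:
            x = x[:, :, :, None]
        if x.shape[1:] != (c.input_height, c.input_width, c.in_channels):
            raise InputError(
                f"input shape {x.shape[1:]} does not match configured "
                f"({c.input_height}, {c.input_width}, {c.in_channels})")
        x = np.ascontiguousarray(x, dtype=DTYPE)
        if c.input_transform == "log":
            x = np.log10(x + DTYPE(c.input_floor))
        return x

    def forward(self, x: np.ndarray, want_grads: bool = False):
        """Run the network.

        Accepts a (H, W) patch or a (B, H, W) stack.  Returns
        ``(logits, features, cache)``: logits (B, H, W, n_classes), features
        (B, H, W, 16) — the activations after the last decoder ReLU — and,
        when ``want_grads``, the cache needed by :meth:`backward`.
        """
        x = self._check_input(x)
        P = self.params
        cache: dict = {}
        skips = []
        h = x
        ns = self.config.n_stages
        for s in range(ns):
            h, cache[f"enc{s}a"] = _nn.conv2d_forward(h, *_wb(P, f"enc{s}a"))
            h, cache[f"enc{s}a_r"] = _nn.relu_forward(h)
            h, cache[f"enc{s}b"] = _nn.conv2d_forward(h, *_wb(P, f"enc{s}b"))
            h, cache[f"enc{s}b_r"] = _nn.relu_forward(h)
            if s < ns - 1:
                skips.append(h)
                h, cache[f"pool{s}"] = _nn.maxpool2_forward(h)
        h, cache["dec0a"] = _nn.conv2d_forward(h, *_wb(P, "dec0a"))
        h, cache["dec0a_r"] = _nn.relu_forward(h)
        h, cache["dec0b"] = _nn.conv2d_forward(h, *_wb(P, "dec0b"))
        h, cache["dec0b_r"] = _nn.relu_forward(h)
        for j in range(1, ns):
            h = _nn.upsample2_forward(h)
            h, cache[f"dec{j}up"] = _nn.conv2d_forward(h, *_wb(P, f"dec{j}up"))
            h, cache[f"dec{j}up_r"] = _nn.relu_forward(h)
            h, cache[f"cat{j}"] = _nn.concat_forward(skips[ns - 1 - j], h)
            h, cache[f"dec{j}a"] = _nn.conv2d_forward(h, *_wb(P, f"dec{j}a"))
            h, cache[f"dec{j}a_r"] = _nn.relu_forward(h)
            h, cache[f"dec{j}b"] = _nn.conv2d_forward(h, *_wb(P, f"dec{j}b"))
            h, cache[f"dec{j}b_r"] = _nn.relu_forward(h)
        feats = h
        logits, cache["head"] = _nn.conv2d_forward(h, *_wb(P, "head"))
        return logits, feats, (cache if want_grads else None)

    def backward(self, dlogits: np.ndarray, cache: dict) -> None:
        """Accumulate parameter gradients for a forward pass with grads."""
        P = self.params
        ns = self.config.n_stages

        def conv_bwd(name, d):
            dx, dW, db = _nn.conv2d_backward(d, cache[name])
            P[name][0].grad += dW
            P[name][1].grad += db
            return dx

        d = conv_bwd("head", dlogits)
        dskips = {}
        for j in range(ns - 1, 0, -1):
            d = _nn.relu_backward(d, cache[f"dec{j}b_r"])
            d = conv_bwd(f"dec{j}b", d)
            d = _nn.relu_backward(d, cache[f"dec{j}a_r"])
            d = conv_bwd(f"dec{j}a", d)
            dskip, d = _nn.concat_backward(d, cache[f"cat{j}"])
            dskips[ns - 1 - j] = dskip
            d = _nn.relu_backward(d, cache[f"dec{j}up_r"])
            d = conv_bwd(f"dec{j}up", d)
            d = _nn.upsample2_backward(d)
        d = _nn.relu_backward(d, cache["dec0b_r"])
        d = conv_bwd("dec0b", d)
        d = _nn.relu_backward(d, cache["dec0a_r"])
        d = conv_bwd("dec0a", d)
        for s in range(ns - 1, -1, -1):
            if s < ns - 1:
                d = _nn.maxpool2_backward(d, cache[f"pool{s}"])
                d = d + dskips[s]
            d = _nn.relu_backward(d, cache[f"enc{s}b_r"])
            d = conv_bwd(f"enc{s}b", d)
            d = _nn.relu_backward(d, cache[f"enc{s}a_r"])
            d = conv_bwd(f"enc{s}a", d)

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        """Single-file checkpoint: config + weights + provenance (npz)."""
        arrays = {}
        for name, (wp, bp) in self.params.items():
            arrays[f"{name}.W"] = wp.value
            arrays[f"{name}.b"] = bp.value
        meta = json.dumps({"config": asdict(self.config),
                           "provenance": self.provenance,
                           "train_log": self.train_log})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "SegmenterModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            model = cls(UNetConfig(**meta["config"]), seed=0)
            model.provenance = meta["provenance"]
            model.train_log = meta["train_log"]
            for name, (wp, bp) in model.params.items():
                wp.value = np.ascontiguousarray(z[f"{name}.W"], dtype=DTYPE)
                bp.value = np.ascontiguousarray(z[f"{name}.b"], dtype=DTYPE)
        return model


def _wb(params, name):
    wp, bp = params[name]
    return wp.value, bp.value


def build_unet(config: UNetConfig | None = None, seed: int = 0) -> SegmenterModel:
    """Build an untrained network with seeded He initialisation."""
    return SegmenterModel(config or UNetConfig(), seed=seed)


def _data_checksum(X: np.ndarray, Y: np.ndarray) -> str:
    return f"{zlib.crc32(X.tobytes()) :08x}{zlib.crc32(Y.tobytes()):08x}"


def _stack_patches(patches, masks, config: UNetConfig):
    X = np.stack([np.asarray(p.pixels, dtype=DTYPE) for p in patches])[..., None]
    Y = np.stack([np.asarray(m.labels) for m in masks]).astype(np.int64)
    for i, m in enumerate(masks):
        lab = np.asarray(m.labels)
        if lab.min() < AIR or lab.max() > DERMIS:
            raise DataError(f"patch {i}: labels outside {{0..3}}")
    if X.shape[1:3] != (config.input_height, config.input_width):
        raise InputError(
            f"patch shape {X.shape[1:3]} does not match configured input "
            f"({config.input_height}, {config.input_width})")
    if Y.shape != X.shape[:3]:
        raise DataError("mask shapes do not match patch shapes")
    return X, Y


def train_unet(model: SegmenterModel,
               patches: list[OCTImage],
               masks: list[SegmentationMask],
               train_cfg: TrainConfig | None = None) -> SegmenterModel:
    """Train in place with Adam on pixelwise cross-entropy; returns the model.

    The per-epoch mean loss is appended to ``model.train_log``.  Training is
    deterministic for a fixed ``train_cfg.seed`` (pure NumPy kernels, seeded
    shuffling).
    """
    cfg = train_cfg or TrainConfig()
    cfg.validate()
    if len(patches) == 0:
        raise DataError("no training data")
    X, Y = _stack_patches(patches, masks, model.config)
    n = X.shape[0]
    rng = np.random.default_rng(cfg.seed)
    opt = _nn.Adam(model.parameters(), lr=cfg.initial_lr)
    model.provenance.update(train_seed=int(cfg.seed),
                            data_checksum=_data_checksum(X, Y),
                            n_patches=int(n))
    bs = min(cfg.mini_batch, n)
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, bs):
            sel = order[start:start + bs]
            logits, _, cache = model.forward(X[sel], want_grads=True)
            weights = (np.asarray(cfg.class_weights, dtype=np.float64)
                       if cfg.class_weights is not None else None)
            loss, dlogits = _nn.softmax_cross_entropy(logits, Y[sel], weights)
            opt.zero_grad()
            model.backward(dlogits, cache)
            opt.step()
            losses.append(loss)
        model.train_log.append(float(np.mean(losses)))
    return model


def segment(model: SegmenterModel, patch: OCTImage) -> SegmentationMask:
    """Per-pixel argmax over the 4 class scores (ties -> lowest class index)."""
    logits, _, _ = model.forward(np.asarray(patch.pixels, dtype=DTYPE))
    return SegmentationMask(labels=np.argmax(logits[0], axis=-1).astype(np.uint8))


def segment_batch(model: SegmenterModel, patches: list[OCTImage]) -> list[SegmentationMask]:
    X = np.stack([np.asarray(p.pixels, dtype=DTYPE) for p in patches])
    logits, _, _ = model.forward(X)
    return [SegmentationMask(labels=np.argmax(logits[i], axis=-1).astype(np.uint8))
            for i in range(len(patches))]


def pixel_accuracy(pred: SegmentationMask, truth: SegmentationMask) -> float:
    """Fraction of pixels whose predicted label matches the ground truth."""
    return float(np.mean(pred.labels == truth.labels))
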