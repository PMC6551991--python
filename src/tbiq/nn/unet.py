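"""U-Net architectures (2D and 3D) with valid or same convolutions.

The 3D configuration follows the classic volumetric U-Net: per resolution
level two 3x3x3 convolutions (ReLU), 2x2x2 max pooling on the analysis path,
2x2x2 up-convolution (stride-2 transposed convolution, halving the channel
count) plus crop-and-concatenate shortcuts on the synthesis path, and a
final 1x1x1 convolution with softmax. With valid convolutions a
132^3 input patch maps to a 44^3 output patch at four resolution levels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ops import (
    conv_backward,
    conv_forward,
    maxpool_forward,
    maxpool_backward,
    softmax,
    upconv_backward,
    upconv_forward,
)

__all__ = ["UNetConfig", "UNet", "shape_trace"]


def shape_trace(input_size: int, depth: int, kernel: int = 3, convs_per_level: int = 2) -> int:
    """Output spatial size per axis of a valid-convolution U-Net.

    Traces the analysis path (per level: `convs_per_level` valid convolutions
    then 2x pooling), the bottom level, and the synthesis path (per level:
    2x upsampling then `convs_per_level` valid convolutions). Raises
    ValueError naming the first failing level if the input size does not
    admit a valid trace.
    """
    loss = convs_per_level * (kernel - 1)
    s = int(input_size)
    if depth < 1:
        raise ValueError("depth must be >= 1")
    for level in range(depth - 1):
        s -= loss
        if s <= 0:
            raise ValueError(f"analysis level {level}: size {s} after convolutions")
        if s % 2:
            raise ValueError(f"analysis level {level}: odd size {s} cannot be 2x pooled")
        s //= 2
    s -= loss  # bottom level convolutions
    if s <= 0:
        raise ValueError(f"bottom level: size {s} after convolutions")
    for level in range(depth - 2, -1, -1):
        s = 2 * s - loss
        if s <= 0:
            raise ValueError(f"synthesis level {level}: size {s} after convolutions")
    return s


@dataclass
class UNetConfig:
    """Architecture hyperparameters.

    `first_layer_filters` are the filter counts of the two convolutions of
    the first level; both double at each deeper level. `padding` 'valid'
    shrinks the output (patch-based use); 'same' preserves the input size
    (slice-wise brain extraction).
    """

    ndim: int = 3
    depth: int = 4
    first_layer_filters: tuple[int, int] = (32, 64)
    kernel: int = 3
    n_classes: int = 2
    in_channels: int = 1
    padding: str = "valid"
    input_patch: int = 132

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if min(self.first_layer_filters) < 1:
            raise ValueError("filters must be >= 1")
        if self.padding not in ("valid", "same"):
            raise ValueError("padding must be 'valid' or 'same'")

    @property
    def output_patch(self) -> int:
        if self.padding == "same":
            return self.input_patch
        return shape_trace(self.input_patch, self.depth, self.kernel)

    @property
    def offset(self) -> int:
        """Total input-minus-output margin (receptive-field context)."""
        return self.input_patch - self.output_patch


class UNet:
    """A U-Net with explicit numpy forward/backward passes.

    Weights are float32 and initialized He-normal from a seeded generator;
    two identically seeded instances are bit-identical.
    """

    def __init__(self, cfg: UNetConfig, seed: int = 0, dtype=np.float32):
        self.cfg = cfg
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        d, (fa, fb) = cfg.depth, cfg.first_layer_filters
        k = (cfg.kernel,) * cfg.ndim
        self.enc_filters = [(fa * 2**i, fb * 2**i) for i in range(d)]
        self.dec_filters = [(fa * 2**i, fb * 2**i) for i in range(d - 1)]
        self.weights: list[np.ndarray] = []

        def add_conv(cin, cout, kk=k):
            fan_in = cin * int(np.prod(kk))
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin) + kk).astype(self.dtype)
            b = np.zeros(cout, dtype=self.dtype)
            self.weights += [w, b]
            return len(self.weights) // 2 - 1

        self._enc_idx = []
        cin = cfg.in_channels
        for i in range(d):
            f1, f2 = self.enc_filters[i]
            self._enc_idx.append((add_conv(cin, f1), add_conv(f1, f2)))
            cin = f2
        self._dec_idx = []
        self._up_idx = []
        for i in range(d - 2, -1, -1):
            f1, f2 = self.dec_filters[i]
            skip_c = self.enc_filters[i][1]
            up_c = max(1, cin // 2)
            self._up_idx.append(add_conv(cin, up_c, kk=(2,) * cfg.ndim))
            self._dec_idx.append((add_conv(up_c + skip_c, f1), add_conv(f1, f2)))
            cin = f2
        self._final_idx = add_conv(cin, cfg.n_classes, kk=(1,) * cfg.ndim)

    # -- parameter access -------------------------------------------------
    @property
    def params(self) -> list[np.ndarray]:
        return self.weights

    def _wb(self, idx):
        return self.weights[2 * idx], self.weights[2 * idx + 1]

    # -- forward / backward ----------------------------------------------
    def _conv_relu(self, x, idx, relu=True, train=False):
        w, b = self._wb(idx)
        y, xc = conv_forward(x, w, b, padding=self.cfg.padding if w.shape[2] > 1 else "valid",
                             cache_slabs=train)
        mask = None
        if relu:
            mask = y > 0
            y = y * mask
        return y, (xc, mask, idx)

    def _conv_relu_back(self, g, cache, grads, need_dx=True):
        xc, mask, idx = cache
        if mask is not None:
            g = g * mask
        w, _ = self._wb(idx)
        dx, dw, db = conv_backward(g, xc, w, padding=self.cfg.padding if w.shape[2] > 1 else "valid",
                                   need_dx=need_dx)
        grads[2 * idx] += dw
        grads[2 * idx + 1] += db
        return dx

    @staticmethod
    def _crop_slices(src_shape, dst_shape):
        sl = [slice(None)]
        for s, t in zip(src_shape[1:], dst_shape[1:]):
            off = (s - t) // 2
            sl.append(slice(off, off + t))
        return tuple(sl)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Map an input patch (Cin, *sp) to class logits (n_classes, *out_sp)."""
        x = np.ascontiguousarray(x, dtype=self.dtype)
        d = self.cfg.depth
        caches = {"enc": [], "pool": [], "dec": [], "skip_shapes": [], "crops": []}
        skips = []
        for i in range(d - 1):
            x, c1 = self._conv_relu(x, self._enc_idx[i][0], train=train)
            x, c2 = self._conv_relu(x, self._enc_idx[i][1], train=train)
            caches["enc"].append((c1, c2))
            skips.append(x)
            caches["skip_shapes"].append(x.shape)
            x, pc = maxpool_forward(x)
            caches["pool"].append(pc)
        x, c1 = self._conv_relu(x, self._enc_idx[d - 1][0], train=train)
        x, c2 = self._conv_relu(x, self._enc_idx[d - 1][1], train=train)
        caches["enc"].append((c1, c2))
        for j, i in enumerate(range(d - 2, -1, -1)):
            uw, ub = self._wb(self._up_idx[j])
            x, upc = upconv_forward(x, uw, ub)
            caches.setdefault("up", []).append(upc)
            skip = skips[i]
            sl = self._crop_slices(skip.shape, x.shape)
            caches["crops"].append(sl)
            x = np.concatenate([skip[sl], x], axis=0)
            x, c1 = self._conv_relu(x, self._dec_idx[j][0], train=train)
            x, c2 = self._conv_relu(x, self._dec_idx[j][1], train=train)
            caches["dec"].append((c1, c2))
        logits, cf = self._conv_relu(x, self._final_idx, relu=False, train=train)
        caches["final"] = cf
        if train:
            self._caches = caches
        return logits

    def backward(self, dlogits: np.ndarray) -> list[np.ndarray]:
        """Backpropagate loss gradient at the logits; returns grads per param."""
        caches = self._caches
        d = self.cfg.depth
        grads = [np.zeros_like(p) for p in self.weights]
        g = self._conv_relu_back(dlogits, caches["final"], grads)
        skip_grads = {}
        # decoder levels in reverse
        for j in range(d - 2, -1, -1):
            i = (d - 2) - j  # encoder level index for decoder step j
            c1, c2 = caches["dec"][j]
            g = self._conv_relu_back(g, c2, grads)
            g = self._conv_relu_back(g, c1, grads)
            skip_c = self.enc_filters[i][1]
            g_skip, g_up = g[:skip_c], g[skip_c:]
            full = np.zeros(caches["skip_shapes"][i], dtype=self.dtype)
            full[caches["crops"][j]] = g_skip
            skip_grads[i] = full
            up_idx = self._up_idx[j]
            uw, _ = self._wb(up_idx)
            g, duw, dub = upconv_backward(np.ascontiguousarray(g_up), caches["up"][j], uw)
            grads[2 * up_idx] += duw
            grads[2 * up_idx + 1] += dub
        c1, c2 = caches["enc"][d - 1]
        g = self._conv_relu_back(g, c2, grads)
        g = self._conv_relu_back(g, c1, grads)
        for i in range(d - 2, -1, -1):
            g = maxpool_backward(g, caches["pool"][i])
            g = g + skip_grads[i]
            c1, c2 = caches["enc"][i]
            g = self._conv_relu_back(g, c2, grads)
            g = self._conv_relu_back(g, c1, grads, need_dx=(i > 0))
        self._caches = None
        return grads

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Per-class probabilities on the output patch (softmax over axis 0)."""
        return softmax(self.forward(x, train=False), axis=0)

    def output_shape(self, spatial_shape) -> tuple[int, ...]:
        """Structural per-axis output size, propagated through the layer stack.

        Independent of the closed-form `shape_trace`: walks the actual
        encoder/decoder wiring of this instance and applies each layer's
        shape rule.
        """
        d = self.cfg.depth
        loss = 0 if self.cfg.padding == "same" else 2 * (self.cfg.kernel - 1)
        sp = list(int(s) for s in spatial_shape)
        for _ in range(d - 1):
            sp = [s - loss for s in sp]
            if any(s <= 0 or s % 2 for s in sp):
                raise ValueError(f"invalid spatial trace at {sp}")
            sp = [s // 2 for s in sp]
        sp = [s - loss for s in sp]
        for _ in range(d - 1):
            sp = [2 * s - loss for s in sp]
        if any(s <= 0 for s in sp):
            raise ValueError(f"invalid spatial trace at {sp}")
        return tuple(sp)

    # -- serialization ----------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), *self.weights)
        meta = {"cfg": self.cfg.__dict__.copy()}
        meta["cfg"]["first_layer_filters"] = list(self.cfg.first_layer_filters)
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "UNet":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        cfgd = meta["cfg"]
        cfgd["first_layer_filters"] = tuple(cfgd["first_layer_filters"])
        net = cls(UNetConfig(**cfgd))
        with np.load(path.with_suffix(".npz")) as z:
            net.weights = [z[k].copy() for k in z.files]
        return net
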