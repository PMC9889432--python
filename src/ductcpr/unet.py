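"""Miniature 3D U-Net segmentation backend, implemented in numpy.

A deliberately small fully-convolutional network — two resolution
levels, 8 base channels, two independent sigmoid heads (pancreas, duct),
soft-Dice loss, 32³ patches — trained on synthetic phantoms at desk
scale (CPU, seconds to minutes).  Convolutions, backpropagation and the
Adam optimizer are written directly on numpy arrays (im2col matmuls), so
the CNN pathway has no framework dependency.

The two binary heads mirror a design with separate pancreas and duct
networks; the head convolution is zero-initialized so an untrained model
predicts probability exactly 0.5 everywhere and, with a strict > 0.5
decision threshold, yields empty masks — the downstream pipeline then
exercises the pancreas-center fallback rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit

from .grid import SegmentationMask, Volume3D
from .segmentation import SegmentationResult, estimate_pancreas, postfilter_duct

PATCH = 32
HU_SHIFT = 50.0     # fixed intensity normalization: (hu + 50) / 150
HU_SCALE = 150.0


def _normalize(data: np.ndarray) -> np.ndarray:
    return ((data + HU_SHIFT) / HU_SCALE).astype(np.float32)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray) -> np.ndarray:
    """(C, D, H, W) -> (D*H*W, C*27) for a 3³ same-padded convolution."""
    c, d, h, w = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3, 3), axis=(1, 2, 3))
    # win: (C, D, H, W, 3, 3, 3) -> (D, H, W, C, 3, 3, 3)
    return np.ascontiguousarray(win.transpose(1, 2, 3, 0, 4, 5, 6)).reshape(
        d * h * w, c * 27
    )


class Conv3x3:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, zero_init=False):
        fan_in = c_in * 27
        scale = 0.0 if zero_init else np.sqrt(2.0 / fan_in)
        self.w = (scale * rng.standard_normal((c_out, fan_in))).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.c_in, self.c_out = c_in, c_out

    def forward(self, x):
        self._shape = x.shape[1:]
        self._col = _im2col(x)
        out = self._col @ self.w.T + self.b
        return np.moveaxis(out.reshape(*self._shape, self.c_out), 3, 0)

    def backward(self, dout):
        dflat = np.moveaxis(dout, 0, 3).reshape(-1, self.c_out)
        self.dw = (dflat.T @ self._col).astype(np.float32)
        self.db = dflat.sum(axis=0).astype(np.float32)
        # dx is itself a same-padded convolution of dout with the
        # channel-transposed, spatially flipped kernels (exact adjoint of
        # the zero-padded forward conv) — one more im2col matmul instead
        # of a python scatter loop
        w_back = (
            self.w.reshape(self.c_out, self.c_in, 27)[:, :, ::-1]
            .transpose(0, 2, 1)
            .reshape(self.c_out * 27, self.c_in)
        )
        dcol = _im2col(dout.astype(np.float32)) @ w_back
        d, h, w = self._shape
        return np.moveaxis(dcol.reshape(d, h, w, self.c_in), 3, 0)


def _relu_fwd(x):
    return np.maximum(x, 0.0), x > 0


def _avgpool2(x):
    c, d, h, w = x.shape
    return x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).mean(axis=(2, 4, 6))


def _avgpool2_back(dout):
    return np.repeat(np.repeat(np.repeat(dout, 2, 1), 2, 2), 2, 3) / 8.0


def _upsample2(x):
    return np.repeat(np.repeat(np.repeat(x, 2, 1), 2, 2), 2, 3)


def _upsample2_back(dout):
    c, d, h, w = dout.shape
    return dout.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(2, 4, 6))


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

@dataclass
class TrainingConfig:
    epochs: int = 20
    learning_rate: float = 3e-3
    seed: int = 0
    base_channels: int = 8


class MiniUNet3D:
    """2-level U-Net: enc(1→8→8) ─pool→ bottleneck(8→16→16) ─up/concat→ dec(24→8) → heads(8→2)."""

    def __init__(self, base: int = 8, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.base = base
        self.enc1 = Conv3x3(1, base, rng)
        self.enc2 = Conv3x3(base, base, rng)
        self.bot1 = Conv3x3(base, 2 * base, rng)
        self.bot2 = Conv3x3(2 * base, 2 * base, rng)
        self.dec1 = Conv3x3(3 * base, base, rng)
        self.head = Conv3x3(base, 2, rng, zero_init=True)
        self.layers = [self.enc1, self.enc2, self.bot1, self.bot2, self.dec1, self.head]

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (1, D, H, W) normalized; returns per-voxel probabilities (2, D, H, W)."""
        a1, self._m1 = _relu_fwd(self.enc1.forward(x))
        a2, self._m2 = _relu_fwd(self.enc2.forward(a1))
        p = _avgpool2(a2)
        b1, self._m3 = _relu_fwd(self.bot1.forward(p))
        b2, self._m4 = _relu_fwd(self.bot2.forward(b1))
        up = _upsample2(b2)
        cat = np.concatenate([up, a2], axis=0)
        d1, self._m5 = _relu_fwd(self.dec1.forward(cat))
        logits = self.head.forward(d1)
        self._probs = expit(logits)
        return self._probs

    def backward(self, dprobs: np.ndarray) -> None:
        dlogits = dprobs * self._probs * (1.0 - self._probs)
        dd1 = self.head.backward(dlogits.astype(np.float32)) * self._m5
        dcat = self.dec1.backward(dd1)
        dup, da2_skip = dcat[: 2 * self.base], dcat[2 * self.base:]
        db2 = _upsample2_back(dup) * self._m4
        db1 = self.bot2.backward(db2) * self._m3
        dp = self.bot1.backward(db1)
        da2 = (_avgpool2_back(dp) + da2_skip) * self._m2
        da1 = self.enc2.backward(da2) * self._m1
        self.enc1.backward(da1)

    # -- persistence -------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            out[f"w{i}"] = layer.w
            out[f"b{i}"] = layer.b
        return out

    def load_state(self, arrays) -> None:
        for i, layer in enumerate(self.layers):
            layer.w = np.asarray(arrays[f"w{i}"], dtype=np.float32)
            layer.b = np.asarray(arrays[f"b{i}"], dtype=np.float32)


class _Adam:
    def __init__(self, layers, lr):
        self.lr, self.b1, self.b2, self.eps, self.t = lr, 0.9, 0.999, 1e-8, 0
        self.layers = layers
        self.m = [np.zeros_like(p) for l in layers for p in (l.w, l.b)]
        self.v = [np.zeros_like(p) for l in layers for p in (l.w, l.b)]

    def step(self):
        self.t += 1
        i = 0
        for layer in self.layers:
            for name in ("w", "b"):
                g = getattr(layer, "d" + name)
                self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
                self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
                mh = self.m[i] / (1 - self.b1 ** self.t)
                vh = self.v[i] / (1 - self.b2 ** self.t)
                p = getattr(layer, name)
                setattr(layer, name, p - self.lr * mh / (np.sqrt(vh) + self.eps))
                i += 1


def _soft_dice_loss(probs: np.ndarray, targets: np.ndarray, smooth=1.0):
    """Mean soft-Dice loss over channels; returns (loss, dL/dprobs)."""
    p = probs.reshape(probs.shape[0], -1).astype(np.float64)
    t = targets.reshape(targets.shape[0], -1).astype(np.float64)
    num = 2.0 * (p * t).sum(axis=1) + smooth
    den = p.sum(axis=1) + t.sum(axis=1) + smooth
    loss = float((1.0 - num / den).mean())
    dp = -(2.0 * t * den[:, None] - num[:, None]) / den[:, None] ** 2
    return loss, (dp / probs.shape[0]).reshape(probs.shape)


# ---------------------------------------------------------------------------
# training / inference API
# ---------------------------------------------------------------------------

@dataclass
class UNetSegmenter:
    """Trained-model handle: the network plus its provenance metadata."""

    model: MiniUNet3D
    config: TrainingConfig
    loss_history: list[float] = field(default_factory=list)

    def save(self, path) -> None:
        """Checkpoint: single .npz of weights + JSON sidecar with metadata."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.model.state_arrays())
        sidecar = {
            "architecture": "mini-unet3d-2level",
            "base_channels": self.model.base,
            "epochs": self.config.epochs,
            "learning_rate": self.config.learning_rate,
            "seed": self.config.seed,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "UNetSegmenter":
        path = Path(path)
        npz, sidecar = path.with_suffix(".npz"), path.with_suffix(".json")
        if not npz.exists() or not sidecar.exists():
            raise IOError(f"missing checkpoint file(s): {npz} / {sidecar}")
        meta = json.loads(sidecar.read_text())
        cfg = TrainingConfig(
            epochs=meta["epochs"], learning_rate=meta["learning_rate"],
            seed=meta["seed"], base_channels=meta["base_channels"],
        )
        model = MiniUNet3D(base=meta["base_channels"], seed=meta["seed"])
        with np.load(npz) as arrays:
            model.load_state(arrays)
        return cls(model=model, config=cfg)


def train_unet(
    phantom_specs,
    config: TrainingConfig | None = None,
) -> UNetSegmenter:
    """Train the miniature U-Net on phantom volumes (pancreas + duct heads).

    Phantoms are generated from the given specs, normalized with the
    fixed HU affine, cropped/padded to 32³, and iterated in a seeded
    shuffle; each step minimizes the mean soft-Dice loss of the two
    heads with Adam.
    """
    from .phantom import generate_phantom  # local import: avoid cycle

    if len(phantom_specs) == 0:
        raise ValueError("empty training set")
    config = config or TrainingConfig()
    rng = np.random.default_rng(config.seed)

    samples = []
    for spec in phantom_specs:
        vol, truth = generate_phantom(spec)
        x = _crop_or_pad(_normalize(vol.data))
        y = np.stack(
            [
                _crop_or_pad(truth.pancreas_mask.data.astype(np.float32)),
                _crop_or_pad(truth.duct_mask.data.astype(np.float32)),
            ]
        )
        samples.append((x[None], y))

    model = MiniUNet3D(base=config.base_channels, seed=config.seed)
    opt = _Adam(model.layers, config.learning_rate)
    history = []
    for _ in range(config.epochs):
        order = rng.permutation(len(samples))
        epoch_loss = 0.0
        for i in order:
            x, y = samples[i]
            probs = model.forward(x)
            loss, dprobs = _soft_dice_loss(probs, y)
            model.backward(dprobs)
            opt.step()
            epoch_loss += loss
        history.append(epoch_loss / len(samples))
    return UNetSegmenter(model=model, config=config, loss_history=history)


def _crop_or_pad(data: np.ndarray, size: int = PATCH) -> np.ndarray:
    """Center-crop / zero-pad each axis to ``size``."""
    out = data
    for ax in range(3):
        n = out.shape[ax]
        if n > size:
            lo = (n - size) // 2
            out = np.take(out, np.arange(lo, lo + size), axis=ax)
        elif n < size:
            pad = [(0, 0)] * 3
            pad[ax] = ((size - n) // 2, size - n - (size - n) // 2)
            out = np.pad(out, pad)
    return out


def segment_unet(
    volume: Volume3D,
    segmenter: UNetSegmenter,
    threshold: float = 0.5,
    min_component_voxels: int = 20,
    opening_radius: int = 1,
    stride: int = 24,
) -> SegmentationResult:
    """Patch-wise U-Net inference with overlap-averaged probabilities.

    Probabilities strictly above ``threshold`` become mask voxels, then
    the same post-filter as the classical backend runs.  If the pancreas
    head predicts nothing (e.g. an untrained model), the intensity-based
    pancreas estimate is substituted so the downstream fallback rule can
    still route a centerline.
    """
    data = _normalize(volume.data)
    prob = np.zeros((2, *data.shape), dtype=np.float64)
    weight = np.zeros(data.shape, dtype=np.float64)
    starts = [_tile_starts(n, PATCH, stride) for n in data.shape]
    for i0 in starts[0]:
        for j0 in starts[1]:
            for k0 in starts[2]:
                patch = np.zeros((PATCH, PATCH, PATCH), dtype=np.float32)
                di = min(PATCH, data.shape[0] - i0)
                dj = min(PATCH, data.shape[1] - j0)
                dk = min(PATCH, data.shape[2] - k0)
                patch[:di, :dj, :dk] = data[i0:i0 + di, j0:j0 + dj, k0:k0 + dk]
                p = segmenter.model.forward(patch[None])
                prob[:, i0:i0 + di, j0:j0 + dj, k0:k0 + dk] += p[:, :di, :dj, :dk]
                weight[i0:i0 + di, j0:j0 + dj, k0:k0 + dk] += 1.0
    prob /= np.maximum(weight, 1.0)

    pancreas = prob[0] > threshold
    duct = prob[1] > threshold
    if not pancreas.any():
        pancreas = estimate_pancreas(volume).data
    duct = postfilter_duct(duct, pancreas, opening_radius, min_component_voxels)
    grid = dict(spacing_mm=volume.spacing_mm, origin_mm=volume.origin_mm)
    return SegmentationResult(
        pancreas_mask=SegmentationMask(pancreas, **grid),
        duct_mask=SegmentationMask(duct, **grid),
        backend_id="unet",
    )


def _tile_starts(n: int, patch: int, stride: int) -> list[int]:
    if n <= patch:
        return [0]
    starts = list(range(0, n - patch, stride))
    starts.append(n - patch)
    return starts
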