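"""Encoder-decoder (U-Net style) segmentation, trained per study system.

One architecture is used for both segmentation sub-tasks (body mask, spot
mask): an encoder of repeated conv-conv-pool blocks with a constant
number of filters per layer and dropout after each encoder block, a
mirrored decoder with skip connections, and a 1x1 sigmoid head.  Inputs
are square RGB images; smaller images are letter-boxed with black padding
(aspect ratio preserved) and a placement record allows predictions to be
mapped back to original coordinates.  For the spot network the input is
first cropped to the extent of the body mask so small spots survive the
down-scaling.

The default configuration (512 px inputs, encoder depth 4, 64 filters,
50% dropout, 150 epochs of 50 samples) is intended for real training
runs; :meth:`UNetConfig.smoke` is a reduced 64 px configuration for
CPU-scale tests and demonstrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import transform as sktransform
from skimage import morphology

from .errors import EmptyMaskError
from .nn import (Adam, Conv2D, Dropout, MaxPool2x2, ReLU, Upsample2x2,
                 bce_loss_and_grad, sigmoid)

__all__ = [
    "UNetConfig",
    "AugmentationSpec",
    "PlacementRecord",
    "pad_to_input",
    "crop_and_rescale_to_mask",
    "build_segmentation_network",
    "train_network",
    "postprocess_mask",
    "SegmentationUNet",
]


@dataclass
class UNetConfig:
    input_size: int = 512
    encoder_depth: int = 4
    filters: int = 64
    dropout: float = 0.5
    epochs: int = 150
    samples_per_epoch: int = 50
    learning_rate: float = 1e-3

    def __post_init__(self):
        if self.input_size % (2 ** self.encoder_depth) != 0:
            raise ValueError("input_size must be divisible by 2^depth")
        if self.encoder_depth < 1 or self.filters < 1:
            raise ValueError("invalid depth/filters")

    @classmethod
    def smoke(cls) -> "UNetConfig":
        """Reduced 64x64 configuration for CPU tests."""
        return cls(input_size=64, encoder_depth=3, filters=8, dropout=0.0,
                   epochs=50, samples_per_epoch=2, learning_rate=2e-3)


@dataclass
class AugmentationSpec:
    """Random rotations, shears, zooms, flips and brightness changes."""

    rotation: tuple[float, float] = (-15.0, 15.0)   # degrees
    shear: tuple[float, float] = (-5.0, 5.0)        # degrees
    zoom: tuple[float, float] = (0.9, 1.1)
    flip_horizontal: bool = True
    flip_vertical: bool = True
    brightness: tuple[float, float] = (0.85, 1.15)

    @classmethod
    def none(cls) -> "AugmentationSpec | None":
        return None

    def apply(self, rng: np.random.Generator, image: np.ndarray,
              mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h, w = image.shape[:2]
        centre = np.array([w / 2.0, h / 2.0])
        tf = (sktransform.AffineTransform(translation=-centre)
              + sktransform.AffineTransform(
                  rotation=np.radians(rng.uniform(*self.rotation)),
                  shear=np.radians(rng.uniform(*self.shear)),
                  scale=rng.uniform(*self.zoom))
              + sktransform.AffineTransform(translation=centre))
        img = sktransform.warp(image, tf.inverse, order=1, mode="constant")
        msk = sktransform.warp(mask.astype(float), tf.inverse, order=0)
        if self.flip_horizontal and rng.random() < 0.5:
            img, msk = img[:, ::-1], msk[:, ::-1]
        if self.flip_vertical and rng.random() < 0.5:
            img, msk = img[::-1], msk[::-1]
        img = np.clip(img * rng.uniform(*self.brightness), 0, 1)
        return np.ascontiguousarray(img), np.ascontiguousarray(msk > 0.5)


@dataclass
class PlacementRecord:
    """How a (cropped and) letter-boxed image sits in the network frame."""

    orig_shape: tuple[int, int]
    bbox: tuple[int, int, int, int]       # r0, c0, r1, c1 in original image
    content_shape: tuple[int, int]        # rows, cols occupied in the frame
    scale: float                          # frame px per original px

    def restore_mask(self, pred: np.ndarray) -> np.ndarray:
        """Map a frame-sized prediction back to the original image frame."""
        r0, c0, r1, c1 = self.bbox
        ch, cw = self.content_shape
        content = pred[:ch, :cw].astype(float)
        back = sktransform.resize(content, (r1 - r0, c1 - c0), order=0,
                                  preserve_range=True, anti_aliasing=False)
        out = np.zeros(self.orig_shape, dtype=bool)
        out[r0:r1, c0:c1] = back > 0.5
        return out

    def to_original(self, points: np.ndarray) -> np.ndarray:
        """Map frame (x, y) coordinates back to original coordinates."""
        points = np.asarray(points, dtype=float)
        r0, c0, _, _ = self.bbox
        return points / self.scale + np.array([c0, r0])


def _letterbox(image: np.ndarray, size: int,
               bbox: tuple[int, int, int, int],
               orig_shape: tuple[int, int]
               ) -> tuple[np.ndarray, PlacementRecord]:
    h, w = image.shape[:2]
    scale = size / max(h, w)
    ch, cw = int(round(h * scale)), int(round(w * scale))
    ch, cw = min(ch, size), min(cw, size)
    resized = sktransform.resize(image, (ch, cw), order=1,
                                 preserve_range=True, anti_aliasing=True)
    if image.ndim == 3:
        out = np.zeros((size, size, image.shape[2]), dtype=float)
        out[:ch, :cw] = resized
    else:
        out = np.zeros((size, size), dtype=float)
        out[:ch, :cw] = resized
    return out, PlacementRecord(orig_shape=orig_shape, bbox=bbox,
                                content_shape=(ch, cw), scale=scale)


def pad_to_input(image: np.ndarray, size: int
                 ) -> tuple[np.ndarray, PlacementRecord]:
    """Scale the longest dimension to ``size`` and pad the rest with black."""
    image = np.asarray(image, dtype=float)
    if image.max() > 1.5:
        image = image / 255.0
    h, w = image.shape[:2]
    return _letterbox(image, size, (0, 0, h, w), (h, w))


def crop_and_rescale_to_mask(image: np.ndarray, body_mask: np.ndarray,
                             size: int) -> tuple[np.ndarray, PlacementRecord]:
    """Crop to the body-mask bounding box, then letter-box to ``size``."""
    body_mask = np.asarray(body_mask, dtype=bool)
    if not body_mask.any():
        raise EmptyMaskError("cannot crop to an empty mask")
    image = np.asarray(image, dtype=float)
    if image.max() > 1.5:
        image = image / 255.0
    rows = np.nonzero(body_mask.any(axis=1))[0]
    cols = np.nonzero(body_mask.any(axis=0))[0]
    r0, r1 = int(rows[0]), int(rows[-1]) + 1
    c0, c1 = int(cols[0]), int(cols[-1]) + 1
    crop = image[r0:r1, c0:c1]
    return _letterbox(crop, size, (r0, c0, r1, c1), body_mask.shape)


class SegmentationUNet:
    """The encoder-decoder network; forward/backward are hand-written."""

    def __init__(self, cfg: UNetConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        f = cfg.filters
        self.enc = []
        cin = 3
        for _ in range(cfg.encoder_depth):
            block = {"c1": Conv2D(rng, cin, f), "r1": ReLU(),
                     "c2": Conv2D(rng, f, f), "r2": ReLU(),
                     "drop": Dropout(cfg.dropout), "pool": MaxPool2x2()}
            self.enc.append(block)
            cin = f
        self.mid = {"c1": Conv2D(rng, f, f), "r1": ReLU(),
                    "c2": Conv2D(rng, f, f), "r2": ReLU()}
        self.dec = []
        for _ in range(cfg.encoder_depth):
            block = {"up": Upsample2x2(),
                     "cu": Conv2D(rng, f, f), "ru": ReLU(),
                     "c1": Conv2D(rng, 2 * f, f), "r1": ReLU(),
                     "c2": Conv2D(rng, f, f), "r2": ReLU()}
            self.dec.append(block)
        self.head = Conv2D(rng, f, 1, k=1)

    def _layers(self):
        for block in self.enc + [self.mid] + self.dec:
            for layer in block.values():
                yield layer
        yield self.head

    def conv_layers(self):
        return [l for l in self._layers() if isinstance(l, Conv2D)]

    def forward(self, x: np.ndarray,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Logits for an (S, S, 3) image; pass ``rng`` to enable dropout."""
        skips = []
        h = x
        for blk in self.enc:
            h = blk["r1"].forward(blk["c1"].forward(h))
            h = blk["r2"].forward(blk["c2"].forward(h))
            h = blk["drop"].forward(h, rng)
            skips.append(h)
            h = blk["pool"].forward(h)
        h = self.mid["r1"].forward(self.mid["c1"].forward(h))
        h = self.mid["r2"].forward(self.mid["c2"].forward(h))
        for blk, skip in zip(self.dec, reversed(skips)):
            h = blk["up"].forward(h)
            h = blk["ru"].forward(blk["cu"].forward(h))
            h = np.concatenate([skip, h], axis=2)
            h = blk["r1"].forward(blk["c1"].forward(h))
            h = blk["r2"].forward(blk["c2"].forward(h))
        return self.head.forward(h)[:, :, 0]

    def backward(self, dlogits: np.ndarray):
        f = self.cfg.filters
        d = self.head.backward(dlogits[:, :, None])
        dskips = []
        for blk in reversed(self.dec):
            d = blk["c2"].backward(blk["r2"].backward(d))
            d = blk["c1"].backward(blk["r1"].backward(d))
            dskip, d = d[:, :, :f], d[:, :, f:]
            dskips.append(dskip)
            d = blk["cu"].backward(blk["ru"].backward(d))
            d = blk["up"].backward(d)
        d = self.mid["c1"].backward(self.mid["r1"].backward(
            self.mid["c2"].backward(self.mid["r2"].backward(d))))
        for blk, dskip in zip(reversed(self.enc), reversed(dskips)):
            d = blk["pool"].backward(d)
            d = d + dskip
            d = blk["drop"].backward(d)
            d = blk["c2"].backward(blk["r2"].backward(d))
            d = blk["c1"].backward(blk["r1"].backward(d))
        return d

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Probability map in [0, 1]; deterministic (dropout disabled)."""
        return sigmoid(self.forward(x, rng=None))


def build_segmentation_network(cfg: UNetConfig,
                               seed: int = 0) -> SegmentationUNet:
    """Construct the network; forward maps SxSx3 to SxS probabilities."""
    return SegmentationUNet(cfg, seed=seed)


def train_network(model: SegmentationUNet,
                  pairs: list[tuple[np.ndarray, np.ndarray]],
                  cfg: UNetConfig | None = None,
                  aug: AugmentationSpec | None = None,
                  seed: int = 0) -> list[float]:
    """Train on (image, mask) pairs; returns the per-epoch mean loss trace.

    Each epoch consumes ``samples_per_epoch`` draws (with replacement)
    from the training pairs; reproducible given ``seed`` when
    augmentation is off.
    """
    if not pairs:
        raise ValueError("need at least one training pair")
    cfg = cfg or model.cfg
    rng = np.random.default_rng(seed)
    opt = Adam(lr=cfg.learning_rate)
    layers = model.conv_layers()
    losses = []
    prepared = []
    for img, msk in pairs:
        img = np.asarray(img, dtype=float)
        if img.max() > 1.5:
            img = img / 255.0
        if img.ndim == 2:
            img = np.repeat(img[:, :, None], 3, axis=2)
        prepared.append((img, np.asarray(msk, dtype=float)))
    for _ in range(cfg.epochs):
        epoch_loss = 0.0
        for _ in range(cfg.samples_per_epoch):
            img, msk = prepared[rng.integers(len(prepared))]
            if aug is not None:
                img, msk = aug.apply(rng, img, msk)
                msk = msk.astype(float)
            drop_rng = rng if model.cfg.dropout > 0 else None
            logits = model.forward(img, rng=drop_rng)
            loss, dlogits = bce_loss_and_grad(logits, msk)
            model.backward(dlogits)
            opt.step(layers)
            epoch_loss += loss
        losses.append(epoch_loss / cfg.samples_per_epoch)
    return losses


def postprocess_mask(pred: np.ndarray, closing_radius: int = 5
                     ) -> np.ndarray:
    """Fill interior holes, close small gaps, keep the central component."""
    pred = np.asarray(pred, dtype=bool)
    if not pred.any():
        return np.zeros_like(pred)
    filled = ndimage.binary_fill_holes(pred)
    closed = morphology.closing(filled, morphology.disk(closing_radius))
    closed = ndimage.binary_fill_holes(closed)
    from skimage import measure
    from .baseline import _central_component
    labels = measure.label(closed)
    return labels == _central_component(labels)
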