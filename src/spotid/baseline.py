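"""Feature-engineered baseline segmentation.

Body-mask extraction: greyscale -> heavy Gaussian blur -> global dark
threshold -> connected components -> pick the large central component ->
morphological erosion.  Spot extraction: resolution-dependent Gaussian
blur -> adaptive mean threshold -> restrict to the body mask -> keep
roughly circular, medium-sized regions.

The stated defaults (body blur sigma 125 px, dark threshold 80) suit
full-resolution photographs around 5184 px wide; ``BaselineConfig.
for_image_size`` rescales the pixel-unit parameters proportionally for
other resolutions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage import color, filters, measure, morphology

from .errors import EmptyMaskError, NoSubjectFoundError

REFERENCE_IMAGE_LENGTH = 5184  # typical full-resolution photograph width


@dataclass
class BaselineConfig:
    sigma1: float = 125.0          # body blur, px
    body_threshold: float = 80.0   # grey level: body pixels are darker
    erosion_radius: int = 5        # px
    adaptive_offset: float = 2.0   # grey levels below the local mean
    circularity_min: float = 0.5   # 4*pi*A/P^2 lower bound
    area_min_frac: float = 1e-5    # of body area
    area_max_frac: float = 5e-3
    sigma2_min: float = 3.0        # clamp for the spot-blur formula

    def __post_init__(self):
        if min(self.sigma1, self.body_threshold, self.erosion_radius,
               self.adaptive_offset, self.sigma2_min) <= 0:
            raise ValueError("all pixel/grey parameters must be positive")
        if not 0 < self.circularity_min <= 1:
            raise ValueError("circularity_min must lie in (0, 1]")
        if not 0 < self.area_min_frac < self.area_max_frac:
            raise ValueError("need 0 < area_min_frac < area_max_frac")

    @classmethod
    def for_image_size(cls, image_length: float, **overrides) -> "BaselineConfig":
        """Defaults with pixel-unit parameters scaled to ``image_length``."""
        s = image_length / REFERENCE_IMAGE_LENGTH
        cfg = cls(sigma1=max(125.0 * s, 1.0),
                  erosion_radius=max(int(round(5 * s)), 1))
        return replace(cfg, **overrides)


def _to_grey(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim == 3:
        return color.rgb2gray(image) * 255.0
    return image.astype(float)


def _central_component(labels: np.ndarray) -> int:
    """Pick the component whose centroid is nearest the image centre.

    Ties (same distance) go to the larger component.
    """
    h, w = labels.shape
    centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    best = None
    for region in measure.regionprops(labels):
        d = float(np.hypot(*(np.asarray(region.centroid) - centre)))
        key = (round(d, 9), -region.area, region.label)
        if best is None or key < best[0]:
            best = (key, region.label)
    return best[1]


def extract_fish_mask_baseline(image: np.ndarray,
                               cfg: BaselineConfig | None = None) -> np.ndarray:
    """Extract the body mask with the hand-crafted pipeline.

    Raises :class:`NoSubjectFoundError` when no pixel falls below the dark
    threshold after blurring.
    """
    if cfg is None:
        cfg = BaselineConfig.for_image_size(max(np.asarray(image).shape[:2]))
    grey = _to_grey(image)
    blurred = ndimage.gaussian_filter(grey, cfg.sigma1)
    dark = blurred < cfg.body_threshold
    labels = measure.label(dark)
    if labels.max() == 0:
        raise NoSubjectFoundError("no region below the body threshold")
    mask = labels == _central_component(labels)
    mask = morphology.erosion(mask, morphology.disk(cfg.erosion_radius))
    if not mask.any():
        raise NoSubjectFoundError("central component vanished under erosion")
    return mask


def spot_blur_sigma(image_length: float, sigma_min: float = 3.0) -> float:
    """Resolution-dependent blur for spot extraction.

    ``((image_length - 1882) / 440) * 2 + 19``, clamped below at
    ``sigma_min`` so it stays positive for small synthetic images.
    ``image_length`` is the larger image dimension.
    """
    if image_length <= 0:
        raise ValueError("image_length must be positive")
    sigma = ((image_length - 1882.0) / 440.0) * 2.0 + 19.0
    return max(sigma, sigma_min)


def filter_spot_regions(labels: np.ndarray, body_area: float,
                        cfg: BaselineConfig) -> np.ndarray:
    """Keep roughly circular, medium-sized components.

    Circularity is 4*pi*A/P^2; the area window is relative to the body
    area.  Returns a filtered label image (labels preserved); idempotent.
    """
    keep = np.zeros_like(labels)
    lo = cfg.area_min_frac * body_area
    hi = cfg.area_max_frac * body_area
    for region in measure.regionprops(labels):
        area = region.area
        perimeter = region.perimeter
        if perimeter <= 0:
            continue
        circularity = 4.0 * math.pi * area / perimeter**2
        if circularity >= cfg.circularity_min and lo <= area <= hi:
            keep[labels == region.label] = region.label
    return keep


def extract_spots_baseline(image: np.ndarray, body_mask: np.ndarray,
                           cfg: BaselineConfig | None = None) -> np.ndarray:
    """Extract the spot mask inside ``body_mask``.

    Gaussian blur at the resolution-dependent sigma, adaptive mean
    thresholding (dark side), masking by the body, then the shape filter.
    """
    body_mask = np.asarray(body_mask, dtype=bool)
    if not body_mask.any():
        raise EmptyMaskError("body mask is empty")
    if cfg is None:
        cfg = BaselineConfig.for_image_size(max(body_mask.shape))
    grey = _to_grey(image)
    sigma2 = spot_blur_sigma(max(grey.shape), sigma_min=cfg.sigma2_min)
    blurred = ndimage.gaussian_filter(grey, sigma2)
    block = int(round(4 * sigma2))
    block += 1 - block % 2  # force odd
    block = max(block, 3)
    local_mean = filters.threshold_local(blurred, block_size=block,
                                         method="mean",
                                         offset=cfg.adaptive_offset)
    spots = blurred < local_mean
    spots &= body_mask
    labels = measure.label(spots)
    labels = filter_spot_regions(labels, float(body_mask.sum()), cfg)
    return labels > 0


def evaluate_segmentation(pred: np.ndarray, truth: np.ndarray
                          ) -> tuple[float, float, float]:
    """Per-pixel precision, recall and F1 of ``pred`` against ``truth``.

    Undefined ratios (empty prediction or empty truth) are reported as 0,
    and F1 is 0 when both precision and recall are 0.
    """
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth must share dimensions")
    tp = float(np.count_nonzero(pred & truth))
    fp = float(np.count_nonzero(pred & ~truth))
    fn = float(np.count_nonzero(~pred & truth))
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    if precision + recall == 0:
        return precision, recall, 0.0
    return precision, recall, 2 * precision * recall / (precision + recall)
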