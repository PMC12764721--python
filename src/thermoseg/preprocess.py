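"""Pixel screening, histogram enhancement, and affine augmentation.

``screen_pixels`` is a Hampel-style reliability filter: a pixel whose value
deviates from its 3x3 neighbourhood median by more than ``k`` times the
neighbourhood's median absolute deviation (MAD) is judged unreliable and
replaced by that median.  ``enhance_histogram`` applies contrast-limited
adaptive histogram equalization (CLAHE).  ``augment`` produces affine
(translate / scale / rotate) copies of a record, applying the identical
transform to image and mask, with bilinear interpolation for the image and
nearest-neighbour for the mask so masks stay binary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure

from .synthio import ThermogramRecord

__all__ = ["AugmentSpec", "AffineParams", "screen_pixels", "enhance_histogram",
           "augment", "apply_affine"]


@dataclass
class AugmentSpec:
    max_translation: float = 0.08   # fraction of image size
    scale_range: tuple[float, float] = (0.9, 1.1)
    max_rotation_deg: float = 15.0
    copies_per_image: int = 2
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.max_translation <= 0.5:
            raise ValueError(
                f"max_translation must be in [0, 0.5], got {self.max_translation}")
        lo, hi = self.scale_range
        if not (0.0 < lo <= hi <= 2.0):
            raise ValueError(f"scale_range must lie in (0, 2], got {self.scale_range}")
        if self.max_rotation_deg < 0:
            raise ValueError("max_rotation_deg must be >= 0")
        if self.copies_per_image < 0:
            raise ValueError("copies_per_image must be >= 0")


@dataclass(frozen=True)
class AffineParams:
    """One sampled transform: rotation (degrees), isotropic scale, and
    translation in pixels (rows, cols)."""

    rotation_deg: float
    scale: float
    translation: tuple[float, float]


def _validate_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {image.shape}")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    return image


def screen_pixels(image: np.ndarray, k: float = 3.0) -> np.ndarray:
    """Replace pixels outside k*MAD of their 3x3 neighbourhood median."""
    image = _validate_image(image)
    padded = np.pad(image, 1, mode="edge")
    win = np.lib.stride_tricks.sliding_window_view(padded, (3, 3))
    win = win.reshape(*image.shape, 9)
    med = np.median(win, axis=-1)
    mad = np.median(np.abs(win - med[..., None]), axis=-1)
    bad = np.abs(image - med) > k * mad
    out = np.where(bad, med, image)
    return np.clip(out, 0.0, 1.0)


def enhance_histogram(image: np.ndarray, tiles: int = 8,
                      clip_limit: float = 0.02) -> np.ndarray:
    """CLAHE with a ``tiles x tiles`` grid; output stays in [0, 1].

    Constant images are returned unchanged (equalization is undefined on a
    degenerate histogram).
    """
    image = _validate_image(image)
    if image.min() < 0 or image.max() > 1:
        raise ValueError("image values must lie in [0, 1]")
    if np.ptp(image) < 1e-12:
        return image.copy()
    kernel = max(image.shape[0] // tiles, 1)
    out = exposure.equalize_adapthist(image, kernel_size=kernel,
                                      clip_limit=clip_limit)
    return np.clip(out, 0.0, 1.0)


def apply_affine(array: np.ndarray, params: AffineParams, order: int) -> np.ndarray:
    """Apply a centred rotate/scale/translate transform to a 2-D array.

    ``order=1`` (bilinear) for images, ``order=0`` (nearest) for masks.
    """
    theta = np.deg2rad(params.rotation_deg)
    c, s = np.cos(theta), np.sin(theta)
    # output -> input mapping: inverse of (scale * rotation) then translation
    inv = np.array([[c, -s], [s, c]]) / params.scale
    centre = (np.asarray(array.shape, dtype=np.float64) - 1) / 2.0
    shift = np.asarray(params.translation, dtype=np.float64)
    # content moves by `shift` in output coordinates, about the image centre
    offset = centre - inv @ (centre + shift)
    return ndimage.affine_transform(array.astype(np.float64), inv, offset=offset,
                                    order=order, mode="constant",
                                    cval=float(np.min(array)))


def _sample_params(spec: AugmentSpec, size: int,
                   rng: np.random.Generator) -> AffineParams:
    return AffineParams(
        rotation_deg=float(rng.uniform(-spec.max_rotation_deg, spec.max_rotation_deg)),
        scale=float(rng.uniform(*spec.scale_range)),
        translation=(float(rng.uniform(-1, 1) * spec.max_translation * size),
                     float(rng.uniform(-1, 1) * spec.max_translation * size)),
    )


def augment(record: ThermogramRecord, spec: AugmentSpec,
            return_transforms: bool = False, max_retries: int = 10):
    """Sample ``copies_per_image`` affine copies of a record.

    Each copy applies one transform identically to image and mask; the mask
    is re-binarized after warping.  Transforms that would push more than half
    of the mask foreground out of frame are resampled (bounded retries).
    Deterministic for a given (spec.seed, subject, side).
    """
    seed_seq = np.random.SeedSequence(
        [spec.seed, int(record.meta.subject_code), ord(record.meta.side.value[0])])
    rng = np.random.default_rng(seed_seq)
    size = record.image.shape[0]
    fg = int(record.mask.sum()) if record.mask is not None else 0

    out_records, out_params = [], []
    for _ in range(spec.copies_per_image):
        for attempt in range(max_retries + 1):
            params = _sample_params(spec, size, rng)
            new_image = np.clip(apply_affine(record.image, params, order=1), 0.0, 1.0)
            new_mask = None
            if record.mask is not None:
                new_mask = (apply_affine(record.mask.astype(np.float64), params,
                                         order=0) >= 0.5).astype(np.uint8)
                scale_sq = params.scale ** 2
                if fg > 0 and new_mask.sum() < 0.5 * fg * min(scale_sq, 1.0):
                    if attempt == max_retries:
                        raise RuntimeError(
                            "could not sample an augmentation keeping at least "
                            f"half the mask foreground for subject "
                            f"{record.meta.subject_code}")
                    continue
            break
        out_records.append(ThermogramRecord(meta=record.meta, image=new_image,
                                            mask=new_mask, label=record.label))
        out_params.append(params)
    if return_transforms:
        return out_records, out_params
    return out_records
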