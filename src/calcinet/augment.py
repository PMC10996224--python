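"""Deterministic preprocessing and stochastic training augmentations.

Composition order (training): random vendor LUT -> linear rescale to [0, 1]
-> perturbed lesion-centered crop -> random horizontal flip -> random gamma
-> additive Gaussian noise.  Evaluation applies only identity LUT, rescale
and the centered crop.  Geometric steps are applied congruently to image
and mask; photometric steps never touch the mask.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from .config import AugmentationConfig
from .manifest import MammogramSample


def apply_random_lut(sample: MammogramSample, rng: np.random.Generator) -> np.ndarray:
    """Apply one uniformly chosen vendor LUT; identity when none exist."""
    img = np.asarray(sample.image)
    if not sample.lut_family:
        return img.astype(float)
    idx = int(rng.integers(0, len(sample.lut_family)))
    return sample.lut_family[idx].apply(img).astype(float)


def rescale_unit(image: np.ndarray) -> np.ndarray:
    """Linear rescale to [0, 1]; a constant image maps to all zeros."""
    img = np.asarray(image, dtype=float)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def crop_lesion(
    image: np.ndarray,
    mask: Optional[np.ndarray],
    center: Tuple[int, int],
    config: AugmentationConfig,
    rng: Optional[np.random.Generator] = None,
    train_mode: bool = False,
) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    """Fixed-size crop around the (optionally perturbed) lesion center.

    The crop covers rows ``[c - s/2, c + s/2)``; out-of-image regions are
    zero-padded, so output geometry is ``(crop_size, crop_size)`` for any
    input, including centers at image corners.  Because ``max_perturb <
    crop_size / 2`` the true lesion center always stays inside the crop.
    """
    h, w = image.shape
    r, c = center
    if not (0 <= r < h and 0 <= c < w):
        raise ValueError(f"lesion center {center} outside image {image.shape}")
    if train_mode:
        if rng is None:
            raise ValueError("train_mode crops need an rng")
        dr = int(rng.integers(-config.max_perturb, config.max_perturb + 1))
        dc = int(rng.integers(-config.max_perturb, config.max_perturb + 1))
    else:
        dr = dc = 0
    size = config.crop_size
    half = size // 2
    top, left = r + dr - half, c + dc - half

    def take(arr, fill=0.0):
        out = np.full((size, size), fill, dtype=float)
        r0, r1 = max(top, 0), min(top + size, h)
        c0, c1 = max(left, 0), min(left + size, w)
        if r0 < r1 and c0 < c1:
            out[r0 - top : r1 - top, c0 - left : c1 - left] = arr[r0:r1, c0:c1]
        return out

    img_crop = take(image)
    mask_crop = None
    if mask is not None:
        mask_crop = take(mask).astype(np.uint8)
    return img_crop, mask_crop


def random_hflip(
    image: np.ndarray,
    mask: Optional[np.ndarray],
    p: float,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    """Mirror both arrays along columns with probability ``p`` — always both
    or neither."""
    if rng.random() < p:
        image = image[:, ::-1].copy()
        if mask is not None:
            mask = mask[:, ::-1].copy()
    return image, mask


def random_gamma(
    image: np.ndarray, gamma_range: Tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    gamma = rng.uniform(*gamma_range)
    return np.power(image, gamma)


def add_gaussian_noise(
    image: np.ndarray, noise_max_frac: float, rng: np.random.Generator
) -> np.ndarray:
    """Additive zero-mean noise, sigma ~ U(0, noise_max_frac) of unit scale,
    clipped back to [0, 1]."""
    if noise_max_frac == 0:
        return image
    sigma = rng.uniform(0.0, noise_max_frac)
    return np.clip(image + rng.normal(0.0, sigma, size=image.shape), 0.0, 1.0)


def train_transform(
    sample: MammogramSample,
    mask: np.ndarray,
    config: AugmentationConfig,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    img = apply_random_lut(sample, rng) if config.randomize_lut else np.asarray(sample.image, float)
    img = rescale_unit(img)
    img, m = crop_lesion(img, mask, sample.lesion_center, config, rng, train_mode=True)
    img, m = random_hflip(img, m, config.flip_p, rng)
    img = random_gamma(img, config.gamma_range, rng)
    img = add_gaussian_noise(img, config.noise_max_frac, rng)
    return img, m


def eval_transform(
    sample: MammogramSample,
    mask: Optional[np.ndarray],
    config: AugmentationConfig,
) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    """Deterministic pipeline: identity LUT, rescale, centered crop."""
    img = rescale_unit(np.asarray(sample.image, dtype=float))
    return crop_lesion(img, mask, sample.lesion_center, config, train_mode=False)
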