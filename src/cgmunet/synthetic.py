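"""Deterministic generator of lesion-like segmentation fixtures.

Produces paired image/mask samples that emulate the qualitative structure of
clinical lesion photographs and ultrasound scans: a smooth background
intensity field modulated by multiplicative speckle, with one or more
blurred, irregular elliptical foreground lesions at a configurable contrast.
Every sample is a pure function of ``(seed, index)``.

No claim of physical fidelity is made; the generator exists so that every
pipeline stage (loss, metrics, training, CLI) is testable without external
datasets.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml
from PIL import Image
from scipy import ndimage
from skimage import color as skcolor
from skimage.transform import resize as sk_resize

from .errors import ConfigError, ValidationError

__all__ = ["SyntheticConfig", "SegmentationSample", "AugmentConfig",
           "generate_sample", "generate_dataset", "write_dataset",
           "read_dataset", "augment", "rotate_sample"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of the synthetic lesion dataset.

    Defaults mirror the benchmark imaging setups the generator stands in
    for: 256x256 RGB frames, one to three lesions per image with radii
    8-22% of the frame, moderate lesion/background contrast, soft (blurred)
    boundaries and multiplicative speckle.
    """

    n_images: int = 100
    image_size: tuple = (256, 256)
    seed: int = 0
    lesions_per_image: tuple = (1, 3)
    radius_range: tuple = (0.08, 0.22)   # fraction of min(H, W)
    contrast: float = 0.35               # foreground-background gap in [0, 1]
    noise_sigma: float = 0.08            # speckle strength
    blur_sigma: float = 2.0              # boundary softness, px
    channels: int = 3

    def __post_init__(self):
        h, w = self.image_size
        if self.n_images < 0 or h < 8 or w < 8:
            raise ConfigError("n_images must be >= 0 and image_size >= 8x8")
        lo, hi = self.lesions_per_image
        if lo < 0 or hi < lo:
            raise ConfigError(f"invalid lesions_per_image range {lo, hi}")
        rlo, rhi = self.radius_range
        if rlo <= 0 or rhi < rlo:
            raise ConfigError(f"invalid radius_range {self.radius_range}")
        if rlo * min(h, w) < 1.0:
            raise ConfigError("radius_range lower bound is below one pixel")
        if not 0.0 <= self.contrast <= 1.0:
            raise ConfigError(f"contrast must be in [0, 1], got {self.contrast}")
        if self.noise_sigma < 0 or self.blur_sigma < 0:
            raise ConfigError("noise_sigma and blur_sigma must be >= 0")
        if self.channels not in (1, 3):
            raise ConfigError(f"channels must be 1 or 3, got {self.channels}")


@dataclass
class SegmentationSample:
    """A paired 8-bit image and strictly binary mask."""

    image: np.ndarray   # (H, W, channels), uint8
    mask: np.ndarray    # (H, W), uint8 in {0, 1}
    id: str

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValidationError(
                f"image {self.image.shape} and mask {self.mask.shape} disagree")


def _lesion_mask(rng: np.random.Generator, h: int, w: int,
                 radius_range: tuple) -> np.ndarray:
    """Rasterize one irregular ellipse with a low-frequency boundary wobble."""
    m = min(h, w)
    r = rng.uniform(*radius_range) * m
    ecc = rng.uniform(0.6, 1.0)
    theta = rng.uniform(0.0, np.pi)
    # boundary perturbation: few low harmonics, small total amplitude
    amps = rng.uniform(0.0, 0.05, size=4)
    phases = rng.uniform(0.0, 2 * np.pi, size=4)
    reach = r * (1.0 + amps.sum())
    if reach < 0.45 * m:
        cy = rng.uniform(reach, h - reach)
        cx = rng.uniform(reach, w - reach)
    else:  # lesion larger than the frame margin allows; place freely
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    ry = np.cos(theta) * dy - np.sin(theta) * dx
    rx = np.sin(theta) * dy + np.cos(theta) * dx
    rho = np.sqrt((rx / r) ** 2 + (ry / (ecc * r)) ** 2)
    phi = np.arctan2(ry, rx)
    wobble = 1.0 + sum(a * np.cos((k + 2) * phi + p)
                       for k, (a, p) in enumerate(zip(amps, phases)))
    return (rho <= wobble).astype(np.uint8)


def generate_sample(cfg: SyntheticConfig, index: int) -> SegmentationSample:
    """Generate sample ``index``; bit-identical for identical (seed, index)."""
    if not 0 <= index:
        raise ConfigError(f"index must be non-negative, got {index}")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, index]))
    h, w = cfg.image_size
    n_lesions = int(rng.integers(cfg.lesions_per_image[0],
                                 cfg.lesions_per_image[1] + 1))
    mask = np.zeros((h, w), dtype=np.uint8)
    for _ in range(n_lesions):
        mask |= _lesion_mask(rng, h, w, cfg.radius_range)

    # smooth background field in [0.25, 0.55]
    base = ndimage.gaussian_filter(rng.standard_normal((h, w)),
                                   sigma=min(h, w) / 8.0)
    span = base.max() - base.min()
    if span > 0:
        base = 0.25 + 0.30 * (base - base.min()) / span
    else:
        base = np.full((h, w), 0.40)
    clean = base + cfg.contrast * mask
    blurred = ndimage.gaussian_filter(clean, cfg.blur_sigma) \
        if cfg.blur_sigma > 0 else clean

    # multiplicative Rayleigh-like speckle with unit mean
    ray = rng.rayleigh(scale=np.sqrt(2.0 / np.pi), size=(h, w))
    speckle = (1.0 - cfg.noise_sigma) + cfg.noise_sigma * ray
    img = np.clip(blurred * speckle, 0.0, 1.0)

    if cfg.channels == 3:
        gains = rng.uniform(0.95, 1.05, size=3)
        img = np.clip(img[..., None] * gains, 0.0, 1.0)
    else:
        img = img[..., None]
    image = np.round(img * 255.0).astype(np.uint8)
    return SegmentationSample(image=image, mask=mask,
                              id=f"s{cfg.seed}_{index:05d}")


def generate_dataset(cfg: SyntheticConfig) -> list[SegmentationSample]:
    return [generate_sample(cfg, i) for i in range(cfg.n_images)]


def write_dataset(cfg: SyntheticConfig, out_dir) -> list[SegmentationSample]:
    """Write PNG pairs under ``images/`` and ``masks/`` (masks stored 0/255),
    plus the generator config for provenance; returns the samples."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    samples = generate_dataset(cfg)
    for s in samples:
        img = s.image[..., 0] if s.image.shape[-1] == 1 else s.image
        Image.fromarray(img).save(out / "images" / f"{s.id}.png")
        Image.fromarray(s.mask * 255).save(out / "masks" / f"{s.id}.png")
    (out / "generator.yaml").write_text(yaml.safe_dump(asdict(cfg)))
    return samples


def read_dataset(root) -> list[SegmentationSample]:
    """Read PNG pairs written by :func:`write_dataset`.

    Images without a matching mask are skipped with a warning; masks must be
    strictly bilevel (0/255).
    """
    root = Path(root)
    img_dir, mask_dir = root / "images", root / "masks"
    if not img_dir.is_dir() or not mask_dir.is_dir():
        raise ValidationError(f"{root} lacks images/ and masks/ directories")
    samples, missing = [], []
    for img_path in sorted(img_dir.glob("*.png")):
        mask_path = mask_dir / img_path.name
        if not mask_path.exists():
            missing.append(img_path.name)
            continue
        image = np.asarray(Image.open(img_path))
        if image.ndim == 2:
            image = image[..., None]
        raw = np.asarray(Image.open(mask_path))
        if raw.ndim == 3:
            raw = raw[..., 0]
        levels = np.unique(raw)
        if not np.isin(levels, (0, 255)).all():
            raise ValidationError(
                f"mask {mask_path} is not bilevel; found values "
                f"{levels[~np.isin(levels, (0, 255))][:5].tolist()}")
        samples.append(SegmentationSample(
            image=image, mask=(raw > 127).astype(np.uint8),
            id=img_path.stem))
    if missing:
        warnings.warn(f"skipped {len(missing)} image(s) without masks: "
                      f"{missing[:5]}", stacklevel=2)
    return samples


# -- augmentation -----------------------------------------------------

@dataclass(frozen=True)
class AugmentConfig:
    """Maximum magnitudes of the random augmentations (0 / 1.0 = identity)."""

    rotate_deg: float = 0.0     # rotation drawn from [-rotate_deg, rotate_deg]
    brightness: float = 0.0     # multiplicative jitter 1 +/- brightness
    hue: float = 0.0            # hue shift in [-hue, hue] (HSV units)
    crop_scale: float = 1.0     # minimum retained fraction per side

    def __post_init__(self):
        if self.rotate_deg < 0 or self.brightness < 0 or self.hue < 0:
            raise ConfigError("augmentation magnitudes must be >= 0")
        if not 0.1 <= self.crop_scale <= 1.0:
            raise ConfigError(
                f"crop_scale must be in [0.1, 1], got {self.crop_scale}")


def rotate_sample(sample: SegmentationSample,
                  angle_deg: float) -> SegmentationSample:
    """Rotate image and mask jointly; exact array rotation for multiples of
    90 degrees, bilinear (image) / nearest (mask) otherwise."""
    if angle_deg % 360 == 0:
        return sample
    if angle_deg % 90 == 0:
        k = int(angle_deg // 90) % 4
        image = np.ascontiguousarray(np.rot90(sample.image, k))
        mask = np.ascontiguousarray(np.rot90(sample.mask, k))
    else:
        image = ndimage.rotate(sample.image.astype(np.float32), angle_deg,
                               reshape=False, order=1, mode="nearest")
        image = np.clip(np.round(image), 0, 255).astype(np.uint8)
        mask = ndimage.rotate(sample.mask, angle_deg, reshape=False, order=0,
                              mode="constant", cval=0)
    return SegmentationSample(image=image, mask=mask, id=sample.id)


def _crop_resize(sample: SegmentationSample, top: int, left: int, ch: int,
                 cw: int) -> SegmentationSample:
    h, w = sample.mask.shape
    if ch > h or cw > w:
        raise ValidationError(f"crop {ch}x{cw} larger than image {h}x{w}")
    img = sample.image[top:top + ch, left:left + cw]
    msk = sample.mask[top:top + ch, left:left + cw]
    img = sk_resize(img.astype(np.float32), (h, w), order=1,
                    preserve_range=True, anti_aliasing=False)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    msk = sk_resize(msk, (h, w), order=0, preserve_range=True,
                    anti_aliasing=False).astype(np.uint8)
    return SegmentationSample(image=img, mask=msk, id=sample.id)


def augment(sample: SegmentationSample, aug_cfg: AugmentConfig,
            rng: np.random.Generator) -> SegmentationSample:
    """Seeded joint augmentation; the mask stays strictly binary and the
    identity config returns the sample unchanged."""
    out = sample
    if aug_cfg.rotate_deg > 0:
        out = rotate_sample(out, float(rng.uniform(-aug_cfg.rotate_deg,
                                                   aug_cfg.rotate_deg)))
    if aug_cfg.brightness > 0 or aug_cfg.hue > 0:
        img = out.image.astype(np.float32) / 255.0
        if aug_cfg.hue > 0 and img.shape[-1] == 3:
            hsv = skcolor.rgb2hsv(img)
            hsv[..., 0] = (hsv[..., 0]
                           + rng.uniform(-aug_cfg.hue, aug_cfg.hue)) % 1.0
            img = skcolor.hsv2rgb(hsv)
        if aug_cfg.brightness > 0:
            img = img * (1.0 + rng.uniform(-aug_cfg.brightness,
                                           aug_cfg.brightness))
        img = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
        out = SegmentationSample(image=img, mask=out.mask, id=out.id)
    if aug_cfg.crop_scale < 1.0:
        h, w = out.mask.shape
        s = float(rng.uniform(aug_cfg.crop_scale, 1.0))
        ch, cw = max(1, round(h * s)), max(1, round(w * s))
        top = int(rng.integers(0, h - ch + 1))
        left = int(rng.integers(0, w - cw + 1))
        out = _crop_resize(out, top, left, ch, cw)
    return out
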