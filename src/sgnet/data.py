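"""Synthetic dermoscopy generation and ISIC-style dataset I/O.

The generator emulates the canonical challenge cases of dermoscopic lesion
segmentation: low-contrast elliptical lesions with irregular (harmonically
deformed) outlines, boundaries blurred into the surrounding skin, textured
skin background with vignetting, and dark hair strokes drawn over the image
but absent from the mask.  Masks are the *pre-blur* lesion support, so the
blurred boundary is a property of the image only — exactly the ambiguity a
segmentation model must resolve.

Every sample is a pure function of ``(config.seed, index)`` through a
``SeedSequence`` spawn, so datasets are bitwise reproducible.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

IMAGE_EXTENSIONS = (".png", ".jpg", ".jpeg")


@dataclass
class SegSample:
    image: np.ndarray        # (3,H,W) float32 in [0,1]
    mask: np.ndarray         # (1,H,W) uint8 in {0,1}
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.image.shape[1:] != self.mask.shape[1:]:
            raise ValueError("image and mask spatial dims differ")
        vals = np.unique(self.mask)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask must be binary, found values {vals[:5]}")


@dataclass
class SynthConfig:
    n_samples: int = 64
    image_size: int = 256
    lesion_axis_range: tuple = (0.12, 0.40)   # semi-axis, fraction of size
    contrast_delta: float = 0.18              # lesion vs skin intensity gap
    boundary_blur_sigma: float = 2.0          # px
    hair_count_range: tuple = (0, 12)
    hair_thickness_range: tuple = (1, 3)
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.lesion_axis_range
        if not (0 < lo <= hi < 0.5):
            raise ValueError("lesion_axis_range must satisfy 0 < lo <= hi < 0.5")
        if self.contrast_delta <= 0:
            raise ValueError("contrast_delta must be > 0")
        if self.boundary_blur_sigma < 0:
            raise ValueError("boundary_blur_sigma must be >= 0")
        for name in ("hair_count_range", "hair_thickness_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"{name} must be a non-negative (lo, hi) range")
        if self.n_samples < 1 or self.image_size < 32:
            raise ValueError("need n_samples >= 1 and image_size >= 32")


def _lesion_mask(rng: np.random.Generator, size: int,
                 axis_range: tuple) -> tuple[np.ndarray, dict]:
    cx, cy = rng.uniform(0.38, 0.62, 2) * size
    a, b = rng.uniform(axis_range[0], axis_range[1], 2) * size
    theta = rng.uniform(0, np.pi)
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    xr = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
    yr = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
    rho = np.sqrt((xr / a) ** 2 + (yr / b) ** 2)
    phi = np.arctan2(yr, xr)
    # low-frequency radial deformation -> irregular, non-elliptic outline
    boundary = np.ones_like(phi)
    for k in range(2, 6):
        boundary += rng.normal(0, 0.05) * np.cos(k * phi + rng.uniform(0, 2 * np.pi))
    mask = rho <= boundary
    return mask, {"center": (cx, cy), "axes": (a, b), "theta": theta}


def _hair_layer(rng: np.random.Generator, size: int, count_range: tuple,
                thickness_range: tuple) -> np.ndarray:
    """Boolean canvas of dark cubic hair strokes."""
    n = int(rng.integers(count_range[0], count_range[1] + 1))
    canvas = np.zeros((size, size), dtype=bool)
    t = np.linspace(0, 1, 4 * size)[:, None]
    for _ in range(n):
        ctrl = rng.uniform(-0.1 * size, 1.1 * size, (4, 2))
        # cubic Bezier through 4 control points
        pts = ((1 - t) ** 3 * ctrl[0] + 3 * (1 - t) ** 2 * t * ctrl[1]
               + 3 * (1 - t) * t ** 2 * ctrl[2] + t ** 3 * ctrl[3])
        ij = np.round(pts).astype(int)
        keep = ((ij >= 0) & (ij < size)).all(axis=1)
        stroke = np.zeros_like(canvas)
        stroke[ij[keep, 1], ij[keep, 0]] = True
        thick = int(rng.integers(thickness_range[0], thickness_range[1] + 1))
        if thick > 1:
            stroke = ndimage.binary_dilation(stroke, iterations=thick - 1)
        canvas |= stroke
    return canvas


def _texture(rng: np.random.Generator, size: int, sigma: float,
             amplitude: float) -> np.ndarray:
    return amplitude * ndimage.gaussian_filter(
        rng.standard_normal((size, size)), sigma)


def generate_sample(config: SynthConfig, index: int) -> SegSample:
    """Deterministically synthesise one dermoscopy-like image/mask pair."""
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(index,)))
    s = config.image_size

    mask, lesion_meta = _lesion_mask(rng, s, config.lesion_axis_range)

    skin_base = np.array([0.80, 0.62, 0.55]) + rng.uniform(-0.05, 0.05, 3)
    lesion_tint = config.contrast_delta * np.array([1.2, 1.0, 0.8])
    lesion_base = skin_base - lesion_tint

    yy, xx = np.mgrid[0:s, 0:s]
    vignette = 0.08 * (((xx - s / 2) ** 2 + (yy - s / 2) ** 2)
                       / (s / 2) ** 2)
    alpha = mask.astype(np.float64)
    if config.boundary_blur_sigma > 0:
        alpha = ndimage.gaussian_filter(alpha, config.boundary_blur_sigma)

    img = np.empty((3, s, s))
    for c in range(3):
        skin = skin_base[c] + _texture(rng, s, s / 16, 0.03) - vignette
        lesion = lesion_base[c] + _texture(rng, s, s / 24, 0.04)
        img[c] = skin * (1 - alpha) + lesion * alpha

    hair = _hair_layer(rng, s, config.hair_count_range,
                       config.hair_thickness_range)
    if hair.any():
        shade = rng.uniform(0.15, 0.35)
        soft = ndimage.gaussian_filter(hair.astype(np.float64), 0.5)
        soft = np.clip(soft / max(soft.max(), 1e-9), 0, 1)
        img = img * (1 - 0.85 * soft) + shade * 0.85 * soft

    meta = {"seed": config.seed, "index": index, "n_hairs": int(hair.sum() > 0),
            **lesion_meta}
    return SegSample(image=np.clip(img, 0, 1).astype(np.float32),
                     mask=mask[None].astype(np.uint8), meta=meta)


def generate_dataset(config: SynthConfig) -> list[SegSample]:
    return [generate_sample(config, i) for i in range(config.n_samples)]


def augment(sample: SegSample, rng: np.random.Generator | int) -> SegSample:
    """Random horizontal/vertical flips (p=0.5 each) and right-angle rotation,
    applied identically to image and mask.

    Restricted to exact isometries so the mask stays strictly binary and the
    foreground pixel count is invariant.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    img, msk = sample.image, sample.mask
    if rng.random() < 0.5:
        img, msk = np.flip(img, 2), np.flip(msk, 2)
    if rng.random() < 0.5:
        img, msk = np.flip(img, 1), np.flip(msk, 1)
    k = int(rng.integers(0, 4))
    if k:
        img = np.rot90(img, k, axes=(1, 2))
        msk = np.rot90(msk, k, axes=(1, 2))
    return SegSample(image=np.ascontiguousarray(img),
                     mask=np.ascontiguousarray(msk),
                     meta={**sample.meta, "augmented": True})


def to_batch(samples: list[SegSample]) -> tuple[np.ndarray, np.ndarray]:
    images = np.stack([s.image for s in samples]).astype(np.float32)
    masks = np.stack([s.mask for s in samples]).astype(np.float32)
    return images, masks


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def write_sample(sample: SegSample, image_path: str | Path,
                 mask_path: str | Path):
    img = (np.clip(sample.image, 0, 1) * 255).round().astype(np.uint8)
    Image.fromarray(img.transpose(1, 2, 0)).save(image_path)
    Image.fromarray((sample.mask[0] * 255).astype(np.uint8)).save(mask_path)


def read_pair(image_path: Path, mask_path: Path, size: int = 256) -> SegSample:
    img = Image.open(image_path).convert("RGB")
    msk = Image.open(mask_path).convert("L")
    if img.size != (size, size):
        img = img.resize((size, size), Image.BILINEAR)
    if msk.size != (size, size):
        msk = msk.resize((size, size), Image.NEAREST)
    image = np.asarray(img, dtype=np.float32).transpose(2, 0, 1) / 255.0
    mask = (np.asarray(msk) > 127).astype(np.uint8)[None]
    return SegSample(image=image, mask=mask,
                     meta={"source": str(image_path)})


def _find_mask(images_dir_sibling: Path, stem: str) -> Path | None:
    for candidate in (f"{stem}_segmentation.png", f"{stem}.png"):
        p = images_dir_sibling / candidate
        if p.exists():
            return p
    return None


def read_isic_folder(root: str | Path, split: str,
                     size: int = 256) -> list[SegSample]:
    """Read an ISIC-style ``<root>/<split>/{images,masks}`` folder pair.

    Masks pair by filename stem, preferring the ``<stem>_segmentation.png``
    convention.  Unpaired images are skipped with a warning; an empty or
    missing split raises.
    """
    split_dir = Path(root) / split
    images_dir, masks_dir = split_dir / "images", split_dir / "masks"
    if not images_dir.is_dir():
        raise FileNotFoundError(f"no images directory at {images_dir}")
    samples = []
    for img_path in sorted(images_dir.iterdir()):
        if img_path.suffix.lower() not in IMAGE_EXTENSIONS:
            continue
        mask_path = _find_mask(masks_dir, img_path.stem)
        if mask_path is None:
            warnings.warn(f"no mask for {img_path.name}; skipping")
            continue
        samples.append(read_pair(img_path, mask_path, size))
    if not samples:
        raise ValueError(f"split {split!r} at {split_dir} contains no "
                         f"paired image/mask files")
    return samples


def write_synthetic_dataset(config: SynthConfig, out_dir: str | Path) -> Path:
    """Materialise a synthetic dataset as PNG pairs plus a manifest CSV."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with manifest.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["index", "image", "mask", "seed", "foreground_fraction"])
        for i in range(config.n_samples):
            sample = generate_sample(config, i)
            img_name = f"synth_{i:05d}.png"
            msk_name = f"synth_{i:05d}_segmentation.png"
            write_sample(sample, out / "images" / img_name,
                         out / "masks" / msk_name)
            w.writerow([i, img_name, msk_name, config.seed,
                        f"{sample.mask.mean():.5f}"])
    return manifest
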