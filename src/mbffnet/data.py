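"""Image/mask I/O, training-set augmentation, splitting and synthesis.

The synthetic scene generator emulates the geometry of colonoscopy
frames with polyps: a textured background and one or more bright,
soft-edged elliptical blobs, each paired with an exact binary
ground-truth mask.  Ellipse semi-axes are ``r*sqrt(e)`` and
``r/sqrt(e)`` for eccentricity ``e``, so the analytic blob area is
``pi * r^2`` regardless of the sampled eccentricity — which makes the
foreground-fraction statistics of the generator checkable in closed
form.

Augmentation follows the published training recipe: brightness shift,
zoom, horizontal flip, translation, rotation and per-channel intensity
shifts.  All geometric transforms are applied through one shared affine
map to the image (bilinear, reflective border) and the mask (nearest
neighbour, zero border), so mask/image geometric consistency is exact
by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import yaml
from PIL import Image
from scipy import ndimage

__all__ = [
    "SegmentationSample",
    "AugmentationConfig",
    "SyntheticSceneSpec",
    "load_sample",
    "save_sample",
    "augment",
    "split",
    "generate_scene",
    "generate_dataset",
    "write_dataset",
    "load_dataset",
]


@dataclass(frozen=True)
class SegmentationSample:
    """A paired RGB image (HxWx3, values in [0, 1]) and binary mask (HxW)."""

    image: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape[:2]} and mask {self.mask.shape} "
                "spatial dimensions differ"
            )
        if not np.isin(np.unique(self.mask), (0, 1)).all():
            raise ValueError("mask values must be binary {0, 1}")


@dataclass(frozen=True)
class AugmentationConfig:
    """Training-set augmentation ranges.

    Conventions: ``zoom_range`` holds scale factors; ``hflip_prob`` is a
    probability; ``shift_frac`` is the maximum translation as a fraction
    of the image side (sampled uniformly in +-shift_frac, always
    applied); ``rotation_range`` is in radians; ``channel_shift`` is the
    per-channel intensity shift magnitude on the 0-255 scale.
    """

    brightness_range: Tuple[float, float] = (-0.2, 0.2)
    zoom_range: Tuple[float, float] = (0.75, 2.0)
    hflip_prob: float = 0.5
    shift_frac: float = 0.5
    rotation_range: Tuple[float, float] = (-0.5, 0.5)
    channel_shift: float = 10.0

    def __post_init__(self):
        for name in ("brightness_range", "zoom_range", "rotation_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered, got ({lo}, {hi})")
        if not 0.0 <= self.hflip_prob <= 1.0:
            raise ValueError("hflip_prob must be in [0, 1]")

    @classmethod
    def identity(cls) -> "AugmentationConfig":
        return cls((0.0, 0.0), (1.0, 1.0), 0.0, 0.0, (0.0, 0.0), 0.0)


@dataclass(frozen=True)
class SyntheticSceneSpec:
    """Parameters of one synthetic colonoscopy-like scene."""

    side: int = 64
    blob_count: Tuple[int, int] = (1, 3)
    blob_radius: Tuple[float, float] = (0.10, 0.25)  # fraction of side
    blob_eccentricity: Tuple[float, float] = (1.0, 1.5)
    background_intensity: float = 0.35
    foreground_intensity: float = 0.75
    texture_noise_sd: float = 0.05
    edge_softness: float = 1.5  # pixels
    seed: int = 0

    def __post_init__(self):
        if self.side < 32:
            raise ValueError("side must be at least 32")
        lo, hi = self.blob_radius
        if not (0.0 < lo <= hi < 0.5):
            raise ValueError("blob radius range must lie within (0, 0.5)")
        if self.blob_count[0] < 1 or self.blob_count[0] > self.blob_count[1]:
            raise ValueError("blob count range must be ordered and >= 1")

    def to_yaml(self, path=None) -> str:
        payload = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        text = yaml.safe_dump(payload, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "SyntheticSceneSpec":
        p = Path(source)
        payload = yaml.safe_load(p.read_text() if p.exists() else source)
        payload = {
            k: (tuple(v) if isinstance(v, list) else v) for k, v in payload.items()
        }
        return cls(**payload)


# -- I/O ------------------------------------------------------------------

def load_sample(image_path, mask_path, target_size: Optional[int] = None) -> SegmentationSample:
    """Load a PNG/JPEG image + mask pair; scale image to [0, 1], binarise
    the mask at intensity 128, optionally resample to ``target_size``
    (bilinear image, nearest-neighbour mask)."""
    img = Image.open(image_path).convert("RGB")
    msk = Image.open(mask_path).convert("L")
    if img.size != msk.size:
        raise ValueError(
            f"image size {img.size} does not match mask size {msk.size}"
        )
    if target_size is not None:
        img = img.resize((target_size, target_size), Image.BILINEAR)
        msk = msk.resize((target_size, target_size), Image.NEAREST)
    image = np.asarray(img, dtype=np.float32) / 255.0
    mask = (np.asarray(msk) >= 128).astype(np.uint8)
    return SegmentationSample(image=image, mask=mask)


def save_sample(sample: SegmentationSample, image_path, mask_path):
    Image.fromarray(
        np.clip(sample.image * 255.0, 0, 255).astype(np.uint8)
    ).save(image_path)
    Image.fromarray((sample.mask * 255).astype(np.uint8)).save(mask_path)


def write_dataset(samples: Sequence[SegmentationSample], root):
    """``images/*.png`` + ``masks/*.png`` with matching stems."""
    root = Path(root)
    (root / "images").mkdir(parents=True, exist_ok=True)
    (root / "masks").mkdir(parents=True, exist_ok=True)
    for i, s in enumerate(samples):
        save_sample(s, root / "images" / f"scene_{i:04d}.png", root / "masks" / f"scene_{i:04d}.png")


def load_dataset(root, target_size: Optional[int] = None) -> List[SegmentationSample]:
    root = Path(root)
    image_dir, mask_dir = root / "images", root / "masks"
    if not image_dir.is_dir() or not mask_dir.is_dir():
        raise FileNotFoundError(f"expected {root}/images and {root}/masks")
    samples = []
    for ip in sorted(list(image_dir.glob("*.png")) + list(image_dir.glob("*.jpg"))):
        mp = mask_dir / f"{ip.stem}.png"
        if not mp.exists():
            raise FileNotFoundError(f"no mask for {ip.name}")
        samples.append(load_sample(ip, mp, target_size))
    if not samples:
        raise FileNotFoundError(f"no image/mask pairs under {root}")
    return samples


# -- augmentation ---------------------------------------------------------

def _affine_params(cfg: AugmentationConfig, rng: np.random.Generator, side: int):
    zoom = rng.uniform(*cfg.zoom_range) if cfg.zoom_range != (1.0, 1.0) else 1.0
    flip = rng.random() < cfg.hflip_prob
    angle = rng.uniform(*cfg.rotation_range)
    shift = (
        rng.uniform(-cfg.shift_frac, cfg.shift_frac, size=2) * side
        if cfg.shift_frac
        else np.zeros(2)
    )
    return zoom, flip, angle, shift


def augment(
    sample: SegmentationSample, cfg: AugmentationConfig = None, seed: int = 0
) -> SegmentationSample:
    """Apply the full augmentation recipe with a seeded generator.

    Geometric transforms share one affine map between image and mask;
    photometric transforms touch the image only.  The output keeps the
    input's spatial size, the mask stays binary and the image is clipped
    back to [0, 1].
    """
    cfg = cfg or AugmentationConfig()
    rng = np.random.default_rng(seed)
    side = sample.mask.shape[0]
    zoom, flip, angle, shift = _affine_params(cfg, rng, side)

    image, mask = sample.image, sample.mask
    if zoom != 1.0 or flip or angle != 0.0 or shift.any():
        c, s = math.cos(angle), math.sin(angle)
        lin = np.array([[c, -s], [s, c]]) / zoom
        if flip:
            lin = lin @ np.array([[1.0, 0.0], [0.0, -1.0]])
        centre = (np.array(sample.mask.shape, dtype=float) - 1.0) / 2.0
        # ndimage convention: input_coord = lin @ output_coord + offset;
        # rotate/zoom/flip about the image centre, then translate by `shift`
        offset = centre - lin @ centre - shift
        channels = [
            ndimage.affine_transform(
                image[..., ch], lin, offset=offset, order=1, mode="reflect"
            )
            for ch in range(image.shape[2])
        ]
        image = np.stack(channels, axis=-1)
        mask = ndimage.affine_transform(
            mask.astype(np.float32), lin, offset=offset, order=0, mode="constant", cval=0.0
        )
        mask = (mask >= 0.5).astype(np.uint8)

    if cfg.brightness_range != (0.0, 0.0):
        image = image + rng.uniform(*cfg.brightness_range)
    if cfg.channel_shift:
        shifts = rng.uniform(-cfg.channel_shift, cfg.channel_shift, size=3) / 255.0
        image = image + shifts[None, None, :]
    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    return SegmentationSample(image=image, mask=mask)


def split(samples: Sequence, ratio: float = 0.8, seed: int = 0):
    """Disjoint, exhaustive, seeded-shuffle partition; train size =
    round(ratio * n).  1450 samples -> 1160 train / 290 test."""
    n = len(samples)
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(round(ratio * n))
    train = [samples[i] for i in order[:n_train]]
    test = [samples[i] for i in order[n_train:]]
    return train, test


# -- synthesis ------------------------------------------------------------

def _smooth_noise(rng, side, sd, smooth_px=3.0):
    if sd == 0.0:
        return np.zeros((side, side), dtype=np.float32)
    raw = rng.normal(0.0, 1.0, size=(side, side))
    sm = ndimage.gaussian_filter(raw, smooth_px)
    sm_sd = sm.std()
    return (sd * sm / sm_sd).astype(np.float32) if sm_sd > 0 else raw.astype(np.float32) * sd


def generate_scene(spec: SyntheticSceneSpec) -> SegmentationSample:
    """Render one scene, fully determined by ``spec.seed``.

    The mask is the exact union of the ellipse supports; edge softening
    affects the rendered image only.
    """
    rng = np.random.default_rng(spec.seed)
    side = spec.side
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float32)

    mask = np.zeros((side, side), dtype=np.uint8)
    fg_alpha = np.zeros((side, side), dtype=np.float32)
    n_blobs = int(rng.integers(spec.blob_count[0], spec.blob_count[1] + 1))
    for _ in range(n_blobs):
        r = rng.uniform(*spec.blob_radius) * side
        ecc = rng.uniform(*spec.blob_eccentricity)
        a, b = r * math.sqrt(ecc), r / math.sqrt(ecc)  # area = pi * r^2
        margin = max(a, b) / side
        cy, cx = rng.uniform(margin, 1.0 - margin, size=2) * side
        theta = rng.uniform(0.0, math.pi)
        ct, st = math.cos(theta), math.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        # q < 1 inside the ellipse; normalise to an approximate pixel
        # distance for the soft edge
        q = np.sqrt((u / a) ** 2 + (v / b) ** 2)
        mask |= q <= 1.0
        if spec.edge_softness > 0:
            alpha = np.clip((1.0 - q) * min(a, b) / spec.edge_softness + 1.0, 0.0, 1.0)
        else:
            alpha = (q <= 1.0).astype(np.float32)
        fg_alpha = np.maximum(fg_alpha, alpha.astype(np.float32))

    base = spec.background_intensity + (
        spec.foreground_intensity - spec.background_intensity
    ) * fg_alpha
    channel_tint = np.array([0.06, -0.02, -0.04], dtype=np.float32)
    image = np.stack(
        [
            base
            + tint * fg_alpha
            + _smooth_noise(rng, side, spec.texture_noise_sd)
            for tint in channel_tint
        ],
        axis=-1,
    )
    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    return SegmentationSample(image=image, mask=mask.astype(np.uint8))


def generate_dataset(
    spec: SyntheticSceneSpec, n: int, seed: Optional[int] = None
) -> List[SegmentationSample]:
    """``n`` scenes with per-scene seeds derived from ``seed`` (or the
    spec's own seed)."""
    base = spec.seed if seed is None else seed
    ss = np.random.SeedSequence(base)
    child_seeds = ss.generate_state(n) % (2**31 - 1)
    return [generate_scene(replace(spec, seed=int(s))) for s in child_seeds]
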