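"""NIfTI I/O and the volume preprocessing chain.

The chain standardizes a raw (volume, label) pair for episodic learning:

1. clip the brightest intensity tail (default upper 0.5%),
2. resample along the slice axis to a fixed slice count (default 21),
3. crop the in-plane region of interest around the labeled foreground,
4. merge all tumor label levels into one binary foreground class,
5. resize slices to 256x256, min-max normalize to [0, 1], and replicate the
   single modality into 3 channels.

A training-time augmentation applies one random affine transform (rotation,
translation, shear) identically to an image slice and its mask.

Conventions: slice index is axis 0 and 0-based; in-plane indexing is
(row, col); masks use 1 = foreground.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from skimage.transform import AffineTransform, resize, warp

__all__ = [
    "Volume",
    "LabelVolume",
    "SliceStack",
    "AugmentConfig",
    "ALLOWED_LABELS",
    "load_volume",
    "clip_high_intensities",
    "resample_to_slices",
    "crop_roi",
    "binarize_labels",
    "standardize_stack",
    "augment",
    "apply_affine",
    "preprocess_case",
]

ALLOWED_LABELS = frozenset({0, 1, 2, 4})
STANDARD_SIDE = 256
STANDARD_SLICES = 21


@dataclass
class Volume:
    """A raw 3-D scan: (slices, height, width) intensities in arbitrary units."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError("volume must be 3-D with at least one slice")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")


@dataclass
class LabelVolume:
    """Integer labels aligned with a Volume; values restricted to {0, 1, 2, 4}."""

    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        bad = set(np.unique(self.data)) - ALLOWED_LABELS
        if bad:
            raise ValueError(f"label volume contains disallowed value(s): {sorted(bad)}")


@dataclass
class SliceStack:
    """Preprocessed slices ready for the encoder.

    images: (n, 3, 256, 256) in [0, 1], the 3 channels identical per slice;
    masks: (n, 256, 256) binary.
    """

    images: np.ndarray
    masks: np.ndarray
    source_id: str = ""

    def __post_init__(self):
        if self.images.ndim != 4 or self.images.shape[1] != 3:
            raise ValueError("images must be (n, 3, H, W)")
        if self.masks.shape != (self.images.shape[0], *self.images.shape[2:]):
            raise ValueError("masks must align with images")

    @property
    def n_slices(self) -> int:
        return self.images.shape[0]

    def foreground_slices(self) -> np.ndarray:
        """Indices of slices whose mask contains at least one foreground pixel."""
        return np.flatnonzero(self.masks.reshape(self.n_slices, -1).any(axis=1))


def load_volume(image_path: str | Path, label_path: str | Path) -> tuple[Volume, LabelVolume]:
    """Load an aligned NIfTI (scan, label) pair, validating shapes and labels."""
    image_path, label_path = Path(image_path), Path(label_path)
    for p in (image_path, label_path):
        if not p.exists():
            raise FileNotFoundError(f"missing NIfTI file: {p}")
    img = nib.load(image_path)
    lbl = nib.load(label_path)
    data = np.asarray(img.dataobj)
    labels = np.asarray(lbl.dataobj)
    if data.shape != labels.shape:
        raise ValueError(f"shape mismatch: image {data.shape} vs label {labels.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    case_id = image_path.name.split(".")[0]
    return (
        Volume(data=data.astype(np.float32), spacing=spacing, id=case_id),
        LabelVolume(data=labels.astype(np.int16)),
    )


def clip_high_intensities(volume: Volume, fraction: float = 0.005) -> Volume:
    """Replace the brightest ``fraction`` of voxels by the (1-fraction) quantile.

    The threshold is the (k+1)-th largest voxel value with k =
    floor(fraction * n), so for n distinct values exactly k of them are
    clipped. Idempotent.
    """
    if not 0.0 <= fraction < 0.5:
        raise ValueError("fraction must be in [0, 0.5)")
    flat = volume.data.ravel()
    k = int(fraction * flat.size)
    if k == 0:
        return Volume(volume.data.copy(), volume.spacing, volume.id)
    q = np.partition(flat, flat.size - k - 1)[flat.size - k - 1]
    return Volume(np.minimum(volume.data, q), volume.spacing, volume.id)


def resample_to_slices(
    volume: Volume, label: LabelVolume, n_slices: int = STANDARD_SLICES
) -> tuple[Volume, LabelVolume]:
    """Resample along the slice axis to exactly ``n_slices`` slices.

    Intensities are linearly interpolated between neighbouring slices; labels
    take the nearest slice so their value set is preserved. In-plane
    resolution is untouched. Identity when the count already matches.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    n_in = volume.data.shape[0]
    if n_in == n_slices:
        return Volume(volume.data.copy(), volume.spacing, volume.id), LabelVolume(
            label.data.copy()
        )
    pos = np.linspace(0.0, n_in - 1.0, n_slices)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    w = (pos - lo)[:, None, None]
    data = (1.0 - w) * volume.data[lo] + w * volume.data[hi]
    labels = label.data[np.round(pos).astype(int)]
    sz = volume.spacing[0] * (n_in - 1) / max(n_slices - 1, 1)
    return (
        Volume(data.astype(volume.data.dtype), (sz, *volume.spacing[1:]), volume.id),
        LabelVolume(labels),
    )


def crop_roi(
    volume: Volume, label: LabelVolume, margin: int = 8
) -> tuple[Volume, LabelVolume]:
    """Crop in-plane to the bounding box of the labeled foreground plus margin.

    The box is computed over all slices and clamped to the grid; every nonzero
    label voxel is retained and all slices are kept.
    """
    fg = label.data > 0
    if not fg.any():
        raise ValueError("cannot crop ROI: label volume has no foreground")
    rows = np.flatnonzero(fg.any(axis=(0, 2)))
    cols = np.flatnonzero(fg.any(axis=(0, 1)))
    r0 = max(rows[0] - margin, 0)
    r1 = min(rows[-1] + margin + 1, volume.data.shape[1])
    c0 = max(cols[0] - margin, 0)
    c1 = min(cols[-1] + margin + 1, volume.data.shape[2])
    return (
        Volume(volume.data[:, r0:r1, c0:c1], volume.spacing, volume.id),
        LabelVolume(label.data[:, r0:r1, c0:c1]),
    )


def binarize_labels(label: LabelVolume) -> np.ndarray:
    """Merge all tumor levels {1, 2, 4} into a single binary foreground class."""
    return (label.data > 0).astype(np.uint8)


def standardize_stack(volume: Volume, mask: np.ndarray) -> SliceStack:
    """Resize to 256x256, min-max normalize to [0, 1], replicate 3 channels.

    Normalization uses the volume-wide intensity range so slices stay
    mutually calibrated: a slice without tumor keeps the same brain-tissue
    level it has elsewhere in the scan instead of being stretched to full
    brightness. Images are resized bilinearly; masks with nearest-neighbour
    so they stay binary. A constant volume (zero range) normalizes to
    all-zeros.
    """
    if volume.data.shape != mask.shape:
        raise ValueError("volume and mask must be aligned")
    n = volume.data.shape[0]
    side = STANDARD_SIDE
    vmin = float(volume.data.min())
    vrange = float(volume.data.max()) - vmin
    images = np.empty((n, 3, side, side), dtype=np.float64)
    masks = np.empty((n, side, side), dtype=np.uint8)
    for k in range(n):
        sl = resize(
            volume.data[k].astype(np.float64),
            (side, side),
            order=1,
            preserve_range=True,
            anti_aliasing=False,
        )
        sl = np.clip((sl - vmin) / vrange, 0.0, 1.0) if vrange > 0 else np.zeros_like(sl)
        images[k] = sl[None, :, :]
        masks[k] = (
            resize(
                mask[k].astype(np.float64),
                (side, side),
                order=0,
                preserve_range=True,
                anti_aliasing=False,
            )
            > 0.5
        ).astype(np.uint8)
    return SliceStack(images=images, masks=masks, source_id=volume.id)


@dataclass(frozen=True)
class AugmentConfig:
    """Bounds for the random per-slice affine transform."""

    max_rotation_deg: float = 15.0
    max_translation_px: float = 10.0
    max_shear_deg: float = 10.0
    probability: float = 0.5


def apply_affine(
    image: np.ndarray,
    mask: np.ndarray,
    rotation_deg: float = 0.0,
    translation_px: tuple[float, float] = (0.0, 0.0),
    shear_deg: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one affine transform (about the image center) to an image slice
    and, identically, to its mask; the mask is warped nearest-neighbour and
    re-binarized."""
    h, w = mask.shape
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])  # (x, y)
    tf = (
        AffineTransform(translation=-center)
        + AffineTransform(
            rotation=np.deg2rad(rotation_deg),
            shear=np.deg2rad(shear_deg),
        )
        + AffineTransform(translation=center)
        + AffineTransform(translation=translation_px)
    )
    chans = image if image.ndim == 3 else image[None]
    out = np.stack(
        [warp(c, tf.inverse, order=1, preserve_range=True) for c in chans]
    )
    if image.ndim == 2:
        out = out[0]
    m = warp(mask.astype(np.float64), tf.inverse, order=0, preserve_range=True)
    return out, (m > 0.5).astype(mask.dtype)


def augment(
    images: np.ndarray,
    masks: np.ndarray,
    rng: np.random.Generator,
    config: AugmentConfig = AugmentConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Randomly transform slices in place of the originals (no duplication).

    Each slice is transformed with probability ``config.probability`` by a
    rotation, translation and shear drawn uniformly within the bounds.
    """
    if images.shape[0] != masks.shape[0]:
        raise ValueError("images and masks must be paired")
    images = images.copy()
    masks = masks.copy()
    for k in range(images.shape[0]):
        if rng.uniform() >= config.probability:
            continue
        rot = rng.uniform(-config.max_rotation_deg, config.max_rotation_deg)
        tx, ty = rng.uniform(
            -config.max_translation_px, config.max_translation_px, size=2
        )
        shear = rng.uniform(-config.max_shear_deg, config.max_shear_deg)
        images[k], masks[k] = apply_affine(
            images[k], masks[k], rotation_deg=rot, translation_px=(tx, ty), shear_deg=shear
        )
    return images, masks


def preprocess_case(
    volume: Volume,
    label: LabelVolume,
    clip_fraction: float = 0.005,
    n_slices: int = STANDARD_SLICES,
    margin: int = 8,
) -> SliceStack:
    """Full chain: clip -> resample -> crop ROI -> binarize -> standardize."""
    vol = clip_high_intensities(volume, clip_fraction)
    vol, lab = resample_to_slices(vol, label, n_slices)
    vol, lab = crop_roi(vol, lab, margin)
    mask = binarize_labels(lab)
    return standardize_stack(vol, mask)
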