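"""Synthetic MRI-like volume generator.

Emulates T2-weighted brain-tumor scans at desk scale: a brain-shaped bright
ellipsoid on a dark field, containing a smaller, brighter, heterogeneous
"tumor" ellipsoid whose size, location and intensity vary per case. Labels
follow the BraTS convention — integer levels drawn from {1, 2, 4}, nested
concentrically (4 innermost, 2 outermost) so that downstream label-merging
into one binary foreground class is exercised.

Every case is fully determined by its seed; files are written as NIfTI pairs
with a JSON manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .preprocess import LabelVolume, Volume

__all__ = ["SynthConfig", "generate_case", "generate_dataset"]

#: nesting order of BraTS-style label levels, outermost first
_LABEL_LEVELS = (2, 1, 4)


@dataclass(frozen=True)
class SynthConfig:
    """Conditions of the synthetic study.

    Defaults emulate the source data: ~150 slices per scan, a small bright
    tumor (a few percent of the volume) on a darker brain background, with
    additive Gaussian noise. Intensities are arbitrary units, clipped at 0.
    """

    n_slices: int = 150
    grid: tuple[int, int] = (240, 240)
    tumor_radius_range: tuple[float, float] = (0.08, 0.18)  # fraction of grid side
    tumor_intensity: tuple[float, float] = (180.0, 20.0)  # mean, sd across cases
    background_intensity: tuple[float, float] = (80.0, 15.0)
    noise_sd: float = 10.0
    n_label_levels: int = 3
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.tumor_radius_range
        if not (0.0 < lo <= hi < 0.5):
            raise ValueError("tumor_radius_range must lie within (0, 0.5)")
        if self.n_slices < 3:
            raise ValueError("n_slices must be >= 3")
        if min(self.grid) < 32:
            raise ValueError("grid must be at least 32 voxels per side")
        if self.n_label_levels not in (1, 2, 3):
            raise ValueError("n_label_levels must be in {1, 2, 3}")
        if self.tumor_intensity[1] < 0 or self.background_intensity[1] < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d = (
        ((zz - center[0]) / radii[0]) ** 2
        + ((yy - center[1]) / radii[1]) ** 2
        + ((xx - center[2]) / radii[2]) ** 2
    )
    return d <= 1.0


def generate_case(config: SynthConfig, seed: int) -> tuple[Volume, LabelVolume]:
    """Generate one (volume, label) pair, deterministic in ``seed``.

    The foreground is an axis-aligned ellipsoid jittered in center and radii,
    guaranteed to intersect at least 3 slices; label levels are concentric
    shells of the tumor ellipsoid.
    """
    rng = np.random.default_rng(seed)
    ns, (h, w) = config.n_slices, config.grid
    shape = (ns, h, w)

    # brain: a large ellipsoid filling most of the grid
    brain = _ellipsoid_mask(
        shape,
        center=(ns / 2, h / 2, w / 2),
        radii=(ns * 0.48, h * 0.42, w * 0.42),
    )

    # tumor: jittered center within the inner half of the brain, jittered radii
    lo, hi = config.tumor_radius_range
    frac = rng.uniform(lo, hi, size=3)
    radii = np.array([max(frac[0] * ns, 1.5), frac[1] * h, frac[2] * w])
    center = np.array(
        [
            ns / 2 + rng.uniform(-0.2, 0.2) * ns,
            h / 2 + rng.uniform(-0.18, 0.18) * h,
            w / 2 + rng.uniform(-0.18, 0.18) * w,
        ]
    )
    tumor = _ellipsoid_mask(shape, center, radii) & brain

    # concentric label shells: outermost level 2, then 1, innermost 4
    levels = _LABEL_LEVELS[-config.n_label_levels :]
    label = np.zeros(shape, dtype=np.int16)
    n = len(levels)
    for k, lv in enumerate(levels):
        shell = _ellipsoid_mask(shape, center, radii * (1.0 - k / n)) & brain
        label[shell] = lv

    bg_mean = rng.normal(config.background_intensity[0], config.background_intensity[1])
    tum_mean = rng.normal(config.tumor_intensity[0], config.tumor_intensity[1])
    data = np.zeros(shape)
    data[brain] = bg_mean
    data[tumor] = tum_mean
    data += rng.normal(0.0, config.noise_sd, size=shape)
    data = np.clip(data, 0.0, None).astype(np.float32)

    case_id = f"synth-{seed:08d}"
    return Volume(data=data, spacing=(1.0, 1.0, 1.0), id=case_id), LabelVolume(data=label)


def generate_dataset(
    n_cases: int,
    config: SynthConfig,
    seed: int,
    out_dir: str | Path,
    overwrite: bool = False,
) -> dict:
    """Write ``n_cases`` NIfTI pairs plus a JSON manifest; returns the manifest.

    Per-case seeds are derived deterministically from ``seed`` and are distinct.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{out_dir} already holds a dataset (pass overwrite=True)")
    out_dir.mkdir(parents=True, exist_ok=True)

    entries = []
    for i in range(n_cases):
        case_seed = int((seed * 100003 + i) % (2**31 - 1))
        vol, lab = generate_case(config, case_seed)
        img_path = out_dir / f"{vol.id}_t2.nii"
        lbl_path = out_dir / f"{vol.id}_seg.nii"
        affine = np.diag(list(vol.spacing) + [1.0])
        nib.save(nib.Nifti1Image(vol.data, affine), img_path)
        nib.save(nib.Nifti1Image(lab.data, affine), lbl_path)
        entries.append(
            {
                "case_id": vol.id,
                "image": img_path.name,
                "label": lbl_path.name,
                "seed": case_seed,
            }
        )

    manifest = {"n_cases": n_cases, "seed": seed, "cases": entries}
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
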