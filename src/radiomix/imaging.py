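"""Volume containers, resampling, SUV conversion and gray-level discretization.

The pipeline works on per-tumor 3-D volumes (PET in activity-concentration
units convertible to SUV; first post-contrast DCE-MR in arbitrary units) with
aligned binary tumor masks. Images are resampled to isotropic voxels (2.0 mm
for PET, 0.5 mm for MR by default), PET is converted to standardized uptake
value, and masked intensities are discretized with a fixed bin width before
texture analysis.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Modality",
    "Units",
    "Image3D",
    "Mask3D",
    "DiscretizedImage",
    "resample_isotropic",
    "to_suv",
    "discretize",
    "load_nifti_image",
    "load_nifti_mask",
    "save_nifti",
    "F18_HALF_LIFE_MIN",
    "DEFAULT_TARGET_SPACING",
    "DEFAULT_BIN_WIDTH",
]

#: Physical half-life of fluorine-18 in minutes.
F18_HALF_LIFE_MIN = 109.77

#: Default isotropic target spacing (mm) per modality.
DEFAULT_TARGET_SPACING = {"PET": 2.0, "MR": 0.5}

#: Default fixed intensity bin width per modality (SUV for PET, a.u. for MR).
DEFAULT_BIN_WIDTH = {"PET": 0.1, "MR": 5.0}


class Modality(str, enum.Enum):
    PET = "PET"
    MR = "MR"


class Units(str, enum.Enum):
    ACTIVITY_CONC_KBQ_PER_ML = "activity_conc_kBq_per_ml"
    SUV = "SUV"
    ARBITRARY = "arbitrary"


@dataclass(frozen=True)
class Image3D:
    """A scalar 3-D grid with per-axis voxel spacing in millimetres."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    modality: Modality
    units: Units

    def __post_init__(self):
        v = np.asarray(self.voxels, dtype=np.float64)
        if v.ndim != 3 or v.size == 0:
            raise ValueError("image grid must be non-empty and 3-D")
        if not np.all(np.isfinite(v)):
            raise ValueError("image contains non-finite values")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError("spacing must be three positive components")
        object.__setattr__(self, "voxels", v)
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "modality", Modality(self.modality))
        object.__setattr__(self, "units", Units(self.units))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass(frozen=True)
class Mask3D:
    """A binary 3-D grid delimiting the tumor region, aligned to its image."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        v = np.asarray(self.voxels).astype(bool)
        if v.ndim != 3 or v.size == 0:
            raise ValueError("mask grid must be non-empty and 3-D")
        if not v.any():
            raise ValueError("mask has no foreground voxels")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError("spacing must be three positive components")
        object.__setattr__(self, "voxels", v)
        object.__setattr__(self, "spacing", sp)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def check_aligned(self, image: Image3D) -> None:
        if self.shape != image.shape or not np.allclose(self.spacing, image.spacing):
            raise ValueError("mask grid/spacing does not match its image")


@dataclass(frozen=True)
class DiscretizedImage:
    """Integer gray levels 1..Ng inside the mask, 0 outside."""

    levels: np.ndarray
    n_levels: int
    bin_width: float
    anchor: float
    spacing: tuple[float, float, float] = field(default=(1.0, 1.0, 1.0))

    def __post_init__(self):
        lv = np.asarray(self.levels, dtype=np.int64)
        object.__setattr__(self, "levels", lv)
        inside = lv[lv > 0]
        if inside.size == 0:
            raise ValueError("discretized image has no masked voxels")
        if int(inside.max()) != self.n_levels:
            raise ValueError("n_levels must equal the maximum masked level")


def _output_length(n: int, src: float, dst: float) -> int:
    # last output voxel center stays inside the input domain (no extrapolation)
    return max(1, int(np.floor((n - 1) * src / dst + 1e-9)) + 1)


def resample_isotropic(
    image: Image3D, mask: Mask3D, target_spacing: float, tumor_id: str | None = None
) -> tuple[Image3D, Mask3D]:
    """Resample an image/mask pair onto an isotropic voxel grid.

    Voxel centers are corner-anchored: output center ``j`` sits at physical
    position ``j * target_spacing`` along each axis. The image is interpolated
    linearly, the mask by nearest neighbor so it stays binary.

    Raises ``ValueError`` if the resampled mask is empty (naming ``tumor_id``
    when given).
    """
    t = float(target_spacing)
    if t <= 0:
        raise ValueError("target_spacing must be positive")
    mask.check_aligned(image)
    if all(abs(s - t) < 1e-12 for s in image.spacing):
        return image, mask

    shape = image.shape
    out_shape = tuple(_output_length(n, s, t) for n, s in zip(shape, image.spacing))
    axes = [np.arange(n) * t / s for n, s in zip(out_shape, image.spacing)]
    coords = np.meshgrid(*axes, indexing="ij")
    vox = ndimage.map_coordinates(image.voxels, coords, order=1, mode="nearest")
    mvox = ndimage.map_coordinates(
        mask.voxels.astype(np.uint8), coords, order=0, mode="nearest"
    ).astype(bool)
    if not mvox.any():
        who = f" for tumor {tumor_id!r}" if tumor_id else ""
        raise ValueError(f"mask became empty after resampling to {t} mm{who}")
    new_img = Image3D(vox, (t, t, t), image.modality, image.units)
    return new_img, Mask3D(mvox, (t, t, t))


def to_suv(
    image: Image3D,
    body_weight_g: float,
    injected_activity_kBq: float,
    injection_to_scan_min: float = 0.0,
    half_life_min: float = F18_HALF_LIFE_MIN,
) -> Image3D:
    """Convert a PET activity-concentration image (kBq/ml) to SUV.

    SUV(v) = C(v) * body_weight_g / (A_inj * 2^(-t/T_half)), i.e. the tracer
    concentration normalized by body weight and the injected activity decayed
    to scan time. Pass ``injection_to_scan_min=0`` if the activity is already
    decay-corrected.
    """
    if image.units is not Units.ACTIVITY_CONC_KBQ_PER_ML:
        raise ValueError("to_suv expects an image in activity concentration units")
    if body_weight_g <= 0 or injected_activity_kBq <= 0:
        raise ValueError("body weight and injected activity must be positive")
    decayed = injected_activity_kBq * 2.0 ** (-injection_to_scan_min / half_life_min)
    suv = image.voxels * (body_weight_g / decayed)
    return replace(image, voxels=suv, units=Units.SUV)


def discretize(image: Image3D, mask: Mask3D, bin_width: float) -> DiscretizedImage:
    """Discretize masked intensities into fixed-width bins.

    level(v) = floor((I(v) - min_masked) / bin_width) + 1 for masked voxels;
    0 outside the mask. A constant region is valid and yields a single level.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    mask.check_aligned(image)
    m = mask.voxels
    vals = image.voxels[m]
    anchor = float(vals.min())
    levels = np.zeros(image.shape, dtype=np.int64)
    # small epsilon guards values sitting exactly on a bin edge after float noise
    idx = np.floor((vals - anchor) / bin_width + 1e-9).astype(np.int64) + 1
    levels[m] = idx
    return DiscretizedImage(
        levels=levels,
        n_levels=int(idx.max()),
        bin_width=float(bin_width),
        anchor=anchor,
        spacing=image.spacing,
    )


# ---------------------------------------------------------------------------
# NIfTI I/O


def _spacing_from(img: nib.Nifti1Image) -> tuple[float, float, float]:
    z = img.header.get_zooms()[:3]
    return tuple(float(s) for s in z)


def load_nifti_image(path, modality: Modality | str, units: Units | str) -> Image3D:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    return Image3D(data, _spacing_from(img), Modality(modality), Units(units))


def load_nifti_mask(path) -> Mask3D:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata()) > 0.5
    return Mask3D(data, _spacing_from(img))


def save_nifti(path, voxels: np.ndarray, spacing) -> None:
    affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    nib.save(nib.Nifti1Image(np.asarray(voxels, dtype=np.float32), affine), str(path))
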