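"""Synthetic PET/MR tumor cohorts with known ground truth.

Because the study cohort's images are private, every pipeline stage is
exercised on generated data: ellipsoidal tumor masks rasterized at each
modality's voxel spacing, filled with a group-dependent mean intensity plus a
Gaussian random field (Gaussian-smoothed white noise, so the per-group
correlation length directly controls GLCM texture) plus white measurement
noise. Latent tumor groups differ in uptake level, texture correlation
length, and size; clinical outcomes (grade, stages, subtype, recurrence and
the 1-5-year recurrence-free labels) are sampled conditionally on the latent
group or on named true features, so association and recovery tests have a
known answer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .imaging import Image3D, Mask3D, Modality, Units, save_nifti

__all__ = ["GroupParams", "CohortSpec", "generate_tumor_volume", "generate_cohort"]

#: SUV = C * body_weight / injected_activity with these manifest constants,
#: so stored PET activity is SUV / SUV_FACTOR.
BODY_WEIGHT_G = 70_000.0
INJECTED_KBQ = 350_000.0
SUV_FACTOR = BODY_WEIGHT_G / INJECTED_KBQ  # 0.2


@dataclass(frozen=True)
class GroupParams:
    """Generative parameters of one latent tumor group."""

    suv_mean: float
    suv_sd: float
    mr_mean: float
    mr_sd: float
    corr_length_vox: float  # Gaussian-field smoothing sigma, in voxels
    semi_axes_mm: tuple[float, float, float]
    grade_probs: tuple[float, float, float]  # grades 1..3
    subtype_probs: tuple[float, float, float, float]
    stage_probs: tuple[float, float, float, float]  # overall stage 0..3


_DEFAULT_GROUPS = (
    GroupParams(2.0, 0.40, 150.0, 18.0, 0.5, (9.0, 8.0, 7.0),
                (0.60, 0.35, 0.05), (0.55, 0.20, 0.15, 0.10), (0.45, 0.35, 0.15, 0.05)),
    GroupParams(4.5, 0.60, 250.0, 28.0, 1.2, (12.0, 10.0, 8.5),
                (0.15, 0.60, 0.25), (0.35, 0.25, 0.20, 0.20), (0.25, 0.40, 0.25, 0.10)),
    GroupParams(8.0, 0.85, 380.0, 40.0, 2.4, (14.0, 12.0, 10.0),
                (0.05, 0.35, 0.60), (0.15, 0.20, 0.25, 0.40), (0.10, 0.30, 0.35, 0.25)),
)

SUBTYPES = ("HR+/HER2-", "HR+/HER2+", "HR-/HER2+", "HR-/HER2-")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level generator settings (all randomness flows from ``seed``)."""

    n_tumors: int = 90
    groups: tuple[GroupParams, ...] = _DEFAULT_GROUPS
    group_proportions: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    pet_spacing: float = 2.0
    mr_spacing: float = 0.5
    pet_noise_sd: float = 0.15  # SUV units of white measurement noise
    mr_noise_sd: float = 8.0
    axis_jitter: float = 0.12  # relative jitter on ellipsoid semi-axes
    # logistic recurrence model on named true features (z-scored cohort-wide)
    rfs_intercept: float = -1.3
    rfs_coef_suv: float = 1.1
    rfs_coef_corrlen: float = 0.5
    never_disease_free_prob: float = 0.06
    seed: int = 0

    def __post_init__(self):
        if len(self.groups) != len(self.group_proportions):
            raise ValueError("one proportion per group required")
        if abs(sum(self.group_proportions) - 1.0) > 1e-9:
            raise ValueError("group proportions must sum to 1")
        if self.n_tumors < len(self.groups):
            raise ValueError("need at least one tumor per group")


def _gaussian_random_field(shape, sigma_vox: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance field with Gaussian autocorrelation of scale sigma_vox."""
    white = rng.standard_normal(shape)
    if sigma_vox <= 0:
        return white
    smooth = gaussian_filter(white, sigma=sigma_vox, mode="wrap")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def _ellipsoid_mask(semi_axes_mm, spacing: float, margin: int = 3) -> np.ndarray:
    half = [int(np.ceil(a / spacing)) + margin for a in semi_axes_mm]
    axes = [np.arange(-h, h + 1) * spacing for h in half]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    a, b, c = semi_axes_mm
    return (xx / a) ** 2 + (yy / b) ** 2 + (zz / c) ** 2 <= 1.0


def generate_tumor_volume(
    group: GroupParams, seed: int, spec: CohortSpec | None = None, jitter: bool = True
) -> tuple[Image3D, Mask3D, Image3D, Mask3D]:
    """One tumor's PET (activity units) and MR volumes with aligned masks.

    The PET volume stores activity concentration such that SUV conversion
    with the manifest's body weight / injected activity recovers the group's
    SUV statistics. Reproducible for a fixed seed.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(seed)
    axes = np.asarray(group.semi_axes_mm, dtype=float)
    if jitter and spec.axis_jitter > 0:
        axes = axes * (1.0 + rng.uniform(-spec.axis_jitter, spec.axis_jitter, size=3))
    out = []
    for modality, spacing, mean, sd, noise_sd in (
        (Modality.PET, spec.pet_spacing, group.suv_mean, group.suv_sd, spec.pet_noise_sd),
        (Modality.MR, spec.mr_spacing, group.mr_mean, group.mr_sd, spec.mr_noise_sd),
    ):
        if min(axes) < spacing:
            raise ValueError(
                f"semi-axes {tuple(axes)} smaller than one {modality.value} voxel "
                f"({spacing} mm)"
            )
        mvox = _ellipsoid_mask(axes, spacing)
        sigma = group.corr_length_vox * (spec.pet_spacing / spacing if modality is Modality.MR else 1.0)
        field_ = _gaussian_random_field(mvox.shape, sigma, rng)
        vox = mean + sd * field_ + noise_sd * rng.standard_normal(mvox.shape)
        if modality is Modality.PET:
            vox = np.clip(vox, 0.01, None) / SUV_FACTOR  # store as kBq/ml
            units = Units.ACTIVITY_CONC_KBQ_PER_ML
        else:
            vox = np.clip(vox, 0.0, None)
            units = Units.ARBITRARY
        sp = (spacing,) * 3
        out.append(Image3D(vox, sp, modality, units))
        out.append(Mask3D(mvox, sp))
    return tuple(out)  # pet, pet_mask, mr, mr_mask


def _group_assignment(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    counts = np.floor(np.asarray(spec.group_proportions) * spec.n_tumors).astype(int)
    while counts.sum() < spec.n_tumors:
        counts[int(np.argmax(np.asarray(spec.group_proportions) * spec.n_tumors - counts))] += 1
    groups = np.repeat(np.arange(len(spec.groups)), counts)
    rng.shuffle(groups)
    return groups


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def generate_cohort(
    spec: CohortSpec, out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict, dict]:
    """Generate a full cohort: volumes, manifest, clinical table, truth record.

    Returns ``(manifest, clinical, truth, volumes)`` where ``volumes`` maps
    tumor_id -> (pet, pet_mask, mr, mr_mask) in memory. When ``out_dir`` is
    given, NIfTI volumes plus ``manifest.csv``, ``clinical.csv`` and
    ``truth.json`` are also written there and the manifest paths point at the
    files.
    """
    rng = np.random.default_rng(spec.seed)
    groups = _group_assignment(spec, rng)
    n = spec.n_tumors

    volumes = {}
    manifest_rows = []
    suv_true = np.array([spec.groups[g].suv_mean for g in groups])
    corr_true = np.array([spec.groups[g].corr_length_vox for g in groups])
    for i in range(n):
        tid = f"T{i:03d}"
        vol_seed = int(rng.integers(2**31 - 1))
        volumes[tid] = generate_tumor_volume(spec.groups[groups[i]], vol_seed, spec)
        manifest_rows.append(
            {
                "tumor_id": tid,
                "pet_path": "",
                "pet_mask_path": "",
                "mr_path": "",
                "mr_mask_path": "",
                "body_weight_g": BODY_WEIGHT_G,
                "injected_activity_kBq": INJECTED_KBQ,
                "delay_min": 0.0,
            }
        )
    manifest = pd.DataFrame(manifest_rows)

    # clinical outcomes coupled to the latent groups / true features
    grade = np.array(
        [1 + rng.choice(3, p=spec.groups[g].grade_probs) for g in groups]
    )
    subtype = np.array(
        [SUBTYPES[rng.choice(4, p=spec.groups[g].subtype_probs)] for g in groups]
    )
    overall_stage = np.array(
        [rng.choice(4, p=spec.groups[g].stage_probs) for g in groups]
    )
    t_stage = np.clip(overall_stage + rng.integers(-1, 2, size=n), 0, 3)
    n_stage = np.clip(overall_stage - 1 + rng.integers(0, 2, size=n), 0, 3)

    eta = (
        spec.rfs_intercept
        + spec.rfs_coef_suv * _zscore(suv_true)
        + spec.rfs_coef_corrlen * _zscore(corr_true)
    )
    p_rec = 1.0 / (1.0 + np.exp(-eta))
    recurs = rng.random(n) < p_rec
    rec_time = np.where(recurs, rng.uniform(0.25, 5.75, size=n), np.nan)
    never_free = rng.random(n) < spec.never_disease_free_prob

    status = np.where(never_free, "never disease free",
                      np.where(recurs, "recur", "no recurrence"))
    site = np.where(
        ~recurs | never_free,
        "no recurrence",
        np.where(rng.random(n) < 0.15, "local recurrence", "distant recurrence"),
    )
    clinical = pd.DataFrame(
        {
            "tumor_id": manifest["tumor_id"],
            "grade": grade,
            "histology": np.where(rng.random(n) < 0.88, "IDC", "ILC"),
            "t_stage": t_stage,
            "n_stage": n_stage,
            "overall_stage": overall_stage,
            "subtype": subtype,
            "recurrence_status": status,
            "recurrence_site": site,
            "recurrence_years": rec_time,
        }
    ).set_index("tumor_id")
    for y in range(1, 6):
        free = np.where(
            never_free, 0, np.where(recurs & (rec_time <= y), 0, 1)
        )
        clinical[f"rfs_free_at_{y}"] = free

    for col in ("grade", "rfs_free_at_1"):
        if clinical[col].nunique() < 2:
            raise ValueError(f"degenerate outcome coupling: {col} has a single level")

    truth = {
        "group_labels": {tid: int(g) for tid, g in zip(manifest["tumor_id"], groups)},
        "suv_mean_true": {tid: float(v) for tid, v in zip(manifest["tumor_id"], suv_true)},
        "corr_length_true": {tid: float(v) for tid, v in zip(manifest["tumor_id"], corr_true)},
        "p_recurrence": {tid: float(v) for tid, v in zip(manifest["tumor_id"], p_rec)},
        "spec": {
            k: v for k, v in asdict(spec).items() if not isinstance(v, tuple) or k == "group_proportions"
        },
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, tid in enumerate(manifest["tumor_id"]):
            pet, pet_mask, mr, mr_mask = volumes[tid]
            paths = {
                "pet_path": out / f"{tid}_pet.nii.gz",
                "pet_mask_path": out / f"{tid}_pet_mask.nii.gz",
                "mr_path": out / f"{tid}_mr.nii.gz",
                "mr_mask_path": out / f"{tid}_mr_mask.nii.gz",
            }
            save_nifti(paths["pet_path"], pet.voxels, pet.spacing)
            save_nifti(paths["pet_mask_path"], pet_mask.voxels.astype(np.uint8), pet_mask.spacing)
            save_nifti(paths["mr_path"], mr.voxels, mr.spacing)
            save_nifti(paths["mr_mask_path"], mr_mask.voxels.astype(np.uint8), mr_mask.spacing)
            for col, p in paths.items():
                manifest.loc[i, col] = str(p)
        manifest.to_csv(out / "manifest.csv", index=False)
        clinical.to_csv(out / "clinical.csv")
        (out / "truth.json").write_text(json.dumps(truth, indent=2))

    return manifest, clinical, truth, volumes
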