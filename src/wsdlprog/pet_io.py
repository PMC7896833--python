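"""Volume I/O, ROI preparation, and conventional PET metrics.

Reads and writes co-registered PET (SUV-valued), CT, and binary lesion-mask
volumes as NIfTI; crops a fixed physical cube around the lesion and resamples
it into the 2-channel tensor the network consumes; and computes the standard
metabolic metrics (SUVmax, SUVmean, MTV, TLG) from the mask.

Conventions: voxel indices are 0-based, crop windows are half-open in index
space, and world coordinates come from the NIfTI affine.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "PatientVolume",
    "RoiTensor",
    "PetMetrics",
    "read_patient",
    "write_patient",
    "crop_resample",
    "compute_pet_metrics",
    "metrics_table",
]


@dataclass
class PatientVolume:
    """One patient's co-registered PET/CT grids with lesion mask."""

    patient_id: str
    pet: np.ndarray      # SUV, >= 0
    ct: np.ndarray       # attenuation-like intensity
    mask: np.ndarray     # binary
    spacing: tuple[float, float, float]  # mm per axis

    def __post_init__(self) -> None:
        if not (self.pet.shape == self.ct.shape == self.mask.shape):
            raise ValueError(
                f"PET/CT/mask shapes differ for {self.patient_id}: "
                f"{self.pet.shape} vs {self.ct.shape} vs {self.mask.shape}"
            )

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0


@dataclass
class RoiTensor:
    """Fixed-size 2-channel (PET, CT) tensor fed to the network."""

    patient_id: str
    data: np.ndarray                      # (side, side, side, channels)
    source_bbox: tuple                    # world-mm window actually sampled
    normalization_params: dict


@dataclass
class PetMetrics:
    patient_id: str
    suv_max: float
    suv_mean: float
    mtv: float   # mL
    tlg: float   # SUV * mL


# --------------------------------------------------------------------------
# NIfTI round trip
# --------------------------------------------------------------------------

def write_patient(volume: PatientVolume, outdir) -> dict[str, Path]:
    """Write PET/CT/mask as .nii.gz with the spacing encoded in the affine."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(volume.spacing) + [1.0])
    paths = {}
    for key, arr, dtype in (
        ("pet", volume.pet, np.float32),
        ("ct", volume.ct, np.float32),
        ("mask", volume.mask, np.uint8),
    ):
        p = outdir / f"{volume.patient_id}_{key}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=dtype), affine), p)
        paths[key] = p
    return paths


def read_patient(paths: dict, patient_id: str) -> PatientVolume:
    """Load PET/CT/mask NIfTI files; mask values are binarized at 0.5.

    Raises if shapes or affines disagree between the three volumes, naming
    the mismatching pair.
    """
    imgs = {k: nib.load(str(paths[k])) for k in ("pet", "ct", "mask")}
    keys = list(imgs)
    for a, b in zip(keys, keys[1:]):
        if imgs[a].shape != imgs[b].shape:
            raise ValueError(
                f"shape mismatch between {a} {imgs[a].shape} and {b} {imgs[b].shape}"
            )
        if not np.allclose(imgs[a].affine, imgs[b].affine, atol=1e-5):
            raise ValueError(f"affine mismatch between {a} and {b}")
    affine = imgs["pet"].affine
    spacing = tuple(float(s) for s in nib.affines.voxel_sizes(affine))
    pet = np.asarray(imgs["pet"].get_fdata(), dtype=np.float32)
    ct = np.asarray(imgs["ct"].get_fdata(), dtype=np.float32)
    mask = (np.asarray(imgs["mask"].get_fdata()) > 0.5).astype(np.uint8)
    return PatientVolume(patient_id=patient_id, pet=pet, ct=ct, mask=mask, spacing=spacing)


# --------------------------------------------------------------------------
# ROI crop + resample
# --------------------------------------------------------------------------

def crop_resample(
    volume: PatientVolume,
    side_mm: float = 96.0,
    out_voxels: int = 32,
    *,
    pet_norm: tuple[float, float] | None = None,
    channels: str = "petct",
) -> RoiTensor:
    """Cube of physical side ``side_mm`` centred on the mask centroid,
    trilinearly resampled to ``out_voxels`` per axis.

    The PET channel is z-scored with ``pet_norm = (mean, sd)`` — typically
    frozen training-cohort statistics of in-mask SUV — and the CT channel is
    min-max scaled to [0, 1] over the crop.  Regions outside the source grid
    take the per-channel background value, which maps to 0 after PET
    normalization and to the minimum after CT scaling.
    """
    if volume.mask.sum() == 0:
        raise ValueError(f"empty mask for {volume.patient_id}")
    spacing = np.asarray(volume.spacing, dtype=float)
    centroid_vox = np.asarray(ndimage.center_of_mass(volume.mask), dtype=float)
    centroid_mm = centroid_vox * spacing

    # sample-point world coordinates: out_voxels points spanning side_mm
    step = side_mm / out_voxels
    offsets = (np.arange(out_voxels) - (out_voxels - 1) / 2.0) * step
    grids_mm = [centroid_mm[i] + offsets for i in range(3)]
    coords_vox = np.meshgrid(
        *[g / spacing[i] for i, g in enumerate(grids_mm)], indexing="ij"
    )
    coords = np.stack([c.ravel() for c in coords_vox])

    mean, sd = (pet_norm if pet_norm is not None else (0.0, 1.0))
    if sd <= 0:
        raise ValueError("PET normalization sd must be positive")
    pet = ndimage.map_coordinates(
        volume.pet.astype(np.float64), coords, order=1, mode="constant", cval=mean
    ).reshape((out_voxels,) * 3)
    pet = (pet - mean) / sd

    chans = [pet]
    ct_params: dict = {}
    if channels == "petct":
        ct_min = float(volume.ct.min())
        ct = ndimage.map_coordinates(
            volume.ct.astype(np.float64), coords, order=1, mode="constant", cval=ct_min
        ).reshape((out_voxels,) * 3)
        ct_max = float(ct.max())
        scale = (ct_max - ct_min) or 1.0
        ct = (ct - ct_min) / scale
        chans.append(ct)
        ct_params = {"ct_min": ct_min, "ct_scale": scale}
    elif channels != "pet":
        raise ValueError(f"channels must be 'petct' or 'pet', got {channels!r}")

    data = np.stack(chans, axis=-1).astype(np.float32)
    bbox = tuple((float(g[0]), float(g[-1])) for g in grids_mm)
    return RoiTensor(
        patient_id=volume.patient_id,
        data=data,
        source_bbox=bbox,
        normalization_params={"pet_mean": mean, "pet_sd": sd, **ct_params},
    )


def cohort_pet_norm(volumes) -> tuple[float, float]:
    """Mean/SD of in-mask SUV pooled over a list of volumes (training cohort
    statistics to freeze and reuse at test time)."""
    vals = np.concatenate([v.pet[v.mask > 0].ravel() for v in volumes])
    return float(vals.mean()), float(vals.std() + 1e-8)


# --------------------------------------------------------------------------
# metabolic metrics
# --------------------------------------------------------------------------

def compute_pet_metrics(
    volume: PatientVolume, mtv_threshold_fraction: float = 0.41
) -> PetMetrics:
    """SUVmax / SUVmean / MTV / TLG with fixed-fraction MTV delineation.

    SUVmax is the maximum SUV over the mask; the metabolic volume is the set
    of mask voxels with SUV >= fraction * SUVmax (41% of SUVmax by default, a
    common harmonization convention); SUVmean is averaged over that volume;
    TLG = SUVmean * MTV.
    """
    if volume.mask.sum() == 0:
        raise ValueError(f"empty mask for {volume.patient_id}")
    if not 0 <= mtv_threshold_fraction <= 1:
        raise ValueError("mtv_threshold_fraction must lie in [0, 1]")
    suv = volume.pet[volume.mask > 0].astype(float)
    suv_max = float(suv.max())
    seg = suv >= mtv_threshold_fraction * suv_max
    mtv = float(seg.sum()) * volume.voxel_volume_ml
    suv_mean = float(suv[seg].mean())
    return PetMetrics(
        patient_id=volume.patient_id,
        suv_max=suv_max,
        suv_mean=suv_mean,
        mtv=mtv,
        tlg=suv_mean * mtv,
    )


def metrics_table(volumes, mtv_threshold_fraction: float = 0.41) -> pd.DataFrame:
    rows = []
    for v in volumes:
        m = compute_pet_metrics(v, mtv_threshold_fraction)
        rows.append(
            {
                "patient_id": m.patient_id,
                "suv_max": m.suv_max,
                "suv_mean": m.suv_mean,
                "mtv_ml": m.mtv,
                "tlg": m.tlg,
            }
        )
    return pd.DataFrame(rows)
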