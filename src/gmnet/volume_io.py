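"""Tissue-probability volume I/O and volumetric covariates.

Volumes are grey-matter (GM), white-matter (WM) or CSF probability maps in
NIfTI-1 format. This module reads and writes them, reslices to the working
isotropic grid (2 mm by default, so that a 3x3x3-voxel cube node spans
6 mm), and computes the volumetric covariates used downstream: total
intracranial volume (TIV, the summed GM+WM+CSF volume) and hippocampal GM
volume corrected for head size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "GMVolume",
    "VolumetricCovariates",
    "load_volume",
    "save_volume",
    "resample_isotropic",
    "compute_tiv",
    "hippocampal_volume_normalized",
]

TISSUE_CLASSES = ("GM", "WM", "CSF")

#: Hippocampal-volume abnormality cut-off in ml (TIV-corrected). Values at or
#: below the cut-off are read as atrophic/abnormal.
HV_CUTOFF_ML = 3.68


@dataclass(frozen=True)
class GMVolume:
    """A 3D tissue-probability volume on a regular grid.

    Parameters
    ----------
    data:
        3D array of tissue probability, values in [0, 1].
    affine:
        4x4 voxel-to-world transform (mm), 0-based voxel indices.
    tissue_class:
        One of ``"GM"``, ``"WM"``, ``"CSF"``.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    tissue_class: str = "GM"

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))
        if data.ndim != 3:
            raise ValueError(f"volume must be 3D, got {data.ndim}D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        finite = data[np.isfinite(data)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("tissue probabilities must lie in [0, 1]")
        if self.tissue_class not in TISSUE_CLASSES:
            raise ValueError(f"tissue_class must be one of {TISSUE_CLASSES}")
        if np.any(self.voxel_size_mm <= 0):
            raise ValueError("voxel size must be strictly positive")

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Voxel edge lengths in mm (per axis), from the affine."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def total_volume_ml(self) -> float:
        """Tissue volume in ml: sum of probabilities times voxel volume."""
        return float(self.data.sum() * self.voxel_volume_mm3 / 1000.0)


@dataclass(frozen=True)
class VolumetricCovariates:
    """TIV and (corrected) hippocampal volume for one subject, in ml."""

    tiv_ml: float
    hv_ml: float
    hv_norm_ml: float

    def __post_init__(self) -> None:
        if not (self.tiv_ml >= self.hv_ml >= 0):
            raise ValueError("need tiv_ml >= hv_ml >= 0")
        if self.hv_norm_ml < 0:
            raise ValueError("hv_norm_ml must be non-negative")

    @property
    def hv_abnormal(self) -> bool:
        """Hippocampal atrophy flag: corrected HV at or below the cut-off."""
        return self.hv_norm_ml <= HV_CUTOFF_ML


def load_volume(path, tissue_class: str = "GM") -> GMVolume:
    """Read a NIfTI tissue-probability volume."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    return GMVolume(data=data, affine=np.asarray(img.affine), tissue_class=tissue_class)


def save_volume(vol: GMVolume, path) -> None:
    """Write a volume as NIfTI-1."""
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), vol.affine), str(path))


def resample_isotropic(vol: GMVolume, target_mm: float = 2.0) -> GMVolume:
    """Reslice a volume to an isotropic grid by trilinear interpolation.

    Samples outside the source grid take the value 0.  A volume already on
    the target grid is returned unchanged.  For smooth inputs the total
    tissue volume is preserved to within ~2%.
    """
    if not np.isfinite(target_mm) or target_mm <= 0:
        raise ValueError(f"target_mm must be positive, got {target_mm}")
    src_mm = vol.voxel_size_mm
    if np.allclose(src_mm, target_mm, rtol=0, atol=1e-9):
        return vol

    scale = target_mm / src_mm  # output-voxel index -> input-voxel index
    new_shape = tuple(int(np.floor(s / f)) for s, f in zip(vol.shape, scale))
    if any(n < 1 for n in new_shape):
        raise ValueError("target grid would be empty; target_mm too large")
    out = ndimage.affine_transform(
        vol.data,
        matrix=np.diag(scale),
        output_shape=new_shape,
        order=1,
        mode="constant",
        cval=0.0,
    )
    np.clip(out, 0.0, 1.0, out=out)
    new_affine = vol.affine @ np.diag([*scale, 1.0])
    return GMVolume(data=out, affine=new_affine, tissue_class=vol.tissue_class)


def _check_same_grid(*vols: GMVolume) -> None:
    ref = vols[0]
    for v in vols[1:]:
        if v.shape != ref.shape or not np.allclose(v.affine, ref.affine):
            raise ValueError("volumes must share one grid (shape and affine)")


def compute_tiv(gm: GMVolume, wm: GMVolume, csf: GMVolume) -> float:
    """Total intracranial volume in ml: summed GM+WM+CSF tissue volume."""
    _check_same_grid(gm, wm, csf)
    total = gm.data + wm.data + csf.data
    return float(total.sum() * gm.voxel_volume_mm3 / 1000.0)


def hippocampal_volume_normalized(
    gm: GMVolume,
    hippo_mask: np.ndarray | GMVolume,
    tiv_ml: float,
    tiv_ref_ml: float = 1500.0,
) -> VolumetricCovariates:
    """Hippocampal GM volume with ratio-based TIV correction.

    ``hv_ml`` sums the GM probabilities inside the (binary) hippocampus mask;
    ``hv_norm_ml = hv_ml * tiv_ref_ml / tiv_ml`` rescales it to a reference
    head size (1500 ml by default), so a subject whose TIV equals the
    reference is left unchanged.
    """
    if tiv_ml <= 0:
        raise ValueError("tiv_ml must be positive")
    if tiv_ref_ml <= 0:
        raise ValueError("tiv_ref_ml must be positive")
    mask = hippo_mask.data if isinstance(hippo_mask, GMVolume) else np.asarray(hippo_mask)
    if mask.shape != gm.shape:
        raise ValueError("mask and GM volume must share one grid")
    mask = mask.astype(bool)
    if not mask.any():
        warnings.warn("empty hippocampus mask; hv_ml set to 0", stacklevel=2)
        hv_ml = 0.0
    else:
        hv_ml = float(gm.data[mask].sum() * gm.voxel_volume_mm3 / 1000.0)
    hv_norm = hv_ml * tiv_ref_ml / tiv_ml
    return VolumetricCovariates(tiv_ml=float(tiv_ml), hv_ml=hv_ml, hv_norm_ml=hv_norm)


def mask_from_labels(label_vol: np.ndarray, label_ids) -> np.ndarray:
    """Binary mask selecting the given integer label ids from a label volume."""
    labels = np.asarray(label_vol)
    return np.isin(labels, np.asarray(label_ids)).astype(np.uint8)
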