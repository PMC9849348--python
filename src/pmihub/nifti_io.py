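"""NIfTI ingestion for the PMI pipeline.

Loads per-subject free-water volume-fraction maps with co-registered binary
tumor-core and edema masks, enforces grid consistency, and resamples
everything to the working resolution (2x2x2 mm by default).

Conventions
-----------
Voxel indices are 0-based; world coordinates follow the NIfTI affine.  All
downstream geometry (hub sizes, diameters, sdvec) is computed in voxel units
of the working grid, which is isotropic, so voxel and mm geometry differ only
by the scalar spacing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)

#: Working resolution of the pipeline, in mm.
DEFAULT_TARGET_MM = (2.0, 2.0, 2.0)

#: Tolerance for declaring two subject files to be on the same grid.
GRID_ATOL = 1e-3


@dataclass
class FreeWaterVolume:
    """A 3D free-water volume-fraction map (unitless, values in [0, 1])."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"free-water volume must be 3D, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        finite = self.data[np.isfinite(self.data)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("free-water values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class SubjectMasks:
    """Co-registered binary tumor-core and edema masks on one grid.

    The two masks are disjoint: tumor core is the stronger label, so any
    voxel claimed by both is assigned to the core at load time (the pipeline
    must never sample "edema" patches inside the core).
    """

    tumor_core: np.ndarray
    edema: np.ndarray

    def __post_init__(self) -> None:
        self.tumor_core = np.asarray(self.tumor_core).astype(bool)
        self.edema = np.asarray(self.edema).astype(bool)
        if self.tumor_core.ndim != 3 or self.edema.ndim != 3:
            raise ValueError("masks must be 3D")
        if self.tumor_core.shape != self.edema.shape:
            raise ValueError("tumor-core and edema masks must share one grid")
        if np.any(self.tumor_core & self.edema):
            raise ValueError("tumor_core and edema overlap; resolve before construction")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.edema.shape


def _read_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float], np.ndarray]:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing, np.asarray(img.affine, dtype=np.float64)


def load_subject(
    fw_path: str | Path, tumor_path: str | Path, edema_path: str | Path
) -> tuple[FreeWaterVolume, SubjectMasks]:
    """Load a subject's free-water map and its tumor-core / edema masks.

    All three files must live on identical grids (shape; spacing and affine
    within 1e-3).  Masks are binarized at 0.5, overlap voxels go to the tumor
    core, and free-water values outside [0, 1] are clipped with a warning.
    """
    fw_data, spacing, affine = _read_volume(fw_path)
    masks_raw = {}
    for name, path in (("tumor", tumor_path), ("edema", edema_path)):
        data, sp, aff = _read_volume(path)
        if data.shape != fw_data.shape:
            raise ValueError(
                f"{path}: grid mismatch (shape {data.shape} vs {fw_data.shape} of {fw_path})"
            )
        if not np.allclose(sp, spacing, atol=GRID_ATOL):
            raise ValueError(f"{path}: spacing mismatch ({sp} vs {spacing} of {fw_path})")
        if not np.allclose(aff, affine, atol=GRID_ATOL):
            raise ValueError(f"{path}: affine mismatch with {fw_path}")
        masks_raw[name] = data > 0.5

    n_clipped = int(np.sum((fw_data < 0) | (fw_data > 1)))
    if n_clipped:
        logger.warning("%s: clipped %d free-water values to [0, 1]", fw_path, n_clipped)
        fw_data = np.clip(fw_data, 0.0, 1.0)

    tumor = masks_raw["tumor"]
    edema = masks_raw["edema"] & ~tumor  # tumor core wins overlaps
    vol = FreeWaterVolume(fw_data, spacing, affine)
    return vol, SubjectMasks(tumor_core=tumor, edema=edema)


def save_volume(path: str | Path, data: np.ndarray, spacing, affine=None) -> None:
    """Write an array as NIfTI-1; affine defaults to a diagonal of the spacing."""
    if affine is None:
        affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), np.asarray(affine))
    img.header.set_zooms(tuple(float(s) for s in spacing))
    nib.save(img, str(path))


def resample_iso(
    vol: FreeWaterVolume,
    masks: SubjectMasks,
    target_mm: tuple[float, float, float] = DEFAULT_TARGET_MM,
) -> tuple[FreeWaterVolume, SubjectMasks]:
    """Resample a subject to the working resolution.

    The scalar volume uses trilinear interpolation, the masks nearest
    neighbor, so mask binarity is preserved exactly.  World-space extent is
    preserved: the output grid covers the same physical field of view and the
    affine is updated accordingly.
    """
    target = tuple(float(t) for t in target_mm)
    if any(t <= 0 for t in target):
        raise ValueError(f"target spacing must be strictly positive, got {target}")
    if any(n == 0 for n in vol.shape):
        raise ValueError("cannot resample a zero-extent volume")

    zoom = np.array(vol.spacing) / np.array(target)
    if np.allclose(zoom, 1.0):
        return vol, masks

    new_shape = tuple(max(1, int(round(n * z))) for n, z in zip(vol.shape, zoom))
    # Map output voxel index j to input index via world coordinates:
    # input_index = j * target/spacing (pure scaling in index space).
    scale = np.array(target) / np.array(vol.spacing)

    def _coords(shape):
        grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
        return [g * s for g, s in zip(grids, scale)]

    coords = _coords(new_shape)
    data = ndimage.map_coordinates(vol.data, coords, order=1, mode="nearest")
    tumor = ndimage.map_coordinates(
        masks.tumor_core.astype(np.uint8), coords, order=0, mode="nearest"
    )
    edema = ndimage.map_coordinates(masks.edema.astype(np.uint8), coords, order=0, mode="nearest")

    new_affine = vol.affine.copy()
    new_affine[:3, :3] = vol.affine[:3, :3] @ np.diag(scale)
    out_vol = FreeWaterVolume(np.clip(data, 0.0, 1.0), target, new_affine)
    edema = edema.astype(bool) & ~tumor.astype(bool)
    return out_vol, SubjectMasks(tumor_core=tumor.astype(bool), edema=edema)


COHORT_COLUMNS = ["subject_id", "age_years", "sex", "survival_months", "event", "idh1_status"]


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV and validate its schema.

    Required columns: subject_id, age_years, sex (M/F), survival_months,
    event (1 death / 0 censored), idh1_status (wildtype|mutant|NA).
    """
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table {path} missing columns: {missing}")
    bad_sex = set(df["sex"].dropna().unique()) - {"M", "F"}
    if bad_sex:
        raise ValueError(f"cohort table {path}: unexpected sex codes {bad_sex}")
    if (df["survival_months"] < 0).any():
        raise ValueError(f"cohort table {path}: negative survival times")
    return df
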