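"""Labeled 2D patch extraction from peritumoral edema.

Training patches are 16x16 in-plane windows drawn at random centers and
random cardinal planes (axial / sagittal / coronal), fully contained in the
edema mask — the largest patch that fits in edema without touching the tumor
core.  Patches from vasogenic (metastasis-like) edema are labeled
``high_fw``, those from infiltrative (glioblastoma-like) edema ``low_fw``.
Augmentation shifts a patch in-plane by a small random integer offset,
allowing at most a fixed fraction (default 20%) of the window to fall
outside edema into healthy brain, and never into the tumor core.

Patch values are raw free-water fractions with no per-patch normalization:
the absolute free-water level IS the class signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .nifti_io import FreeWaterVolume, SubjectMasks

logger = logging.getLogger(__name__)

PLANES = ("axial", "sagittal", "coronal")
#: in-plane axes per plane, for arrays indexed (i, j, k) = (sag, cor, ax)
_PLANE_AXES = {"sagittal": (1, 2), "coronal": (0, 2), "axial": (0, 1)}

DEFAULT_PATCH_SIZE = 16
#: maximum fraction of an augmented patch allowed outside edema
DEFAULT_MAX_OUTSIDE_FRAC = 0.20
#: in-plane shift range for augmentation, voxels
SHIFT_RANGE = 4
#: patches sampled per subject by the CLI / pipeline default
DEFAULT_PATCHES_PER_SUBJECT = 200

LABELS = ("high_fw", "low_fw")


@dataclass
class Patch:
    """One 2D free-water patch in a cardinal plane."""

    values: np.ndarray
    plane: str
    center_voxel: tuple[int, int, int]
    label: str | None = None
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"patch must be square 2D, got {self.values.shape}")
        if self.plane not in PLANES:
            raise ValueError(f"plane must be one of {PLANES}")
        if self.label is not None and self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS} or None")


def _window(center: np.ndarray, plane: str, patch_size: int):
    """Slices of the in-plane window for an even-sized patch.

    A patch of size ``s`` centered at voxel ``c`` covers indices
    ``[c - s//2, c + s//2)`` along each in-plane axis, matching the
    half-voxel-asymmetric convention used for dense PMI inference.
    """
    half = patch_size // 2
    ax = _PLANE_AXES[plane]
    slices = [slice(int(c), int(c) + 1) for c in center]
    for a in ax:
        lo = int(center[a]) - half
        slices[a] = slice(lo, lo + patch_size)
    return tuple(slices), ax


def _extract(vol_data: np.ndarray, center, plane: str, patch_size: int) -> np.ndarray | None:
    slices, _ = _window(np.asarray(center), plane, patch_size)
    for sl, n in zip(slices, vol_data.shape):
        if sl.start < 0 or sl.stop > n:
            return None
    return np.squeeze(vol_data[slices])


def sample_training_patches(
    vol: FreeWaterVolume,
    masks: SubjectMasks,
    n: int,
    label: str,
    patch_size: int = DEFAULT_PATCH_SIZE,
    seed: int = 0,
    subject_id: str | None = None,
) -> list[Patch]:
    """Sample up to ``n`` fully-in-edema patches at random centers and planes.

    Centers and planes are drawn uniformly with rejection; a placement is
    valid when every voxel of the in-plane window lies in edema (edema and
    tumor core are disjoint, so no window voxel can be in the core).  Gives
    up after ``50 * n`` attempts and returns what it found, with a warning;
    an impossible geometry yields an empty list.  Deterministic given seed.
    """
    if patch_size < 2:
        raise ValueError("patch_size must be >= 2")
    edema_idx = np.argwhere(masks.edema)
    if len(edema_idx) == 0:
        raise ValueError("edema mask is empty")
    rng = np.random.default_rng(seed)
    out: list[Patch] = []
    attempts = 0
    max_attempts = 50 * n
    edema = masks.edema
    while len(out) < n and attempts < max_attempts:
        attempts += 1
        center = edema_idx[rng.integers(len(edema_idx))]
        plane = PLANES[rng.integers(3)]
        win = _extract(edema, center, plane, patch_size)
        if win is None or not win.all():
            continue
        values = _extract(vol.data, center, plane, patch_size)
        out.append(
            Patch(values, plane, tuple(int(c) for c in center), label, subject_id)
        )
    if len(out) < n:
        logger.warning(
            "sampled only %d/%d patches after %d attempts%s",
            len(out), n, attempts, f" for {subject_id}" if subject_id else "",
        )
    return out


def augment_shift(
    p: Patch,
    vol: FreeWaterVolume,
    masks: SubjectMasks,
    max_outside_frac: float = DEFAULT_MAX_OUTSIDE_FRAC,
    n_aug: int = 4,
    seed: int = 0,
) -> list[Patch]:
    """Shift-augment a patch in-plane by random integer offsets.

    Accepts a shifted copy when the fraction of window voxels outside edema
    is at most ``max_outside_frac`` (the shifted window may overlap healthy
    brain up to that fraction) and no window voxel lands in the tumor core.
    Labels are preserved.  Returns fewer than ``n_aug`` if placements are
    exhausted.
    """
    if not (0.0 <= max_outside_frac < 1.0):
        raise ValueError("max_outside_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    size = p.values.shape[0]
    _, in_axes = _PLANE_AXES[p.plane], _PLANE_AXES[p.plane]
    out: list[Patch] = []
    attempts = 0
    while len(out) < n_aug and attempts < 50 * max(1, n_aug):
        attempts += 1
        offset = rng.integers(-SHIFT_RANGE, SHIFT_RANGE + 1, size=2)
        center = np.array(p.center_voxel)
        for a, o in zip(in_axes, offset):
            center[a] += o
        win_edema = _extract(masks.edema, center, p.plane, size)
        if win_edema is None:
            continue
        win_core = _extract(masks.tumor_core, center, p.plane, size)
        if win_core.any():
            continue
        outside = 1.0 - win_edema.mean()
        if outside > max_outside_frac + 1e-12:
            continue
        values = _extract(vol.data, center, p.plane, size)
        out.append(Patch(values, p.plane, tuple(int(c) for c in center), p.label, p.subject_id))
    return out


def save_patches(patches: list[Patch], array_path: str | Path, csv_path: str | Path) -> None:
    """Serialize a patch set: one .npz array container + a sidecar CSV."""
    values = np.stack([p.values for p in patches]) if patches else np.zeros((0, 0, 0))
    np.savez_compressed(array_path, values=values)
    pd.DataFrame(
        {
            "subject_id": [p.subject_id for p in patches],
            "label": [p.label for p in patches],
            "plane": [p.plane for p in patches],
            "center_i": [p.center_voxel[0] for p in patches],
            "center_j": [p.center_voxel[1] for p in patches],
            "center_k": [p.center_voxel[2] for p in patches],
        }
    ).to_csv(csv_path, index=False)


def load_patches(array_path: str | Path, csv_path: str | Path) -> list[Patch]:
    values = np.load(array_path)["values"]
    meta = pd.read_csv(csv_path)
    out = []
    for arr, (_, row) in zip(values, meta.iterrows()):
        label = row["label"] if isinstance(row["label"], str) else None
        sid = row["subject_id"] if isinstance(row["subject_id"], str) else None
        out.append(
            Patch(
                arr,
                row["plane"],
                (int(row["center_i"]), int(row["center_j"]), int(row["center_k"])),
                label,
                sid,
            )
        )
    return out
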