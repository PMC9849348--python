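"""The five descriptive hub markers and subject-level exclusion rules.

Per subject the markers are:

* ``n_hubs_norm``   — number of hubs / edema voxel count;
* ``size_norm``     — mean hub size / edema voxel count;
* ``shape_het``     — per-hub anisotropy (s1 - s2)/s1 of the sorted sdvec
  components, averaged over hubs (0 = isotropic, 1 = line-like);
* ``dir_het``       — Hausdorff-style max-min pairwise cosine distance
  (1 - cos) between hub sdvec directions, in [0, 2];
* ``spatial_het``   — mean pairwise centroid distance divided by the edema
  diameter, in (0, 1].

The heterogeneity markers need at least two hubs; subjects below that (or
with near-empty edema) are removed by :func:`apply_exclusions`, mirroring
the cohort filtering of the clinical analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hubs import HubSet, point_set_diameter
from .nifti_io import SubjectMasks

logger = logging.getLogger(__name__)

MARKER_NAMES = ("n_hubs_norm", "size_norm", "shape_het", "dir_het", "spatial_het")

#: minimum edema voxel count (exclusion rule: "small edema")
DEFAULT_MIN_EDEMA_VOXELS = 2
#: minimum hub count needed for the heterogeneity markers
MIN_HUBS = 2


@dataclass
class MarkerVector:
    """The five markers of one subject (NaN where undefined)."""

    n_hubs_norm: float
    size_norm: float
    shape_het: float
    dir_het: float
    spatial_het: float
    n_hubs_raw: int
    edema_voxel_count: int

    def as_dict(self) -> dict:
        return {
            "n_hubs_norm": self.n_hubs_norm,
            "size_norm": self.size_norm,
            "shape_het": self.shape_het,
            "dir_het": self.dir_het,
            "spatial_het": self.spatial_het,
            "n_hubs_raw": self.n_hubs_raw,
            "edema_voxel_count": self.edema_voxel_count,
        }


def marker_number_size(hs: HubSet) -> tuple[float, float]:
    """Hub count and mean hub size, each normalized by edema voxel count."""
    if hs.edema_voxel_count <= 0:
        raise ValueError("edema_voxel_count must be positive")
    if not hs.hubs:
        return 0.0, 0.0
    n_norm = len(hs.hubs) / hs.edema_voxel_count
    size_norm = float(np.mean([h.size for h in hs.hubs])) / hs.edema_voxel_count
    return n_norm, size_norm


def marker_shape_het(hs: HubSet) -> float:
    """Mean per-hub anisotropy (s1 - s2) / s1 of sorted sdvec components.

    Hubs with all-zero sdvec (single voxels) contribute 0; no hubs -> NaN.
    """
    if not hs.hubs:
        return math.nan
    scores = []
    for h in hs.hubs:
        s = np.sort(h.sdvec)[::-1]
        scores.append(0.0 if s[0] == 0 else (s[0] - s[1]) / s[0])
    return float(np.mean(scores))


def marker_dir_het(hs: HubSet) -> float:
    """Max-min pairwise cosine distance between hub sdvec directions.

    With d(i, j) = 1 - cos(sdvec_i, sdvec_j), returns
    max_i min_{j != i} d(i, j) over hubs with nonzero sdvec — the
    Hausdorff-style statistic of the direction set against itself with
    self-matches excluded (the literal two-set Hausdorff of a set with
    itself is identically zero).  Needs >= 2 usable hubs, else NaN.
    """
    vecs = []
    for h in hs.hubs:
        norm = np.linalg.norm(h.sdvec)
        if norm == 0:
            logger.warning("hub with zero sdvec excluded from directional heterogeneity")
            continue
        vecs.append(h.sdvec / norm)
    if len(vecs) < MIN_HUBS:
        return math.nan
    v = np.stack(vecs)
    cos = np.clip(v @ v.T, -1.0, 1.0)
    d = 1.0 - cos
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).max())


def marker_spatial_het(hs: HubSet, masks: SubjectMasks) -> float:
    """Mean pairwise centroid distance over the edema diameter, in (0, 1].

    The normalizer is the maximum pairwise distance between edema voxel
    centers ("the maximum possible distance between any two points").
    Coincident centroids yield 0 and are flagged as degenerate.
    """
    if len(hs.hubs) < MIN_HUBS:
        return math.nan
    edema_idx = np.argwhere(masks.edema)
    if len(edema_idx) == 0:
        raise ValueError("edema mask is empty")
    diam = point_set_diameter(edema_idx)
    if diam == 0:
        raise ValueError("edema diameter is zero")
    cents = np.stack([h.centroid for h in hs.hubs])
    diff = cents[:, None, :] - cents[None, :, :]
    dists = np.sqrt((diff**2).sum(-1))
    iu = np.triu_indices(len(cents), k=1)
    mean_d = float(dists[iu].mean())
    if mean_d == 0:
        logger.warning("all hub centroids coincide: spatial heterogeneity degenerate (0)")
        return 0.0
    return float(min(mean_d / diam, 1.0))


def compute_markers(hs: HubSet, masks: SubjectMasks) -> MarkerVector:
    """All five markers for one subject's HubSet."""
    n_norm, size_norm = marker_number_size(hs)
    return MarkerVector(
        n_hubs_norm=n_norm,
        size_norm=size_norm,
        shape_het=marker_shape_het(hs) if len(hs.hubs) >= MIN_HUBS else math.nan,
        dir_het=marker_dir_het(hs),
        spatial_het=marker_spatial_het(hs, masks),
        n_hubs_raw=len(hs.hubs),
        edema_voxel_count=hs.edema_voxel_count,
    )


def markers_table(subject_ids, marker_vectors) -> pd.DataFrame:
    """Assemble the per-subject markers table (CSV-ready)."""
    rows = []
    for sid, mv in zip(subject_ids, marker_vectors):
        rows.append({"subject_id": sid, **mv.as_dict()})
    return pd.DataFrame(rows)


def apply_exclusions(
    table: pd.DataFrame,
    min_edema_voxels: int = DEFAULT_MIN_EDEMA_VOXELS,
    min_hubs: int = MIN_HUBS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the subject-level exclusion rules.

    Removes subjects with edema smaller than ``min_edema_voxels`` (reason
    ``small_edema``) and subjects with fewer than ``min_hubs`` hubs at the
    working threshold (reason ``too_few_hubs``).  Returns the filtered table
    and an exclusion log of (subject_id, reason).
    """
    required = {"subject_id", "n_hubs_raw", "edema_voxel_count"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"markers table missing columns: {missing}")
    log_rows = []
    keep = np.ones(len(table), dtype=bool)
    for i, row in table.reset_index(drop=True).iterrows():
        if row["edema_voxel_count"] < min_edema_voxels:
            keep[i] = False
            log_rows.append({"subject_id": row["subject_id"], "reason": "small_edema"})
        elif row["n_hubs_raw"] < min_hubs:
            keep[i] = False
            log_rows.append({"subject_id": row["subject_id"], "reason": "too_few_hubs"})
    filtered = table.reset_index(drop=True)[keep].reset_index(drop=True)
    if filtered.empty:
        raise ValueError("all subjects excluded; cohort is empty")
    log = pd.DataFrame(log_rows, columns=["subject_id", "reason"])
    return filtered, log
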