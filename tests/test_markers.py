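"""The five hub markers: arithmetic oracles, geometric invariances,
exclusion rules."""

import math

import numpy as np
import pandas as pd
import pytest

from pmihub.hubs import Hub, HubSet, extract_hubs
from pmihub.markers import (
    MarkerVector,
    apply_exclusions,
    compute_markers,
    marker_dir_het,
    marker_number_size,
    marker_shape_het,
    marker_spatial_het,
    markers_table,
)
from pmihub.nifti_io import SubjectMasks
from pmihub.pmi_model import PMIMap


def _hub_line(axis=0, length=10, offset=(0, 0, 0)):
    vox = np.zeros((length, 3), dtype=int)
    vox[:, axis] = np.arange(length)
    return Hub.from_voxels(vox + np.asarray(offset))


def _hub_cube(side=3, offset=(0, 0, 0)):
    g = np.stack(np.meshgrid(*[np.arange(side)] * 3, indexing="ij"), -1).reshape(-1, 3)
    return Hub.from_voxels(g + np.asarray(offset))


def _hubset(hubs, edema_count=1000, threshold=0.9):
    return HubSet(hubs=hubs, threshold=threshold, edema_voxel_count=edema_count)


def _edema_box(shape=(20, 20, 20), lo=2, hi=18):
    edema = np.zeros(shape, bool)
    edema[lo:hi, lo:hi, lo:hi] = True
    return SubjectMasks(np.zeros(shape, bool), edema)


class TestNumberSize:
    def test_single_hub_arithmetic(self):
        vox = np.argwhere(np.ones((10, 10, 5)))  # 500 voxels
        hs = _hubset([Hub.from_voxels(vox)], edema_count=1000)
        n_norm, size_norm = marker_number_size(hs)
        assert n_norm == pytest.approx(0.001, abs=1e-12)
        assert size_norm == pytest.approx(0.5, abs=1e-12)

    def test_no_hubs_gives_zero(self):
        assert marker_number_size(_hubset([], edema_count=500)) == (0.0, 0.0)

    def test_mirror_duplication_preserves_hub_density(self):
        # doubling edema and hubs by mirroring keeps hubs-per-voxel and the
        # mean hub size unchanged
        hub = _hub_cube(3)
        hs1 = _hubset([hub], edema_count=1000)
        mirrored = Hub.from_voxels(np.array([[50, 50, 50]]) - hub.voxels)
        hs2 = _hubset([hub, mirrored], edema_count=2000)
        assert marker_number_size(hs1)[0] == pytest.approx(marker_number_size(hs2)[0])
        assert np.mean([h.size for h in hs1.hubs]) == np.mean([h.size for h in hs2.hubs])


class TestShapeHet:
    def test_isotropic_hub_scores_zero(self):
        assert marker_shape_het(_hubset([_hub_cube(3)])) == pytest.approx(0.0, abs=1e-12)

    def test_line_hub_scores_one(self):
        assert marker_shape_het(_hubset([_hub_line()])) == pytest.approx(1.0, abs=1e-12)

    def test_mean_of_line_and_cube_is_half(self):
        hs = _hubset([_hub_line(), _hub_cube(3, offset=(20, 20, 20))])
        assert marker_shape_het(hs) == pytest.approx(0.5, abs=1e-12)

    def test_no_hubs_flagged_nan(self):
        assert math.isnan(marker_shape_het(_hubset([])))


class TestDirHet:
    def test_collinear_sdvecs_give_zero(self):
        hs = _hubset([_hub_line(0), _hub_line(0, offset=(0, 5, 5)), _hub_line(0, offset=(0, 9, 2))])
        assert marker_dir_het(hs) == pytest.approx(0.0, abs=1e-9)

    def test_two_parallel_one_orthogonal_gives_one(self):
        # sdvec directions (1,0,0), (1,0,0), (0,1,0):
        # min distances are 0, 0 and 1 -> Hausdorff-style max = 1
        hs = _hubset([_hub_line(0), _hub_line(0, offset=(5, 5, 5)), _hub_line(1)])
        assert marker_dir_het(hs) == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance(self):
        short = _hubset([_hub_line(0, length=4), _hub_line(1, length=4)])
        long = _hubset([_hub_line(0, length=40), _hub_line(1, length=40)])
        assert marker_dir_het(short) == pytest.approx(marker_dir_het(long), abs=1e-9)

    def test_single_hub_flagged_nan(self):
        assert math.isnan(marker_dir_het(_hubset([_hub_line()])))

    def test_zero_sdvec_hub_excluded_with_warning(self, caplog):
        single = Hub.from_voxels(np.array([[1, 1, 1]]))
        hs = _hubset([single, _hub_line(0), _hub_line(1)])
        with caplog.at_level("WARNING"):
            val = marker_dir_het(hs)
        assert val == pytest.approx(1.0, abs=1e-9)
        assert "zero sdvec" in caplog.text


class TestSpatialHet:
    def test_centroids_realizing_edema_diameter_give_one(self):
        # edema of exactly two voxels; single-voxel hubs on both: the
        # centroid distance equals the edema diameter exactly
        edema = np.zeros((20, 20, 20), bool)
        edema[2, 2, 2] = edema[17, 17, 17] = True
        masks = SubjectMasks(np.zeros_like(edema), edema)
        hubs = [
            Hub.from_voxels(np.array([[2, 2, 2]])),
            Hub.from_voxels(np.array([[17, 17, 17]])),
        ]
        assert marker_spatial_het(_hubset(hubs), masks) == pytest.approx(1.0, abs=1e-12)

    def test_coincident_centroids_flagged_zero(self, caplog):
        a = Hub.from_voxels(np.array([[4, 4, 4], [6, 6, 6]]))
        b = Hub.from_voxels(np.array([[4, 6, 4], [6, 4, 6]]))
        with caplog.at_level("WARNING"):
            val = marker_spatial_het(_hubset([a, b]), _edema_box())
        assert val == 0.0
        assert "coincide" in caplog.text

    def test_three_centroids_match_hand_computation(self):
        masks = _edema_box(shape=(12, 12, 12), lo=0, hi=12)
        hubs = [
            Hub.from_voxels(np.array([[0, 0, 0]])),
            Hub.from_voxels(np.array([[6, 0, 0]])),
            Hub.from_voxels(np.array([[0, 8, 0]])),
        ]
        # pairwise distances 6, 8, 10 -> mean 8; edema diameter = 11*sqrt(3)
        expected = 8.0 / (11 * math.sqrt(3))
        val = marker_spatial_het(_hubset(hubs), masks)
        assert val == pytest.approx(expected, abs=1e-9)

    def test_single_hub_flagged_nan(self):
        assert math.isnan(marker_spatial_het(_hubset([_hub_cube()]), _edema_box()))


class TestGeometricInvariance:
    """All five markers are invariant to integer translation and axis
    rotations of the subject; PMI here is a deterministic function of the
    free-water volume so the transformed map is exactly the transformed
    original."""

    @staticmethod
    def _markers_of(vol_data, edema, threshold=0.55):
        masks = SubjectMasks(np.zeros_like(edema), edema)
        pmi = PMIMap(np.where(edema, 1.0 - vol_data, np.nan), edema)
        hs = extract_hubs(pmi, masks, threshold)
        return compute_markers(hs, masks)

    def test_translation_and_rotation_invariance(self, tiny_infiltrative):
        vol, masks, _ = tiny_infiltrative
        base = self._markers_of(vol.data, masks.edema)
        assert base.n_hubs_raw >= 2

        def assert_same(other):
            for name in ("n_hubs_norm", "size_norm", "shape_het", "dir_het", "spatial_het"):
                a, b = getattr(base, name), getattr(other, name)
                assert a == pytest.approx(b, abs=1e-9), name

        shifted = self._markers_of(
            np.roll(vol.data, (3, 2, 1), (0, 1, 2)), np.roll(masks.edema, (3, 2, 1), (0, 1, 2))
        )
        assert_same(shifted)
        for axes in ((0, 1), (1, 2), (0, 2)):
            rotated = self._markers_of(
                np.rot90(vol.data, k=1, axes=axes), np.rot90(masks.edema, k=1, axes=axes)
            )
            assert_same(rotated)


class TestComputeAndExclusions:
    def test_compute_markers_flags_below_two_hubs(self):
        mv = compute_markers(_hubset([_hub_cube()]), _edema_box())
        assert mv.n_hubs_raw == 1
        assert math.isnan(mv.shape_het) and math.isnan(mv.dir_het) and math.isnan(mv.spatial_het)
        assert mv.n_hubs_norm > 0

    def test_exclusion_reasons(self):
        table = markers_table(
            ["tiny_edema", "one_hub", "ok"],
            [
                MarkerVector(0, 0, math.nan, math.nan, math.nan, 0, 1),
                MarkerVector(0.001, 0.5, math.nan, math.nan, math.nan, 1, 500),
                MarkerVector(0.004, 0.2, 0.5, 0.3, 0.4, 2, 500),
            ],
        )
        kept, log = apply_exclusions(table)
        assert list(kept["subject_id"]) == ["ok"]
        reasons = dict(zip(log["subject_id"], log["reason"]))
        assert reasons == {"tiny_edema": "small_edema", "one_hub": "too_few_hubs"}

    def test_all_excluded_is_hard_error(self):
        table = markers_table(
            ["a"], [MarkerVector(0, 0, math.nan, math.nan, math.nan, 1, 500)]
        )
        with pytest.raises(ValueError, match="excluded"):
            apply_exclusions(table)

    def test_bounds_on_phantom_markers(self, trained_model, analysis_subject, working_threshold):
        from pmihub.pmi_model import pmi_map

        vol, masks, _ = analysis_subject
        hs = extract_hubs(pmi_map(trained_model, vol, masks), masks, working_threshold)
        mv = compute_markers(hs, masks)
        assert 0 <= mv.shape_het <= 1
        assert 0 <= mv.dir_het <= 2
        assert 0 < mv.spatial_het <= 1
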