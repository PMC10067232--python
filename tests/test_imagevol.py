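import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plateforge import synthetic
from plateforge.imagevol import (LabelMap, VolumeLoadError, VoxelVolume,
                                 erase_labels, extract_surface, load_volume,
                                 save_volume, split_components,
                                 threshold_segment, write_dicom_series)
from plateforge import _dicom


def sphere_volume(radius=10.0, spacing=(0.5, 0.5, 0.5)):
    mesh = synthetic.icosphere(radius, 4)
    return synthetic.voxelize_phantom(mesh, spacing=spacing)


# ---------------------------------------------------------------------------
# flood-fill oracle (independent of scipy.ndimage.label)
# ---------------------------------------------------------------------------

def oracle_flood_fill(mask: np.ndarray, connectivity: int):
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((dx, dy, dz))
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    for idx in zip(*np.nonzero(mask)):
        if labels[idx]:
            continue
        current += 1
        stack = [idx]
        labels[idx] = current
        while stack:
            x, y, z = stack.pop()
            for dx, dy, dz in offs:
                n = (x + dx, y + dy, z + dz)
                if any(c < 0 or c >= s for c, s in zip(n, mask.shape)):
                    continue
                if mask[n] and not labels[n]:
                    labels[n] = current
                    stack.append(n)
    return labels


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

class TestTypes:
    def test_spacing_positive(self):
        with pytest.raises(ValueError):
            VoxelVolume(np.zeros((2, 2, 2)), (1, 0, 1), (0, 0, 0))

    def test_grid_3d(self):
        with pytest.raises(ValueError):
            VoxelVolume(np.zeros((2, 2)), (1, 1, 1), (0, 0, 0))

    def test_labels_nonnegative(self):
        with pytest.raises(ValueError):
            LabelMap(-np.ones((2, 2, 2), dtype=int), (1, 1, 1), (0, 0, 0))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

class TestIO:
    def test_nrrd_roundtrip(self, tmp_path, rng):
        arr = rng.normal(size=(50, 40, 20))
        vol = VoxelVolume(arr, (1.0, 1.0, 3.0), (-5.0, 2.0, 10.0))
        p = tmp_path / "vol.nrrd"
        save_volume(vol, p)
        back = load_volume(p)
        assert np.array_equal(back.intensities, arr)
        assert np.allclose(back.spacing, vol.spacing)
        assert np.allclose(back.origin, vol.origin)

    def test_nifti_roundtrip(self, tmp_path, rng):
        arr = rng.normal(size=(10, 12, 8)).astype(np.float32).astype(np.float64)
        vol = VoxelVolume(arr, (0.8, 0.8, 3.0), (1.0, 2.0, 3.0))
        p = tmp_path / "vol.nii"
        save_volume(vol, p)
        back = load_volume(p)
        assert np.allclose(back.intensities, arr, atol=1e-6)
        assert np.allclose(back.spacing, vol.spacing, atol=1e-6)

    def test_synthetic_nrrd_shape_spacing(self, tmp_path, rng):
        vol = VoxelVolume(rng.normal(size=(50, 50, 50)), (1, 1, 3), (0, 0, 0))
        p = tmp_path / "a.nrrd"
        save_volume(vol, p)
        back = load_volume(p)
        assert back.shape == (50, 50, 50)
        assert np.allclose(back.spacing, (1, 1, 3))

    def test_dicom_roundtrip(self, tmp_path, rng):
        arr = rng.integers(-500, 1500, size=(16, 12, 5)).astype(float)
        vol = VoxelVolume(arr, (0.8, 0.8, 3.0), (-10.0, -20.0, 5.0))
        d = tmp_path / "series"
        write_dicom_series(vol, d)
        back = load_volume(d)
        assert back.shape == vol.shape
        assert np.array_equal(back.intensities, arr)
        assert np.allclose(back.spacing, vol.spacing)
        assert np.allclose(back.origin, vol.origin)

    def test_dicom_unequal_spacing_errors(self, tmp_path):
        d = tmp_path / "series"
        d.mkdir()
        px = np.zeros((4, 4), dtype=np.int16)
        for k, z in enumerate([0.0, 3.0, 7.5]):  # gap between slice 1 and 2
            _dicom.write_slice(d / f"s{k}.dcm", px, (1.0, 1.0), (0, 0, z))
        with pytest.raises(VolumeLoadError, match="non-uniform"):
            load_volume(d)

    def test_unknown_container(self, tmp_path):
        p = tmp_path / "vol.xyz"
        p.write_text("nope")
        with pytest.raises(VolumeLoadError):
            load_volume(p)


# ---------------------------------------------------------------------------
# threshold
# ---------------------------------------------------------------------------

class TestThreshold:
    def test_sphere_phantom_volume(self):
        vol = sphere_volume(10.0)
        mask = threshold_segment(vol, 300.0)
        got = mask.labels.sum() * vol.voxel_volume
        assert got == pytest.approx(4 / 3 * np.pi * 1000, rel=0.05)

    def test_above_all_background(self):
        vol = sphere_volume(5.0, (1, 1, 1))
        mask = threshold_segment(vol, 1e6)
        assert mask.labels.sum() == 0

    def test_unbounded_all_foreground(self):
        vol = sphere_volume(5.0, (1, 1, 1))
        mask = threshold_segment(vol, -np.inf, np.inf)
        assert mask.labels.all()

    def test_low_gt_high_errors(self):
        vol = sphere_volume(5.0, (1, 1, 1))
        with pytest.raises(ValueError):
            threshold_segment(vol, 10, 5)

    def test_inclusive_bounds(self):
        arr = np.full((2, 2, 2), 100.0)
        vol = VoxelVolume(arr, (1, 1, 1), (0, 0, 0))
        assert threshold_segment(vol, 100, 100).labels.all()

    @settings(max_examples=20, deadline=None)
    @given(st.floats(-200, 200), st.floats(0, 400), st.floats(0, 100))
    def test_monotone_in_window(self, low, width, widen):
        vol = VoxelVolume(np.linspace(-300, 300, 64).reshape(4, 4, 4),
                          (1, 1, 1), (0, 0, 0))
        inner = threshold_segment(vol, low, low + width).labels
        outer = threshold_segment(vol, low - widen, low + width + widen).labels
        assert np.all(outer >= inner)


# ---------------------------------------------------------------------------
# components
# ---------------------------------------------------------------------------

class TestSplit:
    def _labelmap(self, mask):
        return LabelMap(mask.astype(np.int32), (1, 1, 1), (0, 0, 0))

    def test_two_spheres_sorted_by_size(self):
        big = synthetic.icosphere(8.0, 3, center=(0, 0, 0))
        small = synthetic.icosphere(4.0, 3, center=(25, 0, 0))
        from plateforge.meshcore import concatenate
        vol = synthetic.voxelize_phantom(concatenate([big, small]),
                                         spacing=(1, 1, 1))
        mask = threshold_segment(vol, 300)
        labels = split_components(mask)
        present = labels.present_labels()
        assert list(present) == [1, 2]
        c1 = (labels.labels == 1).sum()
        c2 = (labels.labels == 2).sum()
        assert c1 > c2

    def test_diagonal_connectivity_semantics(self):
        mask = np.zeros((3, 3, 3), dtype=np.int32)
        mask[0, 0, 0] = 1
        mask[1, 1, 1] = 1
        lm = self._labelmap(mask)
        assert len(split_components(lm, 6).present_labels()) == 2
        assert len(split_components(lm, 26).present_labels()) == 1

    def test_nonbinary_rejected(self):
        lm = self._labelmap(np.full((2, 2, 2), 2))
        with pytest.raises(ValueError, match="binary"):
            split_components(lm)

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, connectivity, rng):
        for _ in range(3):
            mask = (rng.random((20, 20, 20)) < 0.25).astype(np.int32)
            lm = self._labelmap(mask)
            got = split_components(lm, connectivity).labels
            want = oracle_flood_fill(mask, connectivity)
            # same partition: bijection between label sets
            assert np.array_equal(got > 0, want > 0)
            pairs = set(zip(got[mask > 0].ravel(), want[mask > 0].ravel()))
            assert len(pairs) == len({a for a, _ in pairs})
            assert len(pairs) == len({b for _, b in pairs})

    def test_min_component_voxels_filter(self):
        mask = np.zeros((10, 4, 4), dtype=np.int32)
        mask[0:4] = 1            # 64 voxels
        mask[6, 0, 0] = 1        # speck
        lm = self._labelmap(mask)
        assert len(split_components(lm).present_labels()) == 2
        filtered = split_components(lm, min_component_voxels=5)
        assert list(filtered.present_labels()) == [1]
        assert (filtered.labels > 0).sum() == 64

    def test_partition_property(self, rng):
        mask = (rng.random((20, 20, 20)) < 0.3).astype(np.int32)
        lm = self._labelmap(mask)
        labels = split_components(lm)
        assert np.all((labels.labels > 0) == (mask > 0))
        present = labels.present_labels()
        assert list(present) == list(range(1, len(present) + 1))


class TestErase:
    def _three_blob_map(self):
        mask = np.zeros((12, 4, 4), dtype=np.int32)
        mask[0:4] = 1   # blob A: 64 voxels
        mask[5:8, :2, :2] = 1  # blob B: 12 voxels
        mask[9:12, :3, :3] = 1  # blob C: 27 voxels
        lm = LabelMap(mask, (1, 1, 1), (0, 0, 0))
        return split_components(lm)

    def test_erase_middle_relabels(self):
        labels = self._three_blob_map()
        assert list(labels.present_labels()) == [1, 2, 3]
        out = erase_labels(labels, {2})
        assert list(out.present_labels()) == [1, 2]
        # old label 3 became 2, same voxel count
        assert (out.labels == 2).sum() == (labels.labels == 3).sum()

    def test_erase_all(self):
        labels = self._three_blob_map()
        out = erase_labels(labels, {1, 2, 3})
        assert out.labels.sum() == 0

    def test_erase_none_identity(self):
        labels = self._three_blob_map()
        out = erase_labels(labels, set())
        assert np.array_equal(out.labels, labels.labels)

    def test_unknown_id_named(self):
        labels = self._three_blob_map()
        with pytest.raises(ValueError, match="7"):
            erase_labels(labels, {7})


# ---------------------------------------------------------------------------
# isosurface
# ---------------------------------------------------------------------------

class TestExtractSurface:
    def test_sphere_area_within_5pct(self):
        vol = sphere_volume(10.0, (0.5, 0.5, 0.5))
        labels = split_components(threshold_segment(vol, 300))
        mesh = extract_surface(labels, 1)
        assert mesh.is_watertight()
        assert mesh.surface_area() == pytest.approx(4 * np.pi * 100, rel=0.05)

    def test_volume_invariant(self):
        vol = sphere_volume(10.0, (0.5, 0.5, 0.5))
        labels = split_components(threshold_segment(vol, 300))
        mesh = extract_surface(labels, 1)
        voxel_est = (labels.labels == 1).sum() * vol.voxel_volume
        assert abs(mesh.volume()) == pytest.approx(voxel_est, rel=0.05)

    def test_single_voxel_watertight(self):
        mask = np.zeros((5, 5, 5), dtype=np.int32)
        mask[2, 2, 2] = 1
        lm = LabelMap(mask, (1, 1, 3), (0, 0, 0))
        mesh = extract_surface(lm, 1)
        assert mesh.is_watertight()
        assert mesh.volume() > 0

    def test_vertices_inside_dilated_bbox(self):
        vol = sphere_volume(8.0, (1, 1, 1))
        labels = split_components(threshold_segment(vol, 300))
        mesh = extract_surface(labels, 1)
        idx = np.array(np.nonzero(labels.labels == 1)).T
        lo = labels.origin + (idx.min(axis=0) - 1.5) * labels.spacing
        hi = labels.origin + (idx.max(axis=0) + 1.5) * labels.spacing
        assert np.all(mesh.vertices >= lo) and np.all(mesh.vertices <= hi)

    def test_absent_label_errors(self):
        lm = LabelMap(np.ones((3, 3, 3), dtype=np.int32), (1, 1, 1), (0, 0, 0))
        with pytest.raises(ValueError, match="label 5"):
            extract_surface(lm, 5)
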