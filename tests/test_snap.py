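"""Core refinement chain: extrusion, rough segmentation, z-floor,
largest-component cleanup, and the composed per-cell pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cellsnap import (
    CellMask3D,
    EmptyCellError,
    LabelImage2D,
    RunConfig,
    ShapeMismatchError,
    agreement,
    apply_z_floor,
    extrude_mask,
    generate,
    largest_component_2d,
    largest_component_3d,
    refine_cell,
    rough_segmentation,
    segment_cells,
    z_profile,
)
from cellsnap.snap import RoughCellVolume
from conftest import (
    floor_index_oracle,
    largest_component_oracle,
    make_tomogram,
)


def _labels(arr):
    return LabelImage2D(np.asarray(arr, dtype=np.int32))


class TestExtrude:
    def test_single_slice_identity(self):
        lab = _labels([[0, 1], [2, 0]])
        out = extrude_mask(lab, 1)
        np.testing.assert_array_equal(out[0], lab.labels)

    def test_voxel_count_conserved_over_208_slices(self):
        img = np.zeros((6, 6), dtype=np.int32)
        img[1:4, 2:6] = 2  # 12 pixels of label 2
        out = extrude_mask(_labels(img), 208)
        assert np.count_nonzero(out == 2) == 12 * 208

    def test_pointwise_equals_2d_labels(self):
        rng = np.random.default_rng(5)
        img = rng.integers(0, 4, size=(7, 9)).astype(np.int32)
        out = extrude_mask(_labels(img), 11)
        for _ in range(50):
            z, y, x = rng.integers((11, 7, 9))
            assert out[z, y, x] == img[y, x]


class TestRoughSegmentation:
    def _scene(self):
        vals = np.full((4, 6, 6), 1.337)
        vals[1:3, 1:3, 1:3] = 1.36  # cell 1 body
        vals[1:3, 4:6, 4:6] = 1.35  # cell 2 body
        img = np.zeros((6, 6), dtype=np.int32)
        img[0:4, 0:4] = 1
        img[3:6, 4:6] = 2
        tomo = make_tomogram(vals)
        return tomo, extrude_mask(_labels(img), 4)

    def test_equal_to_medium_is_removed(self):
        """Strict inequality: voxels exactly at the background RI are zeroed."""
        vals = np.full((3, 4, 4), 1.337)
        tomo = make_tomogram(vals)
        ext = extrude_mask(_labels(np.ones((4, 4), dtype=np.int32)), 3)
        rough = rough_segmentation(tomo, ext, 1)
        assert rough.n_voxels == 0

    def test_just_above_medium_is_retained_with_value(self):
        vals = np.full((2, 3, 3), 1.337)
        vals[0, 1, 1] = 1.347
        tomo = make_tomogram(vals)
        ext = extrude_mask(_labels(np.ones((3, 3), dtype=np.int32)), 2)
        rough = rough_segmentation(tomo, ext, 1)
        assert rough.values[0, 1, 1] == pytest.approx(1.347)
        assert rough.n_voxels == 1

    def test_other_cells_footprint_zeroed(self):
        tomo, ext = self._scene()
        rough1 = rough_segmentation(tomo, ext, 1)
        assert np.count_nonzero(rough1.values[:, 4:6, 4:6]) == 0
        rough2 = rough_segmentation(tomo, ext, 2)
        assert np.count_nonzero(rough2.values[:, 0:3, :]) == 0

    def test_inputs_not_mutated(self):
        tomo, ext = self._scene()
        before_t, before_e = tomo.values.copy(), ext.copy()
        rough_segmentation(tomo, ext, 1)
        rough_segmentation(tomo, ext, 2)
        np.testing.assert_array_equal(tomo.values, before_t)
        np.testing.assert_array_equal(ext, before_e)

    def test_unknown_label_raises(self):
        tomo, ext = self._scene()
        with pytest.raises(EmptyCellError, match="not present"):
            rough_segmentation(tomo, ext, 9)


def _rough_from_counts(counts):
    """Rough volume whose per-slice non-zero counts equal `counts`."""
    nmax = max(counts)
    vals = np.zeros((len(counts), 1, nmax))
    for z, c in enumerate(counts):
        vals[z, 0, :c] = 1.36
    return RoughCellVolume(values=vals, cell_label=1, medium_ri=1.337)


class TestZProfile:
    def test_worked_profile(self):
        """counts [2,5,10,10,8,1] -> normalized [.2,.5,1,1,.8,.1], floor 1."""
        prof = z_profile(_rough_from_counts([2, 5, 10, 10, 8, 1]), 0.5)
        np.testing.assert_allclose(prof.normalized, [0.2, 0.5, 1.0, 1.0, 0.8, 0.1])
        assert prof.floor_index == 1

    def test_constant_counts_floor_zero(self):
        assert z_profile(_rough_from_counts([4, 4, 4]), 0.5).floor_index == 0

    def test_monotone_rise_matches_half_of_final(self):
        counts = [1, 2, 3, 5, 8, 12, 20]
        prof = z_profile(_rough_from_counts(counts), 0.5)
        expected = next(i for i, c in enumerate(counts) if c >= 0.5 * counts[-1])
        assert prof.floor_index == expected

    def test_normalization_peaks_at_one(self):
        prof = z_profile(_rough_from_counts([3, 9, 6]), 0.5)
        assert prof.normalized.max() == 1.0
        assert np.all((0 <= prof.normalized) & (prof.normalized <= 1))

    @settings(max_examples=100, deadline=None)
    @given(
        counts=st.lists(st.integers(0, 40), min_size=1, max_size=20).filter(
            lambda c: sum(c) > 0
        ),
        fraction=st.floats(0.05, 1.0),
    )
    def test_matches_brute_force_scan(self, counts, fraction):
        prof = z_profile(_rough_from_counts(counts), fraction)
        assert prof.floor_index == floor_index_oracle(counts, fraction)

    def test_empty_volume_signals_empty_cell(self):
        with pytest.raises(EmptyCellError):
            z_profile(_rough_from_counts([0, 0]))


class TestApplyZFloor:
    def test_floor_zero_is_identity(self):
        rough = _rough_from_counts([2, 3, 4])
        out = apply_z_floor(rough, 0)
        np.testing.assert_array_equal(out.values, rough.values)

    def test_floor_at_top_keeps_only_top_slice(self):
        out = apply_z_floor(_rough_from_counts([2, 3, 4]), 2)
        assert np.count_nonzero(out.values[:2]) == 0
        assert np.count_nonzero(out.values[2]) == 4

    def test_per_slice_counts_preserved_at_and_above_floor(self):
        counts = [2, 5, 10, 10, 8, 1]
        out = apply_z_floor(_rough_from_counts(counts), 3)
        got = np.count_nonzero(out.values, axis=(1, 2))
        np.testing.assert_array_equal(got, [0, 0, 0, 10, 8, 1])


class TestLargestComponent:
    def test_empty_slice_stays_empty(self):
        out = largest_component_2d(np.zeros((4, 4), dtype=bool), 8)
        assert not out.any()

    def test_l_shape_beats_pair(self):
        grid = np.zeros((5, 5), dtype=bool)
        grid[0, 0] = grid[1, 0] = grid[1, 1] = True  # L of 3
        grid[3, 3] = grid[3, 4] = True  # pair of 2
        out = largest_component_2d(grid, 4)
        assert out.sum() == 3 and out[0, 0] and not out[3, 3]

    def test_tie_broken_by_raster_order(self):
        grid = np.zeros((6, 6), dtype=bool)
        grid[0, 4:6] = grid[1, 4:6] = True  # first raster pixel (0,4)
        grid[3, 0:2] = grid[4, 0:2] = True  # first raster pixel (3,0)
        out = largest_component_2d(grid, 8)
        assert out[0, 4] and not out[3, 0]

    def test_single_blob_unchanged_3d(self):
        blob = np.zeros((4, 4, 4), dtype=bool)
        blob[1:3, 1:3, 1:3] = True
        out = largest_component_3d(blob, 26)
        np.testing.assert_array_equal(out.mask, blob)

    def test_specks_removed_3d(self):
        rng = np.random.default_rng(11)
        vol = np.zeros((8, 10, 10), dtype=bool)
        vol[2:6, 3:8, 3:8] = True  # 100-voxel blob
        blob = vol.copy()
        # 5 isolated specks away from the blob
        for _ in range(5):
            z, y, x = rng.integers((8, 10, 10))
            if not blob[max(z - 1, 0) : z + 2, max(y - 1, 0) : y + 2, max(x - 1, 0) : x + 2].any():
                vol[z, y, x] = True
        out = largest_component_3d(vol, 26)
        np.testing.assert_array_equal(out.mask, blob)

    def test_diagonal_voxels_connectivity_dependent(self):
        vol = np.zeros((2, 2, 2), dtype=bool)
        vol[0, 0, 0] = vol[1, 1, 1] = True  # touch only corner-diagonally
        assert largest_component_3d(vol, 26).n_voxels == 2
        assert largest_component_3d(vol, 6).n_voxels == 1

    @settings(max_examples=60, deadline=None)
    @given(
        seed=st.integers(0, 2**31 - 1),
        conn=st.sampled_from([4, 8]),
        p=st.floats(0.2, 0.7),
    )
    def test_2d_matches_flood_fill_oracle(self, seed, conn, p):
        rng = np.random.default_rng(seed)
        grid = rng.random((rng.integers(1, 13), rng.integers(1, 13))) < p
        np.testing.assert_array_equal(
            largest_component_2d(grid, conn), largest_component_oracle(grid, conn)
        )

    @settings(max_examples=40, deadline=None)
    @given(
        seed=st.integers(0, 2**31 - 1),
        conn=st.sampled_from([6, 18, 26]),
        p=st.floats(0.1, 0.5),
    )
    def test_3d_matches_flood_fill_oracle(self, seed, conn, p):
        rng = np.random.default_rng(seed)
        vol = rng.random((rng.integers(1, 9), rng.integers(1, 9), rng.integers(1, 9))) < p
        np.testing.assert_array_equal(
            largest_component_3d(vol, conn).mask, largest_component_oracle(vol, conn)
        )


class TestSegmentCells:
    def test_isolated_phantom_single_component(self, isolated_scene, preset_config):
        tomo, truth = isolated_scene
        masks = segment_cells(tomo, LabelImage2D(truth.footprint_labels()), preset_config)
        assert len(masks) == 1
        rep = agreement(
            masks[0], CellMask3D(mask=truth.labels == 1, cell_label=1), tomo.geometry
        )
        assert rep.iou >= 0.95

    def test_debris_inside_footprint_ignored(self, suite, preset_config):
        """Specks inside the 2D footprint but detached from the body do not
        change the final mask."""
        from dataclasses import replace

        from cellsnap import DebrisSpec

        clean_spec = suite["isolated"]
        tomo_c, truth = generate(clean_spec)
        noisy_spec = replace(
            clean_spec,
            debris=DebrisSpec(count=20, radius_range_um=(0.15, 0.3), delta_n=0.03),
            seed=77,
        )
        tomo_n, _ = generate(noisy_spec)
        seeds = LabelImage2D(truth.footprint_labels())
        m_clean = segment_cells(tomo_c, seeds, preset_config)[0]
        m_noisy = segment_cells(tomo_n, seeds, preset_config)[0]
        np.testing.assert_array_equal(m_clean.mask, m_noisy.mask)

    def test_empty_label_image_gives_empty_list(self, isolated_scene, preset_config):
        tomo, _ = isolated_scene
        seeds = LabelImage2D(np.zeros(tomo.shape[1:], dtype=np.int32))
        assert segment_cells(tomo, seeds, preset_config) == []

    def test_shape_mismatch_raises(self, isolated_scene, preset_config):
        tomo, _ = isolated_scene
        seeds = LabelImage2D(np.zeros((4, 4), dtype=np.int32))
        with pytest.raises(ShapeMismatchError):
            segment_cells(tomo, seeds, preset_config)

    def test_empty_cell_skipped_with_warning(self, isolated_scene, preset_config):
        tomo, truth = isolated_scene
        seeds = truth.footprint_labels().copy()
        seeds[:4, :4] = 9  # footprint over pure background
        with pytest.warns(UserWarning, match="skipping cell 9"):
            masks = segment_cells(tomo, LabelImage2D(seeds), preset_config)
        assert [m.cell_label for m in masks] == [1]


class TestPipelineInvariants:
    @pytest.fixture(scope="class", params=["isolated", "clumped_pair", "fringe",
                                           "debris_field", "rough_floor"])
    def scene(self, request, suite):
        spec = suite[request.param]
        tomo, truth = generate(spec)
        config = RunConfig(geometry=spec.geometry)
        seeds = LabelImage2D(truth.footprint_labels())
        masks = segment_cells(tomo, seeds, config)
        return tomo, truth, config, seeds, masks

    def test_monotone_shrinkage(self, scene):
        """final mask is contained in the rough support, which is contained in
        the extruded footprint."""
        tomo, truth, config, seeds, masks = scene
        ext = extrude_mask(seeds, tomo.n_slices)
        for m in masks:
            rough = rough_segmentation(tomo, ext, m.cell_label)
            assert np.all(~m.mask | rough.support)
            assert np.all(~rough.support | (ext == m.cell_label))

    def test_output_purity(self, scene):
        """Every retained voxel has RI strictly above the medium."""
        tomo, _, _, _, masks = scene
        for m in masks:
            assert np.all(tomo.values[m.mask] > tomo.medium_ri)

    def test_single_component_guarantee(self, scene):
        from scipy import ndimage as ndi

        tomo, _, config, _, masks = scene
        structure = ndi.generate_binary_structure(3, 3)
        for m in masks:
            _, n = ndi.label(m.mask, structure=structure)
            assert n == 1

    def test_idempotence_of_resegmentation(self, scene):
        """Masking the tomogram with a final mask and re-running the chain
        returns the same mask."""
        tomo, _, config, _, masks = scene
        for m in masks:
            remasked = make_tomogram(
                np.where(m.mask, tomo.values, tomo.medium_ri),
                medium_ri=tomo.medium_ri,
                geometry=tomo.geometry,
            )
            ext = extrude_mask(LabelImage2D(m.mask.max(axis=0).astype(np.int32) * m.cell_label),
                               tomo.n_slices)
            again, _ = refine_cell(remasked, ext, m.cell_label, config)
            np.testing.assert_array_equal(again.mask, m.mask)

    def test_per_cell_order_independence(self, scene):
        """Processing cells in reversed order (via reversed label ids) yields
        identical per-cell masks."""
        tomo, _, config, seeds, masks = scene
        labs = seeds.cell_labels
        relabel = dict(zip(labs, reversed(labs)))
        permuted = np.zeros_like(seeds.labels)
        for old, new in relabel.items():
            permuted[seeds.labels == old] = new
        again = segment_cells(tomo, LabelImage2D(permuted), config)
        by_label = {m.cell_label: m for m in again}
        for m in masks:
            np.testing.assert_array_equal(m.mask, by_label[relabel[m.cell_label]].mask)
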