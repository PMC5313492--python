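"""Unit and property tests for the index imaging pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petburden import (
    BoneMask,
    Ellipsoid,
    Grid,
    PhantomSpec,
    SphereLesion,
    HotspotSet,
    ImageVolume,
    PetburdenError,
    SUVMap,
    apply_classification,
    baseline_bone_mask_from_ct,
    compute_index,
    detect_hotspots,
    filter_by_bone_overlap,
    gaussian_smooth,
    resample_mask_to_grid,
    run_pipeline,
)
from petburden.phantom import generate_phantom

from conftest import full_mask, sphere_suv


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

class TestVolumeTypes:
    def test_rejects_nonpositive_spacing(self):
        with pytest.raises(PetburdenError):
            ImageVolume(np.zeros((2, 2, 2)), (1.0, 0.0, 1.0))

    def test_rejects_nonfinite_values(self):
        vals = np.zeros((2, 2, 2))
        vals[0, 0, 0] = np.nan
        with pytest.raises(PetburdenError):
            ImageVolume(vals, (1.0, 1.0, 1.0))

    def test_rejects_negative_suv(self):
        with pytest.raises(PetburdenError):
            SUVMap(np.full((2, 2, 2), -1.0), (1.0, 1.0, 1.0))

    def test_rejects_nonbinary_mask(self):
        with pytest.raises(PetburdenError):
            BoneMask(np.full((2, 2, 2), 2.0), (1.0, 1.0, 1.0))

    def test_voxel_and_bone_volume(self):
        mask = BoneMask(np.ones((3, 3, 3)), (2.0, 3.0, 4.0))
        assert mask.voxel_volume_mm3 == 24.0
        assert mask.bone_volume_mm3 == 27 * 24.0


# --------------------------------------------------------------------------
# gaussian_smooth
# --------------------------------------------------------------------------

class TestGaussianSmooth:
    def test_constant_volume_is_fixed_point(self):
        suv = SUVMap(np.full((15, 15, 15), 5.0), (1.0, 1.0, 1.0))
        out = gaussian_smooth(suv, 2.0)
        np.testing.assert_allclose(out.values, 5.0, atol=1e-12)

    def test_sigma_zero_is_identity(self, simple_suv):
        out = gaussian_smooth(simple_suv, 0.0)
        assert np.array_equal(out.values, simple_suv.values)

    def test_negative_sigma_rejected(self, simple_suv):
        with pytest.raises(PetburdenError):
            gaussian_smooth(simple_suv, -1.0)

    def test_impulse_matches_bruteforce_convolution(self):
        """Oracle: explicit truncated-kernel convolution, voxel by voxel."""
        n, sigma = 21, 2.0
        vals = np.zeros((n, n, n))
        vals[10, 10, 10] = 1.0
        suv = SUVMap(vals, (1.0, 1.0, 1.0))
        out = gaussian_smooth(suv, sigma)

        radius = int(4.0 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        w1 = np.exp(-0.5 * (x / sigma) ** 2)
        w1 /= w1.sum()
        kernel = w1[:, None, None] * w1[None, :, None] * w1[None, None, :]
        padded = np.pad(vals, radius, mode="reflect")
        expected = np.empty_like(vals)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    window = padded[i:i + 2 * radius + 1,
                                    j:j + 2 * radius + 1,
                                    k:k + 2 * radius + 1]
                    expected[i, j, k] = (window * kernel).sum()
        np.testing.assert_allclose(out.values, expected, atol=1e-6)

    def test_anisotropic_grid_smooths_in_physical_space(self):
        # physical-space sigma: the per-axis voxel sigma differs with spacing
        vals = np.zeros((21, 21, 21))
        vals[10, 10, 10] = 1.0
        wide = gaussian_smooth(SUVMap(vals, (1.0, 2.0, 4.0)), 4.0)
        # spread (in voxels) must be widest along the finest axis
        marg0 = wide.values.sum(axis=(1, 2))
        marg2 = wide.values.sum(axis=(0, 1))
        std0 = np.sqrt((marg0 * (np.arange(21) - 10) ** 2).sum() / marg0.sum())
        std2 = np.sqrt((marg2 * (np.arange(21) - 10) ** 2).sum() / marg2.sum())
        assert std0 > std2  # sigma 4 mm = 4 voxels on axis 0, 1 voxel on axis 2

    def test_total_intensity_conserved(self, simple_suv):
        vals = simple_suv.values.copy()
        vals[5, 5, 5] = 30.0
        out = gaussian_smooth(SUVMap(vals, simple_suv.spacing_mm), 2.0)
        assert out.values.sum() == pytest.approx(vals.sum(), rel=1e-10)
        assert (out.values >= 0).all()


# --------------------------------------------------------------------------
# detect_hotspots
# --------------------------------------------------------------------------

class TestDetectHotspots:
    def test_nothing_above_threshold(self, simple_suv):
        assert len(detect_hotspots(simple_suv, 15.0)) == 0

    def test_nonpositive_threshold_rejected(self, simple_suv):
        with pytest.raises(PetburdenError):
            detect_hotspots(simple_suv, 0.0)

    def test_sphere_voxel_count_matches_center_in_sphere_oracle(self):
        shape, spacing = (24, 24, 24), (2.0, 2.0, 2.0)
        center, radius = (24.0, 24.0, 24.0), 6.0
        suv = sphere_suv(shape, spacing, center, radius, plateau=20.0)
        hits = detect_hotspots(suv, 15.0)
        assert len(hits) == 1
        # oracle: exhaustive voxel-center-in-sphere test
        count = 0
        for i in range(shape[0]):
            for j in range(shape[1]):
                for k in range(shape[2]):
                    d2 = ((i * 2 - 24) ** 2 + (j * 2 - 24) ** 2 + (k * 2 - 24) ** 2)
                    count += d2 <= radius**2
        assert hits.hotspots[0].voxel_count == count
        assert hits.hotspots[0].volume_mm3 == count * 8.0
        assert hits.hotspots[0].peak_suv == 20.0

    def test_two_separated_spheres_are_two_disjoint_hotspots(self):
        suv = sphere_suv((30, 30, 30), (2.0, 2.0, 2.0), (12, 12, 12), 5.0, 20.0)
        vals = suv.values
        grids = np.meshgrid(*[np.arange(30) * 2.0] * 3, indexing="ij")
        d2 = sum((g - 46.0) ** 2 for g in grids)
        vals[d2 <= 25.0] = 20.0
        hits = detect_hotspots(SUVMap(vals, (2.0, 2.0, 2.0)), 15.0)
        assert len(hits) == 2
        sets = [set(map(tuple, h.voxels)) for h in hits]
        assert not sets[0] & sets[1]

    def test_strict_threshold_excludes_exact_value(self):
        vals = np.ones((5, 5, 5))
        vals[2, 2, 2] = 15.0
        assert len(detect_hotspots(SUVMap(vals, (1, 1, 1)), 15.0)) == 0
        assert len(detect_hotspots(SUVMap(vals, (1, 1, 1)), 15.0, inclusive=True)) == 1

    def test_ids_follow_raster_order_of_first_voxel(self):
        vals = np.ones((10, 10, 10))
        vals[7, 1, 1] = 20.0   # later in raster order
        vals[1, 8, 8] = 20.0   # earlier (axis 0 dominates)
        hits = detect_hotspots(SUVMap(vals, (1, 1, 1)), 15.0)
        assert hits.ids == [1, 2]
        assert tuple(hits.hotspots[0].voxels[0]) == (1, 8, 8)
        assert tuple(hits.hotspots[1].voxels[0]) == (7, 1, 1)

    def test_fully_supra_threshold_volume_is_one_hotspot_with_warning(self):
        suv = SUVMap(np.full((6, 6, 6), 30.0), (1, 1, 1))
        with pytest.warns(UserWarning, match="supra-threshold"):
            hits = detect_hotspots(suv, 15.0)
        assert len(hits) == 1
        assert hits.hotspots[0].voxel_count == 216

    def test_raising_threshold_never_increases_detected_volume(self):
        rng = np.random.default_rng(5)
        suv = SUVMap(rng.gamma(2.0, 2.0, (16, 16, 16)), (2, 2, 2))
        vols = [
            detect_hotspots(suv, thr).total_volume_mm3
            for thr in (2.0, 4.0, 6.0, 8.0, 10.0)
        ]
        assert all(a >= b for a, b in zip(vols, vols[1:]))


# --------------------------------------------------------------------------
# resample_mask_to_grid
# --------------------------------------------------------------------------

class TestResampleMask:
    def test_identity_on_own_grid(self):
        rng = np.random.default_rng(0)
        mask = BoneMask(rng.integers(0, 2, (9, 9, 9)), (2.0, 2.0, 2.0), (1.0, -3.0, 0.5))
        out = resample_mask_to_grid(mask, mask.grid)
        assert np.array_equal(out.values, mask.values)

    def test_all_ones_to_interior_finer_grid(self):
        mask = full_mask((8, 8, 8), (4.0, 4.0, 4.0))
        target = Grid((10, 10, 10), (2.0, 2.0, 2.0), (4.0, 4.0, 4.0))
        out = resample_mask_to_grid(mask, target)
        assert out.values.all()

    def test_checkerboard_matches_per_voxel_nearest_center_oracle(self):
        idx = np.indices((6, 6, 6)).sum(axis=0)
        mask = BoneMask((idx % 2).astype(np.uint8), (4.0, 4.0, 4.0))
        target = Grid((11, 11, 11), (2.0, 2.0, 2.0), (1.0, 1.0, 1.0))
        out = resample_mask_to_grid(mask, target)
        for i in range(11):
            for j in range(11):
                for k in range(11):
                    expected = 0
                    src = []
                    ok = True
                    for axis, t in zip(range(3), (i, j, k)):
                        world = 1.0 + t * 2.0
                        frac = world / 4.0
                        s = int(np.floor(frac + 0.5))
                        if not (0 <= s < 6):
                            ok = False
                        src.append(min(max(s, 0), 5))
                    if ok:
                        expected = mask.values[tuple(src)]
                    assert out.values[i, j, k] == expected

    def test_disjoint_extent_gives_empty_mask_and_warning(self):
        mask = full_mask((4, 4, 4), (1.0, 1.0, 1.0))
        target = Grid((4, 4, 4), (1.0, 1.0, 1.0), (100.0, 100.0, 100.0))
        with pytest.warns(UserWarning, match="outside"):
            out = resample_mask_to_grid(mask, target)
        assert not out.values.any()


# --------------------------------------------------------------------------
# filter_by_bone_overlap / apply_classification
# --------------------------------------------------------------------------

def _scene_with_straddling_hotspot():
    """One 3-voxel hotspot with exactly 1 voxel inside the bone mask."""
    vals = np.ones((8, 8, 8))
    vals[4, 4, 2:5] = 20.0
    suv = SUVMap(vals, (2.0, 2.0, 2.0))
    bone = np.zeros((8, 8, 8), dtype=np.uint8)
    bone[:, :, :3] = 1  # only voxel (4,4,2) of the hotspot is in bone
    return detect_hotspots(suv, 15.0), BoneMask(bone, (2.0, 2.0, 2.0))


class TestBoneOverlapFilter:
    def test_hotspot_inside_bone_kept_with_full_volume(self):
        suv = sphere_suv((16, 16, 16), (2.0, 2.0, 2.0), (16, 16, 16), 5.0, 20.0)
        hits = detect_hotspots(suv, 15.0)
        kept = filter_by_bone_overlap(hits, full_mask((16, 16, 16), (2.0, 2.0, 2.0)))
        assert len(kept) == 1
        assert kept.hotspots[0].overlaps_bone
        assert kept.hotspots[0].volume_mm3 == hits.hotspots[0].volume_mm3

    def test_zero_overlap_hotspot_removed(self):
        hits, bone = _scene_with_straddling_hotspot()
        empty_bone = BoneMask(np.zeros((8, 8, 8), dtype=np.uint8), (2.0, 2.0, 2.0))
        assert len(filter_by_bone_overlap(hits, empty_bone)) == 0

    def test_straddling_hotspot_full_vs_intersection_volume(self):
        hits, bone = _scene_with_straddling_hotspot()
        assert hits.hotspots[0].voxel_count == 3
        full = filter_by_bone_overlap(hits, bone, volume_mode="full")
        inter = filter_by_bone_overlap(hits, bone, volume_mode="intersection")
        voxvol = 8.0
        assert full.hotspots[0].volume_mm3 == 3 * voxvol
        # oracle: explicit voxel-set intersection
        in_bone = [v for v in map(tuple, hits.hotspots[0].voxels) if bone.values[v]]
        assert inter.hotspots[0].volume_mm3 == len(in_bone) * voxvol == 1 * voxvol
        assert full.hotspots[0].hotspot_id == inter.hotspots[0].hotspot_id

    def test_grid_mismatch_rejected(self):
        hits, _ = _scene_with_straddling_hotspot()
        other = full_mask((8, 8, 8), (1.0, 1.0, 1.0))
        with pytest.raises(PetburdenError):
            filter_by_bone_overlap(hits, other)


class TestApplyClassification:
    @pytest.fixture
    def three_hotspots(self):
        vals = np.ones((12, 12, 12))
        vals[1, 1, 1] = 20.0
        vals[5, 5, 5:7] = 20.0
        vals[9, 9, 6:9] = 20.0
        return detect_hotspots(SUVMap(vals, (1, 1, 1)), 15.0)

    def test_partial_labels_sum_only_metastases(self, three_hotspots):
        labeled = apply_classification(
            three_hotspots, {1: "metastasis", 2: "benign", 3: "metastasis"}
        )
        vols = {h.hotspot_id: h.volume_mm3 for h in three_hotspots}
        included = [h for h in labeled if h.label == "metastasis"]
        assert sum(h.volume_mm3 for h in included) == vols[1] + vols[3]

    def test_all_benign_leaves_empty_inclusion(self, three_hotspots):
        labeled = apply_classification(
            three_hotspots, {i: "benign" for i in (1, 2, 3)}
        )
        assert not [h for h in labeled if h.label == "metastasis"]

    def test_unknown_id_error_lists_offenders(self, three_hotspots):
        with pytest.raises(PetburdenError, match=r"\[7\]"):
            apply_classification(three_hotspots, {7: "benign"})

    def test_duplicate_id_error(self, three_hotspots):
        with pytest.raises(PetburdenError, match="duplicate"):
            apply_classification(three_hotspots, [(1, "benign"), (1, "metastasis")])

    def test_unlabeled_default_to_metastasis_with_warning(self, three_hotspots):
        with pytest.warns(UserWarning, match="unlabeled"):
            labeled = apply_classification(three_hotspots, {2: "benign"})
        assert [h.label for h in labeled] == ["metastasis", "benign", "metastasis"]
        with pytest.raises(PetburdenError, match="missing"):
            apply_classification(three_hotspots, {2: "benign"}, require_complete=True)


# --------------------------------------------------------------------------
# compute_index
# --------------------------------------------------------------------------

def _singleton_set(volume_mm3, threshold=15.0):
    from petburden.imaging import Hotspot

    h = Hotspot(1, 1, volume_mm3, 20.0, (0, 0, 0), True, "metastasis",
                np.zeros((1, 3), dtype=np.int32))
    return HotspotSet([h], Grid((4, 4, 4), (1, 1, 1)), threshold)


class TestComputeIndex:
    def test_empty_set_gives_zero(self):
        empty = HotspotSet([], Grid((4, 4, 4), (1, 1, 1)), 15.0)
        assert compute_index(empty, 1000.0).index_percent == 0.0

    def test_stated_arithmetic(self):
        res = compute_index(_singleton_set(1000.0), 330_000.0, 0.33)
        assert res.index_percent == pytest.approx(0.1, abs=1e-12)

    def test_hotspot_volume_equal_to_bone_volume_gives_33_percent(self):
        res = compute_index(_singleton_set(250_000.0), 250_000.0, 0.33)
        assert res.index_percent == 33.0

    def test_nonpositive_bone_volume_rejected(self):
        with pytest.raises(PetburdenError):
            compute_index(_singleton_set(10.0), 0.0)

    def test_bad_skeletal_fraction_rejected(self):
        with pytest.raises(PetburdenError):
            compute_index(_singleton_set(10.0), 100.0, 1.5)

    @given(st.floats(0.05, 1.0), st.integers(1, 4))
    @settings(max_examples=30, deadline=None)
    def test_scale_equivariance_in_skeletal_fraction(self, fraction, k):
        # multiplying the fraction by k multiplies the index by k
        if fraction * k > 1:
            return
        base = compute_index(_singleton_set(5000.0), 90_000.0, fraction)
        scaled = compute_index(_singleton_set(5000.0), 90_000.0, fraction * k)
        assert scaled.index_percent == pytest.approx(
            k * base.index_percent, rel=1e-12)


# --------------------------------------------------------------------------
# baseline bone mask
# --------------------------------------------------------------------------

class TestBaselineBoneMask:
    def test_all_air_is_empty(self):
        ct = ImageVolume(np.full((10, 10, 10), -1000.0), (2, 2, 2))
        assert not baseline_bone_mask_from_ct(ct).values.any()

    def test_ellipsoid_recovered_exactly(self):
        shape, spacing = (20, 20, 20), (2.0, 2.0, 2.0)
        grids = np.meshgrid(*[np.arange(n) * 2.0 for n in shape], indexing="ij")
        inside = (
            ((grids[0] - 20) / 12) ** 2
            + ((grids[1] - 20) / 10) ** 2
            + ((grids[2] - 20) / 8) ** 2
        ) <= 1.0
        ct_vals = np.where(inside, 1000.0, -1000.0)
        mask = baseline_bone_mask_from_ct(ImageVolume(ct_vals, spacing))
        assert np.array_equal(mask.values.astype(bool), inside)

    def test_small_speck_removed(self):
        vals = np.full((10, 10, 10), -1000.0)
        vals[2, 2, 2:5] = 1000.0  # 3 voxels * 8 mm3 = 24 mm3 < 500
        mask = baseline_bone_mask_from_ct(ImageVolume(vals, (2, 2, 2)))
        assert not mask.values.any()


# --------------------------------------------------------------------------
# run_pipeline
# --------------------------------------------------------------------------

class TestRunPipeline:
    def test_zero_lesion_phantom_gives_zero_index(self, two_lesion_phantom_spec):
        spec = two_lesion_phantom_spec
        spec.lesions = []
        suv, bone, _ = generate_phantom(spec)
        res, _ = run_pipeline(suv, bone, "auto", sigma_mm=0.0)
        assert res.index_percent == 0.0
        assert res.n_hotspots_detected == 0

    def test_out_of_bone_lesion_excluded(self, two_lesion_phantom_spec):
        suv, bone, _ = generate_phantom(two_lesion_phantom_spec)
        res, _ = run_pipeline(suv, bone, "auto", sigma_mm=0.0)
        assert res.n_hotspots_detected == 2
        assert res.n_hotspots_included == 1

    def test_manual_mode_benign_label_zeroes_index(self, two_lesion_phantom_spec):
        suv, bone, _ = generate_phantom(two_lesion_phantom_spec)
        with pytest.warns(UserWarning, match="unlabeled"):
            _, surviving = run_pipeline(suv, bone, "manual", threshold_suv=7.0,
                                        sigma_mm=0.0)
        labels = {h.hotspot_id: "benign" for h in surviving}
        res, _ = run_pipeline(suv, bone, "manual", threshold_suv=7.0,
                              sigma_mm=0.0, labels=labels)
        assert res.index_percent == 0.0

    def test_auto_mode_rejects_labels(self, two_lesion_phantom_spec):
        suv, bone, _ = generate_phantom(two_lesion_phantom_spec)
        with pytest.raises(PetburdenError, match="labels"):
            run_pipeline(suv, bone, "auto", labels={1: "benign"})

    def test_manual_mode_requires_threshold_and_warns_outside_range(
        self, two_lesion_phantom_spec
    ):
        suv, bone, _ = generate_phantom(two_lesion_phantom_spec)
        with pytest.raises(PetburdenError):
            run_pipeline(suv, bone, "manual")
        with pytest.warns(UserWarning, match="plausible"):
            run_pipeline(suv, bone, "manual", threshold_suv=14.0, sigma_mm=0.0)

    def test_empty_bone_mask_is_hard_error(self, simple_suv):
        empty = BoneMask(np.zeros((20, 20, 20), dtype=np.uint8), (2, 2, 2))
        with pytest.raises(PetburdenError, match="empty"):
            run_pipeline(simple_suv, empty, "auto")

    def test_adding_metastatic_hotspot_never_decreases_index(self):
        base = PhantomSpec(
            shape=(32, 32, 32), pet_spacing_mm=(2, 2, 2), ct_spacing_mm=(2, 2, 2),
            bones=[Ellipsoid((32, 32, 32), (24, 20, 16))],
            lesions=[SphereLesion((26, 32, 32), 6.0, 20.0)],
        )
        suv1, bone1, _ = generate_phantom(base)
        res1, _ = run_pipeline(suv1, bone1, "auto", sigma_mm=0.0)
        base.lesions = list(base.lesions) + [SphereLesion((42, 32, 32), 5.0, 20.0)]
        suv2, bone2, _ = generate_phantom(base)
        res2, _ = run_pipeline(suv2, bone2, "auto", sigma_mm=0.0)
        assert res2.index_percent >= res1.index_percent
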