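"""VOI placement: fixed-plane rule, vessel avoidance, hotspot confirmation."""

import numpy as np
import pytest

from petmuscle import (
    HotspotParams,
    PatternSpec,
    SubjectParams,
    SUVVolume,
    confirm_candidate,
    generate_phantom,
    place_fixed_voi,
    place_hotspot_voi,
    sphere_voxels,
    suv_stats,
    to_suv,
)
from petmuscle.voi import fixed_target_plane

from conftest import make_cylinder_region


def uniform_suv(region, value=1.0):
    return SUVVolume(np.where(region.mask, value, 0.0), region.grid)


class TestFixedPlacement:
    def test_target_plane_is_bone_midpoint(self):
        region = make_cylinder_region(height_mm=400.0)
        point, _ = fixed_target_plane(region, fraction=0.5)
        assert point[2] == pytest.approx(200.0)

    def test_centroid_feasible_without_vessels(self):
        region = make_cylinder_region(radius_mm=30.0, height_mm=200.0)
        voi = place_fixed_voi(region, 20.0)
        # cylinder axis passes through (0, 0); mid-plane at z = 100
        assert voi.center_mm[0] == pytest.approx(0.0, abs=1e-9)
        assert voi.center_mm[1] == pytest.approx(0.0, abs=1e-9)
        assert abs(voi.center_mm[2] - 100.0) <= region.grid.spacing / 2

    def test_vessel_through_centroid_forces_minimal_shift(self):
        region = make_cylinder_region(radius_mm=30.0, height_mm=200.0)
        grid = region.grid
        xs = grid.axis_centers(0)[:, None, None]
        ys = grid.axis_centers(1)[None, :, None]
        vessel = np.broadcast_to((xs**2 + ys**2) <= 4.0**2, grid.shape).copy()
        voi = place_fixed_voi(region, 20.0, vessel_mask=vessel)

        # the returned sphere touches no vessel voxel and stays in-muscle
        idx = sphere_voxels(voi.center_mm, voi.diameter_mm, grid)
        assert not vessel[tuple(idx.T)].any()
        assert region.mask[tuple(idx.T)].all()

        # brute-force oracle: scan every voxel center for feasibility and take
        # the one closest to the mid-plane centroid (the cylinder axis)
        centroid = np.array([0.0, 0.0, 100.0])
        best_d = np.inf
        cand = np.argwhere(region.mask)
        for v in cand:
            c = grid.index_to_world(v)
            if abs(c[2] - 100.0) > 0.1 * region.bone_length_mm:
                continue
            try:
                s = sphere_voxels(c, 20.0, grid)
            except Exception:
                continue
            if region.mask[tuple(s.T)].all() and not vessel[tuple(s.T)].any():
                best_d = min(best_d, np.linalg.norm(c - centroid))
        assert np.linalg.norm(np.asarray(voi.center_mm) - centroid) == pytest.approx(best_d)

    def test_infeasible_diameter_raises(self):
        region = make_cylinder_region(radius_mm=10.0, height_mm=60.0)
        from petmuscle import PlacementError

        with pytest.raises(PlacementError, match="quadriceps"):
            place_fixed_voi(region, 40.0)

    def test_deterministic(self):
        region = make_cylinder_region()
        a = place_fixed_voi(region, 20.0)
        b = place_fixed_voi(region, 20.0)
        assert a == b


class TestConfirmation:
    def test_constant_field_confirms_interior_candidates(self):
        region = make_cylinder_region(radius_mm=20.0, height_mm=100.0)
        suv = uniform_suv(region, 1.0)
        center_idx = region.grid.world_to_index((0.0, 0.0, 50.0))
        assert confirm_candidate(suv, center_idx, region.mask, HotspotParams())

    def test_isolated_single_slice_spike_rejected(self):
        region = make_cylinder_region(radius_mm=20.0, height_mm=100.0)
        values = np.where(region.mask, 0.001, 0.0)
        spike_idx = tuple(region.grid.world_to_index((0.0, 0.0, 48.0)))
        values[spike_idx] = 5.0
        suv = SUVVolume(values, region.grid)
        assert not confirm_candidate(suv, spike_idx, region.mask, HotspotParams(tau=0.8))

    def test_plateau_spanning_slices_confirms_at_center(self):
        region = make_cylinder_region(radius_mm=20.0, height_mm=100.0)
        values = np.where(region.mask, 1.0, 0.0)
        zs = region.grid.axis_centers(2)
        plateau = (zs >= 40.0) & (zs <= 60.0)  # 5+ slices at 4 mm
        values[:, :, plateau] = np.where(region.mask[:, :, plateau], 3.0, 0.0)
        suv = SUVVolume(values, region.grid)
        center_idx = region.grid.world_to_index((0.0, 0.0, 50.0))
        assert confirm_candidate(suv, center_idx, region.mask, HotspotParams())

    def test_edge_candidate_without_k_slices_on_either_side_rejected(self):
        # grid only 1 slice thick beyond the candidate on each side
        region = make_cylinder_region(radius_mm=20.0, height_mm=4.0, pad_mm=4.0)
        suv = uniform_suv(region, 1.0)
        center_idx = region.grid.world_to_index((0.0, 0.0, 4.0))
        assert not confirm_candidate(suv, center_idx, region.mask, HotspotParams(k_slices=2))


class TestHotspotPlacement:
    def test_recovers_focus_center_of_noiseless_unifocal_phantom(self, atlas):
        subj = SubjectParams(weight_kg=70.0, dose_mbq=350.0)
        spec = {("quadriceps", "R"): PatternSpec("unifocal", 1, 2.0, 14.0)}
        ph = generate_phantom(atlas, subj, spec, seed=11, psf_fwhm_mm=0.0, noise_coeff=0.0)
        suv = to_suv(ph.activity, 350.0, 70.0, atlas.grid)
        region = atlas.region("quadriceps", "R")
        voi = place_hotspot_voi(suv, region, 20.0, vessel_mask=atlas.vessel_mask)
        true_center = ph.truth[("quadriceps", "R")].focus_centers[0]
        # brute-force oracle: global in-muscle argmax
        masked = np.where(region.mask, suv.values, -np.inf)
        oracle_idx = np.unravel_index(np.argmax(masked), masked.shape)
        oracle_center = atlas.grid.index_to_world(oracle_idx)
        assert np.linalg.norm(np.asarray(voi.center_mm) - oracle_center) <= atlas.grid.spacing
        assert np.linalg.norm(np.asarray(voi.center_mm) - true_center) <= atlas.grid.spacing

    def test_uniform_muscle_hotspot_equals_fixed_statistics(self):
        region = make_cylinder_region(radius_mm=30.0, height_mm=200.0)
        suv = uniform_suv(region, 1.3)
        voi_f = place_fixed_voi(region, 20.0)
        voi_h = place_hotspot_voi(suv, region, 20.0)
        st_f = suv_stats(suv, voi_f.center_mm, 20.0)
        st_h = suv_stats(suv, voi_h.center_mm, 20.0)
        assert st_h.suv_max == st_f.suv_max
        assert st_h.suv_mean == pytest.approx(st_f.suv_mean)

    def test_single_slice_spike_rejected_in_favor_of_broad_focus(self):
        region = make_cylinder_region(radius_mm=30.0, height_mm=200.0)
        grid = region.grid
        values = np.where(region.mask, 1.0, 0.0)
        # broad secondary focus: plateau value 2 spanning z in [120, 140]
        zs = grid.axis_centers(2)
        broad = (zs >= 120.0) & (zs <= 140.0)
        sel = region.mask[:, :, broad]
        block = values[:, :, broad]
        block[sel] = 2.0
        values[:, :, broad] = block
        # single-slice artificial spike, hotter than the focus
        spike_idx = tuple(grid.world_to_index((0.0, 0.0, 48.0)))
        values[spike_idx] = 5.0
        suv = SUVVolume(values, grid)
        voi = place_hotspot_voi(suv, region, 20.0, HotspotParams(k_slices=2, tau=0.8))
        assert not voi.fallback
        assert 120.0 - grid.spacing <= voi.center_mm[2] <= 140.0 + grid.spacing

    def test_fallback_when_muscle_too_thin_for_confirmation_is_flagged(self):
        # a two-slice muscle can never provide k=2 supporting slices on one
        # side, so no candidate confirms and the global maximum is used
        region = make_cylinder_region(radius_mm=30.0, height_mm=4.0)
        suv = uniform_suv(region, 1.0)
        voi = place_hotspot_voi(suv, region, 6.0, HotspotParams(k_slices=2))
        assert voi.fallback
        idx = sphere_voxels(voi.center_mm, voi.diameter_mm, region.grid)
        assert region.mask[tuple(idx.T)].all()

    def test_hotspot_dominates_fixed_on_discrete_focus_phantom(self, atlas):
        subj = SubjectParams(weight_kg=70.0, dose_mbq=350.0)
        spec = {("hamstrings", "L"): PatternSpec("multifocal", 2, 2.0, 10.0)}
        ph = generate_phantom(atlas, subj, spec, seed=21, psf_fwhm_mm=0.0, noise_coeff=0.0)
        suv = to_suv(ph.activity, 350.0, 70.0, atlas.grid)
        region = atlas.region("hamstrings", "L")
        voi_h = place_hotspot_voi(suv, region, 20.0, vessel_mask=atlas.vessel_mask)
        voi_f = place_fixed_voi(region, 20.0, vessel_mask=atlas.vessel_mask)
        st_h = suv_stats(suv, voi_h.center_mm, 20.0)
        st_f = suv_stats(suv, voi_f.center_mm, 20.0)
        assert st_h.suv_peak >= st_f.suv_peak - 1e-12
        assert st_h.suv_peak <= st_h.suv_max + 1e-12


def test_hotspot_params_validation():
    with pytest.raises(ValueError):
        HotspotParams(k_slices=0)
    with pytest.raises(ValueError):
        HotspotParams(tau=0.0)
    with pytest.raises(ValueError):
        HotspotParams(tau=1.2)
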