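"""Signal splitting, leakage ratio, compartments, perfused density."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from avleak import leakage, phantom
from avleak.leakage import (
    CompartmentMap,
    is_perfused,
    leakage_ratio,
    perfused_density,
    segment_compartments,
    split_signal,
)
from avleak.paths import VesselPath
from avleak.phantom import PhantomSpec, PhantomTruth, PlannedLeak
from avleak.stack import ImageStack
from avleak.tracing import LumenMask
from oracles import point_in_polygon


def _mask_like(data_shape, mask):
    owner = np.where(mask, 0, -1).astype(np.int32)
    return LumenMask(mask, owner, {0: 0.0}, (1.0, 1.0, 1.0))


class TestSplitSignal:
    @settings(max_examples=30, deadline=None)
    @given(
        data=arrays(np.float64, (4, 5, 6), elements=st.floats(0, 1000)),
        mask=arrays(np.bool_, (4, 5, 6)),
    )
    def test_conservation_voxel_exact(self, data, mask):
        stack = ImageStack(data, (1.0, 1.0, 1.0))
        lum, ext = split_signal(stack, _mask_like(data.shape, mask))
        np.testing.assert_array_equal(lum.data + ext.data, stack.data)
        assert np.all(lum.data[~mask] == 0)
        assert np.all(ext.data[mask] == 0)

    def test_empty_mask_everything_extraluminal(self, rng):
        stack = ImageStack(rng.random((4, 4, 4)), (1, 1, 1))
        lum, ext = split_signal(stack, _mask_like(stack.shape, np.zeros(stack.shape, bool)))
        assert lum.data.sum() == 0
        np.testing.assert_array_equal(ext.data, stack.data)

    def test_full_mask_everything_luminal(self, rng):
        stack = ImageStack(rng.random((4, 4, 4)), (1, 1, 1))
        lum, ext = split_signal(stack, _mask_like(stack.shape, np.ones(stack.shape, bool)))
        np.testing.assert_array_equal(lum.data, stack.data)
        assert ext.data.sum() == 0

    def test_grid_mismatch_raises(self, rng):
        stack = ImageStack(rng.random((4, 4, 4)), (1, 1, 1))
        with pytest.raises(ValueError, match="grid mismatch"):
            split_signal(stack, _mask_like((5, 5, 5), np.zeros((5, 5, 5), bool)))


def _leaky_scene(spread=5.0, noise=None, psf=(0.5, 0.15, 0.15)):
    spec = PhantomSpec(
        volume_size_um=(36.0, 60.0, 40.0),
        vessel_count_per_class={},
        noise_model=noise,
        psf_sigma_um=psf,
        seed=8,
    )
    n = 16
    pts = np.column_stack([np.full(n, 18.0), np.full(n, 30.0), np.linspace(1, 39, n)])
    path = VesselPath(0, pts, np.full(n, 4.0))
    leaks = [PlannedLeak(0, 0.5, spread, site_length_um=40.0)] if spread else []
    truth = PhantomTruth(paths=[path], classes={0: "Ae"}, true_diameters_um={0: 8.0},
                         leak_sites=leaks, perfused={0: True})
    raster = phantom.rasterize_truth(truth, spec)
    stack = phantom.render_scene(truth, spec, raster)
    lumen = LumenMask(raster.lumen_mask, np.where(raster.lumen_mask, 0, -1),
                      {0: 0.0}, spec.voxel_size_um)
    return spec, truth, stack, lumen


class TestLeakageRatio:
    def test_no_leak_noise_free_ratio_zero(self):
        # ideal imaging (no PSF): all signal is intraluminal
        _, _, stack, lumen = _leaky_scene(spread=0.0, psf=(0.0, 0.0, 0.0))
        lum, ext = split_signal(stack, lumen)
        res = leakage_ratio(lum, ext, lumen_mask=lumen)
        assert res.ratio_total == pytest.approx(0.0, abs=1e-12)
        assert not res.undefined

    def test_noise_floor_makes_pre_timepoint_nonzero(self):
        _, _, stack, lumen = _leaky_scene(spread=0.0, noise=phantom.NoiseModel())
        lum, ext = split_signal(stack, lumen)
        res = leakage_ratio(lum, ext, lumen_mask=lumen)
        assert res.ratio_total > 0

    def test_matches_analytic_halo_over_lumen_integrals(self):
        spread, d = 5.0, 8.0
        spec, truth, stack, lumen = _leaky_scene(spread=spread)
        lum, ext = split_signal(stack, lumen)
        res = leakage_ratio(lum, ext, lumen_mask=lumen, dilation_guard=True)
        r, s = d / 2.0, spread / 2.0
        amp = spec.halo_amplitude_fraction * spec.tracer_intensity
        halo = amp * 2 * np.pi * (r * s * np.sqrt(np.pi / 2) + s**2)
        lum_analytic = spec.tracer_intensity * np.pi * r**2
        # guard ring removes the first voxel shell of halo mass
        guard = 1.0
        from math import erf

        halo_outside_guard = amp * 2 * np.pi * (
            (r + guard) * s * np.sqrt(np.pi / 2) * (1 - erf(guard / (s * np.sqrt(2))))
            + s**2 * np.exp(-(guard**2) / (2 * s**2))
        )
        expected = halo_outside_guard / lum_analytic
        assert res.ratio_total == pytest.approx(expected, rel=0.08)

    def test_invariant_under_global_intensity_scaling(self):
        _, _, stack, lumen = _leaky_scene(spread=5.0)
        lum, ext = split_signal(stack, lumen)
        base = leakage_ratio(lum, ext, lumen_mask=lumen, background=2.0)
        scaled = leakage_ratio(
            lum.copy_with(lum.data * 3.0), ext.copy_with(ext.data * 3.0),
            lumen_mask=lumen, background=6.0,
        )
        # single-precision stacks: invariance holds to float32 round-off
        assert scaled.ratio_total == pytest.approx(base.ratio_total, rel=1e-5)

    def test_zero_luminal_flagged_not_raised(self):
        stack = ImageStack(np.ones((4, 4, 4)), (1, 1, 1))
        lumen = _mask_like(stack.shape, np.zeros(stack.shape, bool))
        lum, ext = split_signal(stack, lumen)
        res = leakage_ratio(lum, ext, lumen_mask=lumen)
        assert res.undefined
        assert np.isnan(res.ratio_total)

    def test_monotone_in_halo_growth(self):
        ratios = []
        for spread in (2.0, 4.0, 6.0, 8.0):
            _, _, stack, lumen = _leaky_scene(spread=spread)
            lum, ext = split_signal(stack, lumen)
            ratios.append(leakage_ratio(lum, ext, lumen_mask=lumen).ratio_total)
        assert all(b > a for a, b in zip(ratios, ratios[1:]))


class TestCompartments:
    def _grid_stack(self):
        return ImageStack(np.zeros((4, 20, 20)), (1.0, 1.0, 1.0))

    def test_whole_plane_parenchyma_no_subarachnoid(self):
        stack = self._grid_stack()
        lumen = _mask_like(stack.shape, np.zeros(stack.shape, bool))
        rois = [{"plane": 0, "label": "parenchyma",
                 "vertices_um": [[0, 0], [0, 20], [20, 20], [20, 0], [0, 0]]}]
        cm = segment_compartments(rois, lumen, stack)
        assert np.all(cm.labels != 3)

    def test_half_plane_split_matches_bruteforce(self):
        stack = self._grid_stack()
        lumen = _mask_like(stack.shape, np.zeros(stack.shape, bool))
        poly = [[0, 0], [0, 9.7], [20, 9.7], [20, 0], [0, 0]]
        rois = [{"plane": 1, "label": "subarachnoid", "vertices_um": poly}]
        cm = segment_compartments(rois, lumen, stack)
        verts = np.array(poly[:-1])
        for iy in range(20):
            for ix in range(20):
                expected = point_in_polygon(iy + 0.5, ix + 0.5, verts)
                got = cm.region[1, iy, ix] == leakage.SUBARACHNOID_REGION
                assert got == expected, (iy, ix)

    def test_unclosed_polygon_rejected(self):
        stack = self._grid_stack()
        lumen = _mask_like(stack.shape, np.zeros(stack.shape, bool))
        rois = [{"plane": 0, "vertices_um": [[0, 0], [0, 10], [10, 10]]}]
        with pytest.raises(ValueError, match="closed"):
            segment_compartments(rois, lumen, stack)

    def test_lumen_overrides_roi_label(self):
        stack = self._grid_stack()
        mask = np.zeros(stack.shape, bool)
        mask[2, 5, 5] = True
        lumen = _mask_like(stack.shape, mask)
        rois = [{"plane": 2, "label": "subarachnoid",
                 "vertices_um": [[0, 0], [0, 20], [20, 20], [20, 0], [0, 0]]}]
        cm = segment_compartments(rois, lumen, stack)
        assert cm.labels[2, 5, 5] == 1  # lumen wins

    def test_phantom_spherical_cap_labels_match_truth(self):
        spec = PhantomSpec(
            volume_size_um=(40.0, 60.0, 60.0),
            vessel_count_per_class={},
            curvature_depth_um=15.0,
            noise_model=None,
            seed=2,
        )
        truth = PhantomTruth(paths=[], classes={}, true_diameters_um={},
                             leak_sites=[], perfused={})
        phantom.rasterize_truth(truth, spec)
        labels = truth.compartment_volume
        # ROI per plane drawn from the truth's own cap boundary circle
        assert set(np.unique(labels)) <= {phantom.PARENCHYMA, phantom.SUBARACHNOID}
        assert (labels == phantom.SUBARACHNOID).any()
        # the cap is shallow at the center, deep at the corners
        assert labels[0, 0, 0] == phantom.SUBARACHNOID
        nz, ny, nx = labels.shape
        assert labels[nz - 1, ny // 2, nx // 2] == phantom.PARENCHYMA


class TestPerfusedDensity:
    def test_no_paths_zero(self):
        assert perfused_density([], None, 1e6) == 0.0

    def test_arithmetic_hundred_micron_path(self):
        pts = np.column_stack([np.zeros(11), np.zeros(11), np.linspace(0, 100, 11)])
        path = VesselPath(0, pts)
        assert perfused_density([path], {0: True}, 1e6) == pytest.approx(1e-4)

    def test_phantom_truth_length_recovered_within_five_percent(self):
        spec = PhantomSpec(seed=6, noise_model=None)
        truth = phantom.generate_tree(spec)
        stack = phantom.render(truth, spec)
        flags = {
            p.vessel_id: is_perfused(stack, p, background=0.0) for p in truth.paths
        }
        density = perfused_density(truth.paths, flags, stack.volume_um3)
        expected = truth.perfused_length_um / stack.volume_um3
        assert density == pytest.approx(expected, rel=0.05)

    def test_density_drops_with_occlusion_and_anticorrelates_with_leakage(self):
        densities, ratios = [], []
        for occ, n_leaks in ((0.0, 0), (0.5, 6)):
            spec = PhantomSpec(seed=14, occluded_fraction=occ, noise_model=None)
            truth = phantom.generate_tree(spec)
            rng = np.random.default_rng(3)
            truth.leak_sites.extend(
                phantom.plan_leaks(truth, n_leaks, rng,
                                   class_shares={"Ae": 0.4, "C": 0.3, "Ve": 0.3})
            )
            raster = phantom.rasterize_truth(truth, spec)
            stack = phantom.render_scene(truth, spec, raster)
            lumen = LumenMask(raster.lumen_mask,
                              np.where(raster.lumen_mask, raster.owner, -1),
                              {}, spec.voxel_size_um)
            lum, ext = split_signal(stack, lumen)
            res = leakage_ratio(lum, ext, lumen_mask=lumen)
            flags = {p.vessel_id: truth.perfused[p.vessel_id] for p in truth.paths}
            densities.append(perfused_density(truth.paths, flags, stack.volume_um3))
            ratios.append(res.ratio_total)
        assert densities[1] < densities[0]
        assert ratios[1] > ratios[0]

    def test_negative_volume_rejected(self):
        with pytest.raises(ValueError):
            perfused_density([], None, 0.0)
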