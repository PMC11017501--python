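"""Phantom generator and forward imaging model."""

import numpy as np
import pytest
from scipy import ndimage

from avleak import phantom
from avleak.paths import VesselPath
from avleak.phantom import PhantomSpec, PhantomTruth, PlannedLeak, PlacementError


def small_spec(**kw):
    defaults = dict(
        volume_size_um=(40.0, 80.0, 80.0),
        vessel_count_per_class={"Ae": 1, "C": 2},
        noise_model=None,
        seed=5,
    )
    defaults.update(kw)
    return PhantomSpec(**defaults)


class TestGenerateTree:
    def test_deterministic_given_seed(self):
        spec = small_spec()
        t1 = phantom.generate_tree(spec)
        t2 = phantom.generate_tree(spec)
        assert len(t1.paths) == len(t2.paths)
        for a, b in zip(t1.paths, t2.paths):
            np.testing.assert_array_equal(a.points_um, b.points_um)
            np.testing.assert_array_equal(a.radius_um, b.radius_um)
        assert t1.classes == t2.classes

    def test_empty_request_gives_empty_truth(self):
        truth = phantom.generate_tree(small_spec(vessel_count_per_class={}))
        assert truth.paths == []
        assert truth.perfused_length_um == 0.0

    def test_single_artery_has_class_consistent_diameter(self):
        spec = PhantomSpec(
            volume_size_um=(200.0, 300.0, 300.0),
            vessel_count_per_class={"A": 1},
            noise_model=None,
            seed=2,
        )
        truth = phantom.generate_tree(spec)
        assert len(truth.paths) == 1
        (vid,) = truth.classes
        assert truth.classes[vid] == "A"
        assert truth.true_diameters_um[vid] > 45.0

    def test_hierarchy_arterioles_branch_off_arteries(self):
        spec = PhantomSpec(
            volume_size_um=(300.0, 500.0, 500.0),
            vessel_count_per_class={"A": 1, "Ae": 2, "C": 2, "Ve": 2, "V": 1},
            noise_model=None,
            seed=11,
        )
        truth = phantom.generate_tree(spec)
        classes = truth.classes
        by_id = {p.vessel_id: p for p in truth.paths}
        for vid, cls in classes.items():
            if cls == "Ae":
                assert classes[by_id[vid].parent_id] == "A"
            if cls == "Ve":
                assert classes[by_id[vid].parent_id] == "V"
            if cls == "C":
                assert classes[by_id[vid].parent_id] == "Ae"

    def test_nonintersecting_walls(self):
        spec = PhantomSpec(
            volume_size_um=(300.0, 500.0, 500.0),
            vessel_count_per_class={"A": 1, "Ae": 2, "C": 3, "Ve": 2, "V": 1},
            noise_model=None,
            seed=13,
        )
        truth = phantom.generate_tree(spec)
        # unrelated vessel pairs keep wall-to-wall clearance
        related = {(p.vessel_id, p.parent_id) for p in truth.paths}
        for a in truth.paths:
            for b in truth.paths:
                if a.vessel_id >= b.vessel_id:
                    continue
                if (a.vessel_id, b.vessel_id) in related or (b.vessel_id, a.vessel_id) in related:
                    continue
                if a.parent_id == b.vessel_id or b.parent_id == a.vessel_id:
                    continue
                d = np.min(
                    np.linalg.norm(
                        a.points_um[:, None, :] - b.points_um[None, :, :], axis=-1
                    )
                )
                # generous check: centerlines at least radii apart except
                # near shared junction chains
                ra = truth.true_diameters_um[a.vessel_id] / 2
                rb = truth.true_diameters_um[b.vessel_id] / 2
                if a.parent_id != b.parent_id:
                    assert d > 0.5 * (ra + rb)

    def test_volume_too_small_raises(self):
        spec = small_spec(volume_size_um=(10.0, 10.0, 10.0),
                          vessel_count_per_class={"A": 1})
        with pytest.raises(PlacementError):
            phantom.generate_tree(spec)

    def test_occluded_fraction_rounds_to_count(self):
        spec = PhantomSpec(
            volume_size_um=(100.0, 200.0, 200.0),
            vessel_count_per_class={"Ae": 2, "C": 6, "Ve": 2},
            occluded_fraction=0.5,
            noise_model=None,
            seed=3,
        )
        truth = phantom.generate_tree(spec)
        assert sum(not v for v in truth.perfused.values()) == round(0.5 * len(truth.paths))
        total = sum(p.length_um for p in truth.paths)
        assert truth.perfused_length_um < total

    def test_perfused_length_is_sum_of_perfused_polylines(self):
        truth = phantom.generate_tree(small_spec())
        expected = sum(p.length_um for p in truth.paths if truth.perfused[p.vessel_id])
        assert truth.perfused_length_um == pytest.approx(expected, abs=1e-9)


def _single_tube(diameter=10.0, size=(30.0, 60.0, 60.0), leak=None, **spec_kw):
    spec = PhantomSpec(
        volume_size_um=size,
        vessel_count_per_class={},
        noise_model=None,
        psf_sigma_um=spec_kw.pop("psf_sigma_um", (0.5, 0.15, 0.15)),
        seed=spec_kw.pop("seed", 1),
        **spec_kw,
    )
    pts = np.column_stack(
        [np.full(16, size[0] / 2), np.full(16, size[1] / 2), np.linspace(1, size[2] - 1, 16)]
    )
    path = VesselPath(0, pts, np.full(16, diameter / 2.0))
    truth = PhantomTruth(
        paths=[path],
        classes={0: "Ae"},
        true_diameters_um={0: diameter},
        leak_sites=[leak] if leak else [],
        perfused={0: True},
    )
    return spec, truth


class TestRender:
    def test_no_leak_no_noise_zero_outside_dilated_lumen(self):
        spec, truth = _single_tube()
        raster = phantom.rasterize_truth(truth, spec)
        stack = phantom.render_scene(truth, spec, raster)
        # beyond the lumen dilated by the PSF support, exactly zero
        margin_vox = int(np.ceil(4 * max(spec.psf_sigma_um) / 0.58)) + 2
        dilated = ndimage.binary_dilation(raster.lumen_mask, iterations=margin_vox)
        assert np.all(stack.data[~dilated] == 0)

    def test_occluded_tracer_dark_reporter_bright(self):
        spec, truth = _single_tube()
        truth.perfused[0] = False
        raster = phantom.rasterize_truth(truth, spec)
        tracer, reporter = phantom.render_scene(truth, spec, raster, with_reporter=True)
        lumen = raster.lumen_mask
        assert tracer.data[lumen].max() < 0.05 * spec.tracer_intensity
        assert np.median(reporter.data[lumen]) > 0.5 * spec.reporter_intensity

    def test_signal_conservation_without_noise(self):
        # tube through the whole x-range, site spanning the full length:
        # total intensity = lumen partial-volume mass + analytic halo mass
        d, spread = 8.0, 5.0
        leak = PlannedLeak(0, 0.5, spread, site_length_um=100.0)
        spec, truth = _single_tube(diameter=d, size=(40.0, 70.0, 40.0), leak=leak,
                                   psf_sigma_um=(0.0, 0.0, 0.0))
        raster = phantom.rasterize_truth(truth, spec)
        stack = phantom.render_scene(truth, spec, raster)
        voxvol = stack.voxel_volume_um3
        r, s = d / 2.0, spread / 2.0
        amp = spec.halo_amplitude_fraction * spec.tracer_intensity
        lx = spec.volume_size_um[2]
        halo_per_len = amp * 2 * np.pi * (r * s * np.sqrt(np.pi / 2) + s**2)
        lumen_mass = spec.tracer_intensity * np.pi * r**2 * lx / voxvol
        expected = lumen_mass + halo_per_len * lx / voxvol
        assert stack.data.sum() == pytest.approx(expected, rel=0.02)

    def test_halo_support_reaches_planned_distance(self):
        # distance-transform oracle: above-threshold halo support extends
        # to the planned spreading distance from the wall, within a voxel
        spread = 6.0
        leak = PlannedLeak(0, 0.5, spread, site_length_um=16.0)
        spec, truth = _single_tube(diameter=6.0, size=(40.0, 60.0, 44.0), leak=leak)
        raster = phantom.rasterize_truth(truth, spec)
        stack = phantom.render_scene(truth, spec, raster)
        thr = phantom.halo_detection_threshold(spec)
        outside = ~raster.lumen_mask
        support = (stack.data >= thr) & outside
        dist_from_lumen = ndimage.distance_transform_edt(
            ~raster.lumen_mask, sampling=stack.voxel_size_um
        )
        reached = dist_from_lumen[support].max()
        assert reached == pytest.approx(spread, abs=1.16)

    def test_render_deterministic_with_noise(self):
        spec = small_spec(noise_model=phantom.NoiseModel())
        truth = phantom.generate_tree(spec)
        s1 = phantom.render(truth, spec)
        s2 = phantom.render(truth, spec)
        np.testing.assert_array_equal(s1.data, s2.data)


class TestApplyTimepoint:
    def _leaky_truth(self, n_sites=12):
        spec = PhantomSpec(
            volume_size_um=(100.0, 200.0, 200.0),
            vessel_count_per_class={"Ae": 2, "C": 4, "Ve": 2},
            noise_model=None,
            seed=9,
        )
        truth = phantom.generate_tree(spec)
        rng = np.random.default_rng(4)
        truth.leak_sites.extend(
            phantom.plan_leaks(
                truth, n_sites, rng, class_shares={"Ae": 0.3, "C": 0.4, "Ve": 0.3}
            )
        )
        return spec, truth

    def test_exact_increase_count(self):
        spec, truth = self._leaky_truth(12)
        spec.leak_increase_fraction = 0.5
        _, t2 = phantom.apply_timepoint(truth, spec, "t2", render_stack=False)
        pre = {s.site_id: s.spreading_distance_um for s in truth.leak_sites}
        n_up = sum(
            s.spreading_distance_um > pre[s.site_id] for s in t2.leak_sites
        )
        assert n_up == round(0.5 * 12)
        assert all(
            s.spreading_distance_um != pre[s.site_id] for s in t2.leak_sites
        )

    def test_identity_constriction_keeps_diameters(self):
        spec, truth = self._leaky_truth(0)
        spec.constriction_factors = {c: (1.0, 0.0) for c in phantom.VESSEL_CLASSES}
        _, t2 = phantom.apply_timepoint(truth, spec, "t2", render_stack=False)
        for vid in truth.classes:
            assert t2.true_diameters_um[vid] == pytest.approx(
                truth.true_diameters_um[vid]
            )

    def test_constriction_factor_sample_mean(self):
        # many arterioles drawn with factor mean 0.735 -> applied post/pre
        # ratios average to ~0.735
        spec = PhantomSpec(
            volume_size_um=(300.0, 500.0, 500.0),
            vessel_count_per_class={"Ae": 30},
            noise_model=None,
            seed=21,
        )
        truth = phantom.generate_tree(spec)
        _, t2 = phantom.apply_timepoint(truth, spec, "post", render_stack=False)
        ratios = [
            t2.true_diameters_um[v] / truth.true_diameters_um[v] for v in truth.classes
        ]
        mean, sd = spec.constriction_factors["Ae"]
        assert np.mean(ratios) == pytest.approx(mean, abs=2.5 * sd / np.sqrt(30))

    def test_tag_collision_raises(self):
        spec, truth = self._leaky_truth(2)
        _, t2 = phantom.apply_timepoint(truth, spec, "t2", render_stack=False)
        with pytest.raises(ValueError, match="already used"):
            phantom.apply_timepoint(t2, spec, "t2", render_stack=False)


class TestSpecValidation:
    def test_rejects_bad_occlusion(self):
        with pytest.raises(ValueError):
            PhantomSpec(occluded_fraction=1.5)

    def test_rejects_diameter_mean_outside_band(self):
        with pytest.raises(ValueError):
            PhantomSpec(diameter_distributions={**phantom.CLASS_DIAMETER_DISTRIBUTIONS,
                                                "C": (20.0, 1.0)})

    def test_rejects_constriction_above_one(self):
        with pytest.raises(ValueError):
            PhantomSpec(constriction_factors={"C": (1.4, 0.0)})

    def test_leak_references_must_exist(self):
        with pytest.raises(ValueError):
            PhantomTruth(paths=[], classes={}, true_diameters_um={},
                         leak_sites=[PlannedLeak(0, 0.5, 3.0)], perfused={})
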