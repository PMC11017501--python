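"""Synthetic parameter-recovery experiments.

Each experiment treats a published per-class statistic as the *generating*
parameter of a phantom cohort, pushes the cohort through the measurement
pipeline, and reports how well the generating value is recovered:

- diameter cohorts re-measured by tracing + FWHM;
- leak sites planted with known class proportions and re-attributed by the
  nearest-wall rule;
- leak halos planted with known spreading distances and re-measured by the
  station-sampled continuous-signal rule;
- constriction factors applied and recovered as percent diameter decrease;
- two-timepoint leak progression with a known fraction of growing sites.

All randomness is derived from the caller's seed; cohort sizes default to
the published group sizes.
"""

from __future__ import annotations

import zlib

import numpy as np

from . import avaxis, leakage, phantom, tracing
from .paths import VesselPath
from .phantom import (
    CLASS_CONSTRICTION_FACTORS,
    CLASS_DIAMETER_DISTRIBUTIONS,
    CLASS_SPREADING_DISTRIBUTIONS,
    LEAK_CLASS_SHARES,
    PhantomSpec,
    PhantomTruth,
    PlannedLeak,
    _truncated_normal,
)
from .stack import ImageStack
from .tracing import LumenMask

__all__ = [
    "COHORT_SIZES",
    "CONSTRICTION_COHORT_SIZES",
    "single_tube_scene",
    "diameter_recovery",
    "attribution_experiment",
    "spreading_recovery",
    "constriction_recovery",
    "progression_experiment",
]

#: Published per-class group sizes of the diameter quantification.
COHORT_SIZES = {"A": 29, "Ae": 28, "C": 236, "Ve": 190, "V": 29}

#: Published per-class group sizes of the constriction quantification.
CONSTRICTION_COHORT_SIZES = {"A": 7, "Ae": 14, "C": 113, "Ve": 128, "V": 16}

MIN_PHYSICAL_DIAMETER_UM = 1.5  # cohort draws are truncated here, not at class bands

_VOXEL = (1.0, 0.58, 0.58)
_TRACER = 1000.0
_PSF = (0.5, 0.15, 0.15)  # physical two-photon PSF sigmas (z, y, x)


def single_tube_scene(
    diameter_um: float,
    rng: np.random.Generator,
    vessel_class: str = "C",
    length_um: float = 26.0,
    pad_z_um: float = 6.0,
    pad_y_um: float = 12.0,
    leak: PlannedLeak | None = None,
) -> tuple[PhantomSpec, PhantomTruth]:
    """One straight tube along x, centered with sub-voxel dither and a
    slight in-plane tilt, sized so the perpendicular profile reaches
    background on both sides."""
    margin = 0.0
    if leak is not None:
        margin = 1.4 * leak.spreading_distance_um + 6.0
        length_um = max(length_um, leak.site_length_um + 2.0 * margin + 6.0)
    size_z = diameter_um + 2.0 * (pad_z_um + margin)
    size_y = diameter_um + 2.0 * (pad_y_um + margin)
    size = (size_z, size_y, length_um)
    spec = PhantomSpec(
        volume_size_um=size,
        voxel_size_um=_VOXEL,
        vessel_count_per_class={},
        tracer_intensity=_TRACER,
        psf_sigma_um=_PSF,
        noise_model=None,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    cz = size_z / 2.0 + rng.uniform(-0.5, 0.5)
    cy = size_y / 2.0 + rng.uniform(-0.3, 0.3)
    tilt = rng.uniform(-0.05, 0.05)
    x = np.linspace(1.0, length_um - 1.0, 24)
    pts = np.column_stack([np.full_like(x, cz), cy + tilt * (x - x.mean()), x])
    path = VesselPath(0, pts, np.full(len(x), diameter_um / 2.0))
    truth = PhantomTruth(
        paths=[path],
        classes={0: vessel_class},
        true_diameters_um={0: diameter_um},
        leak_sites=[leak] if leak is not None else [],
        perfused={0: True},
    )
    return spec, truth


def _draw_diameter(cls: str, rng: np.random.Generator) -> float:
    mean, sd = CLASS_DIAMETER_DISTRIBUTIONS[cls]
    return _truncated_normal(rng, mean, sd, MIN_PHYSICAL_DIAMETER_UM, np.inf)


def diameter_recovery(
    vessel_class: str,
    n: int | None = None,
    seed: int = 0,
    trace_paths: bool = True,
) -> dict:
    """Draw a diameter cohort, render each tube, trace it from its end
    seeds and re-measure the diameter by the FWHM operation at mid-path."""
    n = COHORT_SIZES[vessel_class] if n is None else n
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 11, zlib.crc32(vessel_class.encode())])
    truths, measured = [], []
    for _ in range(n):
        d = _draw_diameter(vessel_class, rng)
        spec, truth = single_tube_scene(d, rng, vessel_class)
        stack = phantom.render(truth, spec)
        true_path = truth.paths[0]
        if trace_paths:
            sm = tracing.smooth(stack, 1.0)
            ends = [true_path.point_at(2.0), true_path.point_at(true_path.length_um - 2.0)]
            path = tracing.trace(sm, np.array(ends), estimate_radii=False)
        else:
            path = true_path
        m = avaxis.measure_diameter(
            stack, path, path.length_um / 2.0, max_radius_um=d / 2.0 + 10.0
        )
        truths.append(d)
        measured.append(m)
    measured = np.asarray(measured)
    gen_mean, gen_sd = CLASS_DIAMETER_DISTRIBUTIONS[vessel_class]
    return {
        "class": vessel_class,
        "n": n,
        "generating_mean_um": gen_mean,
        "generating_sd_um": gen_sd,
        "se_um": gen_sd / np.sqrt(n),
        "truth_mean_um": float(np.mean(truths)),
        "recovered_mean_um": float(np.nanmean(measured)),
        "n_unmeasurable": int(np.sum(~np.isfinite(measured))),
    }


def plant_site_point(
    truth: PhantomTruth,
    leak: PlannedLeak,
    rng: np.random.Generator,
    size: np.ndarray,
    max_offset_um: float = 10.0,
) -> np.ndarray:
    """A parenchymal stand-in for the halo's intensity-weighted centroid:
    within ``max_offset_um`` of the source vessel's wall, at a wall offset
    drawn from the halo's radial mass profile (half-Gaussian of scale
    spread/2, weighted by the shell circumference), inside the volume, and
    outside every other vessel's lumen (extravasated tracer is
    extravascular by definition)."""
    path = truth.path_by_id(leak.vessel_id)
    s = leak.position_along_path * path.length_um
    center = path.point_at(s)
    r = path.radius_at(s)
    tangent = path.tangent_at(s)
    scale = leak.spreading_distance_um / 2.0

    def draw_offset() -> float:
        # rejection-sample p(d) ∝ (r + d) exp(-d²/2 scale²) on (0.5, max]
        for _ in range(200):
            d = abs(rng.normal(0.0, scale))
            if not 0.5 <= d <= max_offset_um:
                continue
            if rng.uniform() <= (r + d) / (r + max_offset_um):
                return d
        return 0.5 + 0.1 * scale

    point = None
    for _ in range(100):
        v = rng.normal(size=3)
        v -= v.dot(tangent) * tangent
        norm = np.linalg.norm(v)
        if norm < 1e-6:
            continue
        v /= norm
        candidate = center + v * (r + draw_offset())
        if not (np.all(candidate > 0) and np.all(candidate < size)):
            continue
        point = candidate
        inside_other = any(
            avaxis.wall_distance(candidate, other) < 0.5
            for other in truth.paths
            if other.vessel_id != leak.vessel_id
        )
        if not inside_other:
            break
    if point is None:
        raise ValueError(f"could not place a site point for vessel {leak.vessel_id}")
    return point


def attribution_experiment(n_sites: int = 200, seed: int = 0) -> dict:
    """Plant leak sites on a mixed-class tree with the published class
    shares and re-attribute each by the nearest-vessel-wall rule."""
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 23])
    truth = None
    for _ in range(10):  # placement can fail for unlucky root layouts
        spec = PhantomSpec(
            volume_size_um=(300.0, 591.36, 591.36),
            vessel_count_per_class={"A": 3, "Ae": 8, "C": 16, "Ve": 12, "V": 3},
            noise_model=None,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        try:
            truth = phantom.generate_tree(spec)
            break
        except phantom.PlacementError:
            continue
    if truth is None:
        raise phantom.PlacementError("could not place the attribution scene")
    leaks = phantom.plan_leaks(truth, n_sites, rng)
    size = np.asarray(spec.volume_size_um)

    planted: dict[str, int] = {c: 0 for c in phantom.VESSEL_CLASSES}
    recovered: dict[str, int] = {c: 0 for c in phantom.VESSEL_CLASSES}
    total_attributed = 0
    for leak in leaks:
        path = truth.path_by_id(leak.vessel_id)
        planted[truth.classes[leak.vessel_id]] += 1
        point = plant_site_point(truth, leak, rng, size)
        ids = avaxis.attribute_leak(point, truth.paths)
        for vid in ids:
            recovered[truth.classes[vid]] += 1
            total_attributed += 1

    planted_pct = {c: 100.0 * planted[c] / n_sites for c in planted}
    recovered_pct = {
        c: 100.0 * recovered[c] / total_attributed if total_attributed else float("nan")
        for c in recovered
    }
    return {
        "n_sites": n_sites,
        "planted_share_pct": planted_pct,
        "recovered_share_pct": recovered_pct,
        "generating_share_pct": {c: 100.0 * v for c, v in LEAK_CLASS_SHARES.items()},
        "n_attributions": total_attributed,
    }


def _measure_halo(
    spec: PhantomSpec,
    truth: PhantomTruth,
    leak: PlannedLeak,
    raster: "phantom.TruthRaster | None" = None,
) -> float:
    """Render a single-tube leak scene, separate the extraluminal signal
    with the ground-truth lumen, and measure the spreading distance over
    the planted site span at 1 µm stations."""
    if raster is None:
        raster = phantom.rasterize_truth(truth, spec)
    stack = phantom.render_scene(truth, spec, raster)
    lumen = LumenMask(
        raster.lumen_mask,
        np.where(raster.lumen_mask, raster.owner, -1),
        {0: 0.0},
        spec.voxel_size_um,
    )
    _, extraluminal = leakage.split_signal(stack, lumen)
    path = truth.paths[0]
    c = leak.position_along_path * path.length_um
    span = (c - leak.site_length_um / 2.0, c + leak.site_length_um / 2.0)
    return avaxis.spreading_distance(
        extraluminal,
        None,
        path,
        detection_threshold=phantom.halo_detection_threshold(spec),
        sample_interval_um=1.0,
        arclength_range_um=span,
    )


def spreading_recovery(vessel_class: str, n: int = 50, seed: int = 0) -> dict:
    """Plant halos with spreading distances drawn from the per-class
    distribution and re-measure them with the spreading operation."""
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 31, zlib.crc32(vessel_class.encode())])
    mean, sd = CLASS_SPREADING_DISTRIBUTIONS[vessel_class]
    truths, measured = [], []
    for _ in range(n):
        d = _draw_diameter(vessel_class, rng)
        spread = _truncated_normal(rng, mean, sd, 0.1, np.inf)
        leak = PlannedLeak(0, 0.5, spread, site_length_um=20.0, site_id=0)
        spec, truth = single_tube_scene(d, rng, vessel_class, leak=leak)
        truths.append(spread)
        measured.append(_measure_halo(spec, truth, leak))
    return {
        "class": vessel_class,
        "n": n,
        "generating_mean_um": mean,
        "generating_sd_um": sd,
        "se_um": sd / np.sqrt(n),
        "truth_mean_um": float(np.mean(truths)),
        "recovered_mean_um": float(np.mean(measured)),
    }


def constriction_recovery(vessel_class: str, n: int | None = None, seed: int = 0) -> dict:
    """Apply per-class constriction factors to tube phantoms and recover
    the mean percent diameter decrease from pre/post FWHM measurements."""
    n = CONSTRICTION_COHORT_SIZES[vessel_class] if n is None else n
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 41, zlib.crc32(vessel_class.encode())])
    mean_f, sd_f = CLASS_CONSTRICTION_FACTORS[vessel_class]
    factors, decreases = [], []
    for _ in range(n):
        d_pre = _draw_diameter(vessel_class, rng)
        f = float(np.clip(rng.normal(mean_f, sd_f), 0.05, 1.0))
        factors.append(f)
        spec, truth = single_tube_scene(d_pre, rng, vessel_class)
        stack_pre = phantom.render(truth, spec)
        path = truth.paths[0]
        mid = path.length_um / 2.0
        m_pre = avaxis.measure_diameter(stack_pre, path, mid, max_radius_um=d_pre / 2.0 + 10.0)

        post_truth = PhantomTruth(
            paths=[VesselPath(0, path.points_um.copy(), path.radius_um * f)],
            classes=dict(truth.classes),
            true_diameters_um={0: d_pre * f},
            leak_sites=[],
            perfused={0: True},
        )
        stack_post = phantom.render(post_truth, spec)
        m_post = avaxis.measure_diameter(
            stack_post, post_truth.paths[0], mid, max_radius_um=d_pre / 2.0 + 10.0
        )
        pre_rec = avaxis.DiameterRecord(0, 0, "pre", m_pre)
        post_rec = avaxis.DiameterRecord(0, 0, "post", m_post)
        decreases.append((1.0 - avaxis.relative_change(pre_rec, post_rec)) * 100.0)
    return {
        "class": vessel_class,
        "n": n,
        "generating_decrease_pct": (1.0 - mean_f) * 100.0,
        "truth_decrease_pct": float((1.0 - np.mean(factors)) * 100.0),
        "recovered_decrease_pct": float(np.mean(decreases)),
    }


def progression_experiment(
    n_sites: int = 100, increase_fraction: float = 0.67, seed: int = 0
) -> dict:
    """Two-timepoint leak progression on capillary sites: a fixed fraction
    of halos grows between t1 and t1+40 min, the rest shrink; both
    timepoints are rendered, measured, and compared by leak_progression."""
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 53])
    defaults = PhantomSpec()
    n_up = int(round(increase_fraction * n_sites))
    increased = np.zeros(n_sites, dtype=bool)
    increased[rng.permutation(n_sites)[:n_up]] = True

    sites_t1, sites_t2 = [], []
    for i in range(n_sites):
        d = _draw_diameter("C", rng)
        spread1 = _truncated_normal(rng, 6.0, 3.0, 2.0, np.inf)
        if increased[i]:
            g = rng.uniform(*defaults.leak_growth_range)
        else:
            g = rng.uniform(*defaults.leak_shrink_range)
        spread2 = spread1 * g
        # one scene (sized for the larger halo) reused at both timepoints so
        # the two measurements share identical geometry
        sizing = PlannedLeak(0, 0.5, max(spread1, spread2), site_length_um=20.0, site_id=i)
        spec, truth = single_tube_scene(d, rng, "C", leak=sizing)
        raster = phantom.rasterize_truth(truth, spec)
        for spread, bucket, tag in ((spread1, sites_t1, "t1"), (spread2, sites_t2, "t2")):
            leak = PlannedLeak(0, 0.5, spread, site_length_um=20.0, onset_label=tag, site_id=i)
            truth.leak_sites[:] = [leak]
            value = _measure_halo(spec, truth, leak, raster)
            site = avaxis.LeakSite(site_id=i, timepoint_tag=tag)
            site.spreading_distance_um = value
            bucket.append(site)

    result = avaxis.leak_progression(sites_t1, sites_t2)
    return {
        "n_sites": n_sites,
        "planted_fraction_increased": n_up / n_sites,
        "recovered_fraction_increased": result.fraction_increased,
        "n_ties": result.n_ties,
        "p_value": result.p_value,
    }
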