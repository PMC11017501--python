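"""Synthetic 3D two-photon vascular phantoms.

Generates scenes of tubular vessels of the five arteriovenous classes
(artery A, arteriole Ae, capillary C, venule Ve, vein V) with known
centerlines, diameters, perfusion state, leak sites and compartment labels,
and renders them into image stacks with intraluminal tracer, extravascular
leakage halos, a Gaussian point-spread function and optional noise.  Every
downstream stage of the analysis pipeline can thereby be tested against
exact ground truth.

Class-level defaults (diameter distributions, leak-site class shares,
spreading-distance distributions, constriction factors) reproduce the
acute-phase statistics of photothrombotic cortical stroke in mouse:
arteries 74.1 ± 14.5 µm, arterioles 26.8 ± 8.0 µm, capillaries 6.1 ± 1.2 µm,
venules 21.3 ± 8.9 µm, veins 76.7 ± 25.0 µm; venules carry ~48% and
capillaries ~25% of leak sites; tracer spreads 14.1 ± 5.4 µm (A),
13.9 ± 5.8 µm (V) and 6.0 ± 3.0 µm (C) from the vessel wall; post-occlusion
diameters fall by 26.5% (Ae), 21.8% (A), 20.6% (V), 13.1% (Ve), 11.3% (C)
on average.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .paths import VesselPath, polyline_length, resample_polyline
from .stack import ImageStack

__all__ = [
    "VESSEL_CLASSES",
    "CLASS_DIAMETER_DISTRIBUTIONS",
    "CLASS_DIAMETER_BOUNDS",
    "LEAK_CLASS_SHARES",
    "CLASS_SPREADING_DISTRIBUTIONS",
    "CLASS_CONSTRICTION_FACTORS",
    "HALO_DETECTION_FRACTION",
    "NoiseModel",
    "PlannedLeak",
    "PhantomSpec",
    "PhantomTruth",
    "TruthRaster",
    "PlacementError",
    "generate_tree",
    "rasterize_truth",
    "render",
    "render_scene",
    "apply_timepoint",
    "plan_leaks",
    "halo_detection_threshold",
]

VESSEL_CLASSES = ("A", "Ae", "C", "Ve", "V")

#: Per-class diameter distributions (mean µm, sd µm) of the cortical
#: vasculature before occlusion.
CLASS_DIAMETER_DISTRIBUTIONS: dict[str, tuple[float, float]] = {
    "A": (74.1, 14.5),
    "Ae": (26.8, 8.0),
    "C": (6.1, 1.2),
    "Ve": (21.3, 8.9),
    "V": (76.7, 25.0),
}

#: Diameter bands of the classification rules; draws are truncated to the
#: band so generated vessels are consistent with their class label.
CLASS_DIAMETER_BOUNDS: dict[str, tuple[float, float]] = {
    "A": (45.0, np.inf),
    "Ae": (10.0, 45.0),
    "C": (1.5, 10.0),
    "Ve": (10.0, 50.0),
    "V": (50.0, np.inf),
}

#: Acute-phase share of leak sites per vessel class.
LEAK_CLASS_SHARES: dict[str, float] = {"Ve": 0.48, "C": 0.25, "Ae": 0.125, "V": 0.08, "A": 0.065}

#: Wall-to-front spreading-distance distributions (mean µm, sd µm) of
#: extravasated tracer.  Arteriole/venule values are not reported for the
#: acute phase; the defaults interpolate between the capillary and the
#: artery/vein values.
CLASS_SPREADING_DISTRIBUTIONS: dict[str, tuple[float, float]] = {
    "A": (14.1, 5.4),
    "V": (13.9, 5.8),
    "C": (6.0, 3.0),
    "Ae": (10.0, 4.0),
    "Ve": (10.0, 4.0),
}

#: Post/pre diameter fraction (mean, sd) applied at a post-occlusion
#: timepoint.  Means encode the reported average percent decreases
#: (Ae 26.5, A 21.8, V 20.6, Ve 13.1, C 11.3); the sd reflects a modest
#: within-class variability of the constriction response.
CLASS_CONSTRICTION_FACTORS: dict[str, tuple[float, float]] = {
    "Ae": (0.735, 0.03),
    "A": (0.782, 0.03),
    "V": (0.794, 0.03),
    "Ve": (0.869, 0.03),
    "C": (0.887, 0.03),
}

CLASS_MORPHOLOGY: dict[str, str] = {
    "A": "elongated",
    "Ae": "elongated",
    "C": "single-cell",
    "Ve": "irregular",
    "V": "irregular",
}

CLASS_TOPOLOGY: dict[str, str] = {
    "A": "none",
    "Ae": "branches_off_artery",
    "C": "none",
    "Ve": "converges_to_vein",
    "V": "none",
}

#: Leak halos fall off as a half-Gaussian of scale ``spread/2`` outside the
#: wall.  The intensity at the planned spreading distance is therefore
#: ``exp(-2)`` of the halo amplitude: a detector thresholding at this
#: fraction of the amplitude localises the most distant continuous signal
#: at the planned distance.  This is the generator's calibration constant.
HALO_DETECTION_FRACTION = float(np.exp(-2.0))


#: Minimum wall-to-wall separation between non-connected vessels (µm).
PARENCHYMAL_CLEARANCE_UM = 8.0


class PlacementError(ValueError):
    """Raised when the requested vessels cannot be placed in the volume."""


@dataclass
class NoiseModel:
    """Acquisition noise: additive Gaussian read noise plus Poisson shot noise.

    ``gaussian_sd`` is in intensity units; ``None`` means 5% of the tracer
    intensity.  ``poisson_scale`` is the photon count per intensity unit
    (0 disables shot noise).
    """

    gaussian_sd: float | None = None
    poisson_scale: float = 0.1


@dataclass
class PlannedLeak:
    """Ground truth of one planted leak site."""

    vessel_id: int
    position_along_path: float  # fraction of the path arclength in [0, 1]
    spreading_distance_um: float
    site_length_um: float = 20.0
    onset_label: str = "t1"
    site_id: int = -1

    def __post_init__(self) -> None:
        if not 0.0 <= self.position_along_path <= 1.0:
            raise ValueError("position_along_path must lie in [0, 1]")
        if self.spreading_distance_um <= 0:
            raise ValueError("spreading_distance_um must be > 0")
        if self.site_length_um <= 0:
            raise ValueError("site_length_um must be > 0")


@dataclass
class PhantomSpec:
    """Full description of a phantom acquisition.

    Sizes and voxel sizes are (z, y, x) µm.  The default grid is
    256 × 256 × 64 voxels at 0.58 × 0.58 × 1 µm — the acquisition geometry
    (1024 × 1024 × 0.58 µm/pixel, 1 µm z-steps) scaled down 4× in xy for
    desk-scale work; pass the full size explicitly to reproduce the
    acquisition field of view.
    """

    volume_size_um: tuple[float, float, float] = (64.0, 148.48, 148.48)
    voxel_size_um: tuple[float, float, float] = (1.0, 0.58, 0.58)
    vessel_count_per_class: dict[str, int] = field(
        default_factory=lambda: {"A": 0, "Ae": 2, "C": 6, "Ve": 2, "V": 0}
    )
    diameter_distributions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(CLASS_DIAMETER_DISTRIBUTIONS)
    )
    tracer_intensity: float = 1000.0
    # two-photon PSF at ~920 nm, NA 1.0 water immersion: lateral FWHM
    # ~0.35 µm, axial FWHM ~1.2 µm -> Gaussian sigmas (z, y, x)
    psf_sigma_um: tuple[float, float, float] = (0.5, 0.15, 0.15)
    noise_model: NoiseModel | None = field(default_factory=NoiseModel)
    leak_spec: list[PlannedLeak] = field(default_factory=list)
    constriction_factors: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(CLASS_CONSTRICTION_FACTORS)
    )
    occluded_fraction: float = 0.0
    curvature_depth_um: float = 0.0
    leak_increase_fraction: float = 0.67
    leak_growth_range: tuple[float, float] = (1.2, 1.8)
    leak_shrink_range: tuple[float, float] = (0.5, 0.85)
    halo_amplitude_fraction: float = 0.5
    reporter_intensity: float = 600.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.volume_size_um = tuple(float(v) for v in self.volume_size_um)
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        if any(v <= 0 for v in self.volume_size_um) or any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("volume and voxel sizes must be positive")
        if not 0.0 <= self.occluded_fraction <= 1.0:
            raise ValueError("occluded_fraction must lie in [0, 1]")
        for cls, (mean, _sd) in self.constriction_factors.items():
            if not 0.0 < mean <= 1.0:
                raise ValueError(f"constriction factor mean for {cls} must be in (0, 1]")
        for cls, (mean, _sd) in self.diameter_distributions.items():
            lo, hi = CLASS_DIAMETER_BOUNDS[cls]
            if not lo <= mean <= hi:
                raise ValueError(
                    f"diameter mean {mean} for class {cls} violates the class band [{lo}, {hi}]"
                )
        for cls in self.vessel_count_per_class:
            if cls not in VESSEL_CLASSES:
                raise ValueError(f"unknown vessel class {cls!r}")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(
            int(round(s / v)) for s, v in zip(self.volume_size_um, self.voxel_size_um)
        )

    @property
    def spacing(self) -> np.ndarray:
        return np.asarray(self.voxel_size_um, dtype=float)


# compartment label codes
LUMEN, PARENCHYMA, SUBARACHNOID = 1, 2, 3


@dataclass
class PhantomTruth:
    """Complete ground truth of one simulated scene."""

    paths: list[VesselPath]
    classes: dict[int, str]
    true_diameters_um: dict[int, float]
    leak_sites: list[PlannedLeak]
    perfused: dict[int, bool]
    morphology: dict[int, str] = field(default_factory=dict)
    topology: dict[int, str] = field(default_factory=dict)
    compartment_volume: np.ndarray | None = None  # filled by rasterize_truth
    constriction_applied: dict[int, float] = field(default_factory=dict)
    leak_increased: dict[int, bool] = field(default_factory=dict)
    tags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = {p.vessel_id for p in self.paths}
        for leak in self.leak_sites:
            if leak.vessel_id not in ids:
                raise ValueError(f"leak site references unknown vessel {leak.vessel_id}")

    @property
    def perfused_length_um(self) -> float:
        return float(
            sum(p.length_um for p in self.paths if self.perfused.get(p.vessel_id, True))
        )

    def path_by_id(self, vessel_id: int) -> VesselPath:
        for p in self.paths:
            if p.vessel_id == vessel_id:
                return p
        raise KeyError(vessel_id)


def _salt(tag: str) -> int:
    return zlib.crc32(tag.encode()) & 0x7FFFFFFF


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return float(x)
    raise ValueError(f"could not draw from N({mean},{sd}) within ({lo},{hi})")


def _tortuous(points: np.ndarray, rng: np.random.Generator,
              amplitude_um: float, periods: float) -> np.ndarray:
    """Low-amplitude sinusoidal perturbation perpendicular to a polyline."""
    if amplitude_um <= 0 or len(points) < 3:
        return points
    t = points[-1] - points[0]
    t = t / np.linalg.norm(t)
    ref = np.array([1.0, 0.0, 0.0]) if abs(t[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    n1 = np.cross(t, ref)
    n1 /= np.linalg.norm(n1)
    n2 = np.cross(t, n1)
    phase = rng.uniform(0, 2 * np.pi)
    mix = rng.uniform(0, 2 * np.pi)
    s = np.linspace(0, 1, len(points))
    wave = np.sin(2 * np.pi * periods * s + phase) * np.sin(np.pi * s)  # pinned ends
    disp = amplitude_um * wave[:, None] * (np.cos(mix) * n1 + np.sin(mix) * n2)[None, :]
    return points + disp


def _min_distance(samples_a: np.ndarray, tree_b: cKDTree) -> float:
    d, _ = tree_b.query(samples_a)
    return float(np.min(d)) if len(d) else np.inf


def generate_tree(spec: PhantomSpec, with_compartments: bool = False) -> PhantomTruth:
    """Place a vascular tree with the requested per-class vessel counts.

    Arteries and veins are roots spanning the volume; arterioles branch off
    arteries (or are roots when no artery is requested), venules converge
    to veins likewise, and capillaries run from an arteriole towards a
    venule, respecting the A→Ae→C→Ve→V hierarchy.  Placement rejects
    candidates that intersect already-placed vessels and raises
    :class:`PlacementError` when the volume cannot host the request.

    Deterministic for a fixed ``spec.seed``.  ``with_compartments``
    additionally rasterizes the compartment label volume (lumen /
    parenchyma / subarachnoid), which materialises the full voxel grid.
    """
    rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, 101])
    size = np.asarray(spec.volume_size_um, dtype=float)

    paths: list[VesselPath] = []
    classes: dict[int, str] = {}
    diameters: dict[int, float] = {}
    samples: dict[int, np.ndarray] = {}
    trees: dict[int, cKDTree] = {}
    next_id = 0

    def draw_diameter(cls: str) -> float:
        mean, sd = spec.diameter_distributions[cls]
        lo, hi = CLASS_DIAMETER_BOUNDS[cls]
        return _truncated_normal(rng, mean, sd, lo, hi)

    def admissible(
        pts: np.ndarray, radius: float, skip_near: list[tuple[np.ndarray, float]]
    ) -> bool:
        if len(paths) == 0:
            return True
        probe = pts
        for junction, skip in skip_near:
            # a branch legitimately overlaps the clearance band of the vessel
            # it joins until it has fully emerged from the junction
            keep = np.linalg.norm(probe - junction[None, :], axis=1) > skip
            probe = probe[keep]
        if len(probe) == 0:
            return True
        for other in paths:
            r_other = diameters[other.vessel_id] / 2.0
            # non-connected vessels are separated by neuropil; keep a
            # parenchymal wall-to-wall clearance between them
            clearance = radius + r_other + PARENCHYMAL_CLEARANCE_UM
            if _min_distance(probe, trees[other.vessel_id]) < clearance:
                return False
        return True

    def commit(pts: np.ndarray, cls: str, diameter: float, parent: int | None) -> int:
        nonlocal next_id
        vid = next_id
        next_id += 1
        pts_rs, _ = resample_polyline(pts, 2.0)
        radii = np.full(len(pts_rs), diameter / 2.0)
        paths.append(VesselPath(vid, pts_rs, radii, parent))
        classes[vid] = cls
        diameters[vid] = diameter
        dense, _ = resample_polyline(pts_rs, 1.0)
        samples[vid] = dense
        trees[vid] = cKDTree(dense)
        return vid

    def place_root(cls: str) -> int:
        diameter = draw_diameter(cls)
        margin = diameter / 2.0 + 1.0
        lo, hi = np.full(3, margin), size - margin
        if np.any(hi <= lo):
            raise PlacementError(
                f"volume {tuple(size)} µm too small for a class-{cls} vessel of "
                f"diameter {diameter:.1f} µm"
            )
        for _ in range(400):
            # roots run across the volume, roughly horizontally
            axis = rng.integers(1, 3)  # 1 = y, 2 = x
            start = np.array([rng.uniform(lo[0], hi[0]),
                              rng.uniform(lo[1], hi[1]),
                              rng.uniform(lo[2], hi[2])])
            end = start.copy()
            start[axis], end[axis] = lo[axis], hi[axis]
            end[0] = np.clip(end[0] + rng.uniform(-0.1, 0.1) * (hi[0] - lo[0]), lo[0], hi[0])
            base = np.linspace(start, end, 64)
            amp = min(3.0, 0.02 * np.linalg.norm(end - start),
                      float(np.min((hi - lo) / 2)) * 0.2)
            pts = _tortuous(base, rng, amp, rng.uniform(1.0, 2.0))
            pts = np.clip(pts, lo, hi)
            if admissible(pts, diameter / 2.0, []):
                return commit(pts, cls, diameter, None)
        raise PlacementError(f"failed to place class-{cls} root vessel")

    def wall_anchor(vessel: VesselPath, towards: np.ndarray | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
        """A point on the vessel wall and the outward wall normal there."""
        u = rng.uniform(0.15, 0.85)
        c = vessel.point_at(u * vessel.length_um)
        t = vessel.tangent_at(u * vessel.length_um)
        if towards is not None:
            w = towards - c
        else:
            w = rng.normal(size=3)
        w = w - w.dot(t) * t
        n = np.linalg.norm(w)
        if n < 1e-6:
            w = np.array([0.0, 1.0, 0.0]) - t[1] * t
            n = np.linalg.norm(w)
        w /= n
        r = diameters[vessel.vessel_id] / 2.0
        return c + w * r, w

    def place_branch(cls: str, parent_ids: list[int], target_ids: list[int]) -> int:
        diameter = draw_diameter(cls)
        margin = diameter / 2.0 + 1.0
        lo, hi = np.full(3, margin), size - margin
        if np.any(hi <= lo):
            raise PlacementError(f"volume too small for class {cls}")

        def junction_skip(j_radius: float) -> float:
            # a branch emerging at the wall stays within the clearance band
            # of its trunk for roughly sqrt(2 R dr) of arclength
            return float(np.sqrt(2.0 * j_radius * (diameter / 2.0 + 2.0)) + diameter / 2.0 + 4.0)

        for attempt in range(300):
            junctions: list[tuple[np.ndarray, float]] = []
            if parent_ids:
                parent = paths[[p.vessel_id for p in paths].index(
                    int(rng.choice(parent_ids)))]
                start, outward = wall_anchor(parent)
                parent_id = parent.vessel_id
                junctions.append((start, junction_skip(diameters[parent_id] / 2.0)))
            else:
                parent_id = None
                start = rng.uniform(lo, hi)
                outward = None
            # after many failed routed attempts, fall back to a free end
            route_to_target = bool(target_ids) and attempt < 200
            if route_to_target:
                # prefer the nearest of a few candidate junctions: short
                # connectors are less likely to collide with thick vessels
                candidates = []
                for _ in range(4):
                    target = paths[[p.vessel_id for p in paths].index(
                        int(rng.choice(target_ids)))]
                    pt, _ = wall_anchor(target, towards=start)
                    candidates.append((np.linalg.norm(pt - start), pt, target.vessel_id))
                _, end, target_vid = min(candidates, key=lambda c: c[0])
                junctions.append((end, junction_skip(diameters[target_vid] / 2.0)))
            else:
                direction = rng.normal(size=3)
                direction[0] *= 0.3  # mostly horizontal
                if outward is not None:
                    direction = direction / np.linalg.norm(direction) + 1.2 * outward
                direction /= np.linalg.norm(direction)
                length = rng.uniform(40.0, 110.0)
                end = start + direction * length
            end = np.clip(end, lo, hi)
            if np.linalg.norm(end - start) < 15.0:
                continue
            if outward is not None and (end - start).dot(outward) <= 0:
                continue  # must leave the trunk, not dive back through it
            base = np.linspace(start, end, 48)
            amp = min(2.5, 0.04 * np.linalg.norm(end - start))
            pts = _tortuous(base, rng, amp, rng.uniform(1.0, 2.5))
            pts = np.clip(pts, lo, hi)
            if admissible(pts, diameter / 2.0, junctions):
                return commit(pts, cls, diameter, parent_id)
        raise PlacementError(f"failed to place class-{cls} vessel")

    counts = {cls: int(spec.vessel_count_per_class.get(cls, 0)) for cls in VESSEL_CLASSES}
    arteries = [place_root("A") for _ in range(counts["A"])]
    veins = [place_root("V") for _ in range(counts["V"])]
    arterioles = [place_branch("Ae", arteries, []) for _ in range(counts["Ae"])]
    venules = [place_branch("Ve", veins, []) for _ in range(counts["Ve"])]
    _capillaries = [place_branch("C", arterioles, venules) for _ in range(counts["C"])]

    perfused = {vid: True for vid in classes}
    n_occ = int(round(spec.occluded_fraction * len(paths)))
    if n_occ:
        occluded = rng.choice(sorted(classes), size=n_occ, replace=False)
        for vid in occluded:
            perfused[int(vid)] = False

    truth = PhantomTruth(
        paths=paths,
        classes=classes,
        true_diameters_um=diameters,
        leak_sites=list(spec.leak_spec),
        perfused=perfused,
        morphology={vid: CLASS_MORPHOLOGY[c] for vid, c in classes.items()},
        topology={vid: CLASS_TOPOLOGY[c] for vid, c in classes.items()},
    )
    if with_compartments:
        rasterize_truth(truth, spec)
    return truth


# ---------------------------------------------------------------------------
# rasterization and rendering
# ---------------------------------------------------------------------------

@dataclass
class TruthRaster:
    """Voxelised geometry of a scene: distance to the nearest centerline,
    its owning vessel and local radius, and the derived lumen mask."""

    distance_um: np.ndarray       # distance to nearest centerline sample
    owner: np.ndarray             # vessel_id of nearest centerline, -1 if none
    local_radius_um: np.ndarray   # radius at the nearest centerline sample
    lumen_mask: np.ndarray        # distance <= local radius
    spacing: np.ndarray


def _surface_height(spec: PhantomSpec, yy: np.ndarray, xx: np.ndarray) -> np.ndarray:
    """Spherical-cap brain surface: depth 0 at the field center, reaching
    ``curvature_depth_um`` at the xy corners.  Voxels above the surface
    (smaller z) belong to the subarachnoid space."""
    depth = spec.curvature_depth_um
    cy, cx = spec.volume_size_um[1] / 2.0, spec.volume_size_um[2] / 2.0
    rho2 = (yy - cy) ** 2 + (xx - cx) ** 2
    rho_max2 = cy**2 + cx**2
    if depth <= 0:
        return np.zeros_like(rho2)
    sphere_r = (rho_max2 + depth**2) / (2.0 * depth)
    return sphere_r - np.sqrt(np.maximum(sphere_r**2 - rho2, 0.0))


def rasterize_truth(truth: PhantomTruth, spec: PhantomSpec) -> TruthRaster:
    """Rasterize centerlines into distance/owner/radius fields on the spec grid.

    Ownership of each voxel goes to the vessel with the nearest centerline
    sample in physical µm.  Also fills ``truth.compartment_volume`` with
    lumen / parenchyma / subarachnoid labels.
    """
    shape = spec.grid_shape
    spacing = spec.spacing
    id_grid = np.full(shape, -1, dtype=np.int32)
    r_grid = np.zeros(shape, dtype=np.float32)

    step = 0.45 * float(np.min(spacing))
    for path in truth.paths:
        pts, radii = resample_polyline(path.points_um, step, path.radius_um)
        idx = np.round(pts / spacing - 0.5).astype(int)
        np.clip(idx, 0, np.asarray(shape) - 1, out=idx)
        id_grid[idx[:, 0], idx[:, 1], idx[:, 2]] = path.vessel_id
        if radii is not None:
            r_grid[idx[:, 0], idx[:, 1], idx[:, 2]] = radii

    if np.all(id_grid < 0):
        dist = np.full(shape, np.inf, dtype=np.float32)
        owner = id_grid
        local_r = r_grid
        lumen = np.zeros(shape, dtype=bool)
    else:
        dist, inds = ndimage.distance_transform_edt(
            id_grid < 0, sampling=spacing, return_indices=True
        )
        owner = id_grid[inds[0], inds[1], inds[2]]
        local_r = r_grid[inds[0], inds[1], inds[2]]
        lumen = dist <= local_r

    comp = np.full(shape, PARENCHYMA, dtype=np.uint8)
    if spec.curvature_depth_um > 0:
        yy = (np.arange(shape[1]) + 0.5) * spacing[1]
        xx = (np.arange(shape[2]) + 0.5) * spacing[2]
        zz = (np.arange(shape[0]) + 0.5) * spacing[0]
        surf = _surface_height(spec, yy[:, None], xx[None, :])
        comp[zz[:, None, None] < surf[None, :, :]] = SUBARACHNOID
    comp[lumen] = LUMEN
    truth.compartment_volume = comp

    return TruthRaster(
        distance_um=np.asarray(dist, dtype=np.float32),
        owner=owner.astype(np.int32),
        local_radius_um=np.asarray(local_r, dtype=np.float32),
        lumen_mask=lumen,
        spacing=spacing,
    )


def _soft_lumen_fraction(raster: TruthRaster) -> np.ndarray:
    """Partial-volume lumen occupancy: 1 inside, 0 outside, a linear ramp of
    one xy-voxel width across the wall (half occupancy exactly at the wall,
    so the full width at half maximum of a tube profile equals the true
    diameter)."""
    edge = float(raster.spacing[1])
    return np.clip(0.5 + (raster.local_radius_um - raster.distance_um) / edge, 0.0, 1.0)


def _add_halo(
    channel: np.ndarray,
    leak: PlannedLeak,
    path: VesselPath,
    spacing: np.ndarray,
    amplitude: float,
) -> None:
    """Render one leak halo: intensity ``amp * exp(-d_wall^2 / (2 (s/2)^2))``
    outside the wall over a stretch of ``site_length_um`` along the path."""
    s = leak.spreading_distance_um / 2.0
    total = path.length_um
    center = leak.position_along_path * total
    s0 = max(center - leak.site_length_um / 2.0, 0.0)
    s1 = min(center + leak.site_length_um / 2.0, total)
    stations = np.arange(s0, s1 + 0.2, 0.4)
    pts = np.array([path.point_at(t) for t in stations])
    radii = np.array([path.radius_at(t) for t in stations]) if path.radius_um is not None \
        else np.zeros(len(stations))

    reach = float(np.max(radii)) + 3.5 * s + 2.0
    lo = np.maximum(np.floor((pts.min(axis=0) - reach) / spacing - 0.5).astype(int), 0)
    hi = np.minimum(
        np.ceil((pts.max(axis=0) + reach) / spacing - 0.5).astype(int) + 1,
        np.asarray(channel.shape),
    )
    if np.any(hi <= lo):
        return
    zz = (np.arange(lo[0], hi[0]) + 0.5) * spacing[0]
    yy = (np.arange(lo[1], hi[1]) + 0.5) * spacing[1]
    xx = (np.arange(lo[2], hi[2]) + 0.5) * spacing[2]
    grid = np.stack(np.meshgrid(zz, yy, xx, indexing="ij"), axis=-1).reshape(-1, 3)
    d, idx = cKDTree(pts).query(grid)
    d_wall = d - radii[idx]
    halo = np.where(
        d_wall > 0.0, amplitude * np.exp(-(d_wall**2) / (2.0 * s**2)), 0.0
    )
    halo[halo < 1e-4 * amplitude] = 0.0
    box = halo.reshape(hi[0] - lo[0], hi[1] - lo[1], hi[2] - lo[2])
    channel[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += box


def render_scene(
    truth: PhantomTruth,
    spec: PhantomSpec,
    raster: TruthRaster | None = None,
    timepoint_tag: str = "",
    with_reporter: bool = False,
    rng: np.random.Generator | None = None,
) -> ImageStack | tuple[ImageStack, ImageStack]:
    """Forward imaging model: luminal tracer, leak halos, PSF, noise.

    The tracer channel holds ``tracer_intensity`` inside perfused lumina and
    0 inside unperfused ones; leak halos decay from the vessel wall with
    half-Gaussian profiles calibrated so the detectable extent equals the
    planned spreading distance.  The optional reporter channel fills every
    lumen regardless of perfusion, emulating an endothelial GFP reporter.
    """
    if raster is None:
        raster = rasterize_truth(truth, spec)
    if rng is None:
        rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, 211, _salt(timepoint_tag)])

    frac = _soft_lumen_fraction(raster)
    perfused_lut = np.zeros(max(truth.classes, default=0) + 2, dtype=bool)
    for vid, flag in truth.perfused.items():
        perfused_lut[vid] = flag
    owner = np.where(raster.owner >= 0, raster.owner, len(perfused_lut) - 1)
    tracer = np.where(perfused_lut[owner], frac, 0.0) * spec.tracer_intensity

    for leak in truth.leak_sites:
        _add_halo(
            tracer,
            leak,
            truth.path_by_id(leak.vessel_id),
            raster.spacing,
            spec.halo_amplitude_fraction * spec.tracer_intensity,
        )

    sigma_vox = np.asarray(spec.psf_sigma_um) / raster.spacing
    if np.any(sigma_vox > 0):
        tracer = ndimage.gaussian_filter(tracer, sigma_vox, mode="constant")

    if spec.noise_model is not None:
        nm = spec.noise_model
        if nm.poisson_scale > 0:
            tracer = rng.poisson(np.maximum(tracer, 0.0) * nm.poisson_scale) / nm.poisson_scale
        sd = 0.05 * spec.tracer_intensity if nm.gaussian_sd is None else nm.gaussian_sd
        if sd > 0:
            tracer = np.maximum(tracer + rng.normal(0.0, sd, tracer.shape), 0.0)

    tracer_stack = ImageStack(
        tracer.astype(np.float32), tuple(raster.spacing), "tracer", timepoint_tag
    )
    if not with_reporter:
        return tracer_stack

    reporter = frac * spec.reporter_intensity
    if np.any(sigma_vox > 0):
        reporter = ndimage.gaussian_filter(reporter, sigma_vox, mode="constant")
    if spec.noise_model is not None:
        nm = spec.noise_model
        if nm.poisson_scale > 0:
            reporter = rng.poisson(np.maximum(reporter, 0.0) * nm.poisson_scale) / nm.poisson_scale
        sd = 0.05 * spec.reporter_intensity if nm.gaussian_sd is None else nm.gaussian_sd
        if sd > 0:
            reporter = np.maximum(reporter + rng.normal(0.0, sd, reporter.shape), 0.0)
    reporter_stack = ImageStack(
        reporter.astype(np.float32), tuple(raster.spacing), "reporter", timepoint_tag
    )
    return tracer_stack, reporter_stack


def render(
    truth: PhantomTruth,
    spec: PhantomSpec,
    timepoint_tag: str = "",
    with_reporter: bool = False,
) -> ImageStack | tuple[ImageStack, ImageStack]:
    """Render a scene on the spec grid (see :func:`render_scene`)."""
    return render_scene(truth, spec, None, timepoint_tag, with_reporter)


def halo_detection_threshold(spec: PhantomSpec) -> float:
    """Detection threshold matched to the halo calibration: the intensity a
    halo has at exactly its planned spreading distance."""
    return spec.halo_amplitude_fraction * spec.tracer_intensity * HALO_DETECTION_FRACTION


def _blocked_intervals_um(truth: PhantomTruth, path: VesselPath) -> list[tuple[float, float]]:
    """Arclength intervals of a path that lie inside a junction zone — its
    own ends where it joins a trunk, and mid-path points where other
    vessels terminate on it.  Sites planted there would make 'the nearest
    vessel' ill-defined."""
    r_self = float(path.radius_um[0]) if path.radius_um is not None else 3.0
    length = path.length_um
    arcs = path.arclengths
    blocked: list[tuple[float, float]] = [(0.0, 8.0), (length - 8.0, length)]

    def radius_of(p: VesselPath, k: int) -> float:
        return float(p.radius_um[k]) if p.radius_um is not None else 0.0

    for other in truth.paths:
        if other.vessel_id == path.vessel_id:
            continue
        # does one of this path's ends join `other`?
        for end_s, end_point in ((0.0, path.points_um[0]), (length, path.points_um[-1])):
            d = np.linalg.norm(other.points_um - end_point[None, :], axis=1)
            k = int(np.argmin(d))
            r_other = radius_of(other, k)
            if d[k] < r_other + r_self + 2.0:
                c = float(np.sqrt(2.0 * r_other * (r_self + 2.0)) + r_self + 6.0)
                blocked.append((end_s - c, end_s + c))
        # does `other` terminate on this path mid-length?
        for other_end in (other.points_um[0], other.points_um[-1]):
            d = np.linalg.norm(path.points_um - other_end[None, :], axis=1)
            k = int(np.argmin(d))
            r_other = radius_of(other, 0 if np.allclose(other_end, other.points_um[0]) else -1)
            if d[k] < r_self + r_other + 2.0:
                c = float(np.sqrt(2.0 * r_self * (r_other + 2.0)) + r_other + 6.0)
                blocked.append((arcs[k] - c, arcs[k] + c))
    return blocked


def _draw_site_position(
    truth: PhantomTruth, vid: int, rng: np.random.Generator
) -> float:
    """Fraction along the path, uniform over junction-free arclength."""
    path = truth.path_by_id(vid)
    length = path.length_um
    blocked = _blocked_intervals_um(truth, path)
    for _ in range(100):
        s = rng.uniform(0.0, length)
        if not any(lo <= s <= hi for lo, hi in blocked):
            return s / length
    # fully blocked path (short vessel between big trunks): use the midpoint
    return 0.5


def plan_leaks(
    truth: PhantomTruth,
    n: int,
    rng: np.random.Generator,
    class_shares: dict[str, float] | None = None,
    spreading: dict[str, tuple[float, float]] | None = None,
    site_length_um: float = 20.0,
    onset_label: str = "t1",
) -> list[PlannedLeak]:
    """Plant ``n`` leak sites on the scene with per-class proportions.

    Class counts are ``round(share * n)`` (largest-remainder balanced to sum
    to ``n``); the carrying vessel is chosen uniformly within the class and
    the ground-truth spreading distance is drawn from the per-class
    distribution truncated to positive values.
    """
    shares = dict(LEAK_CLASS_SHARES if class_shares is None else class_shares)
    spreading = dict(CLASS_SPREADING_DISTRIBUTIONS if spreading is None else spreading)
    by_class: dict[str, list[int]] = {c: [] for c in VESSEL_CLASSES}
    for vid, cls in truth.classes.items():
        by_class[cls].append(vid)

    raw = {c: shares.get(c, 0.0) * n for c in shares}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    remainder = n - sum(counts.values())
    for c in sorted(raw, key=lambda c: raw[c] - counts[c], reverse=True)[:remainder]:
        counts[c] += 1

    leaks: list[PlannedLeak] = []
    sid = 0
    for cls, count in counts.items():
        if count and not by_class[cls]:
            raise ValueError(f"no class-{cls} vessel available for planted leaks")
        for _ in range(count):
            vid = int(rng.choice(by_class[cls]))
            mean, sd = spreading[cls]
            spread = _truncated_normal(rng, mean, sd, 0.1, np.inf)
            # keep sites clear of branch junctions, where "the nearest
            # vessel" would be genuinely ambiguous
            leaks.append(
                PlannedLeak(
                    vessel_id=vid,
                    position_along_path=_draw_site_position(truth, vid, rng),
                    spreading_distance_um=spread,
                    site_length_um=site_length_um,
                    onset_label=onset_label,
                    site_id=sid,
                )
            )
            sid += 1
    return leaks


def apply_timepoint(
    truth: PhantomTruth,
    spec: PhantomSpec,
    tag: str,
    render_stack: bool = True,
) -> tuple[ImageStack | None, PhantomTruth]:
    """Advance the scene to a follow-up timepoint.

    A fraction ``spec.leak_increase_fraction`` of leak sites (exactly
    ``round(fraction * n)``, chosen at random) grows by a factor drawn from
    ``leak_growth_range``; the rest shrink by a factor from
    ``leak_shrink_range``.  Per-class constriction factors are applied to
    all vessel diameters.  Returns the rendered follow-up stack (or ``None``
    when ``render_stack`` is false) and the updated truth.
    """
    if tag in truth.tags or (truth.leak_sites and tag == truth.leak_sites[0].onset_label):
        raise ValueError(f"timepoint tag {tag!r} already used")
    rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, 7919, _salt(tag)])

    factors: dict[int, float] = {}
    new_paths: list[VesselPath] = []
    new_diam: dict[int, float] = {}
    for path in truth.paths:
        cls = truth.classes[path.vessel_id]
        mean, sd = spec.constriction_factors.get(cls, (1.0, 0.0))
        f = float(np.clip(rng.normal(mean, sd), 0.05, 1.0)) if sd > 0 else float(mean)
        factors[path.vessel_id] = f
        radii = None if path.radius_um is None else path.radius_um * f
        new_paths.append(VesselPath(path.vessel_id, path.points_um.copy(), radii, path.parent_id))
        new_diam[path.vessel_id] = truth.true_diameters_um[path.vessel_id] * f

    n = len(truth.leak_sites)
    n_up = int(round(spec.leak_increase_fraction * n))
    order = rng.permutation(n)
    increased = {truth.leak_sites[i].site_id: bool(k < n_up) for k, i in enumerate(order)}
    new_leaks: list[PlannedLeak] = []
    for leak in truth.leak_sites:
        if increased[leak.site_id]:
            g = rng.uniform(*spec.leak_growth_range)
        else:
            g = rng.uniform(*spec.leak_shrink_range)
        new_leaks.append(replace(leak, spreading_distance_um=leak.spreading_distance_um * g,
                                 onset_label=tag))

    new_truth = PhantomTruth(
        paths=new_paths,
        classes=dict(truth.classes),
        true_diameters_um=new_diam,
        leak_sites=new_leaks,
        perfused=dict(truth.perfused),
        morphology=dict(truth.morphology),
        topology=dict(truth.topology),
        constriction_applied=factors,
        leak_increased=increased,
        tags=truth.tags + [tag],
    )
    stack = render(new_truth, spec, timepoint_tag=tag) if render_stack else None
    return stack, new_truth
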