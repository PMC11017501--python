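"""Arteriovenous-axis analysis: vessel classification, diameter dynamics,
leak-site attribution and spreading-distance measurement.

Vessel classes follow the morphology/diameter criteria of cortical
vasculature: arteries (A) have elongated, streamlined endothelium and are
> 45 µm in diameter; arterioles (Ae) branch off arteries, 10–45 µm; a
single endothelial cell covers the lumen of a capillary (C), < 10 µm;
venules (Ve) converge to form veins, 10–50 µm; veins (V) have irregular
endothelium and are > 50 µm.  The diameter bands overlap by design, so
morphology and topology flags resolve the ambiguous ranges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .paths import VesselPath
from .profile import fwhm_diameter_at_point
from .stack import ImageStack

log = logging.getLogger(__name__)

__all__ = [
    "VESSEL_CLASS_BANDS",
    "MORPHOLOGY_CLASSES",
    "TOPOLOGY_CLASSES",
    "LeakSite",
    "DiameterRecord",
    "ProgressionResult",
    "classify",
    "measure_diameter",
    "wall_distance",
    "attribute_leak",
    "spreading_distance",
    "relative_change",
    "leak_progression",
]

# (low, high, low_inclusive, high_inclusive) in µm, exactly as printed
VESSEL_CLASS_BANDS: dict[str, tuple[float, float, bool, bool]] = {
    "A": (45.0, np.inf, False, True),
    "Ae": (10.0, 45.0, True, True),
    "C": (0.0, 10.0, False, False),
    "Ve": (10.0, 50.0, True, True),
    "V": (50.0, np.inf, False, True),
}

MORPHOLOGY_CLASSES: dict[str, frozenset[str]] = {
    "elongated": frozenset({"A", "Ae"}),
    "irregular": frozenset({"V", "Ve"}),
    "single-cell": frozenset({"C"}),
}

TOPOLOGY_CLASSES: dict[str, frozenset[str]] = {
    "branches_off_artery": frozenset({"Ae"}),
    "converges_to_vein": frozenset({"Ve"}),
}

DEFAULT_TIE_TOLERANCE_UM = 0.58   # one xy pixel
DEFAULT_MAX_ATTRIBUTION_UM = 50.0
DEFAULT_WALL_TOLERANCE_UM = 1.5   # ~ one voxel diagonal


@dataclass
class LeakSite:
    """A localized extraluminal tracer accumulation."""

    site_id: int
    voxel_support: np.ndarray | None = None      # (N, 3) voxel indices
    attributed_vessel_ids: list[int] = field(default_factory=list)
    spreading_distance_um: float | None = None
    sample_interval_um: float = 1.0
    timepoint_tag: str = ""

    def __post_init__(self) -> None:
        if not 1.0 <= self.sample_interval_um <= 2.0:
            raise ValueError("sample_interval_um must lie in [1, 2] µm")
        if self.voxel_support is not None:
            self.voxel_support = np.asarray(self.voxel_support, dtype=int)


@dataclass
class DiameterRecord:
    """One diameter measurement of one vessel segment at one timepoint.
    A vessel is counted as two new segments at each branch point."""

    vessel_id: int
    segment_id: int
    timepoint_tag: str
    diameter_um: float

    def __post_init__(self) -> None:
        if not self.diameter_um > 0:
            raise ValueError("diameter must be positive")


def classify(
    diameter_um: float,
    morphology: str | None = None,
    topology: str | None = None,
) -> str | frozenset[str]:
    """Assign an arteriovenous class from diameter and optional flags.

    Bounds are applied exactly as printed (strict "> 45", "< 10"; the
    10–45 / 10–50 bands inclusive), so exact boundary diameters and the
    overlapping 45–50 µm band yield several candidates; morphology
    (``elongated`` / ``irregular`` / ``single-cell``) and topology
    (``branches_off_artery`` / ``converges_to_vein`` / ``none``) narrow
    them.  Returns the class name, or the frozenset of remaining candidates
    when the flags cannot resolve the overlap.
    """
    if not diameter_um > 0:
        raise ValueError("diameter must be positive")
    candidates = set()
    for cls, (lo, hi, lo_inc, hi_inc) in VESSEL_CLASS_BANDS.items():
        above = diameter_um >= lo if lo_inc else diameter_um > lo
        below = diameter_um <= hi if hi_inc else diameter_um < hi
        if above and below:
            candidates.add(cls)
    if morphology is not None:
        if morphology not in MORPHOLOGY_CLASSES:
            raise ValueError(f"unknown morphology flag {morphology!r}")
        candidates &= MORPHOLOGY_CLASSES[morphology]
    if topology is not None and topology != "none":
        if topology not in TOPOLOGY_CLASSES:
            raise ValueError(f"unknown topology flag {topology!r}")
        candidates &= TOPOLOGY_CLASSES[topology]
    if not candidates:
        raise ValueError(
            f"no class consistent with diameter {diameter_um} µm and flags "
            f"({morphology}, {topology})"
        )
    if len(candidates) == 1:
        return next(iter(candidates))
    return frozenset(candidates)


def measure_diameter(
    stack: ImageStack,
    path: VesselPath,
    arclength_um: float,
    n_stations: int = 3,
    station_spacing_um: float = 1.0,
    max_radius_um: float = 80.0,
    baseline: float = 0.0,
) -> float:
    """Vessel diameter at an arclength position, in µm.

    Full width at half maximum of the intensity profile along the in-plane
    perpendicular to the local tangent, averaged over ``n_stations``
    adjacent perpendiculars ``station_spacing_um`` apart.  Returns NaN when
    the profile never falls to half maximum (vessel exits the field:
    flagged unmeasurable).
    """
    total = path.length_um
    if not 0.0 <= arclength_um <= total:
        raise ValueError("arclength position outside the path extent")
    offsets = (np.arange(n_stations) - (n_stations - 1) / 2.0) * station_spacing_um
    widths = []
    for off in offsets:
        s = float(np.clip(arclength_um + off, 0.0, total))
        point = path.point_at(s)
        tangent = path.tangent_at(s)
        w = fwhm_diameter_at_point(stack, point, tangent, max_radius_um, baseline=baseline)
        if np.isfinite(w) and w > 0:
            widths.append(w)
    if not widths:
        return float("nan")
    return float(np.mean(widths))


def wall_distance(point_um: np.ndarray, path: VesselPath, mode: str = "3d") -> float:
    """Euclidean µm distance from a point to the vessel wall surface
    (centerline distance minus local radius; negative values — inside the
    lumen — clamp to 0)."""
    dense = path.resampled(0.5)
    radii = dense.radius_um if dense.radius_um is not None else np.zeros(len(dense.points_um))
    delta = dense.points_um - np.asarray(point_um, dtype=float)[None, :]
    if mode == "2d":
        delta = delta[:, 1:]
    d = np.linalg.norm(delta, axis=1) - radii
    return float(max(np.min(d), 0.0))


def attribute_leak(
    site_points_um: np.ndarray,
    paths: list[VesselPath],
    tie_tolerance_um: float = DEFAULT_TIE_TOLERANCE_UM,
    max_attribution_um: float = DEFAULT_MAX_ATTRIBUTION_UM,
    weights: np.ndarray | None = None,
) -> list[int]:
    """Attribute a leak site to the nearest vessel(s).

    The site's (intensity-weighted) centroid is compared against every
    vessel's wall surface; the nearest vessel is returned, and the runner-up
    as well when the two wall distances differ by at most
    ``tie_tolerance_um`` ("equally close" rule).  A site farther than
    ``max_attribution_um`` from every wall stays unattributed (empty list,
    logged).
    """
    pts = np.atleast_2d(np.asarray(site_points_um, dtype=float))
    if len(pts) == 0:
        raise ValueError("empty leak site")
    if not paths:
        raise ValueError("no vessel paths to attribute against")
    centroid = np.average(pts, axis=0, weights=weights)

    dists = [(wall_distance(centroid, p), p.vessel_id) for p in paths]
    dists.sort()
    if dists[0][0] > max_attribution_um:
        log.warning(
            "leak site at %s is %.1f µm from the nearest wall (max %.1f): unattributed",
            np.round(centroid, 1), dists[0][0], max_attribution_um,
        )
        return []
    out = [dists[0][1]]
    if len(dists) > 1 and dists[1][0] - dists[0][0] <= tie_tolerance_um:
        out.append(dists[1][1])
    return out


def spreading_distance(
    extraluminal: ImageStack,
    site: LeakSite | None,
    path: VesselPath,
    detection_threshold: float,
    sample_interval_um: float = 1.0,
    arclength_range_um: tuple[float, float] | None = None,
    mode: str = "3d",
    wall_tolerance_um: float = DEFAULT_WALL_TOLERANCE_UM,
) -> float:
    """Mean maximal wall-to-signal distance of continuous extravascular
    tracer, in µm.

    Above-threshold voxels count only when 26-connected to the vessel wall
    (continuity: a detached bright blob does not extend the measurement).
    The site is sampled at stations every ``sample_interval_um`` (1–2 µm)
    along its length (arclength along the attributed vessel); at each
    station the maximum wall distance of continuous signal is taken and the
    station values are averaged.  ``arclength_range_um`` restricts the
    analysis to a delineated site; otherwise the extent of the site's voxel
    support (or of the continuous signal) is used.  ``mode="2d"`` measures
    in-plane distances instead of 3D ones.

    Returns 0.0 (logged) when no above-threshold voxel is connected to the
    wall.
    """
    if not 1.0 <= sample_interval_um <= 2.0:
        raise ValueError("sample_interval_um must lie in [1, 2] µm")
    from skimage.measure import label as cc_label

    data = extraluminal.data
    shape = np.asarray(data.shape)
    if site is not None and site.voxel_support is not None and len(site.voxel_support):
        lo = np.maximum(site.voxel_support.min(axis=0) - 2, 0)
        hi = np.minimum(site.voxel_support.max(axis=0) + 3, shape)
    else:
        lo = np.zeros(3, dtype=int)
        hi = shape
    box = data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    above = box >= detection_threshold
    if not above.any():
        log.warning("no signal above %.3g in the site region", detection_threshold)
        if site is not None:
            site.spreading_distance_um = 0.0
        return 0.0

    coords = np.argwhere(above) + lo
    world = (coords + 0.5) * extraluminal.spacing
    dense = path.resampled(0.5)
    radii = dense.radius_um if dense.radius_um is not None else np.zeros(len(dense.points_um))
    arcs = dense.arclengths
    if mode == "2d":
        d, idx = cKDTree(dense.points_um[:, 1:]).query(world[:, 1:])
    else:
        d, idx = cKDTree(dense.points_um).query(world)
    d_wall = d - radii[idx]
    s_along = arcs[idx]

    labels = cc_label(above, connectivity=3)
    lab = labels[coords[:, 0] - lo[0], coords[:, 1] - lo[1], coords[:, 2] - lo[2]]
    touching = set(np.unique(lab[d_wall <= wall_tolerance_um]))
    keep = np.isin(lab, list(touching)) if touching else np.zeros(len(lab), dtype=bool)
    keep &= d_wall > 0
    if site is not None and site.voxel_support is not None and len(site.voxel_support):
        in_support = np.zeros(box.shape, dtype=bool)
        sup = site.voxel_support - lo
        ok = np.all((sup >= 0) & (sup < np.asarray(box.shape)), axis=1)
        sup = sup[ok]
        in_support[sup[:, 0], sup[:, 1], sup[:, 2]] = True
        keep &= in_support[coords[:, 0] - lo[0], coords[:, 1] - lo[1], coords[:, 2] - lo[2]]
    if not keep.any():
        log.warning("no continuous above-threshold signal at the vessel wall")
        if site is not None:
            site.spreading_distance_um = 0.0
        return 0.0

    s_keep, d_keep = s_along[keep], d_wall[keep]
    if arclength_range_um is not None:
        s0, s1 = arclength_range_um
        sel = (s_keep >= s0) & (s_keep <= s1)
        if not sel.any():
            if site is not None:
                site.spreading_distance_um = 0.0
            return 0.0
        s_keep, d_keep = s_keep[sel], d_keep[sel]
        lo_s, hi_s = s0, s1
    else:
        lo_s, hi_s = float(s_keep.min()), float(s_keep.max())

    n_bins = max(int(np.ceil((hi_s - lo_s) / sample_interval_um)), 1)
    bins = np.clip(((s_keep - lo_s) / sample_interval_um).astype(int), 0, n_bins - 1)
    maxima = np.full(n_bins, -np.inf)
    np.maximum.at(maxima, bins, d_keep)
    station_max = maxima[np.isfinite(maxima)]
    value = float(np.mean(station_max))
    if site is not None:
        site.spreading_distance_um = value
        site.sample_interval_um = sample_interval_um
    return value


def relative_change(pre: DiameterRecord, post: DiameterRecord) -> float:
    """Post/pre diameter ratio for one segment (percent decrease is
    ``(1 - ratio) * 100``).  Raises on a segment mismatch."""
    if (pre.vessel_id, pre.segment_id) != (post.vessel_id, post.segment_id):
        raise ValueError("pre and post records refer to different segments")
    return post.diameter_um / pre.diameter_um


@dataclass
class ProgressionResult:
    per_site: dict[int, str]            # site_id -> increased / decreased / tie
    fraction_increased: float
    n_matched: int
    n_ties: int
    unmatched: list[int]
    p_value: float                      # paired t-test on spreading distances


def leak_progression(
    sites_t1: list[LeakSite], sites_t2: list[LeakSite]
) -> ProgressionResult:
    """Classify matched leak sites as increased or decreased between two
    timepoints by the sign of the spreading-distance change (strict
    comparisons; exact ties reported separately).  Unmatched sites are
    excluded and logged.  The paired t-test p-value is reported as
    supporting output."""
    by_id1 = {s.site_id: s for s in sites_t1}
    by_id2 = {s.site_id: s for s in sites_t2}
    matched = sorted(set(by_id1) & set(by_id2))
    unmatched = sorted(set(by_id1) ^ set(by_id2))
    if unmatched:
        log.warning("excluding %d unmatched leak sites: %s", len(unmatched), unmatched)
    per_site: dict[int, str] = {}
    pre_vals, post_vals = [], []
    for sid in matched:
        a, b = by_id1[sid].spreading_distance_um, by_id2[sid].spreading_distance_um
        if a is None or b is None:
            raise ValueError(f"site {sid} has no spreading distance measured")
        per_site[sid] = "increased" if b > a else ("decreased" if b < a else "tie")
        pre_vals.append(a)
        post_vals.append(b)
    n_inc = sum(v == "increased" for v in per_site.values())
    n_tie = sum(v == "tie" for v in per_site.values())
    frac = n_inc / len(matched) if matched else float("nan")
    if len(matched) >= 2 and np.ptp(np.subtract(post_vals, pre_vals)) > 0:
        p = float(stats.ttest_rel(post_vals, pre_vals).pvalue)
    else:
        p = float("nan")
    return ProgressionResult(per_site, frac, len(matched), n_tie, unmatched, p)
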