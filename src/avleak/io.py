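"""File formats: multi-page TIFF stacks, SWC centerlines, ROI JSON, masks.

TIFF stacks round-trip intensities and voxel sizes losslessly: xy pixel
sizes go into the resolution tags, the z step into the ImageJ ``spacing``
metadata, so the files open correctly in Fiji.  Centerlines use the SWC
text format (point id, type, x, y, z, radius, parent) with coordinates in
µm.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import tifffile

from .paths import VesselPath
from .stack import ImageStack
from .tracing import LumenMask

__all__ = [
    "read_stack",
    "write_stack",
    "read_swc",
    "write_swc",
    "read_rois",
    "write_rois",
    "write_mask",
    "read_mask",
]

DEFAULT_VOXEL_SIZE_UM = (1.0, 0.58, 0.58)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as ImageJ-style multi-page TIFF (one page per plane)."""
    vz, vy, vx = stack.voxel_size_um
    tifffile.imwrite(
        str(path),
        stack.data.astype(np.float32),
        imagej=True,
        resolution=(1.0 / vx, 1.0 / vy),
        metadata={
            "spacing": vz,
            "unit": "um",
            "channel_tag": stack.channel_tag,
            "timepoint_tag": stack.timepoint_tag,
        },
    )


def _resolution_to_um(tag_value) -> float | None:
    if tag_value is None:
        return None
    num, den = tag_value if isinstance(tag_value, tuple) else (tag_value, 1)
    if num == 0:
        return None
    return float(den) / float(num)


def read_stack(path: str | Path) -> ImageStack:
    """Read a multi-page TIFF stack; a missing voxel-size tag falls back to
    the acquisition default 0.58 × 0.58 × 1 µm with a warning."""
    path = Path(path)
    try:
        with tifffile.TiffFile(str(path)) as tif:
            data = tif.asarray()
            page = tif.pages[0]
            vx = _resolution_to_um(page.tags.valueof("XResolution"))
            vy = _resolution_to_um(page.tags.valueof("YResolution"))
            vz = None
            channel_tag = timepoint_tag = ""
            meta = tif.imagej_metadata or {}
            if "spacing" in meta:
                vz = float(meta["spacing"])
            channel_tag = str(meta.get("channel_tag", ""))
            timepoint_tag = str(meta.get("timepoint_tag", ""))
    except (tifffile.TiffFileError, ValueError, OSError) as exc:
        raise ValueError(f"malformed TIFF file {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None, ...]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a single-channel z-stack, got shape {data.shape}")
    if vx is None or vy is None or vz is None:
        warnings.warn(
            f"{path}: missing voxel-size metadata; assuming "
            f"{DEFAULT_VOXEL_SIZE_UM[::-1]} µm (x, y, z)",
            stacklevel=2,
        )
        voxel = DEFAULT_VOXEL_SIZE_UM
    else:
        voxel = (vz, vy, vx)
    return ImageStack(data, voxel, channel_tag, timepoint_tag)


# -- SWC centerlines --------------------------------------------------------

def write_swc(paths: list[VesselPath], path: str | Path) -> None:
    """Write centerlines as SWC: one connected chain per vessel; columns
    are id, type, x, y, z (µm), radius (µm), parent id."""
    lines = ["# id type x y z radius parent  (µm; one chain per vessel)"]
    node = 1
    for vp in paths:
        radii = vp.radius_um if vp.radius_um is not None else np.zeros(len(vp.points_um))
        lines.append(f"# vessel {vp.vessel_id} parent_vessel {vp.parent_id}")
        for k, (pt, r) in enumerate(zip(vp.points_um, radii)):
            parent = -1 if k == 0 else node - 1
            z, y, x = pt
            r = r if np.isfinite(r) else 0.0
            lines.append(f"{node} 0 {x:.3f} {y:.3f} {z:.3f} {r:.3f} {parent}")
            node += 1
    Path(path).write_text("\n".join(lines) + "\n")


def read_swc(path: str | Path) -> list[VesselPath]:
    """Read SWC centerlines written by :func:`write_swc` (or any SWC whose
    chains are simple paths)."""
    nodes: dict[int, tuple[np.ndarray, float, int]] = {}
    vessel_meta: list[tuple[int, int | None]] = []
    order: list[int] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if line.startswith("# vessel "):
            parts = line.split()
            pid = None if parts[4] == "None" else int(parts[4])
            vessel_meta.append((int(parts[2]), pid))
            continue
        if not line or line.startswith("#"):
            continue
        f = line.split()
        nid, parent = int(f[0]), int(f[6])
        x, y, z, r = (float(v) for v in f[2:6])
        nodes[nid] = (np.array([z, y, x]), r, parent)
        order.append(nid)

    chains: list[list[int]] = []
    for nid in order:
        if nodes[nid][2] == -1 or nodes[nid][2] not in nodes:
            chains.append([nid])
        else:
            chains[-1].append(nid)
    out = []
    for k, chain in enumerate(chains):
        pts = np.array([nodes[n][0] for n in chain])
        radii = np.array([nodes[n][1] for n in chain])
        vid, parent_vessel = vessel_meta[k] if k < len(vessel_meta) else (k, None)
        out.append(
            VesselPath(vid, pts, radii if np.any(radii > 0) else None, parent_vessel)
        )
    return out


# -- ROI polygons -----------------------------------------------------------

def write_rois(rois: list[dict], path: str | Path) -> None:
    Path(path).write_text(json.dumps(rois, indent=1))


def read_rois(path: str | Path) -> list[dict]:
    rois = json.loads(Path(path).read_text())
    if not isinstance(rois, list):
        raise ValueError("ROI file must hold a list of polygon records")
    return rois


# -- label masks ------------------------------------------------------------

def write_mask(mask: LumenMask, path: str | Path) -> None:
    """Write a lumen mask as an 8-bit label TIFF (0 = background,
    vessel_id + 1 elsewhere; at most 254 vessels)."""
    ids = np.unique(mask.owner[mask.owner >= 0])
    if ids.size and ids.max() > 253:
        raise ValueError("8-bit label volume supports at most 254 vessel ids")
    labels = np.where(mask.owner >= 0, mask.owner + 1, 0).astype(np.uint8)
    vz, vy, vx = mask.voxel_size_um
    tifffile.imwrite(
        str(path), labels, imagej=True,
        resolution=(1.0 / vx, 1.0 / vy), metadata={"spacing": vz, "unit": "um"},
    )


def read_mask(path: str | Path) -> LumenMask:
    stack = read_stack(path)
    labels = stack.data.astype(np.int32)
    owner = labels - 1
    return LumenMask(labels > 0, owner, {}, stack.voxel_size_um)
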