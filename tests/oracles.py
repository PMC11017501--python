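"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's search machinery: plain heapq
Dijkstra over explicit voxel neighbourhoods, exhaustive flood fill, and
per-voxel point-in-polygon, so they can certify the production
implementations on small inputs.
"""

from __future__ import annotations

import heapq

import numpy as np

OFFSETS_26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


def dijkstra_min_cost(
    cost: np.ndarray,
    spacing: tuple[float, float, float],
    start: tuple[int, int, int],
    end: tuple[int, int, int],
) -> float:
    """Minimum path cost on the 26-connected voxel graph where a move from
    u to v costs the physical step length times (cost[u] + cost[v]) / 2."""
    shape = cost.shape
    sp = np.asarray(spacing, dtype=float)
    step_len = {
        off: float(np.linalg.norm(sp * np.asarray(off))) for off in OFFSETS_26
    }
    best = {start: 0.0}
    heap = [(0.0, start)]
    done = set()
    while heap:
        d, u = heapq.heappop(heap)
        if u in done:
            continue
        if u == end:
            return d
        done.add(u)
        cu = cost[u]
        for off in OFFSETS_26:
            v = (u[0] + off[0], u[1] + off[1], u[2] + off[2])
            if not (0 <= v[0] < shape[0] and 0 <= v[1] < shape[1] and 0 <= v[2] < shape[2]):
                continue
            w = d + step_len[off] * (cu + cost[v]) / 2.0
            if np.isfinite(w) and w < best.get(v, np.inf):
                best[v] = w
                heapq.heappush(heap, (w, v))
    return float("inf")


def flood_fill_geodesic(
    accept: np.ndarray,
    spacing: tuple[float, float, float],
    seeds: list[tuple[int, int, int]],
) -> np.ndarray:
    """Geodesic distance (µm) from the seed voxels through the accepted
    region over 26-neighbours; +inf where unreachable or not accepted."""
    shape = accept.shape
    sp = np.asarray(spacing, dtype=float)
    step_len = {
        off: float(np.linalg.norm(sp * np.asarray(off))) for off in OFFSETS_26
    }
    dist = np.full(shape, np.inf)
    heap = []
    for s in seeds:
        if accept[s]:
            dist[s] = 0.0
            heap.append((0.0, s))
    heapq.heapify(heap)
    while heap:
        d, u = heapq.heappop(heap)
        if d > dist[u]:
            continue
        for off in OFFSETS_26:
            v = (u[0] + off[0], u[1] + off[1], u[2] + off[2])
            if not (0 <= v[0] < shape[0] and 0 <= v[1] < shape[1] and 0 <= v[2] < shape[2]):
                continue
            if not accept[v]:
                continue
            w = d + step_len[off]
            if w < dist[v]:
                dist[v] = w
                heapq.heappush(heap, (w, v))
    return dist


def point_in_polygon(py: float, px: float, verts: np.ndarray) -> bool:
    """Ray casting, vertices as (y, x) pairs (open polygon)."""
    inside = False
    n = len(verts)
    for i in range(n):
        y1, x1 = verts[i]
        y2, x2 = verts[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            x_cross = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_cross:
                inside = not inside
    return inside


def classify_rule_table(diameter: float, morphology: str | None, topology: str | None):
    """Exhaustive rule-table classification: every class whose printed
    diameter band, morphology and topology are all consistent."""
    bands = {
        "A": diameter > 45.0,
        "Ae": 10.0 <= diameter <= 45.0,
        "C": diameter < 10.0,
        "Ve": 10.0 <= diameter <= 50.0,
        "V": diameter > 50.0,
    }
    morph_of = {"A": "elongated", "Ae": "elongated", "V": "irregular",
                "Ve": "irregular", "C": "single-cell"}
    topo_of = {"Ae": "branches_off_artery", "Ve": "converges_to_vein"}
    out = set()
    for cls, in_band in bands.items():
        if not in_band:
            continue
        if morphology is not None and morph_of[cls] != morphology:
            continue
        if topology is not None and topology != "none" and topo_of.get(cls) != topology:
            continue
        out.add(cls)
    return out
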