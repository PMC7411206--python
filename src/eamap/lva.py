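"""Low-voltage substrate analysis: segmentation, area, earliest site,
boundary block coverage and preferential-conduction channel gaps.

A low-voltage region is a maximal edge-connected set of triangles whose
three vertices are all mapped below the voltage cutoff (default 0.5 mV).
Its boundary is scanned against the detected conduction-delay edges: a
region whose border is mostly blocked but retains at least one contiguous
unblocked run is a protected region with a conduction channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .eeml import BlockLineSet
from .maps import ActivationMap, VoltageMap
from .mesh import SurfaceMesh

DEFAULT_VOLTAGE_CUTOFF_MV = 0.5
DEFAULT_MIN_AREA_CM2 = 0.1
DEFAULT_BLOCK_TOLERANCE_MM = 2.0
DEFAULT_PROTECTION_THRESHOLD = 0.6
#: runs of unblocked boundary narrower than this are not conduction
#: channels: a preferential-conduction corridor must span a few
#: interelectrode spacings to carry a wavefront and be resolvable at
#: clinical mapping density; narrower runs are boundary-sampling artifacts
DEFAULT_MIN_GAP_WIDTH_MM = 4.0


@dataclass
class LowVoltageRegion:
    """One confluent low-voltage region."""

    triangles: np.ndarray
    area_cm2: float
    boundary_edges: np.ndarray
    contains_earliest_site: bool = False


@dataclass
class ChannelGap:
    """A contiguous run of unblocked boundary edges."""

    edges: np.ndarray
    width_mm: float


@dataclass
class ChannelReport:
    boundary_block_fraction: float
    gaps: list[ChannelGap] = field(default_factory=list)
    protected: bool = False

    @property
    def n_gaps(self) -> int:
        return len(self.gaps)


def region_area(mesh: SurfaceMesh, triangle_indices: np.ndarray) -> float:
    """Summed triangle area of a region, in cm^2 (1 cm^2 = 100 mm^2)."""
    return float(mesh.triangle_areas()[np.asarray(triangle_indices, int)].sum() / 100.0)


def _region_boundary(mesh: SurfaceMesh, tri_indices: np.ndarray) -> np.ndarray:
    """Edges used by exactly one member triangle (the region rim)."""
    tri = mesh.triangles[np.asarray(tri_indices, int)]
    raw = np.sort(np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [0, 2]]]), axis=1)
    uniq, counts = np.unique(raw, axis=0, return_counts=True)
    return uniq[counts == 1]


def segment_lva(
    voltage_map: VoltageMap,
    mesh: SurfaceMesh,
    cutoff: float = DEFAULT_VOLTAGE_CUTOFF_MV,
    min_area_cm2: float = DEFAULT_MIN_AREA_CM2,
) -> list[LowVoltageRegion]:
    """Confluent low-voltage regions, largest first.

    Triangles qualify when all three vertices are mapped and strictly
    below ``cutoff``; regions are edge-connected components of qualifying
    triangles, with components below ``min_area_cm2`` discarded as
    speckle.  A fully unmapped map yields an empty list.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    v = voltage_map.voltage
    low_vertex = np.where(np.isnan(v), False, v < cutoff)
    tri_low = low_vertex[mesh.triangles].all(axis=1)
    members = np.flatnonzero(tri_low)
    if len(members) == 0:
        return []
    adj = mesh.triangle_adjacency()[members][:, members]
    n_comp, labels = connected_components(adj, directed=False)
    regions = []
    for c in range(n_comp):
        tris = members[labels == c]
        area = region_area(mesh, tris)
        if area < min_area_cm2:
            continue
        regions.append(
            LowVoltageRegion(
                triangles=tris,
                area_cm2=area,
                boundary_edges=_region_boundary(mesh, tris),
            )
        )
    regions.sort(key=lambda r: r.area_cm2, reverse=True)
    return regions


def earliest_activation_site(
    amap: ActivationMap, mesh: SurfaceMesh
) -> tuple[int, np.ndarray]:
    """Vertex of minimal LAT; ties resolved to the tied vertex nearest the
    centroid of the tied set (deterministic)."""
    mapped = amap.mapped
    if not mapped.any():
        raise ValueError("no mapped vertices")
    lat_min = np.nanmin(amap.lat)
    tied = np.flatnonzero(mapped & (amap.lat == lat_min))
    if len(tied) > 1:
        centroid = mesh.vertices[tied].mean(axis=0)
        tied = tied[np.argsort(np.linalg.norm(mesh.vertices[tied] - centroid, axis=1), kind="stable")]
    v = int(tied[0])
    return v, mesh.vertices[v].copy()


def _order_boundary_loops(edges: np.ndarray) -> list[list[int]]:
    """Order boundary edges into loops (or open chains at a mesh border).

    Returns lists of indices into ``edges``; each list is in walk order.
    """
    from collections import defaultdict

    incident = defaultdict(list)
    for i, (a, b) in enumerate(edges):
        incident[int(a)].append(i)
        incident[int(b)].append(i)
    unused = set(range(len(edges)))
    loops = []
    while unused:
        # prefer starting from an endpoint of an open chain
        start = None
        for i in unused:
            a, b = edges[i]
            if len(incident[int(a)]) == 1 or len(incident[int(b)]) == 1:
                start = i
                break
        if start is None:
            start = next(iter(unused))
        a, b = (int(x) for x in edges[start])
        if len(incident[b]) == 1:
            a, b = b, a
        walk = [start]
        unused.discard(start)
        node = b
        while True:
            nxt = [i for i in incident[node] if i in unused]
            if not nxt:
                break
            i = nxt[0]
            walk.append(i)
            unused.discard(i)
            x, y = (int(v) for v in edges[i])
            node = y if x == node else x
        loops.append(walk)
    return loops


def boundary_block_coverage(
    region: LowVoltageRegion,
    block: BlockLineSet,
    mesh: SurfaceMesh,
    tolerance: float = DEFAULT_BLOCK_TOLERANCE_MM,
    protection_threshold: float = DEFAULT_PROTECTION_THRESHOLD,
    min_gap_width_mm: float = DEFAULT_MIN_GAP_WIDTH_MM,
) -> ChannelReport:
    """Blocked fraction of the region boundary and its channel gaps.

    A boundary edge counts as blocked when its midpoint lies within
    ``tolerance`` mm of any detected conduction-delay edge midpoint.
    Maximal cyclic runs of consecutive unblocked boundary edges at least
    ``min_gap_width_mm`` wide are the channel gaps, each reported with its
    along-boundary width.  The region is protected when the blocked
    fraction reaches the protection threshold and at least one gap
    remains.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    bedges = region.boundary_edges
    if len(bedges) == 0:
        raise ValueError("region has an empty boundary")
    mid = 0.5 * (mesh.vertices[bedges[:, 0]] + mesh.vertices[bedges[:, 1]])
    if len(block) == 0:
        blocked = np.zeros(len(bedges), dtype=bool)
    else:
        bmid = 0.5 * (mesh.vertices[block.edges[:, 0]] + mesh.vertices[block.edges[:, 1]])
        d, _ = cKDTree(bmid).query(mid)
        blocked = d <= tolerance
    fraction = float(blocked.mean())

    lengths = np.linalg.norm(
        mesh.vertices[bedges[:, 0]] - mesh.vertices[bedges[:, 1]], axis=1
    )
    gaps: list[ChannelGap] = []
    for walk in _order_boundary_loops(bedges):
        flags = blocked[walk]
        n = len(walk)
        if not flags.any():
            gaps.append(ChannelGap(edges=bedges[walk], width_mm=float(lengths[walk].sum())))
            continue
        closed = len(walk) > 2 and _is_closed(bedges, walk)
        runs = _unblocked_runs(flags, cyclic=closed)
        for run in runs:
            idx = [walk[i] for i in run]
            width = float(lengths[idx].sum())
            if width >= min_gap_width_mm:
                gaps.append(ChannelGap(edges=bedges[idx], width_mm=width))
    protected = fraction >= protection_threshold and len(gaps) >= 1
    return ChannelReport(boundary_block_fraction=fraction, gaps=gaps, protected=protected)


def _is_closed(edges: np.ndarray, walk: list[int]) -> bool:
    first, last = edges[walk[0]], edges[walk[-1]]
    return bool(set(map(int, first)) & set(map(int, last))) and len(walk) > 2


def _unblocked_runs(flags: np.ndarray, cyclic: bool) -> list[list[int]]:
    """Maximal runs of False in ``flags``, merging across the seam if cyclic."""
    n = len(flags)
    runs, current = [], []
    for i in range(n):
        if not flags[i]:
            current.append(i)
        elif current:
            runs.append(current)
            current = []
    if current:
        runs.append(current)
    if cyclic and len(runs) > 1 and runs[0][0] == 0 and runs[-1][-1] == n - 1:
        runs[0] = runs.pop() + runs[0]
    return runs
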