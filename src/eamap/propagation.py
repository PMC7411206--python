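"""Wavefront propagation on the mesh: ground-truth activation times.

Propagation is modelled as graph shortest-path travel time over mesh edges
(Dijkstra), with each edge traversed at the harmonic mean of its endpoint
conduction velocities.  This is a deliberate first-order approximation of
an eikonal wavefront: it recovers planted conduction block and channels at
the mesh scale while remaining exactly checkable against brute-force
shortest-path oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import dijkstra

from .mesh import SurfaceMesh
from .substrate import SubstrateMap, _angdiff

MECHANISMS = ("microreentry", "triggered", "automaticity")

#: Induction-protocol responses implied by each mechanism: triggered activity
#: is inducible and terminated by programmed stimulation; enhanced
#: automaticity is not inducible by pacing and needs isoproterenol.
DEFAULT_FLAGS = {
    "microreentry": dict(inducible_by_pes=True, terminated_by_pes=False, requires_isoproterenol=False),
    "triggered": dict(inducible_by_pes=True, terminated_by_pes=True, requires_isoproterenol=False),
    "automaticity": dict(inducible_by_pes=False, terminated_by_pes=False, requires_isoproterenol=True),
}


class SimulationError(RuntimeError):
    """Raised when activation cannot be propagated to the whole mesh."""


@dataclass
class TruthActivation:
    """Ground-truth local activation times (ms) with mechanism metadata."""

    lat: np.ndarray
    source_vertex: int
    mechanism: str
    tcl: float
    induction_flags: dict
    loop_vertices: np.ndarray | None = field(default=None, repr=False)

    @property
    def span(self) -> float:
        return float(self.lat.max() - self.lat.min())


def edge_travel_times(mesh: SurfaceMesh, cv: np.ndarray) -> np.ndarray:
    """Per-edge travel time (ms): length / harmonic-mean endpoint velocity."""
    cv = np.asarray(cv, dtype=float)
    if (cv <= 0).any():
        raise SimulationError("conduction velocities must be positive")
    e = mesh.edges
    hm = 2.0 * cv[e[:, 0]] * cv[e[:, 1]] / (cv[e[:, 0]] + cv[e[:, 1]])
    return mesh.edge_lengths() / hm


def _reentry_loop(mesh: SurfaceMesh, substrate: SubstrateMap) -> np.ndarray:
    """Closed vertex loop inside the LVA encircling its centre.

    Built from two half-loops: shortest paths between the ring vertices
    nearest azimuth 0 and pi, each restricted to its own half-plane so the
    joined path winds once around the centre.
    """
    r = substrate.params["lva_radius"]
    d, az = substrate.dist_from_center, substrate.azimuth
    band = (d > 0.35 * r) & (d < 0.75 * r)
    if band.sum() < 6:
        raise SimulationError("LVA too small to host a reentrant loop")
    cand = np.flatnonzero(band)
    a = cand[np.argmin(_angdiff(az[cand], 0.0))]
    b = cand[np.argmin(_angdiff(az[cand], np.pi))]

    loop: list[int] = []
    for lo, hi in ((0.0, np.pi), (-np.pi, 0.0)):
        allowed = band & (az >= lo - 0.3) & (az <= hi + 0.3)
        allowed[[a, b]] = True
        w = mesh.edge_lengths().copy()
        e = mesh.edges
        w[~(allowed[e[:, 0]] & allowed[e[:, 1]])] = 1e9  # bar edges leaving the band
        gw = mesh.edge_graph(w)
        src = a if lo == 0.0 else b
        dst = b if lo == 0.0 else a
        dist, pred = dijkstra(gw, directed=False, indices=src, return_predecessors=True)
        if not np.isfinite(dist[dst]) or dist[dst] >= 1e8:
            raise SimulationError("could not close a reentrant loop inside the LVA")
        path = [dst]
        while path[-1] != src:
            path.append(int(pred[path[-1]]))
        loop.extend(path[::-1][:-1])  # drop dst; next half starts with it
    arr = np.asarray(loop, dtype=int)
    _, first = np.unique(arr, return_index=True)
    return arr[np.sort(first)]  # guard against rare overlap at the junctions


def simulate_activation(
    mesh: SurfaceMesh,
    substrate: SubstrateMap,
    source_vertex: int,
    mechanism: str,
    tcl: float,
    induction_flags: dict | None = None,
) -> TruthActivation:
    """Propagate a focal or microreentrant activation over the mesh.

    Focal mechanisms (triggered activity, enhanced automaticity): LAT is the
    shortest-path travel time from the source vertex.  Microreentry: a
    closed loop inside the LVA is traversed with period ``tcl`` (loop edge
    times rescaled), and the rest of the mesh activates by shortest path
    from the loop vertices offset by their phase.  LATs are a single
    unwrapped window, not reduced modulo the cycle.
    """
    if mechanism not in MECHANISMS:
        raise SimulationError(f"unknown mechanism {mechanism!r}")
    if tcl <= 0:
        raise SimulationError("tcl must be positive")
    if not (0 <= source_vertex < mesh.n_vertices):
        raise SimulationError("source_vertex out of range")
    flags = dict(DEFAULT_FLAGS[mechanism]) if induction_flags is None else dict(induction_flags)

    times = edge_travel_times(mesh, substrate.cv)
    graph = mesh.edge_graph(times)

    if mechanism != "microreentry":
        lat = dijkstra(graph, directed=False, indices=source_vertex)
        if not np.isfinite(lat).all():
            raise SimulationError("mesh is not fully reachable from the source")
        return TruthActivation(lat, int(source_vertex), mechanism, float(tcl), flags)

    loop = _reentry_loop(mesh, substrate)
    pos = mesh.vertices[loop]
    seg = np.linalg.norm(np.diff(np.vstack([pos, pos[:1]]), axis=0), axis=1)
    cvl = substrate.cv[loop]
    cv_seg = 2 * cvl * np.roll(cvl, -1) / (cvl + np.roll(cvl, -1))
    seg_t = seg / cv_seg
    phases = np.concatenate([[0.0], np.cumsum(seg_t)[:-1]]) * (tcl / seg_t.sum())

    # the reentrant core is refractory: paths may not cut across the loop
    # interior, or early phases would short-circuit the circulating head
    core = np.flatnonzero(
        substrate.dist_from_center < 0.35 * substrate.params["lva_radius"]
    )
    core = np.setdiff1d(core, loop)
    blocked = times.copy()
    e = mesh.edges
    in_core = np.zeros(mesh.n_vertices, dtype=bool)
    in_core[core] = True
    blocked[in_core[e[:, 0]] | in_core[e[:, 1]]] = 1e9
    dist = dijkstra(mesh.edge_graph(blocked), directed=False, indices=loop)
    if not np.isfinite(dist).all(axis=0).all():
        raise SimulationError("mesh is not fully reachable from the loop")
    lat = np.min(phases[:, None] + dist, axis=0)
    # core vertices take the phase of the nearest loop vertex (the head
    # sweeps over the core margin as it circulates)
    if len(core):
        d2 = np.linalg.norm(
            mesh.vertices[core][:, None, :] - pos[None, :, :], axis=2
        )
        nearest = np.argmin(d2, axis=1)
        lat[core] = phases[nearest] + d2[np.arange(len(core)), nearest] / cv_normal_of(
            substrate, core
        )
    lat[loop] = phases  # forced circulation: loop vertices keep their phase
    return TruthActivation(lat, int(loop[0]), mechanism, float(tcl), flags, loop_vertices=loop)


def cv_normal_of(substrate: SubstrateMap, idx: np.ndarray) -> np.ndarray:
    return substrate.cv[np.asarray(idx, int)]
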