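"""Triangulated surface meshes for electroanatomical mapping.

All geometry is in millimetres.  A mesh is a set of 3-D vertices plus a
triangle index list; edges are derived.  The synthetic chamber geometry is
an open spherical-cap patch standing in for the mapped portion of an
atrium (default sphere radius 25 mm, i.e. an atrial-scale chamber).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra


class MeshError(ValueError):
    """Raised for invalid mesh construction parameters or degenerate meshes."""


@dataclass
class SurfaceMesh:
    """Triangulated surface: ``vertices`` (n, 3) in mm, ``triangles`` (m, 3) int."""

    vertices: np.ndarray
    triangles: np.ndarray
    _edges: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        if len(self.triangles):
            if self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices):
                raise MeshError("triangle references an out-of-range vertex index")
            same = (
                (self.triangles[:, 0] == self.triangles[:, 1])
                | (self.triangles[:, 1] == self.triangles[:, 2])
                | (self.triangles[:, 0] == self.triangles[:, 2])
            )
            if same.any():
                raise MeshError("triangle with repeated vertex index")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    @property
    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (e, 2) int array with v0 < v1."""
        if self._edges is None:
            tri = self.triangles
            raw = np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [0, 2]]])
            raw = np.sort(raw, axis=1)
            self._edges = np.unique(raw, axis=0)
        return self._edges

    def edge_lengths(self) -> np.ndarray:
        e = self.edges
        return np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)

    def triangle_areas(self) -> np.ndarray:
        """Per-triangle area (mm^2) via the cross-product formula."""
        p = self.vertices[self.triangles]
        cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def total_area_mm2(self) -> float:
        return float(self.triangle_areas().sum())

    def edge_graph(self, edge_weights: np.ndarray | None = None) -> csr_matrix:
        """Symmetric sparse adjacency over vertices, weighted by edge length
        unless explicit per-edge weights are given."""
        e = self.edges
        w = self.edge_lengths() if edge_weights is None else np.asarray(edge_weights, float)
        if len(w) != len(e):
            raise MeshError("edge weight array does not match edge count")
        n = self.n_vertices
        g = coo_matrix(
            (np.concatenate([w, w]), (np.concatenate([e[:, 0], e[:, 1]]), np.concatenate([e[:, 1], e[:, 0]]))),
            shape=(n, n),
        )
        return g.tocsr()

    def is_connected(self) -> bool:
        n_comp, _ = connected_components(self.edge_graph(), directed=False)
        return n_comp == 1

    def vertex_rings(self, seed_vertices: np.ndarray, n_rings: int = 1) -> np.ndarray:
        """Vertices within ``n_rings`` graph hops of the seed set (inclusive)."""
        g = self.edge_graph(np.ones(len(self.edges)))
        mask = np.zeros(self.n_vertices, dtype=bool)
        mask[np.asarray(seed_vertices, int)] = True
        for _ in range(n_rings):
            mask = mask | (g @ mask.astype(float) > 0)
        return np.flatnonzero(mask)

    def triangle_adjacency(self) -> csr_matrix:
        """Triangle-to-triangle adjacency across shared edges."""
        tri = self.triangles
        raw = np.sort(
            np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [0, 2]]]), axis=1
        )
        owner = np.tile(np.arange(len(tri)), 3)
        order = np.lexsort((raw[:, 1], raw[:, 0]))
        raw, owner = raw[order], owner[order]
        same = (raw[1:] == raw[:-1]).all(axis=1)
        a, b = owner[:-1][same], owner[1:][same]
        m = len(tri)
        g = coo_matrix(
            (np.ones(2 * len(a)), (np.concatenate([a, b]), np.concatenate([b, a]))),
            shape=(m, m),
        )
        return g.tocsr()

    def boundary_edges(self) -> np.ndarray:
        """Edges belonging to exactly one triangle (the open rim of a patch)."""
        tri = self.triangles
        raw = np.sort(np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [0, 2]]]), axis=1)
        uniq, counts = np.unique(raw, axis=0, return_counts=True)
        return uniq[counts == 1]


def geodesic_distances(
    mesh: SurfaceMesh,
    sources: np.ndarray | int,
    edge_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Graph-geodesic distance from source vertex (or vertices) to every vertex.

    Shortest paths run along mesh edges (Dijkstra); with the default
    length weighting this approximates surface geodesic distance to within
    the mesh resolution.
    """
    idx = np.atleast_1d(np.asarray(sources, dtype=int))
    d = dijkstra(mesh.edge_graph(edge_weights), directed=False, indices=idx)
    return d[0] if np.isscalar(sources) or np.ndim(sources) == 0 else d


def _icosphere(resolution: float, sphere_radius: float) -> trimesh.Trimesh:
    # icosahedron edge for circumradius R is ~1.051*R; each subdivision halves it
    base_edge = sphere_radius / np.sin(2 * np.pi / 5)
    subdivisions = int(np.clip(round(np.log2(base_edge / resolution)), 0, 7))
    return trimesh.creation.icosphere(subdivisions=subdivisions, radius=sphere_radius)


def generate_flat_patch(resolution: float, width: float, height: float) -> SurfaceMesh:
    """Flat equilateral-lattice patch in the z=0 plane (test phantom).

    Plane geometry makes chord distance, surface geodesic distance and
    analytic areas coincide, which is what area-recovery oracles need.
    """
    if resolution <= 0:
        raise MeshError("resolution must be positive")
    dy = resolution * np.sqrt(3) / 2
    n_rows = int(round(height / dy)) + 1
    n_cols = int(round(width / resolution)) + 1
    verts = []
    index = {}
    for r in range(n_rows):
        offset = 0.5 * resolution * (r % 2)
        for c in range(n_cols):
            index[(r, c)] = len(verts)
            verts.append((c * resolution + offset - width / 2, r * dy - height / 2, 0.0))
    tris = []
    for r in range(n_rows - 1):
        for c in range(n_cols - 1):
            a, b = index[(r, c)], index[(r, c + 1)]
            d, e = index[(r + 1, c)], index[(r + 1, c + 1)]
            if r % 2 == 0:
                tris += [(a, b, d), (b, e, d)]
            else:
                tris += [(a, b, e), (a, e, d)]
    return SurfaceMesh(np.array(verts), np.array(tris))


def generate_atrial_mesh(
    resolution: float,
    extent: float,
    seed: int,
    sphere_radius: float = 25.0,
    vertex_jitter: float = 0.15,
) -> SurfaceMesh:
    """Open spherical-cap patch emulating a mapped atrial region.

    Parameters
    ----------
    resolution : target edge length (mm); realised edges fall in
        [0.5, 2] x resolution.
    extent : geodesic radius of the cap from its apex (mm); must exceed
        5 x resolution.  An extent of ``pi * sphere_radius`` closes the
        sphere (used for area self-tests).
    seed : orients the icosphere tessellation relative to the cap apex and
        drives the vertex jitter, so different seeds give different (but
        reproducible) triangulations.
    vertex_jitter : tangential displacement of each vertex, as a fraction
        of ``resolution``; breaks the crystalline regularity of the
        icosphere lattice the way an anatomical triangulation would.
    """
    if resolution <= 0:
        raise MeshError("resolution must be positive")
    if extent <= 5 * resolution:
        raise MeshError("extent must exceed 5x resolution")
    sphere = _icosphere(resolution, sphere_radius)
    rng = np.random.default_rng(seed)
    rot = trimesh.transformations.random_rotation_matrix(rng.random(3))[:3, :3]
    verts = np.asarray(sphere.vertices @ rot.T)
    if vertex_jitter > 0:
        # bounded tangential displacement (uniform over a disk of radius
        # jitter*resolution) keeps edge lengths inside their guard band
        disp = rng.normal(0.0, 1.0, verts.shape)
        normals = verts / sphere_radius
        disp -= (disp * normals).sum(axis=1, keepdims=True) * normals
        norm = np.linalg.norm(disp, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        radius = vertex_jitter * resolution * np.sqrt(rng.random((len(verts), 1)))
        verts = verts + disp / norm * radius
        verts *= sphere_radius / np.linalg.norm(verts, axis=1, keepdims=True)

    # keep the cap of geodesic radius `extent` about the +z apex
    polar = np.arccos(np.clip(verts[:, 2] / sphere_radius, -1.0, 1.0))
    keep = polar <= min(extent / sphere_radius, np.pi) + 1e-12
    if keep.all():
        mesh = SurfaceMesh(verts, sphere.faces.copy())
    else:
        tri_keep = keep[sphere.faces].all(axis=1)
        faces = sphere.faces[tri_keep]
        used = np.unique(faces)
        remap = -np.ones(len(verts), dtype=np.int64)
        remap[used] = np.arange(len(used))
        mesh = SurfaceMesh(verts[used], remap[faces])
        if not mesh.is_connected():  # trim stray fragments, keep the apex component
            _, labels = connected_components(mesh.edge_graph(), directed=False)
            apex = int(np.argmax(mesh.vertices[:, 2]))
            vkeep = labels == labels[apex]
            tri_keep = vkeep[mesh.triangles].all(axis=1)
            used = np.unique(mesh.triangles[tri_keep])
            remap = -np.ones(mesh.n_vertices, dtype=np.int64)
            remap[used] = np.arange(len(used))
            mesh = SurfaceMesh(mesh.vertices[used], remap[mesh.triangles[tri_keep]])

    lengths = mesh.edge_lengths()
    if lengths.min() < 0.5 * resolution or lengths.max() > 2.0 * resolution:
        raise MeshError(
            f"achievable edge lengths [{lengths.min():.3g}, {lengths.max():.3g}] mm "
            f"fall outside [0.5, 2] x resolution={resolution} mm"
        )
    if (mesh.triangle_areas() <= 0).any():
        raise MeshError("degenerate zero-area triangle produced")
    return mesh
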