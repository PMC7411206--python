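"""File formats: PLY and legacy ASCII VTK meshes, CSV point/trace tables,
JSON truth sidecars and reports.

PLY goes through trimesh (binary little-endian).  The legacy VTK polydata
writer emits POINTS/POLYGONS plus one SCALARS array per map quantity so
the overlays open in standard viewers; the matching reader round-trips
everything this package writes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .egm import EgmTrace
from .mesh import SurfaceMesh
from .propagation import TruthActivation
from .sampling import MappingPointSet
from .substrate import SubstrateMap


# ---------------------------------------------------------------- meshes

def save_ply(mesh: SurfaceMesh, path: str | Path) -> None:
    """Binary little-endian PLY with double-precision vertices (so meshes
    round-trip bit-exactly; most writers downcast to float32)."""
    header = "\n".join([
        "ply",
        "format binary_little_endian 1.0",
        f"element vertex {mesh.n_vertices}",
        "property double x",
        "property double y",
        "property double z",
        f"element face {mesh.n_triangles}",
        "property list uchar int vertex_indices",
        "end_header",
    ]) + "\n"
    body = mesh.vertices.astype("<f8").tobytes()
    faces = np.empty((mesh.n_triangles, 13), dtype=np.uint8)
    faces[:, 0] = 3
    faces[:, 1:] = mesh.triangles.astype("<i4").view(np.uint8).reshape(-1, 12)
    Path(path).write_bytes(header.encode("ascii") + body + faces.tobytes())


def load_ply(path: str | Path) -> SurfaceMesh:
    tm = trimesh.load(str(path), file_type="ply", process=False, force="mesh")
    return SurfaceMesh(np.asarray(tm.vertices, float), np.asarray(tm.faces, np.int64))


def save_vtk(
    mesh: SurfaceMesh,
    path: str | Path,
    point_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Legacy ASCII VTK polydata with optional per-vertex SCALARS arrays.

    NaNs (unmapped vertices) are written as-is; VTK viewers render them as
    blanked scalars.
    """
    lines = [
        "# vtk DataFile Version 3.0",
        "eamap surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {mesh.n_vertices} double",
    ]
    lines += [" ".join(f"{x:.9g}" for x in v) for v in mesh.vertices]
    lines.append(f"POLYGONS {mesh.n_triangles} {4 * mesh.n_triangles}")
    lines += ["3 " + " ".join(str(i) for i in t) for t in mesh.triangles]
    if point_data:
        lines.append(f"POINT_DATA {mesh.n_vertices}")
        for name, arr in point_data.items():
            arr = np.asarray(arr, dtype=float)
            if len(arr) != mesh.n_vertices:
                raise ValueError(f"point_data[{name!r}] length mismatch")
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{x:.9g}" for x in arr]
    Path(path).write_text("\n".join(lines) + "\n")


def load_vtk(path: str | Path) -> tuple[SurfaceMesh, dict[str, np.ndarray]]:
    tokens: list[str] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    verts = tris = None
    data: dict[str, np.ndarray] = {}
    n_pts = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("POINTS"):
            n_pts = int(line.split()[1])
            vals: list[float] = []
            i += 1
            while len(vals) < 3 * n_pts:
                vals += [float(x) for x in lines[i].split()]
                i += 1
            verts = np.array(vals).reshape(n_pts, 3)
            continue
        if line.startswith("POLYGONS"):
            n_tri = int(line.split()[1])
            ints: list[int] = []
            i += 1
            while len(ints) < 4 * n_tri:
                ints += [int(x) for x in lines[i].split()]
                i += 1
            tris = np.array(ints).reshape(n_tri, 4)[:, 1:]
            continue
        if line.startswith("SCALARS"):
            name = line.split()[1]
            i += 2  # skip LOOKUP_TABLE
            vals = []
            while len(vals) < n_pts:
                vals += [float(x) for x in lines[i].split()]
                i += 1
            data[name] = np.array(vals)
            continue
        i += 1
    if verts is None or tris is None:
        raise ValueError(f"{path}: not a polydata VTK file")
    return SurfaceMesh(verts, tris), data


def save_block_lines_vtk(mesh: SurfaceMesh, edges: np.ndarray, path: str | Path) -> None:
    """Flagged edges as a VTK line set for overlay rendering."""
    used = np.unique(edges) if len(edges) else np.array([], dtype=int)
    remap = {int(v): i for i, v in enumerate(used)}
    lines = [
        "# vtk DataFile Version 3.0",
        "eamap block lines",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(used)} double",
    ]
    lines += [" ".join(f"{x:.9g}" for x in mesh.vertices[v]) for v in used]
    lines.append(f"LINES {len(edges)} {3 * len(edges)}")
    lines += [f"2 {remap[int(a)]} {remap[int(b)]}" for a, b in edges]
    Path(path).write_text("\n".join(lines) + "\n")


# ------------------------------------------------------- points and traces

def save_points_csv(points: MappingPointSet, path: str | Path) -> None:
    points.table.to_csv(path, index=False)


def save_traces_csv(points: MappingPointSet, path: str | Path) -> None:
    """All traces in one long-format CSV: point_id, t_ms, v_mV."""
    frames = [
        pd.DataFrame(
            {"point_id": pid, "t_ms": tr.t, "v_mV": tr.v}
        )
        for pid, tr in zip(points.table["point_id"], points.traces)
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6g")


def load_traces_csv(path: str | Path) -> dict[int, EgmTrace]:
    df = pd.read_csv(path)
    return {
        int(pid): EgmTrace(g["t_ms"].to_numpy(), g["v_mV"].to_numpy())
        for pid, g in df.groupby("point_id")
    }


# ------------------------------------------------------------ truth / JSON

def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def save_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def save_truth_json(
    truth: TruthActivation, substrate: SubstrateMap, path: str | Path
) -> None:
    save_json(
        dict(
            lat_ms=truth.lat,
            source_vertex=truth.source_vertex,
            mechanism=truth.mechanism,
            tcl_ms=truth.tcl,
            induction_flags=truth.induction_flags,
            loop_vertices=None if truth.loop_vertices is None else truth.loop_vertices,
            lva_vertices=substrate.lva_vertices,
            slow_zone_edges=substrate.slow_zone_edges,
            channel_vertices=substrate.channel_vertices,
            substrate_params=substrate.params,
        ),
        path,
    )
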