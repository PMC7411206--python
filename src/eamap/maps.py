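"""Activation and voltage map construction by interpolation onto the mesh.

Per-vertex values are inverse-distance-weighted (power 2) means of the
k nearest annotated points within the fill threshold; vertices with no
point in range stay unmapped (the clinical convention of leaving the
surface uncoloured beyond the fill threshold, here interpreted as a 5 mm
Euclidean distance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .mesh import SurfaceMesh

DEFAULT_FILL_THRESHOLD_MM = 5.0


class EmptyMapError(ValueError):
    """Raised when no annotated points (or too few mapped vertices) exist."""


@dataclass
class ActivationMap:
    """Per-vertex LAT (ms); NaN marks unmapped vertices."""

    lat: np.ndarray
    tcl: float
    reference_time: float = 0.0

    @property
    def mapped(self) -> np.ndarray:
        return ~np.isnan(self.lat)

    @property
    def mapped_span(self) -> float:
        return mapped_cycle_span(self)


@dataclass
class VoltageMap:
    """Per-vertex bipolar peak-to-peak amplitude (mV); NaN unmapped."""

    voltage: np.ndarray

    @property
    def mapped(self) -> np.ndarray:
        return ~np.isnan(self.voltage)


@dataclass
class IsochroneSet:
    band_edges: np.ndarray
    band_index: np.ndarray  # -1 for unmapped vertices

    @property
    def n_bands(self) -> int:
        return len(self.band_edges) - 1


def _idw(
    mesh: SurfaceMesh,
    positions: np.ndarray,
    values: np.ndarray,
    fill_threshold: float,
    k: int,
    power: float,
) -> np.ndarray:
    tree = cKDTree(positions)
    k_eff = min(k, len(positions))
    dist, idx = tree.query(mesh.vertices, k=k_eff, distance_upper_bound=fill_threshold)
    dist = np.atleast_2d(dist.T).T if dist.ndim == 1 else dist
    idx = np.atleast_2d(idx.T).T if idx.ndim == 1 else idx
    out = np.full(mesh.n_vertices, np.nan)
    in_range = np.isfinite(dist)
    any_in = in_range.any(axis=1)
    # exact hits adopt the point value outright
    exact = in_range & (dist < 1e-12)
    for vi in np.flatnonzero(any_in):
        sel = in_range[vi]
        if exact[vi].any():
            out[vi] = values[idx[vi][exact[vi]]].mean()
            continue
        w = 1.0 / dist[vi][sel] ** power
        out[vi] = float(np.sum(w * values[idx[vi][sel]]) / w.sum())
    return out


def build_maps(
    mesh: SurfaceMesh,
    features: pd.DataFrame,
    tcl: float,
    fill_threshold: float = DEFAULT_FILL_THRESHOLD_MM,
    k_neighbors: int = 10,
    power: float = 2.0,
    voltage_k_neighbors: int | None = 1,
) -> tuple[ActivationMap, VoltageMap]:
    """Interpolate annotated points onto the mesh.

    ``features`` needs columns x_mm, y_mm, z_mm, lat_ms, p2p_mv (the
    output of :func:`eamap.features.annotate_points`).

    Activation uses the k-neighbor IDW mean; the voltage map defaults to
    nearest-point projection (``voltage_k_neighbors=1``), matching the
    clinical convention of colouring amplitude by the measured point value
    — averaging across the sharp healthy/diseased amplitude step would
    bias low-voltage borders inward.  Pass ``None`` to reuse
    ``k_neighbors`` for voltage as well.
    """
    if len(features) == 0:
        raise EmptyMapError("no annotated points to interpolate")
    if fill_threshold <= 0:
        raise ValueError("fill_threshold must be positive")
    pos = features[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    kv = k_neighbors if voltage_k_neighbors is None else voltage_k_neighbors
    lat = _idw(mesh, pos, features["lat_ms"].to_numpy(dtype=float), fill_threshold, k_neighbors, power)
    volt = _idw(mesh, pos, features["p2p_mv"].to_numpy(dtype=float), fill_threshold, kv, power)
    return ActivationMap(lat=lat, tcl=float(tcl)), VoltageMap(voltage=volt)


def mapped_cycle_span(amap: ActivationMap) -> float:
    """Max minus min LAT over mapped vertices (the cycle length mapped)."""
    mapped = amap.mapped
    if mapped.sum() < 2:
        raise EmptyMapError("need at least 2 mapped vertices for a span")
    vals = amap.lat[mapped]
    return float(vals.max() - vals.min())


def isochrones(amap: ActivationMap, n_bands: int = 8) -> IsochroneSet:
    """Equal-width activation-time bands over [min LAT, max LAT].

    Bands are right-open except the last; a zero-span map degenerates to a
    single band holding every mapped vertex.
    """
    if n_bands < 2:
        raise ValueError("n_bands must be >= 2")
    mapped = amap.mapped
    if not mapped.any():
        raise EmptyMapError("cannot band an empty map")
    lo, hi = float(np.nanmin(amap.lat)), float(np.nanmax(amap.lat))
    band_index = np.full(len(amap.lat), -1, dtype=int)
    if hi == lo:
        band_index[mapped] = 0
        return IsochroneSet(band_edges=np.array([lo, hi]), band_index=band_index)
    edges = np.linspace(lo, hi, n_bands + 1)
    idx = np.clip(np.searchsorted(edges, amap.lat[mapped], side="right") - 1, 0, n_bands - 1)
    band_index[mapped] = idx
    return IsochroneSet(band_edges=edges, band_index=band_index)
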