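"""End-to-end pipeline: simulate -> annotate -> map -> EEML -> LVA -> classify.

A run is fully described by a :class:`RunConfig` (serialisable to JSON or
YAML) and a seed; identical configs reproduce identical reports.  When an
output directory is given, every intermediate artifact is written in an
open format (PLY/VTK/CSV/JSON) so each stage can be re-read and rerun in
isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as eio
from .eeml import detect_block_edges
from .features import annotate_points
from .lva import (
    boundary_block_coverage,
    earliest_activation_site,
    segment_lva,
)
from .maps import build_maps, isochrones, mapped_cycle_span
from .mechanism import classify_mechanism, coverage_fraction
from .mesh import SurfaceMesh, generate_atrial_mesh, geodesic_distances
from .propagation import TruthActivation, simulate_activation
from .sampling import MappingPointSet, sample_points
from .substrate import SubstrateMap, _angdiff, lva_truth_area_cm2, plant_substrate

log = logging.getLogger("eamap")

SCENARIOS = ("triggered", "automaticity", "microreentry")


@dataclass
class RunConfig:
    """All pipeline parameters with their defaults.

    Defaults encode the study conditions: >= 1500 sampled points, 5 mm fill
    threshold, EEML lower/upper fractions 25%/75%, 0.5 mV voltage cutoff,
    70 ms duration cutoff, 3-deflection cutoff, and a planted low-voltage
    patch of about 3.2 cm^2 on an atrial-scale spherical patch.
    """

    scenario: str = "triggered"
    seed: int = 0
    # mesh
    resolution: float = 1.0
    extent: float = 30.0
    sphere_radius: float = 25.0
    # substrate: a thin near-block rim (functional block line) around the
    # low-voltage patch, interrupted by one normally conducting channel
    lva_radius: float = 10.1
    annulus_width: float = 1.5
    channel_angle_span: float = 60.0
    channel_angle_center: float = 0.0
    cv_normal: float = 0.8
    cv_slow: float = 0.0075
    # tachycardia
    tcl: float = 300.0
    # sampling
    n_points: int = 1500
    lat_noise_sd: float = 3.0
    dense_weight: float = 3.0
    # annotation
    noise_floor: float = 0.05
    prominence: float = 0.05
    # mapping
    fill_threshold: float = 5.0
    k_neighbors: int = 6
    n_bands: int = 8
    # EEML
    lower_fraction: float = 0.25
    upper_fraction: float = 0.75
    # LVA / channel
    voltage_cutoff: float = 0.5
    min_area_cm2: float = 0.1
    block_tolerance: float = 2.0
    protection_threshold: float = 0.6
    min_gap_width_mm: float = 4.0
    # artifacts
    write_traces: bool = False

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if not (0 < self.lower_fraction <= self.upper_fraction < 1):
            raise ValueError("need 0 < lower_fraction <= upper_fraction < 1")
        for name in (
            "resolution", "extent", "sphere_radius", "lva_radius", "annulus_width",
            "cv_normal", "cv_slow", "tcl", "fill_threshold", "voltage_cutoff",
            "noise_floor", "prominence", "block_tolerance",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    config: dict
    n_vertices: int
    n_points: int
    mapped_span_ms: float
    tcl_ms: float
    coverage_fraction: float
    mechanism_label: str
    mechanism_truth: str
    earliest_vertex: int
    earliest_position_mm: list
    mean_voltage_at_earliest_mv: float
    n_regions: int
    largest_region_area_cm2: float
    earliest_site_in_lva: bool
    boundary_block_fraction: float
    n_channel_gaps: int
    gap_widths_mm: list
    protected: bool
    n_eeml_edges: int
    n_eml_edges: int
    truth_metrics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> None:
        eio.save_json(self.to_dict(), path)


def dilate_edge_set(mesh: SurfaceMesh, edges: np.ndarray, n_rings: int = 1) -> set:
    """Edges whose endpoints both lie within ``n_rings`` hops of the given
    edge set's vertices (the edge set itself included)."""
    if len(edges) == 0:
        return set()
    verts = np.unique(edges)
    grown = mesh.vertex_rings(verts, n_rings)
    mask = np.zeros(mesh.n_vertices, dtype=bool)
    mask[grown] = True
    e = mesh.edges
    ok = mask[e[:, 0]] & mask[e[:, 1]]
    return {(int(a), int(b)) for a, b in e[ok]}


def block_edge_metrics(
    mesh: SurfaceMesh,
    detected: np.ndarray,
    truth: np.ndarray,
    n_rings: int = 1,
) -> dict:
    """Sensitivity/precision of detected block edges against planted truth,
    with an ``n_rings`` dilation allowance on both sides (annotation
    jitter moves a detected line by about one mesh edge)."""
    det = {(int(a), int(b)) for a, b in np.sort(np.asarray(detected).reshape(-1, 2), axis=1)}
    tru = {(int(a), int(b)) for a, b in np.sort(np.asarray(truth).reshape(-1, 2), axis=1)}
    if not tru:
        return dict(sensitivity=np.nan, precision=np.nan, n_detected=len(det), n_truth=0)
    det_dil = dilate_edge_set(mesh, np.array(sorted(det)) if det else np.empty((0, 2)), n_rings)
    tru_dil = dilate_edge_set(mesh, np.array(sorted(tru)), n_rings)
    sens = sum(1 for t in tru if t in det_dil) / len(tru)
    prec = (sum(1 for d in det if d in tru_dil) / len(det)) if det else 0.0
    return dict(
        sensitivity=float(sens),
        precision=float(prec),
        n_detected=len(det),
        n_truth=len(tru),
    )


def gap_overlaps_channel(
    gap_edges: np.ndarray, substrate: SubstrateMap
) -> bool:
    """Does a boundary gap overlap the planted channel sector (by azimuth)?"""
    az = substrate.azimuth
    mid_az = np.arctan2(
        np.sin(az[gap_edges[:, 0]]) + np.sin(az[gap_edges[:, 1]]),
        np.cos(az[gap_edges[:, 0]]) + np.cos(az[gap_edges[:, 1]]),
    )
    half = np.deg2rad(substrate.params["channel_angle_span"]) / 2
    center = np.deg2rad(substrate.params["channel_angle_center"])
    return bool((_angdiff(mid_az, center) <= half).any())


def simulate_scenario(
    config: RunConfig,
) -> tuple[SurfaceMesh, SubstrateMap, TruthActivation, MappingPointSet]:
    """Generate mesh, substrate, ground-truth activation and sampled points."""
    t0 = time.perf_counter()
    mesh = generate_atrial_mesh(
        config.resolution, config.extent, config.seed, config.sphere_radius
    )
    log.info("mesh: %d vertices, %d triangles (%.2f s)",
             mesh.n_vertices, mesh.n_triangles, time.perf_counter() - t0)
    apex = np.array([0.0, 0.0, config.sphere_radius])
    substrate = plant_substrate(
        mesh,
        apex,
        config.lva_radius,
        annulus_width=config.annulus_width,
        channel_angle_span=config.channel_angle_span,
        channel_angle_center=config.channel_angle_center,
        cv_normal=config.cv_normal,
        cv_slow=config.cv_slow,
        seed=config.seed + 1,
    )
    truth = simulate_activation(
        mesh, substrate, substrate.center_vertex, config.scenario, config.tcl
    )
    points = sample_points(
        mesh, truth, substrate,
        n_points=config.n_points,
        lat_noise_sd=config.lat_noise_sd,
        seed=config.seed + 2,
        dense_weight=config.dense_weight,
    )
    log.info("scenario %s: %d points, truth span %.1f ms (TCL %.0f ms)",
             config.scenario, len(points), truth.span, truth.tcl)
    return mesh, substrate, truth, points


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> RunReport:
    """Execute the full analysis chain and return (optionally write) the report."""
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        for sub in ("mesh", "points", "maps", "eeml", "lva"):
            (out / sub).mkdir(exist_ok=True)
        fh = logging.FileHandler(out / "run.log")
        fh.setLevel(logging.INFO)
        log.addHandler(fh)

    try:
        mesh, substrate, truth, points = simulate_scenario(config)

        t0 = time.perf_counter()
        feats = annotate_points(points, config.noise_floor, config.prominence)
        log.info("features: %d/%d abnormal (%.2f s)",
                 int(feats["abnormal"].sum()), len(feats), time.perf_counter() - t0)

        amap, vmap = build_maps(
            mesh, feats, config.tcl,
            fill_threshold=config.fill_threshold, k_neighbors=config.k_neighbors,
        )
        span = mapped_cycle_span(amap)
        bands = isochrones(amap, config.n_bands)
        log.info("maps: %d mapped vertices, span %.1f ms",
                 int(amap.mapped.sum()), span)

        block = detect_block_edges(
            amap, mesh, config.lower_fraction, config.upper_fraction
        )
        n_eml = int((block.kind == "EML").sum())
        log.info("eeml: %d delay edges (%d early-meets-late)", len(block), n_eml)

        regions = segment_lva(vmap, mesh, config.voltage_cutoff, config.min_area_cm2)
        earliest_v, earliest_pos = earliest_activation_site(amap, mesh)
        for r in regions:
            r.contains_earliest_site = bool(
                np.isin(mesh.triangles[r.triangles], earliest_v).any()
            )
        target = next((r for r in regions if r.contains_earliest_site),
                      regions[0] if regions else None)
        if target is not None:
            channel = boundary_block_coverage(
                target, block, mesh, config.block_tolerance,
                config.protection_threshold, config.min_gap_width_mm,
            )
        else:
            channel = None
        log.info("lva: %d regions, largest %.2f cm^2",
                 len(regions), regions[0].area_cm2 if regions else 0.0)

        # bipolar amplitude of the signals recorded at the earliest site
        pt_pos = feats[["x_mm", "y_mm", "z_mm"]].to_numpy()
        near = np.linalg.norm(pt_pos - earliest_pos, axis=1) <= 3.0
        vnear = feats.loc[near, "p2p_mv"]
        mean_v_earliest = float(vnear.mean()) if len(vnear) else float("nan")

        cov = coverage_fraction(span, config.tcl)
        call = classify_mechanism(cov, **truth.induction_flags)
        log.info("mechanism: %s (coverage %.2f, truth %s)",
                 call.label, cov, truth.mechanism)

        metrics = compare_to_truth(
            mesh, substrate, truth, block, regions, earliest_v, call.label
        )
        if channel is not None and channel.n_gaps and metrics is not None:
            metrics["widest_gap_overlaps_channel"] = gap_overlaps_channel(
                max(channel.gaps, key=lambda g: g.width_mm).edges, substrate
            )

        report = RunReport(
            config=config.to_dict(),
            n_vertices=mesh.n_vertices,
            n_points=len(points),
            mapped_span_ms=span,
            tcl_ms=config.tcl,
            coverage_fraction=cov,
            mechanism_label=call.label,
            mechanism_truth=truth.mechanism,
            earliest_vertex=int(earliest_v),
            earliest_position_mm=[float(x) for x in earliest_pos],
            mean_voltage_at_earliest_mv=mean_v_earliest,
            n_regions=len(regions),
            largest_region_area_cm2=regions[0].area_cm2 if regions else 0.0,
            earliest_site_in_lva=bool(target is not None and target.contains_earliest_site),
            boundary_block_fraction=channel.boundary_block_fraction if channel else float("nan"),
            n_channel_gaps=channel.n_gaps if channel else 0,
            gap_widths_mm=[g.width_mm for g in channel.gaps] if channel else [],
            protected=bool(channel.protected) if channel else False,
            n_eeml_edges=len(block),
            n_eml_edges=n_eml,
            truth_metrics=metrics,
        )

        if out is not None:
            _write_artifacts(out, config, mesh, substrate, truth, points, feats,
                             amap, vmap, bands, block, regions, report)
        return report
    finally:
        if out is not None:
            log.removeHandler(fh)
            fh.close()


def compare_to_truth(
    mesh: SurfaceMesh,
    substrate: SubstrateMap,
    truth: TruthActivation,
    block,
    regions,
    earliest_vertex: int,
    mechanism_label: str,
) -> dict:
    """Validation metrics against the planted ground truth."""
    m = block_edge_metrics(mesh, block.edges, substrate.slow_zone_edges)
    truth_area = lva_truth_area_cm2(mesh, substrate)
    if regions:
        measured = max(regions, key=lambda r: r.area_cm2).area_cm2
        area_rel_err = abs(measured - truth_area) / truth_area if truth_area else np.nan
    else:
        area_rel_err = np.nan
    geo = geodesic_distances(mesh, truth.source_vertex)
    m.update(
        lva_area_truth_cm2=truth_area,
        lva_area_relative_error=float(area_rel_err),
        source_localization_error_mm=float(geo[earliest_vertex]),
        mechanism_agreement=bool(mechanism_label == truth.mechanism),
    )
    return m


def _write_artifacts(out, config, mesh, substrate, truth, points, feats,
                     amap, vmap, bands, block, regions, report) -> None:
    config.save(out / "config.json")
    eio.save_ply(mesh, out / "mesh" / "surface.ply")
    eio.save_vtk(mesh, out / "mesh" / "surface.vtk")
    eio.save_truth_json(truth, substrate, out / "mesh" / "truth.json")
    eio.save_points_csv(points, out / "points" / "points.csv")
    if config.write_traces:
        eio.save_traces_csv(points, out / "points" / "traces.csv")
    feats.to_csv(out / "points" / "features.csv", index=False)
    eio.save_vtk(
        mesh, out / "maps" / "maps.vtk",
        point_data=dict(
            lat_ms=amap.lat, voltage_mv=vmap.voltage,
            band=bands.band_index.astype(float),
        ),
    )
    eio.save_json(
        dict(mapped_span_ms=report.mapped_span_ms, tcl_ms=report.tcl_ms,
             n_mapped=int(amap.mapped.sum()),
             n_unmapped=int((~amap.mapped).sum())),
        out / "maps" / "summary.json",
    )
    import pandas as pd

    pd.DataFrame(
        dict(v1=block.edges[:, 0], v2=block.edges[:, 1],
             dlat_ms=block.dlat,
             fraction=block.dlat / block.normalizer,
             kind=block.kind)
    ).to_csv(out / "eeml" / "block_edges.csv", index=False)
    eio.save_block_lines_vtk(mesh, block.edges, out / "eeml" / "block_lines.vtk")
    pd.DataFrame(
        [
            dict(region_id=i, n_triangles=len(r.triangles), area_cm2=r.area_cm2,
                 contains_earliest_site=r.contains_earliest_site)
            for i, r in enumerate(regions)
        ]
    ).to_csv(out / "lva" / "regions.csv", index=False)
    report.save(out / "report.json")
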