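"""Shared fixtures: small meshes and cached scenario runs.

Everything is generated programmatically and seeded; session scope keeps
the expensive end-to-end runs to one execution each.
"""

from __future__ import annotations

import numpy as np
import pytest

from eamap import (
    RunConfig,
    generate_atrial_mesh,
    generate_flat_patch,
    plant_substrate,
    run_pipeline,
)
from eamap.mesh import SurfaceMesh


@pytest.fixture(scope="session")
def flat_patch():
    """40 x 40 mm flat lattice at 1 mm resolution (area phantom)."""
    return generate_flat_patch(1.0, 40.0, 40.0)


@pytest.fixture(scope="session")
def small_mesh():
    """~30-vertex mesh for brute-force oracles."""
    return generate_flat_patch(1.0, 5.0, 4.0)


@pytest.fixture(scope="session")
def cap_mesh():
    """Default atrial-scale spherical-cap patch."""
    return generate_atrial_mesh(1.0, 30.0, seed=7)


@pytest.fixture(scope="session")
def default_scenario():
    """Full seeded focal scenario: mesh, substrate, truth, points."""
    from eamap.pipeline import simulate_scenario

    return simulate_scenario(RunConfig(scenario="triggered", seed=1))


@pytest.fixture(scope="session")
def default_report():
    """End-to-end report for the default focal scenario (seed 1)."""
    return run_pipeline(RunConfig(scenario="triggered", seed=1))


@pytest.fixture(scope="session")
def flat_substrate(flat_patch):
    """Planted disc + rim + channel on the flat phantom."""
    return plant_substrate(
        flat_patch, [0.0, 0.0, 0.0], 10.1, annulus_width=1.5,
        channel_angle_span=60.0, cv_slow=0.0075, seed=3,
    )


@pytest.fixture(scope="session")
def cap_substrate(cap_mesh):
    """Planted 3.2 cm^2-scale disc + rim + channel on the atrial cap."""
    return plant_substrate(
        cap_mesh, [0.0, 0.0, 25.0], 10.1, annulus_width=1.5,
        channel_angle_span=60.0, cv_slow=0.0075, seed=3,
    )


def tiny_config(**overrides) -> RunConfig:
    """A fast, small pipeline configuration for smoke tests."""
    base = dict(
        scenario="triggered", seed=4, resolution=1.5, extent=13.0,
        lva_radius=5.0, annulus_width=1.5, channel_angle_span=80.0,
        n_points=300, tcl=300.0,
    )
    base.update(overrides)
    return RunConfig(**base)


def brute_force_shortest_paths(mesh: SurfaceMesh, weights: np.ndarray) -> np.ndarray:
    """Floyd-Warshall all-pairs shortest paths over mesh edges.

    Independent of the scipy Dijkstra used by the simulator; cubic in the
    vertex count, so only for meshes of a few dozen vertices.
    """
    n = mesh.n_vertices
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for (a, b), w in zip(mesh.edges, weights):
        d[a, b] = d[b, a] = min(d[a, b], w)
    for k in range(n):
        d = np.minimum(d, d[:, k : k + 1] + d[k : k + 1, :])
    return d
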