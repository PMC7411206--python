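"""Detect conduction-delay lines with the extended early-meets-late rule.

An edge of the interpolated activation map is flagged when its endpoint
activation difference exceeds 25% (delay/block) or 75% (early-meets-late)
of the mapped cycle span.  The rule uses only relative differences, so
shifting every activation time leaves the flagged set unchanged — shown
below as a self-test.
"""

from eamap import RunConfig, detect_block_edges, offset_and_scale_check
from eamap.features import annotate_points
from eamap.maps import build_maps, mapped_cycle_span
from eamap.pipeline import simulate_scenario

cfg = RunConfig(scenario="triggered", seed=1)
mesh, substrate, truth, points = simulate_scenario(cfg)
amap, vmap = build_maps(mesh, annotate_points(points), cfg.tcl, k_neighbors=cfg.k_neighbors)

block = detect_block_edges(amap, mesh, lower_fraction=0.25, upper_fraction=0.75)
print(f"mapped span            : {mapped_cycle_span(amap):.1f} ms")
print(f"delay (EEML) edges     : {len(block)}")
print(f"early-meets-late edges : {int((block.kind == 'EML').sum())}")
print(f"planted block edges    : {len(substrate.slow_zone_edges)}")
print(f"offset invariance      : {offset_and_scale_check(amap, mesh, offset=137.0)}")

# The flagged edges trace the planted slow-conduction rim around the
# low-voltage patch; the invariance check confirms the detection depends
# only on relative activation differences.
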