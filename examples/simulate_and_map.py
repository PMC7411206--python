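"""Simulate a focal atrial tachycardia and rebuild its clinical maps.

Generates the default synthetic scenario — a ~3.2 cm^2 low-voltage patch
ringed by a near-block rim with one conduction channel, mapped with 1500
electrogram points — then reconstructs the activation and voltage maps
and prints what the mapping chain recovered.
"""

from eamap import RunConfig, run_pipeline

report = run_pipeline(RunConfig(scenario="triggered", seed=1))

print(f"mesh vertices            : {report.n_vertices}")
print(f"mapping points           : {report.n_points}")
print(f"mapped span              : {report.mapped_span_ms:.1f} ms of TCL {report.tcl_ms:.0f} ms")
print(f"largest low-voltage area : {report.largest_region_area_cm2:.2f} cm^2")
print(f"voltage at earliest site : {report.mean_voltage_at_earliest_mv:.2f} mV")
print(f"boundary block fraction  : {report.boundary_block_fraction:.2f}")
print(f"channel gaps             : {report.n_channel_gaps} "
      f"(widths {[f'{w:.1f}' for w in report.gap_widths_mm]} mm)")
print(f"mechanism call           : {report.mechanism_label} "
      f"(truth: {report.mechanism_truth})")
print(f"block-edge recovery      : sensitivity "
      f"{report.truth_metrics['sensitivity']:.2f}, precision "
      f"{report.truth_metrics['precision']:.2f}")

# The low-voltage area contains the earliest activation site, its border is
# mostly flagged as conduction block, and exactly one gap — the planted
# preferential-conduction channel — interrupts the block line.
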