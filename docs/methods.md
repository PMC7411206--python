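# Methods

## The measurement chain

The package mirrors the clinical workflow of high-density activation
mapping of focal atrial tachycardia (AT). A catheter samples bipolar
electrograms at ≥ 1500 sites on the atrial endocardium; each signal is
annotated with a local activation time (LAT) and a peak-to-peak voltage;
the annotations are interpolated onto the chamber mesh; the interpolated
activation map is scanned for edges whose activation difference is a
large fraction of the mapped cycle span (conduction delay/block and
early-meets-late lines); bipolar voltage below 0.5 mV delineates the
diseased low-voltage area (LVA); and the mechanism is read off the
fraction of the tachycardia cycle length (TCL) covered by the map
together with the response to programmed stimulation and isoproterenol.

All of it runs on synthetic tachycardias with planted ground truth, so
each stage's output can be scored against what was actually planted.

## Propagation model

Activation spreads as a graph shortest-path wavefront: each mesh edge is
traversed in `length / harmonic-mean(cv_i, cv_j)` milliseconds, where
`cv` is the per-vertex conduction velocity, and the LAT of a vertex is
the earliest arrival over all edge paths from the source (Dijkstra).
This is a first-order approximation of an eikonal wavefront. It is exact
on the graph (and checked against brute-force Floyd–Warshall enumeration
to 1e-9 ms on small meshes) but inherits the lattice anisotropy of the
triangulation: along unfavourable directions graph paths overestimate
true geodesic travel time by a few percent. That bias is irrelevant to
block detection, which compares relative differences.

Microreentry is modelled as a forced circulating loop: a closed vertex
ring inside the LVA is assigned phases proportional to cumulative
conduction time, rescaled so one lap takes exactly one TCL; the rest of
the mesh activates by shortest path from the loop vertices offset by
their phase. The loop core (inside 0.35 × patch radius) is treated as
refractory — paths may not cut across it — otherwise early phases would
short-circuit the circulating head and the mapped span would collapse.
This is a kinematic stand-in for reentrant dynamics, not a
reaction–diffusion model; it guarantees the mapping-level signature
(> 70% of TCL covered, a head-meets-tail discontinuity) without claiming
electrophysiological realism of the core.

## The synthetic substrate

The default scenario plants, on a spherical patch of radius 25 mm
(geodesic extent 30 mm, ≈ 1 mm edges, ≈ 3300 vertices):

| parameter | default | meaning |
| --- | --- | --- |
| `lva_radius` | 10.1 mm | low-voltage patch, π r² ≈ 3.2 cm² |
| `amp` in LVA | U(0.05, 0.45) mV | diseased bipolar amplitude |
| `amp` outside | U(1.0, 3.0) mV | healthy bipolar amplitude |
| `annulus_width` | 1.5 mm | near-block rim around the patch |
| `cv_normal` | 0.8 mm/ms | healthy conduction velocity |
| `cv_slow` | 0.0075 mm/ms | rim velocity (functional block) |
| `channel_angle_span` | 60° | one normally conducting gap in the rim |
| `tcl` | 300 ms | tachycardia cycle length |
| `n_points` | 1500 | sampled mapping points |
| `lat_noise_sd` | 3 ms | annotation jitter |
| `fill_threshold` | 5 mm | interpolation reach |
| `voltage_cutoff` / `duration` / `deflections` | 0.5 mV / 70 ms / 3 | abnormality rule |
| EEML lower / upper fraction | 0.25 / 0.75 | delay / early-meets-late thresholds |

Distances from the patch centre use chord (Euclidean) distance, which is
exact on flat phantoms and within 1% of the surface geodesic at these
radii; Dijkstra graph distance is available as an option but inflates by
up to ~8% through lattice anisotropy, visibly shrinking a planted disc.

The rim is deliberately modelled as a *thin near-block line*
(1.5 mm at 0.0075 mm/ms, a ~200 ms crossing) rather than a broad,
moderately slow band. The reason is detectability arithmetic, worked out
during design: an edge-wise detector flags jumps confined to about one
mesh edge. A 3 mm band at 0.05 mm/ms spreads its 60 ms delay over three
edge rings of interpolated map, ≈ 19 ms per edge — below 25% of a
~ 90 ms mapped span, so the planted "block" would be invisible to the
detector that is supposed to find it. With the thin near-block rim, the
rim interior activates ~ 100 ms after both faces, every border crossing
carries a large jump, and the mapped span stays below half the TCL so
focal scenarios still classify correctly. Functional block lines of this
kind are exactly what the clinical delay-zone pattern represents;
velocities below 0.01 mm/ms are reported in scarred atrium.

Mapping points are drawn area-uniformly with a ×3 density weight within
1.5 × patch radius (the clinical habit of mapping the earliest site
densely). Each point carries a synthetic electrogram consistent with the
local truth: 4–6 deflections over > 70 ms inside the diseased zone
(patch + rim), 1–2 sharp deflections elsewhere. Point amplitude is taken
from the nearest triangle corner — scar is a tissue type, and blending
amplitudes across the lesion border would manufacture a band of
intermediate voltages that exists in neither tissue.

## Electrogram synthesis and annotation

A trace is a train of alternating-polarity Gaussian lobes with geometric
amplitude taper (ratio 0.7), asymmetric rise/decay (0.75 σ / 1.25 σ, the
sharp-upstroke shape), sized in closed form so the above-noise-floor
width equals the requested duration, aligned so the steepest smoothed
slope falls at the prescribed LAT, scaled to an exact peak-to-peak, plus
0.01 mV Gaussian noise. The taper makes the first deflection dominant,
so steepest-slope annotation is stable; each lobe contributes exactly
one prominence-filtered extremum, so the deflection count round-trips
through the feature extractor.

Annotation: LAT is the time of maximum |dV/dt| (Savitzky–Golay smoothed,
7 samples; 15 for signals within 4× the noise floor), searched inside
the contiguous envelope run containing the dominant deflection; voltage
is max − min; duration is first-to-last sample above the 0.05 mV floor;
deflections are prominence-filtered extrema of both polarities. Mean
absolute LAT error over the generator's two morphology regimes is
≈ 1.4 ms; the sub-floor (< 0.1 mV) diseased signals are intrinsically
ambiguous and carry occasional ~ 10 ms errors, which is why the
earliest-site vertex of a noisy map wanders several mm within the
(nearly simultaneously activated) patch interior.

## Maps, detection, segmentation

Interpolation is inverse-distance-weighted (power 2) over the k nearest
points within 5 mm (k = 6 by default; an exact hit adopts the point
value). The voltage map instead projects the nearest point's amplitude
(k = 1), the convention of clinical voltage display; averaging across
the scar border would bias the measured LVA inward by ~ 0.4 mm.

EEML detection evaluates every edge with two mapped endpoints against
`fraction × mapped span` with strict inequality; the normaliser can be
switched to the TCL. Lower fractions of 0.20/0.15 are plain parameter
choices.

Low-voltage segmentation takes triangles whose three vertices are mapped
below cutoff, groups them by edge connectivity, and discards regions
under 0.1 cm². The all-three-vertices rule erodes roughly half an edge
ring of border — a deterministic −8…−10% on a 3.2 cm² disc at 1 mm
resolution — so measured areas sit just inside the 10% bound of the
analytic π r²; this is a property of the segmentation rule, not of the
sampling. Boundary block coverage marks a region-boundary edge blocked
when its midpoint is within 2 mm of a detected delay-edge midpoint;
maximal unblocked runs at least 4 mm wide count as channel gaps (a
conduction corridor must span a few interelectrode distances; narrower
runs are boundary-sampling artifacts). A region is *protected* when
≥ 60% of its border is blocked and at least one gap remains.

## What the generator does and does not emulate

It emulates: centrifugal activation from a focus inside a low-voltage
patch, fractionated low-amplitude electrograms in diseased tissue, a
delay ring with one conducting channel, microreentrant full-cycle
coverage, realistic point densities and annotation jitter, and the
irregular (jittered) triangulation of anatomical meshes.

It does not emulate: extracellular potential physics or electrode
geometry, anisotropic conduction tensors, catheter contact or motion
artifacts, respiratory gating, multi-beat variability, or whole-chamber
anatomy (the patch is one mapped region, not an atrium with veins and
valves). Passing tests therefore demonstrate that the analysis chain
recovers what its own forward model plants at clinical scales and noise
levels — not performance on clinical recordings.

## Numerical choices and degenerate inputs

- Strict inequalities everywhere the rules state thresholds (0.5 mV,
  70 ms, 3 deflections, 25%/75%, 70%/50% coverage).
- Earliest-site ties resolve to the tied vertex nearest the tied set's
  centroid; deterministic.
- A zero-span map raises a degenerate-map error in EEML and collapses to
  a single isochronal band.
- Unmapped vertices propagate as NaN and are excluded from spans, bands,
  edges and segmentation.
- Open region boundaries (mesh rim) are treated as single runs when
  scanning for gaps.
- All randomness flows from integer seeds through `numpy` generators;
  identical configurations reproduce reports exactly.

## Problem sizes and variability

Default runs use a ≈ 3300-vertex patch with 1500 points (≈ 4 s each);
the area-recovery checks use 3000 points; the mechanism suite runs 30
end-to-end simulations; brute-force oracles run on ≤ 50-vertex meshes.
Across 15 seeds of the default focal scenario, block-edge recovery
sensitivity ranges 0.74–1.00 (median ≈ 0.95; the bound of 0.90 is not
met by every seed because detection rides a relative threshold) with
precision 0.89–0.99, exactly one channel gap found in 15/15 runs and
always overlapping the planted sector; measured LVA area falls within
8–13% of the analytic disc. Mechanism classification is correct in all
tested runs; focal coverage stays below 0.5 with ≈ 0.02–0.05 margin.

## Known limitations

- The kinematic reentry model fixes the loop period rather than deriving
  it; restitution and wavefront curvature effects are absent.
- Graph propagation's lattice anisotropy (few %) enters truth LATs.
- Earliest-site localization in noisy maps has several-mm spread because
  the patch interior activates nearly simultaneously.
- The EEML sensitivity/precision operating point depends on the planted
  rim being a near-block line; broad moderately-slow zones are smoothed
  below the 25% threshold by interpolation, as they would be on a real
  mapping system at comparable point density.
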