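# Methods

This note documents the models, parameters, numerical choices and
limitations of `rnaswim`, in the order a user meets them.

## Density maps and statistics

A `DensityMap` is a scalar grid with per-axis voxel size and an Ångström
origin; `values[i, j, k]` indexes the (x, y, z) axes. MRC/CCP4 files in
any axis order are normalized on read; both the MRC2014 ORIGIN record
and the older start-index convention are honored (ORIGIN wins when
non-zero). All σ-thresholds are expressed as `avgD + k·σ` of the **full
grid** — never a sub-region — so a threshold means the same thing for
every operation. Interpolation is trilinear and refuses to extrapolate:
positions outside the grid raise rather than returning silent zeros.

## Q score

Q at a point is the Pearson correlation between interpolated map values
at radially sampled points and a reference Gaussian evaluated at the
same radii. Defaults: reference width 0.6 Å, radii 0–2.0 Å in 0.1 Å
steps, 8 quasi-uniform (Fibonacci-sphere, per-shell twisted) points per
shell — deterministic, so Q is exactly reproducible. Because the
correlation is taken about the mean, Q is independent of map scale,
offset and contour level; only the radial *shape* matters. Sample points
nearer to another atom than to the query are excluded so each atom is
scored against its own density. If fewer than 8 usable points (or fewer
than 3 distinct radii) remain, Q is undefined (NaN) and **fails** every
threshold — stringency, never leniency. Per-residue Q is the unweighted
mean over heavy atoms; half-map Q uses the same exclusion neighbors as
the full map.

Two accuracy notes. (1) On a map rendered as a single Gaussian of the
reference width, Q reaches 1 only up to trilinear discretization error:
measured 1−Q ≈ 2.6×10⁻³ at 0.5 Å voxels and 6×10⁻⁵ at 0.2 Å voxels. The
tests therefore assert 1−Q < 10⁻³ at 0.3 Å voxels. (2) In a tightly
packed duplex, overlapping neighbor density depresses per-atom Q to
~0.85–0.95 even on noiseless maps; this is a property of the metric, not
an artifact.

## Segmentation and peak localization

Supra-threshold voxels are partitioned by steepest ascent: each voxel
points to its largest strictly-greater 26-neighbor inside the mask;
voxels with none are local maxima and seed segments. This is a watershed
with no grouping. Connectivity is fixed at 26 neighbors for
reproducibility. Segments are ordered by decreasing volume, ties broken
by peak value then lexicographic voxel index.

The off-grid maximum is found by damped ascent on the **trilinearly
interpolated central-difference gradient field**, not on the trilinear
value interpolant: a multilinear function is maximized at cell corners,
so a value-guarded ascent would pin every peak to a voxel center (~0.5 Å
error at 0.8 Å voxels). Following the gradient field to its zero instead
recovers off-grid Gaussian centers to ≤ 0.05 Å at 0.8 Å voxels. Steps
are capped at a quarter voxel, halved when the gradient norm stops
decreasing, and converge when the step falls below 0.01 Å (at most 1000
steps). The ascent is clamped to the segment's bounding region, and the
reported peak value is the larger of the refined interpolated value and
the best member voxel, so it never undercuts the grid.

## The SWIM rule cascade

Rules are evaluated strictly in order (i)→(vii); the first failure is
recorded as the rejection reason. Defaults (all configurable via
`SwimParams` or a YAML file): segmentation 3σ, peak density 5σ, Q at the
peak ≥ 0.7 in full and both half-maps, residue Q of the nearest
nucleotide ≥ 0.6, water clash 3.2 Å (non-polar = C, P), ion clash 3.0 Å
(carbon), Mg²⁺ binder window 1.8–2.5 Å, donor-N repulsion window
1.8–3.4 Å, water binder window 2.5–3.4 Å, placed-Mg²⁺-as-binder window
1.8–2.5 Å, minWaterD 2.5 Å, minIonD 4.5 Å. Only water and inner-sphere
Mg²⁺ are ever assigned; monovalent ions and outer-sphere coordination
are out of scope.

One rule is made explicit here that a literal reading of the cascade
leaves implicit: a peak closer than 1.8 Å to any modelled atom (or
accepted placement) is rejected as that atom's own density. Without it,
a peak sitting on a phosphate oxygen would be assigned Mg²⁺ — its
geminal oxygen lies ~2.4 Å away (inside the Mg window) and phosphate
oxygens often have no carbon within 3.0 Å. 1.8 Å is the lower bound of
every binding window in the cascade, so nothing closer can be a distinct
solvent site.

Iteration: segments whose peak produced an accepted placement are masked
in later passes; the rest are re-evaluated (newly placed Mg²⁺ can enable
rule (vi) waters) until a pass adds nothing, up to 10 passes. The
"nearest atom" of rule (ii) is always an RNA heavy atom; solvent never
gates residue quality. Hydrogens are ignored throughout; altlocs resolve
to the highest-occupancy conformer. O3′/O5′ ester oxygens count as water
binders under rule (vi) (the rule admits any N/O) and as electronegative
under rule (v).

## Consensus cross-validation

Two criteria must hold concurrently. *Superimposable*: ≤ 1 Å after
least-squares rigid superposition (Kabsch/SVD) of all heavy atoms of
nucleotides with any atom within 10 Å of either solvent position, atoms
matched by residue id + name (identical numbering across the two models
is assumed — they are models of one molecule). *Same binding site*:
every close binder of each placement (water 2.5–3.2 Å, expanded once by
0.3 Å if empty; Mg²⁺ 1.8–2.2 Å) must lie within the expanded window
(2.5–3.5 / 1.8–2.5 Å) of the other placement, measured in each model's
own frame. The expansion is applied only on the close-binder search, not
beyond the expanded window. A placement is labelled consensus when at
least one counterpart qualifies; the reported pairs are additionally
matched one-to-one, greedily by ascending post-alignment distance, so
the consensus tally never double-counts. Candidate pairs are prefiltered
at 5 Å unaligned distance for speed.

## Shell metrics

The solvent shell is every voxel whose center lies 1.8–3.5 Å from a
heavy atom of a well-resolved (residue Q > 0.6) nucleotide. Shell grid
sampling uses 1.67 Å spacing and a 1.5–3.5 Å window. For similarity,
both maps are Z-score normalized over the full grid and then masked (the
metrics are affine-invariant, so normalizing over the mask instead would
give identical values); CCC is the Pearson correlation and MI the
plug-in estimator on a 20×20 equal-width joint histogram, without bias
correction — on independent noise MI sits at the analytic small-sample
floor (B−1)²/(2N ln 2). For classification, positives are reference
shell voxels above avgD + 3σ; the comparison threshold sweeps 512 evenly
spaced values over its masked range; AUPRC and AUROC are trapezoidal;
precision at zero predicted positives is defined as 1. Comparison maps
on a different grid are resampled trilinearly onto the reference after
any model alignment. Per-nucleotide AUPRC scores are min–max normalized
between the shuffled-map floor (0) and the experimental-reproducibility
ceiling (1), clipped to [0, 1], with nucleotides whose experimental
AUPRC < 0.2 scored 0 as too uncertain.

Model/solvent maps are rendered as normalized 3D Gaussians of width
σ = 0.225 × nominal resolution (FWHM ≈ 0.53 × resolution, the molmap
convention), truncated at 5σ, summed with weights water 1.0, Mg²⁺ 1.5,
Na⁺ 1.3 (other atoms 1.0).

## Solvent dynamics

Frames arrive as a plain TSV (frame, species, molecule id, x, y, z, RNA
RMSD, binder list); parsing binary trajectory formats is out of scope,
keeping the module format-agnostic. Frames with no solvent are preserved
by a placeholder row so occupancy denominators survive round-trips.
Binder identifiers collapse OP1/OP2 to a common OP class. Binding sites
are density peaks deduplicated at 1 Å (keeping the denser); a molecule
belongs to a site when it is within 2 Å of the peak, matches the
species, and binds the same RNA atoms (windows: ions 1.8–2.5 Å, waters
2.5–3.5 Å). Occupancy excludes frames whose RNA RMSD to the reference
exceeds 3.4 Å from both numerator and denominator (a single per-frame
RMSD is used; when two reference structures exist, the caller chooses
min or max before filling the column). RMSF is the root-mean-square 3D
deviation about the member mean. Mg²⁺ residence times are maximal
same-ion runs tolerating one absent frame, durations counted first to
last presence inclusive. Composite maps average locally aligned submaps
per voxel, weighted by inverse distance to each submap center (10 Å
cutoff, 0.1 Å floor against division by zero); uncovered voxels are NaN,
never zero.

## Synthetic fixtures

The generator's defaults define the standard test conditions: a 12-bp
duplex, 12 waters, 2 Mg²⁺, 2.2 Å nominal rendering resolution, 0.8 Å
voxels, 19.2 Å padding, and half-map noise of 2% of the peak signal —
giving planted peaks of ~10–20σ, i.e. a clean, high-SNR regime. The
duplex is built from rigid idealized nucleotide templates (correct atom
names, elements and bonded-distance scale; planar bases; not refined
stereochemistry) on fiber geometry: rise 2.81 Å, twist 32.7°/bp, base
centers 4.5 Å off-axis, second strand at a 210° dyad offset — parameters
chosen once so the duplex is compact and clash-free (closest
inter-atomic contact ≥ 1.2 Å over seeds). Waters are planted 2.6–3.2 Å
from a polar O/N along outward directions with no non-polar atom within
3.2 Å and no electronegative atom within 2.9 Å (so a peak localized
within ~0.3 Å of the truth can never satisfy the Mg²⁺ rule); Mg²⁺ sites
sit 2.05 Å from a phosphate oxygen with no donor N within 3.4 Å and no
carbon within 3.0 Å. Half-maps carry independent Gaussian noise and the
full map is their exact voxelwise mean.

What the fixtures do **not** emulate: spectrally colored cryo-EM noise,
B-factor falloff and sharpening artifacts, partial occupancy, model
coordinate error, tertiary-structure irregularity, and monovalent-ion
density. Passing the recovery tests therefore demonstrates the
correctness of the rule cascade and its thresholds under the stated
conditions, not the field performance of the method on experimental
maps — that is what the deposited-data test (which requires downloaded
maps) is for.

Ensembles plant per-site occupancy p and spread s; occupied positions
are the peak plus isotropic Gaussian displacement of per-axis SD s/√3,
so RMSF converges to s. Binder annotations come from the model when one
is supplied, otherwise they inherit the site definition (useful when a
site's identity, not its instantaneous geometry, is under study).

## Problem sizes and determinism

The default test and acceptance workloads use the 12-bp fixture
(~700k voxels, ~500 heavy atoms), 10⁴-frame ensembles, and 4×4×4 to 48³
crafted grids — chosen so the full suite runs in well under a minute per
module on one core. All randomness flows through explicit seeds
(`numpy.random.default_rng`); identical inputs and seeds give
bit-identical maps, models, placements and metrics. The CLI writes a
manifest (inputs, parameters, seed, version) next to every output.

## Known limitations

* Monovalent ions are never assigned; ambiguous peaks become water or
  nothing.
* Consensus assumes identical residue numbering across the two models.
* The Q-vs-resolution calibration line is not built in; it is exposed as
  a configurable parameter since its coefficients belong to external
  calibrations.
* The synthetic duplex is idealized; rule thresholds interact with real
  RNA geometry (e.g. O2′/OP microenvironments) in ways the fixture only
  approximates.
* Watershed connectivity is fixed at 26; 6-connectivity would split
  plateaus differently (no grouping is performed in either case).
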