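# Methods

## Scope and data model

The package quantifies the lateral and axial organization of membrane
receptors and their bound ligands from multi-channel DNA-PAINT
localization tables. Inputs are assumed drift-corrected and
channel-aligned; each record carries coordinates in nm, a photon count and
per-axis localization precisions (lpx, lpy and, for 3D astigmatism data,
lpz). Tables are exchanged as HDF5 (one dataset per channel, columns
`frame, x, y[, z], photons, lpx, lpy[, lpz]`) or CSV with the same
headers. Coordinates use the image convention: origin at the
field-of-view corner, y increasing downward, z = 0 at the focal plane.
Regions of interest are simple polygons (JSON vertex lists, nm);
boundary points count as inside so containment is deterministic.

Analyses are explicitly ROI-scoped: the ROI fixes the area over which
densities are measured and hence the intensity of the CSR null. Whether a
whole-cell outline or a full field of view is used is the analyst's
choice; the ROI is a required, recorded input rather than an implicit
default.

## Protein-position clustering

A protein position is the precision-weighted center of a circular cluster
of localizations around a local density maximum.

* **Neighbor counts** are computed within `count_radius` (default
  `radius / 2` = 5 nm).
* **Candidate centers** are localizations whose count is at least
  `min_locs` (default 10) and not exceeded by any neighbor within the
  grouping `radius` (default 10 nm); equal counts resolve toward the
  lower record index, making the result order-deterministic.
* **Assignment**: every localization within `radius` of a candidate joins
  the nearest one (exact distance ties toward the lower cluster id);
  clusters that end up below `min_locs` members are dropped.
* **Centers**: per axis, the mean weighted by the inverse squared
  axis-matched precision; `mean_precision` is the arithmetic mean of the
  members' lateral precisions.

The two-scale rule (counting kernel narrower than the grouping radius) is
deliberate. Counting neighbors over the full grouping radius low-pass
filters the localization density at exactly the scale of the radius, so
two binding sites separated by roughly the radius — such as the two
ligands of a receptor dimer, 11 nm apart, analyzed at a 10 nm radius —
would always collapse into a single cluster seeded between them. With a
half-radius kernel the two density peaks remain distinct while each
site's full cloud is still collected. The radius default (10 nm, about
3–5× the 2–3 nm DNA-PAINT localization precision) cleanly separates
proteins spaced ≥ 20 nm and resolves a usable fraction of 11-nm pairs;
both radii and `min_locs` are configuration-exposed.

3D tables are clustered on lateral distance by default (axial precision
is markedly worse than lateral, so mixing axes degrades separation); z is
carried through to the weighted center, and a switch enables full 3D
clustering. Multi-round re-localization averaging (RESI-style) is out of
scope; a table is treated as a single imaging round.

Known limitation: density-maximum clustering at grouping radius *r*
cannot resolve sites closer than roughly *r*/2–*r*; unresolved pairs
merge into one position. At realistic membrane-receptor densities
(5–50 µm⁻²) the fraction of random neighbor pairs below that scale is
under a few percent, but above ~100 µm⁻² merging becomes a visible upward
bias of the Δ-area statistic (mass missing from the shortest bins is
redistributed by normalization). The synthetic benchmarks therefore use
densities in the realistic range.

## NND statistics and the CSR null

First-NND (within a channel) and cross-NND (query channel against a
reference channel, asymmetric, no self-exclusion) are computed with a
KD-tree. Histograms use 5 nm bins aligned to zero and are normalized so
that the integral over the evaluation window (0–200 nm by default) is
one; distances beyond the window are excluded from the normalization.
Normalizing over the window rather than the full range makes the Δ-area
statistic exactly bounded by [0, 1] and comparable across cells of
different density; full-range normalization remains available as an
option.

The CSR null is a uniform pattern of `n_molecules` points (default
5,000,000) in a square sized so its density equals the cell's measured
density (positions inside ROI ÷ ROI area). No edge correction is applied
to either the null (negligible at that n) or the data, so edge-adjacent
positions carry slightly inflated NNDs; with windows much smaller than
cell ROIs the effect is far below the statistic's sampling noise.

**Δ area** = Σ max(0, h_obs − h_csr) × bin width over the window. For the
cross-NND variant the null randomizes both channels: an independent CSR
reference pattern at the reference channel's density is queried from an
independent CSR pattern at the query channel's density.

Finite-sample behavior: for an n-position cell the Δ-area noise floor
(positive-part sum of per-bin sampling noise) is approximately
0.4 · Σ_b √(p_b/n). It is ≈ 0.02 at n = 10⁴ and ≈ 0.07 at n = 10³, which
sets the minimum cell size for which small Δ areas are interpretable.

Conditions are summarized by the per-bin mean and population standard
deviation of cell histograms, and per-cell Δ areas are compared across
conditions with a one-way ANOVA (the F test is inherently one-tailed;
stars at p < 0.05/0.01/0.001). Population (not sample) SD is used in the
"mean ± SD" summaries. Post-hoc pairwise testing is not provided.

## Axial analysis

For 3D data, per-channel z histograms (5 nm bins) inside an ROI are
fitted with a single Gaussian by least squares; the layer peak is the
fitted center, falling back to the modal bin center when the fit cannot
converge (fewer than three bins, or a center outside the data range).
Peak-to-peak separation between an intracellularly labeled receptor layer
and an extracellularly bound ligand layer measures the membrane crossing
(≈ 25 nm including tag geometry). A Gaussian fit was chosen over the raw
modal bin because it is insensitive to bin-edge placement; with ≥ 2000
positions per layer and 5 nm axial scatter, recovery is accurate to well
under 1 nm. Internalization stages are user-supplied named ROIs; the
per-region 3D ligand–ligand NND histograms (shared binning, modal bin
centers) order stages by packing tightness. Vesicle sphere-fitting and
inside/outside orientation analysis are not implemented.

## Synthetic scenes and the acquisition forward model

The generator emulates the statistical structure of an activated
receptor–ligand membrane system:

| parameter | default | meaning |
|---|---|---|
| receptor_density_um2 | 10 | receptors per µm² (order-of-magnitude choice; cellular values vary) |
| monomer/dimer/cluster/vesicle fractions | 1/0/0/0 | partition of receptors by group kind |
| pair_separation_nm | 11 | exact in-pair spacing, from the ligand–receptor crystal structure |
| cluster_diameter_nm | 200–500 | oligomer cluster diameter, uniform per cluster |
| cluster_size / vesicle_size | 20 / 30 | molecules per group |
| vesicle_radius_nm / depth | 50 / 100–400 | sphere radius; center depth below membrane |
| ligand_occupancy | 1.0 | fraction of receptors with bound ligand (ligand treatment near saturation) |
| label_offset_lateral_nm | 17 | 2D ligand-label-to-receptor-label proximity |
| label_offset_axial_nm | 25 | membrane crossing between label layers |
| labeling_efficiency | 0.4 | Bernoulli per molecule (single-domain antibody labeling) |

Monomers are uniform; dimers are uniformly placed pairs at the exact
configured separation and uniform orientation; clusters are disc-uniform;
vesicles place receptors on a sphere surface with ligands projected onto
an inner shell. Membrane-bound ligands sit at the lateral offset (uniform
orientation) and the axial offset above their receptor.

The acquisition model abstracts imager-strand blinking into a Poisson
event count per labeled site (default mean 50); each event is the true
position plus isotropic Gaussian noise whose per-event sigma (fixed, or
lognormal with configurable log-SD 0.3 to mimic photon-count variation;
medians 2 nm lateral / 5 nm axial) is recorded as the localization
precision. Frames are uniform random; photon counts are Poisson
(mean 5000) and carried for schema completeness only. What the forward
model does **not** emulate: blinking kinetics and frame-correlated
events, repeated-binding overcounting structure, unspecific binding
background, anisotropic PSFs, residual drift or channel misalignment.
Passing end-to-end tests therefore demonstrates correctness of the
statistical machinery on idealized data, not robustness to every
real-data artifact.

All randomness flows through NumPy generators seeded explicitly; scene
generation, acquisition noise and CSR simulation consume independent
child seeds derived from a run's root seed, so every run is bit-level
reproducible.

## Numerical and testing choices

* Exact float comparisons define tie-breaks (lowest record index / lowest
  cluster id); constructed-tie tests exercise them.
* Text round-trips write floats with `%.17g` and parse with the exact
  (`round_trip`) CSV parser so tables survive storage bit-identically.
* The closed-form check of the generator (uniform scenes vs the 2D CSR
  NND law, CDF 1 − exp(−πρr²)) measures true NNDs on a torus (KD-tree
  with periodic box), matching the infinite-plane law without edge bias;
  the pipeline itself never uses periodic distances. Because mutual
  nearest-neighbor pairs duplicate distances, the full NND sample is not
  i.i.d. and would miscalibrate a KS test; the check uses a sparse random
  subsample (1000 of 5000 values), which preserves the exact marginal law
  and restores calibration.
* Benchmark problem sizes (500 dimer pairs, 2000 positions per axial
  layer, 10⁴-position calibration cells, 10⁵-molecule CSR samples in
  tests) are chosen so that each statistic's sampling noise is several
  times smaller than the effect or tolerance being checked, while a full
  run of suite plus benchmarks stays in the minutes range on one core.
  The CSR default for production runs remains 5,000,000 molecules.
* The Δ-area direction is observed-minus-null, positive part: the
  statistic reads "area of the observed histogram above the CSR curve",
  which makes stronger clustering give larger values.
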