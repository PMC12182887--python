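# paintnnd

Quantification of membrane receptor–ligand organization from DNA-PAINT
single-molecule localization data: protein-position clustering,
nearest-neighbor-distance (NND) statistics against a complete-spatial-
randomness (CSR) null, the Δ-area co-clustering statistic, axial-layer
analysis, and a synthetic ground-truth scene generator that makes the
whole pipeline testable end to end.

## Who this is for

Super-resolution microscopists quantifying receptor oligomerization and
ligand co-localization — e.g. EGF binding driving EGFR dimerization,
clustering and internalization — from drift-corrected, channel-aligned
localization tables produced by upstream software. The package starts
where PSF fitting, drift correction and channel alignment end.

## The statistics at its core

1. **Protein positions.** DNA-PAINT yields many localizations per target.
   Circular clusters of localizations around local density maxima are
   grouped (grouping radius *r* = 10 nm, minimum 10 localizations by
   default) and each cluster is reduced to a precision-weighted center,
   per axis *a*:

   x̂ₐ = Σᵢ wᵢ aᵢ / Σᵢ wᵢ,  with wᵢ = 1 / lpᵢ²

   where lpᵢ is the axis-matched localization precision of event *i*.

2. **NND distributions.** For each position, the distance to its nearest
   neighbor in the same channel (first-NND, oligomerization) or in
   another channel (cross-NND, co-localization). Histograms use 5 nm bins
   and are density-normalized to unit integral over 0–200 nm.

3. **CSR null.** A homogeneous Poisson pattern is simulated at the
   measured density of the cell (default 5,000,000 molecules) and its NND
   histogram is computed the same way. For a 2D CSR process at intensity
   ρ the NND density is p(r) = 2πρr·exp(−πρr²), which the simulation
   reproduces and the test suite checks in closed form.

4. **Δ area.** The positive excess of the observed histogram over the CSR
   histogram, summed over 0–200 nm and multiplied by the bin width:

   Δ = Σ_b max(0, h_obs(b) − h_csr(b)) · Δr ∈ [0, 1]

   0 means indistinguishable from random; larger values mean more
   short-range structure (dimers, oligomer clusters, bound ligand).

5. **Condition comparison.** Per-cell Δ areas are aggregated as
   mean ± population SD per condition and compared with a one-way ANOVA
   (upper-tail F), starred at p < 0.05 / 0.01 / 0.001.

## Worked example

Simulate a half-dimerized receptor scene (20 receptors/µm², dimer spacing
11 nm), image it with the DNA-PAINT forward model, cluster the receptor
channel and fit the NND-vs-CSR model:

```python
from paintnnd import (SceneParameters, AcquisitionModel, generate_scene,
                      simulate_localizations, cluster_channel,
                      OligomerizationModel, ConditionComparison,
                      RegionOfInterest)

params = SceneParameters(monomer_fraction=0.5, dimer_fraction=0.5,
                         receptor_density_um2=20.0, labeling_efficiency=1.0)
scene = generate_scene(params, seed=1)
tables = simulate_localizations(scene, AcquisitionModel(), seed=2)
receptor = cluster_channel(tables["receptor"][0], radius=10.0, min_locs=10)
roi = RegionOfInterest.rectangle(10_000, 10_000)
result = OligomerizationModel(receptor, roi=roi, csr_n=500_000).fit(seed=3)
print(result.summary())
```

```
NND vs CSR analysis
===================
statistic:        first-NND
query positions:  1586
density:          15.860 per um^2
CSR molecules:    500000
bin size:         5 nm
window:           0-200 nm
modal bin center: 12.5 nm
median NND:       114.30 nm
delta area:       0.1569
```

The modal bin center (12.5 nm, i.e. the 10–15 nm bin) reflects the 11 nm
dimer spacing; Δ area = 0.157 quantifies the excess of short distances
over CSR. (1586 of 2000 molecules are recovered as distinct positions;
dimer partners closer than the clustering resolution merge, which is why
the measured density is below the generated one.) Comparing per-cell Δ
areas across two labeling conditions:

```python
comparison = ConditionComparison({
    "ALFA-tagged ligand": [0.29, 0.31, 0.27],
    "DNA-conjugated ligand": [0.16, 0.14, 0.18]}).fit()
print(comparison.summary())
```

```
Condition comparison (one-way ANOVA on delta areas)
====================================================
ALFA-tagged ligand   0.290 +/- 0.016  (N = 3)
DNA-conjugated ligand 0.160 +/- 0.016  (N = 3)
F = 63.37, p = 0.001349  [**]
```

A command-line interface mirrors the library
(`paintnnd simulate | cluster | nnd | csr | delta-area | axial | run`);
`paintnnd run config.yaml` executes the full multi-condition analysis
graph from a YAML configuration and writes a JSON/CSV report.

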