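# rewildmap

Spatially explicit monitoring of rewilding progress from wildlife tracking
and habitat maps.

Rewilding projects reintroduce locally extinct animals and need to know not
just *whether* the released populations persist, but *where* the reserve's
potential for them is already realized and where it is not. `rewildmap`
implements that as a reproducible pipeline for conservation scientists and
reserve practitioners: from a classified habitat raster and GPS occurrence
records of the reintroduced species it computes, per species, the current
range, a habitat-selection model and a probability-of-presence surface, and
then cross-species maps and area tables of occupancy, faunal complexity and
ecological integrity before vs after rewilding.

## The model in brief

For each reintroduced species *s* with tracking points inside the reserve
(individuals with > 10 points only):

1. **Range** — the 95% volume contour of a Gaussian KDE over the pooled
   points: the smallest region holding 95% of the density mass. Per-
   individual contours give a median individual range area *A_s*.
2. **Habitat selection** — presences vs an equal number of pseudo-absences
   drawn uniformly in the reserve but outside exclusion discs of area
   *A_s* centred on every presence. Each point is described by the mean
   fractional cover of the four main habitats (broadleaf forest,
   free-standing trees, short grassland, tall grassland) in a buffer of
   area *A_s*; a 500-tree random forest fits P(presence) and is evaluated
   by cross-validated AUC.
3. **Occupancy** — the fitted probability, predicted on the 30 m cover
   raster, classifies each cell: P > 0.5 inside the range = **realized**,
   P > 0.5 outside = **potential**, P ≤ 0.5 = not predicted.

Across the S species, each cell gets a **faunal complexity** count (number
of species with realized, or potential, occupancy) and an **ecological
integrity** score

&nbsp;&nbsp;&nbsp;&nbsp;EI = (1/S) Σ_s 1[cell is not unrealized potential for s] ∈ {0, 1/S, …, 1},

which is 1 where every prediction — occupancy or absence — is already
realized. "Before rewilding" evaluates the same maps with empty ranges.
The headline indicator is the share of the site with EI > 0.5.

## Worked example

The package ships seeded generators that emulate the study inputs, so the
whole pipeline runs without any download. `standard_scenario` builds a
4.5 × 4.5 km mosaic landscape (70% tall grassland, 12% broadleaf forest)
with two planted species — a forest specialist and a habitat generalist:

```python
import rewildmap as rw

habitat, boundary, tracking = rw.standard_scenario(seed=0)
config = rw.PipelineConfig(
    species=["forest specialist", "generalist"],
    seed=0, output_dir="demo_run",
)
report = rw.run_pipeline(config, habitat=habitat, tracking=tracking, boundary=boundary)

print(report.occupancy_summary.to_string(index=False))
for sp, meta in report.models.items():
    print(f"{sp}: CV AUC = {meta['cv_auc']:.3f}, buffer radius = {meta['buffer_radius_m']:.0f} m")
print(f"high-integrity share before: {report.integrity['high_integrity_before_pct']:.1f}%")
print(f"high-integrity share after:  {report.integrity['high_integrity_after_pct']:.1f}%")
```

prints

```
          species  realized_km2  realized_pct  potential_km2  potential_pct
forest specialist        0.0900          37.5         0.1503           62.5
       generalist       16.8246          95.8         0.7317           4.2
forest specialist: CV AUC = 0.971, buffer radius = 163 m
generalist: CV AUC = 0.623, buffer radius = 201 m
high-integrity share before: 12.1%
high-integrity share after:  95.6%
```

Read: the specialist's selection model discriminates strongly (AUC 0.97 —
there really is a planted forest preference) and the species has so far
realized 37.5% of the 0.24 km² predicted for it; the generalist's AUC sits
near chance (it has no preference to find) while its scattered individuals
already cover 95.8% of its predicted area. Rewilding lifted the share of
the site whose predictions are realized (EI > 0.5) from 12.1% to 95.6% —
the generalist is predicted almost everywhere, so before rewilding almost
every cell held unrealized potential. `demo_run/` afterwards contains the
probability and integrity GeoTIFFs, range and occupancy GeoJSONs, the CSV
area tables, and the resolved YAML config for provenance.

The same workflow is available from the shell:

```bash
rewildmap simulate --config scenario.yaml --seed 1 --outdir sim
rewildmap run-all --config pipeline.yaml --seed 1
```

with per-stage subcommands (`classify`, `downscale`, `range`, `pseudoabs`,
`select`, `score`, `report`) for running stages individually.

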