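# Methods

`rewildmap` implements a spatially explicit monitoring workflow for
rewilding projects: given a categorical habitat map of a reserve and GPS
occurrence records of reintroduced species, it estimates where each species
currently ranges, models where it would be expected to occur given its
habitat selection, and condenses the two into per-cell scores of rewilding
progress. This note documents the models, the numerical choices, and what
the synthetic test bed does and does not demonstrate.

## Coordinate model and rasters

All analysis happens on one north-up planar grid in metres (`GridSpec`).
Rasters in a geographic (degree) CRS are rejected rather than reprojected:
silent reprojection resamples categorical rasters and changes areas, so
reprojection is left to the user as an explicit pre-processing step. Written
GeoTIFFs are tagged with EPSG:32721 (UTM zone 21S) by default; any projected
metric CRS is acceptable and the EPSG code is carried through unchanged on
read/write. Cell membership in any polygon (range contours, the study
boundary) is decided by the cell **centre**. The centre rule is used
identically in range intersection and in area accounting, so the two can
never disagree; areas of categories therefore always partition the mapped
area exactly.

NODATA cells (for example an unclassifiable burn scar) are excluded from
every numerator *and* denominator: class areas, buffer means, and all
percentages refer only to mapped cells.

## Habitat mapping (two steps)

Step one is a per-pixel classifier of fine-resolution multispectral imagery
into the ten-class land-cover catalogue. Training pixels are class-balanced
to the **median** original class count (common classes downsampled without
replacement, rare classes upsampled with replacement) — the median keeps
memory bounded and treats both directions symmetrically. Features are
centred and scaled; a stratified, seeded 20% split is held out, and the fit
is reported as overall accuracy and Cohen's kappa. The default architecture
is a two-layer, 100-neuron multilayer perceptron trained for 100 epochs
with batch size 1000. Any probabilistic classifier whose class
probabilities sum to one satisfies the module contract; the scikit-learn
MLP backend has no dropout layer, so the `dropout_rate` knob maps onto L2
weight decay, its closest regularisation analogue there. Argmax ties
resolve to the lowest catalogue index, for determinism.

Step two extends the fine classification to coarse imagery as *fractional
cover*: the fine label map is aggregated into coarse cells (class frequency
among each block's fine pixels; a coarse cell is NODATA iff more than half
of its block is — the majority rule keeps edge cells usable), and a second
network (two layers, 200 neurons, 200 epochs, batch 10000) regresses those
per-class fractions on the coarse bands. Predictions are projected onto the
probability simplex (negative values clipped, then renormalised to sum to
one); fit is the hold-out r², overall and per class, with zero-variance
classes reported as NaN with a warning rather than silently skipped.

## Species ranges

A species' range (area of occupancy) is the 95% volume contour of a
Gaussian kernel density estimate over its pooled tracking points, after two
filters applied in this order: points outside the reserve boundary are
dropped, then only individuals with **more than** `min_obs` (default 10)
remaining points are retained — strictly more, so an individual with
exactly 10 points is excluded.

The KDE uses an isotropic Gaussian kernel evaluated at cell centres of a
grid at the analysis resolution (30 m by default) extended three bandwidths
beyond the point bounding box, then renormalised to unit mass on that grid.
The bandwidth defaults to Scott's rule on the pooled points,
`h = sigma_bar * n^(-1/6)` with `sigma_bar` the root mean of the coordinate
variances; it can be overridden per species, and the value used is recorded
in the `RangeEstimate` so runs are reproducible. The volume contour is the
smallest-area cell set whose cumulated mass reaches the isopleth (cells
ranked by density), polygonised as a union of cell squares; its attained
mass overshoots the level by at most one cell's mass. On a bivariate normal
with standard deviation sigma the 95% contour should enclose
`pi * (sigma * sqrt(2 ln 20))^2 ~= pi * (2.448 sigma)^2`; the test suite
and the acceptance script verify this to within 10% at n = 10,000
(Scott's bandwidth inflates the contour by ~(1 + h²/sigma²), about 5% there,
and grid discretisation contributes the rest).

The *median individual range* is the median of per-individual 95% contour
areas. Two readings of "median range" were possible (across individuals or
across species); across individuals is the common usage in home-range work
and is what every downstream radius derives from. Individuals whose points
are completely coincident (zero spread) cannot support an automatic
bandwidth and are skipped with a warning.

## Pseudo-absences and habitat selection

True absences are unobservable in tracking data, so each species gets as
many pseudo-absence ("available") points as it has presences. An exclusion
disc whose area equals the median individual range
(`radius = sqrt(area / pi)`) is centred on **every** presence point — one
disc per point, matching the construction where each presence is surrounded
by its own circumference — and candidates are drawn uniformly inside the
boundary by seeded rejection sampling, accepted when farther than the
radius from every presence. Sampling errors out if less than 1% of the
boundary remains available, and after 10^6 draws regardless, to bound
runtime on pathological geometry.

Each presence and pseudo-absence is described by the mean fractional cover
of the four modelled habitats (broadleaf forest, free-standing trees, short
grassland, tall grassland) within a disc of that same median-range area.
NODATA cells inside a buffer are excluded from the mean rather than
zero-filled, which would bias cover toward zero at the reserve edge. The
remaining six classes are deliberately not features: they make up the
simplex remainder and carry the residual information.

The selection model is a seeded random forest (500 trees by default)
predicting P(presence) from the four cover fractions; any seeded
bagged-tree ensemble with probability output satisfies the contract.
Discrimination is reported as the Mann–Whitney AUC —
P(presence scored above absence) plus half the tie mass — both on the
training data and 5-fold stratified cross-validated. The cross-validated
number is the headline: resubstitution AUC of a flexible ensemble is close
to 1 by construction and says little. The fitted model is predicted onto
the 30 m aggregated cover raster (aggregation factor `ceil(30 / cell
size)`), giving a per-cell probability surface; 30 m absorbs typical GPS
error in hand-recorded occurrence points.

## Occupancy, complexity, integrity

Per species and cell, with threshold 0.5 (strict inequality on both sides
of the definitions):

* probability > 0.5 and centre inside the range → **realized** occupancy;
* probability > 0.5 and centre outside → **potential** occupancy;
* probability ≤ 0.5 → **not predicted** (a cell at exactly 0.5 is not
  predicted).

Realized and potential cells partition the predicted set exactly. The
**faunal complexity** maps count, per cell, the species with realized
(resp. potential) occupancy. The **ecological integrity** score averages,
over the S species, an indicator that is 0 where a species' predicted
occupancy is unrealized (potential) and 1 otherwise — realized occupancy
and correctly predicted absence both count as fulfilled potential. Scores
therefore live on the lattice {0, 1/S, …, 1}, and mean integrity equals
`1 − mean(potential count)/S`, an identity the tests assert. The "before
rewilding" scenario is not a separate formula: it re-evaluates the same
maps with every range treated as empty, so every predicted cell is
unrealized. A site's headline figure is the percent of mapped area with
integrity strictly above 0.5.

Area tables report per-label km² (cell count × cell area) and percents.
For complexity tables the percent denominator is ambiguous in common usage
(share of the whole site vs share of the predicted area); both are
supported via `denominator_mode`, with *site* the default since that is the
reading under which published per-score percentages reconcile.

## Synthetic data and what the tests show

The generators plant known structure so every stage has a
parameter-recovery oracle:

* **Landscape** — one Gaussian-smoothed white-noise latent field per class
  (smoothing length = the autocorrelation length, 200 m default), combined
  by offset argmax; the offsets are calibrated iteratively on the realized
  fields so cover fractions land within ±0.5 pp of the requested weights.
  The exact covariance model is not contractual — only cover fractions and
  patchiness are.
* **Imagery** — per-class band signatures plus independent Gaussian noise.
* **Tracking** — individual centres jittered around a species centre
  (re-drawn until preferred habitat is locally available), points drawn as
  Gaussian home-range deviates and accepted with probability proportional
  to the preference weight of the underlying habitat class. Planting
  preference at the acceptance level (not via a movement model) means the
  true selection ratio is known analytically.

The reference scenario (`standard_scenario`) is a 4.5 × 4.5 km site at
15 m resolution (so the aggregation factor is exactly 2 → 30 m cells) with
cover shares like a tall-grassland-dominated reserve (70/12/10/8% tall
grassland / broadleaf forest / short grassland / free-standing trees), a
forest specialist (5 individuals, 120 m home-range scale, 250 points) and a
habitat generalist (30 individuals, 80 m scale, 500 points, scattered over
the whole site). The generalist is the null condition: with uniform
preference *and* availability-like spatial sampling, its cross-validated
AUC sits near chance (0.58–0.67 over seeds), while the specialist's exceeds
0.95. A generalist whose individuals cluster in one corner would *not* be a
null — spatial clustering alone leaks into buffer features — which is why
the scenario scatters its individuals site-wide.

What passing these tests does **not** show: the generators have no
movement autocorrelation, no observation bias, no seasonal or interannual
dynamics, and spectral noise is i.i.d. Gaussian; real tracking data and
imagery violate all of these. The synthetic recovery results certify the
pipeline's internal correctness, not field-data performance.

## Problem sizes and numerical choices

Test and acceptance runs use the 300 × 300-cell scenario, 500-tree forests,
and n = 10,000 for the KDE oracle — sizes chosen so the full suite
exercises every claim at meaningful resolution while staying quick on a
laptop. Other fixed choices: densities renormalised to unit mass on their
evaluation grid (tolerance 1e-3); simplex tolerance 1e-6 on cover rasters;
argmax and contour ties broken deterministically (lowest index / densest
cell first); rejection-sampling caps of 10^6 (pseudo-absences) and
2 × 10^6 (tracking) draws; all randomness flows from explicit integer
seeds through `numpy.random.default_rng`.

## Known limitations

* KDE ranges ignore temporal autocorrelation of tracking fixes;
  autocorrelation-aware estimators (aKDE, movement models) are out of scope.
* The habitat-selection model uses only the four cover fractions; no
  distance-to-water, terrain, or interaction covariates.
* Pseudo-absence AUC on autocorrelated landscapes retains a small
  spatial-contrast component even under null preference (≈0.6 rather than
  0.5); interpret absolute AUCs accordingly.
* Detection probability is assumed perfect; no imperfect-detection
  occupancy modelling.
* On-the-fly reprojection and vector topology repair are out of scope.
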