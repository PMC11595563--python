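# Methods

This package joins two analyses that are usually run separately: ensemble
species-distribution modeling (SDM) of occurrence records against
environmental layers, and divergence-time mapping from a time-calibrated
phylogeny. Their join — per-grid-cell mean divergence times compared
across habitat-suitability classes — asks whether the oldest lineages of a
clade sit in its most suitable habitat, the spatial signature of a group
that diversified in place and dispersed outward. The motivating system is
a macrofungal genus in China whose highly suitable habitat concentrates in
the southeast; the package reproduces that analysis design end to end on
synthetic data with known ground truth.

## Pipeline stages

1. **Occurrence thinning.** Records closer together than 10 km are treated
   as replicates; a greedy first-come scan in input order keeps a record
   iff it lies farther than the radius from every record already kept.
   The scan order is deterministic; a seed option permits randomized order
   to probe sensitivity. Geographic records use haversine distances
   (Earth radius 6371.0088 km); synthetic planar records use Euclidean km.
   Thinning is applied to all species pooled (one genus-level model), with
   a per-species mode available.
2. **Collinearity filter.** Pearson correlations are computed over all
   jointly valid raster cells (an ENMTools-style whole-layer comparison,
   not presence-point samples). Layers are scanned in priority order
   (default: stack order); a layer is kept iff its |r| with every kept
   layer is at most 0.8, so the surviving set never contains a pair above
   the threshold, and every drop is logged with its partner and r.
3. **Pseudo-absences.** 3 independent sets of 500 background points,
   uniform over valid cells not occupied by a presence, each cell at most
   once per set, placed at cell centers.
4. **Member grid.** 4 learner families x 3 pseudo-absence sets x 10
   cross-validation runs = 120 members. Each run splits presences and its
   pseudo-absence set 75/25 (separately, so class balance is preserved),
   fits on the training portion and is scored on the held-out portion:
   AUC (Mann-Whitney, ties one half), the max-TSS binarization threshold
   (candidates are midpoints of consecutive sorted unique scores; ties go
   to the lowest), and TSS at that threshold. The same split serves all
   four algorithms within a (PA set, CV run). A failed fit is recorded and
   excluded from ensembling but never removed from the grid, so the count
   is always the full design. Members with AUC > 0.8 and TSS >= 0.7 are
   flagged as passing the conventional quality bar; all members enter the
   ensembles regardless (a QC-filtered mode exists).
5. **Ensembles.** Committee Averaging: the per-cell fraction of members
   voting presence after binarizing each at its own max-TSS threshold.
   Weighted Mean: the per-cell AUC-weighted mean of member continuous
   scores (TSS weighting available). Ensemble AUC/TSS are reported on the
   pooled presences + pseudo-absences; this in-sample evaluation is
   optimistic for flexible members (the boosted and random-forest members
   partially memorize presence cells) and is reported alongside the
   honest member-level cross-validation scores.
6. **Variable importance.** Permutation importance per member: 1 minus
   |Pearson r| between predictions on the original cell table and
   predictions with one variable's column shuffled, averaged over 3
   shuffles, then averaged over members. A variable the model ignores
   scores exactly 0.
7. **Suitability classes.** Exact Fisher-Jenks natural breaks (dynamic
   program minimizing total within-class sum of squared deviations,
   O(k n^2) with prefix sums) cut the weighted-mean map into 4 levels;
   class assignment uses half-open (lower, upper] intervals, and per-class
   areas are cell counts times cell area.
8. **Divergence times.** Stem age of a species = age of its terminal
   branch's parent node (for a ssp. represented by several tips, the age
   of the parent of their MRCA; configurable to first-tip). Trees must be
   ultrametric within a relative tolerance of 1e-6 of the root age —
   chronogram files round branch lengths, so exact equality is
   unrealistic. Ages run backward from tips at 0 Myr. The per-cell mean
   divergence time (MDT) over a 100-km grid counts each species once per
   cell however many records it has there.
9. **Ancestral areas.** Mk likelihoods by Felsenstein pruning with
   P(t) = expm(Qt) (SciPy's scaling-and-squaring Pade implementation,
   used directly rather than an eigendecomposition since it is robust to
   defective Q), per-node scaling against underflow, uniform root prior
   (stationary frequencies optional in principle — the uniform prior is
   the APE-style default). ER/SYM/ARD rates are optimized on the log
   scale in [1e-8, 1e3] per Myr by L-BFGS-B from two fixed starts (one
   change per root age, and 10x that), making fits reproducible. Marginal
   node probabilities combine the downward conditionals with an upward
   pass propagating the likelihood of the rest of the tree. Model choice
   is by AIC by default; the raw-likelihood rule is exposed because some
   studies report it, but ARD nests ER, so under raw likelihood richer
   schemes can never lose — AIC is the defensible default. Ambiguous tip
   areas ("SE|SW") enter as indicator sets; a "Null" code marks tips
   (outgroups) pruned before reconstruction.
10. **Spatiotemporal test.** Occupied cells are grouped by the habitat
    class of their mean ensemble suitability (mean of raster cells whose
    centers fall in the grid cell, then the global Jenks breaks — mean
    first avoids resolution artifacts of majority voting). Group MDTs are
    compared by the tie-corrected Kruskal-Wallis H with the chi-square
    p (df = groups - 1); an exact permutation p over all distinct
    assignments is available for small samples (Monte Carlo above 1e5
    permutations). Pairwise follow-up uses Dunn's z on pooled ranks with
    Holm adjustment — the conventional choice where a study reports
    pairwise significance from a KW framework without naming a method.
11. **Regions.** Two dividing polylines (a west/east divider and a
    north/south divider) split the map into NE/NW/SE/SW. A point's side is
    the sign of the cross product against its nearest segment's direction;
    points exactly on a line go east/south. Real-data gridding projects
    WGS84 coordinates with a spherical Albers equal-area conic (standard
    parallels 25N/47N, central meridian 105E) so 100-km cells have honest
    areas; synthetic data are planar and projection-free.

## The synthetic generator

The generator produces every input with known ground truth, on a planar
km grid (distances exact; no projection ambiguity in tests).

- **Environmental layers** are standardized low-frequency cosine mixtures
  — smooth and spatially autocorrelated, which is what matters for SDM
  behavior; they carry no climate semantics (no seasonality, no units).
  A declared collinear pair (i, j, r) rebuilds layer j as
  r * layer_i + sqrt(1 - r^2) * e_perp with e_perp orthogonalized against
  layer i over the grid, so the empirical correlation equals the target
  exactly.
- **Truth and presences.** Suitability is logistic(intercept + sum
  coef * layer); presences are drawn per cell proportionally to it and
  placed at cell centers.
- **Chronograms** come from the constructive Yule algorithm (waiting
  times Exp(k * birth rate), uniform lineage choice, a final interval to
  the present) and can be rescaled to a target root age. **Tip areas**
  evolve root-to-tips under ER Mk with a uniform root state.
- **The end-to-end scenario** plants the pattern the pipeline must
  detect. On a 1000 x 1000 km extent (25-km raster cells, 1600 cells),
  suitability peaks over the SE quadrant: a smoothed quadrant plateau
  plus a milder gradient toward the SE corner, so the highly suitable
  habitat is one contiguous block whose core is the most suitable of
  all. The chronogram has 36 tips rescaled to a 77.74-Myr root. The
  oldest-diverging third of species (by stem age) occur only inside the
  SE quadrant, sampled proportionally to suitability cubed — relict
  lineages with narrow realized niches concentrated in the habitat core —
  while the younger species range uniformly over the whole area, 16
  records per species. Grid cells in the top suitability class therefore
  carry the oldest mean divergence times by construction. Design notes:
  a pure plateau (no core gradient) leaves the top two Jenks classes
  statistically interchangeable, and confining young species to poor
  habitat starves the pooled genus-level SDM of core presences; both
  variants weaken the planted pattern and were rejected.

What passing on this generator does and does not show: it validates the
estimators and their composition — thinning, filtering, the ensemble
machinery, Jenks, stem ages, Mk reconstruction, the KW comparison —
against planted truth. It does not validate climate realism, spatial
sampling bias, georeferencing error, phylogenetic uncertainty (a single
fixed chronogram stands in for a posterior), or the ecological claim
itself on real data.

## Numerical choices and edge cases

- AUC ties count one half; single-class evaluation sets are rejected.
- All-equal scores: the threshold candidate is that single value, TSS 0.
- Jenks requires at least k distinct values and rejects otherwise;
  identical-MDT cell sets therefore reject rather than fabricate classes.
- Kruskal-Wallis with all observations identical returns H = 0, p = 1.
- Constant raster layers are rejected by the correlation with an explicit
  "constant layer" message rather than returning NaN.
- Spline-basis GAMs cannot extrapolate; prediction inputs are clipped to
  the training range (boundary hold).
- Records exactly on grid boundaries belong to the lower-left cell
  (half-open cells).
- Mk rate fits with fewer than two observed states return the lower-bound
  rate with a warning instead of failing.
- One global seed expands to per-stage seeds through numpy's
  SeedSequence, so stages can be rerun independently and reruns are
  bit-identical for deterministic outputs.

## Fixed learner settings

GLM: standardized features, unpenalized logistic regression. GAM:
binomial with per-feature B-splines (df 5, degree 3). GBM: 2500 trees,
depth 3, shrinkage 0.01. RF: 500 trees. All exposed through the config;
the bundled replicate analyses use smaller forests (the package's
desk-scale problem sizes are 1600-cell rasters, ~580 records, 120
members, 36-tip trees, and 10-20 pipeline replicates).

## Known limitations

- The Jenks dynamic program is exact but O(k n^2): fine for the cell
  counts here (10^3-10^4), slow for continental 30-arc-second rasters.
- The Albers transform is spherical, not ellipsoidal; errors are well
  under the 100-km cell size.
- Ensemble-level evaluation on pooled training data overstates absolute
  accuracy (see stage 5); member cross-validation scores are the honest
  numbers.
- The real-data path (WGS84 occurrences + GeoTIFF-free ASCII rasters) is
  implemented but only exercised synthetically; published reference
  values that depend on WorldClim/GBIF/GenBank inputs are not
  reproducible here and are treated as documentation, not tests.
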